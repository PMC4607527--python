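# Cross-symbiosis matrix relating symbiont gene content to bacteriocyte
# expression of host genes coding the equivalent reactions, across the
# four sap-feeding sternorrhynchan symbioses.
#
# Cell vocabulary: "+" symbiont gene present / host transcript abundant or
# enriched in bacteriocytes; "0" absent; "?" uncertain; "" (blank) no
# information.
#
# metadata.transcription_notes records cells whose assignment from the
# extracted source table is ambiguous.
columns: [ilvE, BCAT, tyrB, GOT, ilvA, TD, CGL, argABCDE, PCD, PRODH, OAT]
column_kind:
  ilvE: symbiont
  BCAT: host
  tyrB: symbiont
  GOT: host
  ilvA: symbiont
  TD: host
  CGL: host
  argABCDE: symbiont
  PCD: host
  PRODH: host
  OAT: host
rows:
  whitefly:
    display: "Whitefly (Bemisia tabaci/Portiera)"
    cells: {ilvE: "0", BCAT: "+", tyrB: "0", GOT: "+", ilvA: "+", TD: "+",
            CGL: "+", argABCDE: "0", PCD: "+", PRODH: "+", OAT: "+"}
  mealybug:
    display: "Mealybug (Planococcus citri/Tremblaya+Moranella)"
    cells: {ilvE: "0", BCAT: "+", tyrB: "0", GOT: "+", ilvA: "0", TD: "+",
            CGL: "0", argABCDE: "?", PCD: "?", PRODH: "", OAT: "+"}
  psyllid:
    display: "Psyllid (Pachypsylla venusta/Carsonella)"
    cells: {ilvE: "+", BCAT: "?", tyrB: "0", GOT: "+", ilvA: "0", TD: "+",
            CGL: "+", argABCDE: "0", PCD: "", PRODH: "", OAT: "+"}
  aphid:
    display: "Aphid (Acyrthosiphon pisum/Buchnera)"
    cells: {ilvE: "0", BCAT: "+", tyrB: "0", GOT: "+", ilvA: "0", TD: "+",
            CGL: "+", argABCDE: "+", PCD: "", PRODH: "", OAT: "+"}
metadata:
  transcription_notes: >
    The mealybug row of the source prints ten symbols for eleven columns
    (exactly one blank cell); the transcription here assigns "?" to
    argABCDE and PCD and the blank to PRODH.  The aphid row prints nine
    symbols; PCD and PRODH are taken as the blanks.  Only the whitefly row
    is pinned cell-for-cell by the source text.
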