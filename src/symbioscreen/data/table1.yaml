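# The ten expressed metabolism genes of bacterial origin found in the
# Bemisia tabaci MEAM1 bacteriocyte transcriptome, with their published
# bacteriocyte / whole-body FPKM, fold changes (RNA-seq log2 ratio and
# qRT-PCR log2 relative expression vs RPL7), intron presence, inferred
# donor lineage, and detection in related whitefly transcriptomes
# (MED and AsiaII3 are members of the B. tabaci complex; Tvap is the
# outgroup Trialeurodes vaporariorum).
#
# The per-gene homology-hit fields (bitscores, identities) are SYNTHETIC:
# the published table does not print them.  They are constructed so the
# screening cascade reproduces the documented outcomes - all ten genes
# retained, with bioA and bioB clearing the cascade only through the
# functional whitelist (h < 30).
genes:
  - gene: argG
    description: Argininosuccinate synthase
    ec: "6.3.4.5"
    fpkm_bacteriocyte: 407.68
    fpkm_wholebody: 236.06
    log2_ratio_rnaseq: 0.79
    log2_ratio_qpcr: 3.44
    intron: "+"
    origin: "Gammaproteobacteria: Enterobacteriales"
    presence: {MED: true, AsiaII3: true, Tvap: false}
    hit: {bitscore_prok: 230.0, bitscore_euk: 160.0, pident: 62.0,
          lineage: "Bacteria;Proteobacteria;Gammaproteobacteria;Enterobacterales;Pantoea"}
  - gene: argH
    description: Argininosuccinate lyase
    ec: "4.3.2.1"
    fpkm_bacteriocyte: 73.05
    fpkm_wholebody: 27.36
    log2_ratio_rnaseq: 1.42
    log2_ratio_qpcr: 4.4
    intron: "+"
    origin: "Gammaproteobacteria: Enterobacteriales"
    presence: {MED: true, AsiaII3: false, Tvap: false}
    hit: {bitscore_prok: 215.0, bitscore_euk: 150.0, pident: 58.0,
          lineage: "Bacteria;Proteobacteria;Gammaproteobacteria;Enterobacterales;Pantoea"}
  - gene: dapB
    description: 4-Hydroxy-tetrahydrodipicolinate reductase
    ec: "1.17.1.8"
    fpkm_bacteriocyte: 567.70
    fpkm_wholebody: 40.64
    log2_ratio_rnaseq: 3.80
    log2_ratio_qpcr: 4.78
    intron: "-"
    origin: "Alphaproteobacteria: Rickettsiales"
    presence: {MED: true, AsiaII3: true, Tvap: false}
    hit: {bitscore_prok: 190.0, bitscore_euk: 110.0, pident: 55.0,
          lineage: "Bacteria;Proteobacteria;Alphaproteobacteria;Rickettsiales;Rickettsia"}
  - gene: dapF
    description: Diaminopimelate epimerase
    ec: "5.1.1.7"
    fpkm_bacteriocyte: 13.67
    fpkm_wholebody: 7.13
    log2_ratio_rnaseq: 0.94
    log2_ratio_qpcr: 5.75
    intron: "+"
    origin: "Gammaproteobacteria: Enterobacteriales"
    presence: {MED: true, AsiaII3: true, Tvap: false}
    hit: {bitscore_prok: 205.0, bitscore_euk: 130.0, pident: 60.0,
          lineage: "Bacteria;Proteobacteria;Gammaproteobacteria;Enterobacterales;Pantoea"}
  - gene: lysA
    description: Diaminopimelate decarboxylase
    ec: "4.1.1.20"
    fpkm_bacteriocyte: 311.44
    fpkm_wholebody: 22.28
    log2_ratio_rnaseq: 3.81
    log2_ratio_qpcr: 5.31
    intron: "-"
    origin: Planctomycetes
    presence: {MED: true, AsiaII3: true, Tvap: false}
    hit: {bitscore_prok: 240.0, bitscore_euk: 155.0, pident: 57.0,
          lineage: "Bacteria;Planctomycetes;Planctomycetia;Isosphaerales;Isosphaera"}
  - gene: CM
    description: Chorismate mutase
    ec: "5.4.99.5"
    fpkm_bacteriocyte: 242.25
    fpkm_wholebody: 123.56
    log2_ratio_rnaseq: 0.97
    log2_ratio_qpcr: 2.74
    intron: "+"
    origin: "Gammaproteobacteria: Enterobacteriales"
    presence: {MED: true, AsiaII3: true, Tvap: true}
    hit: {bitscore_prok: 175.0, bitscore_euk: 105.0, pident: 52.0,
          lineage: "Bacteria;Proteobacteria;Gammaproteobacteria;Enterobacterales;Pantoea"}
  - gene: bioA
    description: Adenosylmethionine-8-amino-7-oxononanoate aminotransferase
    ec: "2.6.1.62"
    fpkm_bacteriocyte: 8.85
    fpkm_wholebody: 5.36
    log2_ratio_rnaseq: 0.72
    log2_ratio_qpcr: 1.72
    intron: "-"
    origin: "Alphaproteobacteria or Bacteroidetes or Betaproteobacteria"
    presence: {MED: true, AsiaII3: true, Tvap: true}
    hit: {bitscore_prok: 140.0, bitscore_euk: 120.0, pident: 48.0,
          lineage: "Bacteria;Proteobacteria;Alphaproteobacteria;Rickettsiales;Rickettsia"}
  - gene: bioB
    description: Biotin synthase
    ec: "2.8.1.6"
    fpkm_bacteriocyte: 4.61
    fpkm_wholebody: 4.26
    log2_ratio_rnaseq: 0.12
    log2_ratio_qpcr: 0.27
    intron: "+"
    origin: "Alphaproteobacteria: Rickettsiales"
    presence: {MED: true, AsiaII3: true, Tvap: true}
    hit: {bitscore_prok: 150.0, bitscore_euk: 125.0, pident: 50.0,
          lineage: "Bacteria;Proteobacteria;Alphaproteobacteria;Rickettsiales;Rickettsia"}
  - gene: AH
    description: Allophanate hydrolase
    ec: "3.5.1.54"
    fpkm_bacteriocyte: 14.96
    fpkm_wholebody: 2.05
    log2_ratio_rnaseq: 2.87
    log2_ratio_qpcr: 5.05
    intron: "-"
    origin: Bacteroidetes
    presence: {MED: false, AsiaII3: false, Tvap: false}
    hit: {bitscore_prok: 185.0, bitscore_euk: 115.0, pident: 54.0,
          lineage: "Bacteria;Bacteroidetes;Chitinophagia;Chitinophagales;Niastella"}
  - gene: "DUR1,2"
    description: Urea carboxylase/allophanate hydrolase
    ec: "6.3.4.6 3.5.1.54"
    fpkm_bacteriocyte: 4.23
    fpkm_wholebody: 2.44
    log2_ratio_rnaseq: 0.80
    log2_ratio_qpcr: 3.46
    intron: "-"
    origin: "Gammaproteobacteria: Enterobacteriales"
    presence: {MED: false, AsiaII3: false, Tvap: false}
    hit: {bitscore_prok: 260.0, bitscore_euk: 175.0, pident: 61.0,
          lineage: "Bacteria;Proteobacteria;Gammaproteobacteria;Enterobacterales;Pantoea"}
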