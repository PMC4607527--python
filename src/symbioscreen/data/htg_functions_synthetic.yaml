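# SYNTHETIC, partial stand-in for the four-symbiosis comparison of HTG
# functional repertoires.  Only memberships supported by the source text
# are encoded: the whitefly carries ten HTG functions, of which argH and
# CM have functional equivalents among psyllid HTGs and DUR1,2, lysA,
# dapF, bioA and bioB among mealybug HTGs (7/10 = 70% shared); no function
# is present in all four symbioses.  The full psyllid, mealybug and aphid
# HTG complements are NOT transcribed here, so symbiosis-wide uniqueness
# fractions computed from this fixture describe the fixture, not the
# published four-way comparison.
function_sets:
  whitefly: [argG, argH, dapB, dapF, lysA, CM, bioA, bioB, AH, "DUR1,2"]
  psyllid: [argH, CM]
  mealybug: ["DUR1,2", lysA, dapF, bioA, bioB]
  aphid: []
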