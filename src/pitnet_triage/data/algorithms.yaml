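# Tier-2 stain orders for the tiered algorithms, by the single positive
# transcription factor found in tier 1.
#
# Tier 1 always stains SF1, TPIT and PIT1.  When zero or more than one
# transcription factor is positive, every algorithm reflexes to the complete
# six-hormone panel; those branches are fixed and not configurable here.
# This file covers only the single-positive branches, which is where the
# algorithms differ:
#   1 - confirmatory in-lineage hormones for SF1/TPIT, full panel for PIT1
#   2 - no hormones for SF1/TPIT, full panel for PIT1
#   3 - no hormones for SF1/TPIT, PIT1-lineage hormones only for PIT1
algorithm_1:
  SF1: [LH, FSH]
  TPIT: [ACTH]
  PIT1: [PRL, TSH, GH, ACTH, LH, FSH]
algorithm_2:
  SF1: []
  TPIT: []
  PIT1: [PRL, TSH, GH, ACTH, LH, FSH]
algorithm_3:
  SF1: []
  TPIT: []
  PIT1: [GH, PRL, TSH]
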