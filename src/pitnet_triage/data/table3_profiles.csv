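id,clinical,PIT1,SF1,TPIT,PRL,TSH,GH,ACTH,LH,FSH,monomorphous,immature,acidophil_stem_cell_features,reference_type
T3-01,non_functioning,-,-,-,-,-,-,-,-,-,,,,null_cell
T3-02,non_functioning,-,+,+,-,-,-,-,-,-,,,,plurihormonal_no_distinct_lineage
T3-03,non_functioning,-,-,-,+,+,+,-,-,-,,,,plurihormonal_no_distinct_lineage
T3-04,non_functioning,+,+,-,-,-,-,-,-,+,,,,plurihormonal_no_distinct_lineage
T3-05,non_functioning,+,+,-,+,-,-,-,-,-,,,,plurihormonal_no_distinct_lineage
T3-06,non_functioning,-,+,+,-,-,-,-,-,+,,,,plurihormonal_no_distinct_lineage
T3-07,acromegaly,+,+,-,+,+,+,-,-,-,,,,plurihormonal_no_distinct_lineage
T3-08,acromegaly,+,+,-,+,+,+,-,-,-,,,,plurihormonal_no_distinct_lineage
T3-09,acromegaly,+,+,+,-,-,+,-,-,+,,,,plurihormonal_no_distinct_lineage
T3-10,acromegaly,+,+,-,-,+,+,-,-,-,,,,plurihormonal_no_distinct_lineage
T3-11,acromegaly,+,+,-,+,+,+,-,-,-,,,,plurihormonal_no_distinct_lineage
T3-12,prolactinoma,+,+,-,+,-,-,-,-,-,,,,plurihormonal_no_distinct_lineage
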