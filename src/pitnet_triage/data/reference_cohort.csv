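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
SOM-01,acromegaly,+,-,-,-,-,+,-,-,-,,,,somatotroph
SOM-02,acromegaly,+,-,-,-,-,+,-,-,-,,,,somatotroph
SOM-03,acromegaly,+,-,-,-,-,+,-,-,-,,,,somatotroph
SOM-04,acromegaly,+,-,-,-,-,+,-,-,-,,,,somatotroph
SOM-05,acromegaly,+,-,-,-,-,+,-,-,-,,,,somatotroph
SOM-06,acromegaly,+,-,-,-,-,+,-,-,-,,,,somatotroph
SOM-07,acromegaly,+,-,-,-,-,+,-,-,-,,,,somatotroph
SOM-08,acromegaly,+,-,-,-,-,+,-,-,-,,,,somatotroph
SOM-09,acromegaly,+,-,-,-,-,+,-,-,-,,,,somatotroph
SOM-10,acromegaly,+,-,-,-,-,+,-,-,-,,,,somatotroph
SOM-11,non_functioning,+,-,-,-,-,+,-,-,-,,,,somatotroph
LAC-01,prolactinoma,+,-,-,+,-,-,-,-,-,,,,lactotroph
LAC-02,prolactinoma,+,-,-,+,-,-,-,-,-,,,,lactotroph
LAC-03,prolactinoma,+,-,-,+,-,-,-,-,-,,,,lactotroph
LAC-04,prolactinoma,+,-,-,+,-,-,-,-,-,,,,lactotroph
LAC-05,prolactinoma,+,-,-,+,-,-,-,-,-,,,,lactotroph
LAC-06,prolactinoma,+,-,-,+,-,-,-,-,-,,,,lactotroph
LAC-07,prolactinoma,+,-,-,+,-,-,-,-,-,,,,lactotroph
LAC-08,prolactinoma,+,-,-,+,-,-,-,-,-,,,,lactotroph
LAC-09,prolactinoma,+,-,-,+,-,-,-,-,-,,,,lactotroph
LAC-10,prolactinoma,+,-,-,+,-,-,-,-,-,,,,lactotroph
LAC-11,prolactinoma,+,-,-,+,-,-,-,-,-,,,,lactotroph
LAC-12,prolactinoma,+,-,-,+,-,-,-,-,-,,,,lactotroph
LAC-13,prolactinoma,+,-,-,+,-,-,-,-,-,,,,lactotroph
LAC-14,prolactinoma,+,-,-,+,-,-,-,-,-,,,,lactotroph
LAC-15,prolactinoma,+,-,-,+,-,-,-,-,-,,,,lactotroph
LAC-16,prolactinoma,+,-,-,+,-,-,-,-,-,,,,lactotroph
LAC-17,prolactinoma,+,-,-,+,-,-,-,-,-,,,,lactotroph
LAC-18,prolactinoma,+,-,-,+,-,-,-,-,-,,,,lactotroph
LAC-19,prolactinoma,+,-,-,+,-,-,-,-,-,,,,lactotroph
LAC-20,prolactinoma,+,-,-,+,-,-,-,-,-,,,,lactotroph
LAC-21,non_functioning,+,-,-,+,-,-,-,-,-,,,,lactotroph
MSM-01,acromegaly,+,-,-,+,-,+,-,-,-,true,,,mammosomatotroph
MSM-02,acromegaly,+,-,-,+,-,+,-,-,-,true,,,mammosomatotroph
MSM-03,acromegaly,+,-,-,+,-,+,-,-,-,true,,,mammosomatotroph
THY-01,other,+,-,-,-,+,-,-,-,-,,,,thyrotroph
THY-02,non_functioning,+,-,-,-,+,-,-,-,-,,,,thyrotroph
MPH-01,acromegaly,+,-,-,+,+,+,-,-,-,,,,mature_plurihormonal_PIT1
IMM-01,other,+,-,-,-,-,-,-,-,-,,true,,immature_PIT1
IMM-02,non_functioning,+,-,-,-,-,-,-,-,-,,true,,immature_PIT1
MIX-01,acromegaly,+,-,-,+,-,+,-,-,-,false,,,mixed_somatotroph_lactotroph
MIX-02,non_functioning,+,-,-,+,-,+,-,-,-,false,,,mixed_somatotroph_lactotroph
COR-01,cushing,-,-,+,-,-,-,+,-,-,,,,corticotroph
COR-02,cushing,-,-,+,-,-,-,+,-,-,,,,corticotroph
COR-03,cushing,-,-,+,-,-,-,+,-,-,,,,corticotroph
COR-04,cushing,-,-,+,-,-,-,+,-,-,,,,corticotroph
COR-05,cushing,-,-,+,-,-,-,+,-,-,,,,corticotroph
COR-06,cushing,-,-,+,-,-,-,+,-,-,,,,corticotroph
COR-07,cushing,-,-,+,-,-,-,+,-,-,,,,corticotroph
COR-08,cushing,-,-,+,-,-,-,+,-,-,,,,corticotroph
COR-09,cushing,-,-,+,-,-,-,+,-,-,,,,corticotroph
COR-10,cushing,-,-,+,-,-,-,+,-,-,,,,corticotroph
COR-11,non_functioning,-,-,+,-,-,-,+,-,-,,,,corticotroph
COR-12,non_functioning,-,-,+,-,-,-,+,-,-,,,,corticotroph
COR-13,non_functioning,-,-,+,-,-,-,+,-,-,,,,corticotroph
COR-14,non_functioning,-,-,+,-,-,-,+,-,-,,,,corticotroph
GON-01,non_functioning,-,+,-,-,-,-,-,+,+,,,,gonadotroph
GON-02,non_functioning,-,+,-,-,-,-,-,+,+,,,,gonadotroph
GON-03,non_functioning,-,+,-,-,-,-,-,+,+,,,,gonadotroph
GON-04,non_functioning,-,+,-,-,-,-,-,+,+,,,,gonadotroph
GON-05,non_functioning,-,+,-,-,-,-,-,+,+,,,,gonadotroph
GON-06,non_functioning,-,+,-,-,-,-,-,+,+,,,,gonadotroph
GON-07,non_functioning,-,+,-,-,-,-,-,+,+,,,,gonadotroph
GON-08,non_functioning,-,+,-,-,-,-,-,+,+,,,,gonadotroph
GON-09,non_functioning,-,+,-,-,-,-,-,+,+,,,,gonadotroph
GON-10,non_functioning,-,+,-,-,-,-,-,+,+,,,,gonadotroph
GON-11,non_functioning,-,+,-,-,-,-,-,+,+,,,,gonadotroph
GON-12,non_functioning,-,+,-,-,-,-,-,+,+,,,,gonadotroph
GON-13,non_functioning,-,+,-,-,-,-,-,+,+,,,,gonadotroph
GON-14,non_functioning,-,+,-,-,-,-,-,+,+,,,,gonadotroph
GON-15,non_functioning,-,+,-,-,-,-,-,+,+,,,,gonadotroph
GON-16,non_functioning,-,+,-,-,-,-,-,+,+,,,,gonadotroph
GON-17,non_functioning,-,+,-,-,-,-,-,+,+,,,,gonadotroph
GON-18,non_functioning,-,+,-,-,-,-,-,+,+,,,,gonadotroph
GON-19,non_functioning,-,+,-,-,-,-,-,+,+,,,,gonadotroph
GON-20,non_functioning,-,+,-,-,-,-,-,+,+,,,,gonadotroph
GON-21,non_functioning,-,+,-,-,-,-,-,+,+,,,,gonadotroph
GON-22,non_functioning,-,+,-,-,-,-,-,+,+,,,,gonadotroph
GON-23,non_functioning,-,+,-,-,-,-,-,+,+,,,,gonadotroph
GON-24,non_functioning,-,+,-,-,-,-,-,+,+,,,,gonadotroph
GON-25,non_functioning,-,+,-,-,-,-,-,+,+,,,,gonadotroph
GON-26,non_functioning,-,+,-,-,-,-,-,+,+,,,,gonadotroph
GON-27,non_functioning,-,+,-,-,-,-,-,+,+,,,,gonadotroph
GON-28,non_functioning,-,+,-,-,-,-,-,+,+,,,,gonadotroph
GON-29,non_functioning,-,+,-,-,-,-,-,+,+,,,,gonadotroph
GON-30,non_functioning,-,+,-,-,-,-,-,+,+,,,,gonadotroph
GON-31,non_functioning,-,+,-,-,-,-,-,+,+,,,,gonadotroph
GON-32,non_functioning,-,+,-,-,-,-,-,+,+,,,,gonadotroph
GON-33,non_functioning,-,+,-,-,-,-,-,+,+,,,,gonadotroph
GON-34,non_functioning,-,+,-,-,-,-,-,+,+,,,,gonadotroph
GON-35,non_functioning,-,+,-,-,-,-,-,+,+,,,,gonadotroph
GON-36,non_functioning,-,+,-,-,-,-,-,+,+,,,,gonadotroph
GON-37,non_functioning,-,+,-,-,-,-,-,+,+,,,,gonadotroph
GON-38,non_functioning,-,+,-,-,-,-,-,+,+,,,,gonadotroph
GON-39,non_functioning,-,+,-,-,-,-,-,+,+,,,,gonadotroph
GON-40,non_functioning,-,+,-,-,-,-,-,+,+,,,,gonadotroph
GON-41,non_functioning,-,+,-,-,-,-,-,+,+,,,,gonadotroph
GON-42,non_functioning,-,+,-,-,-,-,-,+,+,,,,gonadotroph
GON-43,non_functioning,-,+,-,-,-,-,-,+,+,,,,gonadotroph
GON-44,non_functioning,-,+,-,-,-,-,-,+,+,,,,gonadotroph
GON-45,non_functioning,-,+,-,-,-,-,-,+,+,,,,gonadotroph
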