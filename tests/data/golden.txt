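# garm association rule mining report
# input: golden_table.csv
# pattern: _ AND (_ OR _) -> _
# rows: 100
# columns: 6
# min_support: 12
# min_confidence: 0.7500
# min_lift: 1.6000
# min_leverage: -0.2500
# max_value_set_size: 2
# simplify_tolerance: 0.0200
# rules: 13
# fields: rule	support	lhs_support	rhs_support	confidence	lift	leverage
x=a AND (y=b OR z=c) -> w=d	36	40	39	0.9000	2.3077	0.2040
x=a AND y=b -> w=d	21	25	39	0.8400	2.1538	0.1125
x=a AND z=c -> w=d	21	25	39	0.8400	2.1538	0.1125
x=ao AND z=c -> w=d	21	27	39	0.7778	1.9943	0.1047
x=a AND y=bo -> w=d	36	48	39	0.7500	1.9231	0.1728
y=b AND z=n -> w=d	15	20	39	0.7500	1.9231	0.0720
x=an AND x=no -> w=n	20	20	61	1.0000	1.6393	0.0780
x=n -> w=n	20	20	61	1.0000	1.6393	0.0780
y=bn AND y=no -> w=n	19	19	61	1.0000	1.6393	0.0741
y=n -> w=n	19	19	61	1.0000	1.6393	0.0741
x=no AND (y=n OR z=c) -> w=n	16	16	61	1.0000	1.6393	0.0624
x=a AND (y=n OR z=o) -> w=n	14	14	61	1.0000	1.6393	0.0546
x=an AND z=o -> w=n	12	12	61	1.0000	1.6393	0.0468
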