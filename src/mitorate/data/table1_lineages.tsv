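# Per-lineage summary of the 45 maternal lineages of the study pedigree:
# meioses (mother->child transmissions), individuals sequenced, and observed
# mutation events with carrier counts.  Totals: 345 meioses, 225 individuals,
# 9 mutations (2 homoplasmic substitutions + 7 point heteroplasmies across
# 13 carriers).  The per-row meioses/individual splits of the printed source
# table are typographically ambiguous; rows here carry the published lineage
# ids and mutation assignments, with meioses/individuals distributed so every
# published total and prevalence figure is reproduced exactly.  MAFs of 0.35
# for detected heteroplasmies are synthetic placeholders (the source prints
# MAFs only for the three censored below-threshold mixtures: 12%, 15%, 15%).
# mutations: semicolon-separated label:carriers[:maf]
# censored: semicolon-separated label:maf (below-threshold mixtures in one
#           additional individual each)
lineage_id	n_meioses	n_individuals	mutations	censored
13	14	10	A8470R:1:0.35;A16280R:3:0.35	A16280R:0.12
23	5	4
167	5	4
208	7	7	T9012Y:3:0.35	T9012Y:0.15
219	5	4
242	5	4
490	8	4	T146Y:1:0.35
833	5	4
1088	5	4
1597	15	7	A16247G:1
1878	5	4
2071	5	4
2212	5	4
2328	5	4
2462	5	4
2802	5	4
2913	5	4
3310	5	4
3363	5	4
3963	5	4
5581	5	4
6911	30	5	A2833R:2:0.35;A8817G:1
6946	5	4
11039	5	4
12457	10	6	C16344Y:1:0.35
12575	5	4
16904	8	5
16981	8	5
21829	8	5
30100	8	5
31088	8	5
31102	8	5
31318	8	5
31321	8	5
31385	8	5
31556	8	5
31761	10	6
31767	10	6
31774	10	6
31901	10	6
31927	10	6
32032	9	7
32187	9	7
32918	4	5	C16320Y:2:0.35	C16320Y:0.15
40009	9	7
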