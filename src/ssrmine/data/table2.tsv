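# Published repeat-motif type distribution from the sesame (Sesamum indicum)
# RNA-seq genic-SSR survey (42,566 uni-transcripts): locus counts and printed
# percentages by classification and unit-size subtype at the >=15 bp and
# >=18 bp tract-length thresholds.
category	subtype	n_ge15	pct_ge15	n_ge18	pct_ge18
perfect	mono	129	1.99	21	0.57
perfect	di	2592	39.97	1764	48.01
perfect	tri	1845	28.45	770	20.96
perfect	tetra	335	5.17	78	2.12
perfect	penta	652	10.05	109	2.97
perfect	hexa	932	14.37	932	25.37
imperfect	mono	82	37.27	77	38.31
imperfect	di	137	62.27	123	61.19
imperfect	tri	1	0.45	1	0.50
compound_perfect	mono-mono	35	14.29	22	9.78
compound_perfect	di-di	199	81.22	193	85.78
compound_perfect	tri-tri	4	1.63	4	1.78
compound_perfect	mono-di	4	1.63	3	1.33
compound_perfect	mono-tri	2	0.82	2	0.89
compound_perfect	di-tri	1	0.41	1	0.44
compound_imperfect	mono-mono	12	3.21	12	3.53
compound_imperfect	di-di	352	94.12	318	93.53
compound_imperfect	tri-tri	6	1.60	6	1.76
compound_imperfect	mono-di	1	0.27	1	0.29
compound_imperfect	mono-tri	1	0.27	1	0.29
compound_imperfect	di-tri	2	0.53	2	0.59
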