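# Published copy-number histogram of perfect SSRs (>=15 bp) by unit size from
# the sesame RNA-seq genic-SSR survey. Column totals: 129 / 2,592 / 1,845 /
# 335 / 652 / 932 (grand total 6,485). Filtering rows at
# copies * unit_size >= 18 reproduces the published >=18 bp column
# (21 / 1,764 / 770 / 78 / 109 / 932, total 3,674).
copies	mono	di	tri	tetra	penta	hexa
2	0	0	0	0	0	0
3	0	0	0	0	543	742
4	0	0	0	257	93	150
5	0	0	1075	59	10	32
6	0	0	452	14	1	4
7	0	0	169	3	1	3
8	0	828	81	2	2	1
9	0	549	45	0	0	0
10	0	358	13	0	1	0
11	0	254	4	0	1	0
12	0	178	2	0	0	0
13	0	103	1	0	0	0
14	0	70	0	0	0	0
15	51	50	0	0	0	0
16	40	52	1	0	0	0
17	17	28	2	0	0	0
18	11	19	0	0	0	0
19	4	7	0	0	0	0
20	2	16	0	0	0	0
21	0	10	0	0	0	0
22	1	19	0	0	0	0
23	0	23	0	0	0	0
24	2	21	0	0	0	0
25	1	5	0	0	0	0
26	0	2	0	0	0	0
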