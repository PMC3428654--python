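# Published counts of the four most abundant perfect-SSR motif families
# (sesame RNA-seq genic-SSR survey), labelled as printed; labels canonicalize
# through the rotation/reverse-complement class function.
motif_class	n_ge15	pct_ge15	n_ge18	pct_ge18
AG/CT	1733	26.72	1268	34.51
CA/TG	469	7.23	281	7.65
AT/AT	390	6.01	215	5.85
GAA/TTC	279	4.30	131	3.57
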