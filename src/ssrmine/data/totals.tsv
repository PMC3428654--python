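# Published headline totals from the sesame RNA-seq genic-SSR survey.
key	value
n_transcripts	42566
total_length_bp	47986977
n_ssr_ge15	7324
n_ssr_ge18	4440
n_perfect_ge15	6485
n_perfect_ge18	3674
n_primer_pairs_ge18	2164
n_validated_primers	300
n_amplifying_primers	276
n_polymorphic_primers	32
n_alleles	74
n_accessions_cultivated	24
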