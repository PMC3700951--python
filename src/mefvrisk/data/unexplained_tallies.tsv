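# Published genotype tallies of genetically-unexplained FMF patients
# (no two-mutation carriers by definition) from four Mediterranean
# populations, as reported by the original case series.
group_label	n_two_mut	n_het	n_none
Armenian	0	25	19
Sephardic	0	41	25
Arab	0	38	98
Turkish	0	15	24
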