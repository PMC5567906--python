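# Read-accounting category counts reported for a published citrus
# callus vs callus-derived-protoplast small-RNA sequencing experiment.
# Counts are raw reads per category; unique/mapped rows count unique
# sequences. Used to exercise the ledger arithmetic on real-scale data.
category	calli	protoplasts
total_reads	17975734	15828591
high_quality	17945812	15786575
no_3adapter	11146	10665
insert_null	700	1436
contaminant_5adapter	9082	10284
shorter_than_18	23368	98740
poly_a	2476	2416
unique_srnas	5943092	5134879
mapped_unique	2303525	2017839
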