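# Normalized expression (TPM) pairs and p-values reported for the
# differentially expressed known miRNAs of a published citrus callus vs
# protoplast small-RNA experiment; used to replay fold-change and
# call-status computation on published values.
mirna	tpm_calli	tpm_protoplasts	p_value
crt-miR396a	73.91	148.57	1.71E-95
crt-miR396b	74.42	154.95	8.66E-108
crt-miR171.3	20.00	49.48	2.91E-49
crt-miR408	22.29	57.46	7.64E-61
crt-miR482a	18.83	55.29	8.49E-71
crt-miR172a	10.67	31.48	2.71E-41
crt-miR171a	0.56	1.66	0.002
crt-miR171.2	0.56	1.66	0.002
crt-miR167c	45.70	199.83	0
crt-miR827	11.90	53.57	1.01E-107
crt-miR472	28.66	132.61	6.55E-270
crt-miR482b	5.14	43.41	1.03E-129
crt-miR166e*	20.34	3.70	5.20E-47
crt-miR319.2	2.12	0.57	0.0001
crt-miR172a*	2.57	0.70	2.05E-05
crt-miR482a*	88.33	28.16	4.09E-119
crt-miR535	171.63	65.19	2.48E-180
crt-miR319.1	3.97	1.72	0.0001
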