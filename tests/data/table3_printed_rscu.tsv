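# Published per-codon RSCU values (2 dp) for the four albumin-superfamily
# genes, as printed alongside the counts carried by the packaged fixtures.
codon	ALB	AFP	AFM	VDBP
TTT	1.43	1.06	1.30	1.16
TTC	0.57	0.94	0.70	0.84
TTA	0.94	1.00	1.20	0.53
TTG	1.13	1.10	0.87	0.63
CTT	1.78	0.90	1.20	1.16
CTC	0.66	0.40	0.98	0.95
CTA	0.38	0.90	0.65	1.05
CTG	1.13	1.70	1.09	1.68
ATT	1.33	1.32	1.07	1.13
ATC	1.33	0.71	0.75	1.13
ATA	0.33	0.97	1.18	0.75
GTT	1.12	1.47	1.44	0.89
GTC	0.65	0.80	0.67	1.19
GTA	0.74	0.80	0.67	1.04
GTG	1.49	0.93	1.22	0.89
TCT	0.64	1.26	2.06	1.43
TCC	1.50	0.47	0.86	1.29
TCA	1.29	1.58	1.03	1.71
TCG	0.64	0.47	0.00	0.00
CCT	1.67	1.71	1.71	1.38
CCC	1.00	0.76	0.71	0.92
CCA	1.17	1.52	1.57	1.54
CCG	0.17	0.00	0.00	0.15
ACT	0.97	1.78	1.18	1.25
ACC	1.24	0.67	0.82	1.38
ACA	1.52	1.33	1.53	1.13
ACG	0.28	0.22	0.47	0.25
GCT	1.90	1.20	1.57	1.82
GCC	0.89	0.88	0.71	1.09
GCA	1.08	1.68	1.29	0.85
GCG	0.13	0.24	0.43	0.24
TAT	1.37	1.06	1.06	1.13
TAC	0.63	0.94	0.94	0.88
CAT	1.38	1.63	1.23	1.00
CAC	0.63	0.38	0.77	1.00
CAA	1.10	1.15	1.26	1.33
CAG	0.90	0.85	0.74	0.67
AAT	1.29	1.00	1.03	1.33
AAC	0.71	1.00	0.97	0.67
AAA	1.33	1.29	1.33	0.93
AAG	0.67	0.71	0.67	1.07
GAT	1.39	1.27	1.30	1.23
GAC	0.61	0.73	0.70	0.77
GAA	1.23	1.24	1.36	1.26
GAG	0.77	0.76	0.64	0.74
TGT	0.86	1.06	0.81	1.00
TGC	1.14	0.94	1.19	1.00
CGT	0.67	0.50	0.55	0.00
CGC	0.22	0.25	0.27	0.00
CGA	0.67	0.50	0.55	0.92
CGG	0.44	0.25	0.00	0.46
AGT	1.29	1.54	0.79	0.86
AGC	0.64	0.51	1.42	0.71
AGA	2.89	2.75	3.27	2.31
AGG	1.11	1.75	1.36	2.31
GGT	0.92	0.75	0.62	0.29
GGC	0.92	0.75	0.77	1.43
GGA	1.85	1.50	2.00	1.43
GGG	0.31	1.50	0.62	0.86
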