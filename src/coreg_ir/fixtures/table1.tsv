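gene_id	rela_2h	rela_4h	p53_2h	p53_4h	fc_4gy	sig_4gy	fc_10gy	sig_10gy	sirela_4gy	sirela_10gy	sitp53_4gy	sitp53_10gy	table_block
BBC3	1	1	1	1	2.14	1	2.99	1	0.86	0.87	0.45	0.42	p53
BTG2	0	0	1	0	3.28	1	3.92	1	0.69	0.68	0.40	0.42	p53
CDKN1A	1	1	1	1	2.69	1	3.68	1	1.16	1.16	0.44	0.46	p53
CNN1	0	0	1	0	1.21	0	1.61	1	1.60	1.72	1.49	1.54	p53
DDB2	0	0	0	1	1.34	1	1.53	1	0.94	0.94	0.43	0.48	p53
EDA2R	0	0	0	1	2.06	1	2.24	1	1.10	1.06	0.49	0.49	p53
FHL2	1	1	1	0	2.40	1	2.92	1	1.02	1.06	0.61	0.63	p53
GRHL3	0	0	1	0	1.90	1	2.23	1	1.04	0.87	0.52	0.37	p53
PHLDA3	0	0	0	1	1.72	1	2.06	1	0.91	0.93	0.45	0.40	p53
PLK2	0	0	1	1	1.96	1	2.22	1	1.08	1.09	0.60	0.64	p53
SERPINE1	0	1	1	0	2.15	1	2.79	1	0.98	0.99	0.56	0.56	p53
SLC30A1	0	0	1	1	1.81	1	1.77	1	1.12	1.09	0.73	0.66	p53
TRIM22	0	0	1	1	1.56	0	1.80	1	0.87	0.87	0.42	0.44	p53
ZMAT3	0	0	0	1	1.81	1	1.84	1	1.05	1.08	0.48	0.50	p53
BIRC3	1	1	0	0	7.04	1	17.23	1	0.52	0.47	1.41	1.27	nfkb
CD83	0	1	0	0	2.23	1	4.03	1	0.71	0.62	0.94	0.95	nfkb
CXCL8	1	1	0	0	3.89	1	11.53	1	0.42	0.37	1.87	1.95	nfkb
CYP4F11	1	0	0	0	1.52	1	1.64	1	0.63	0.68	0.56	0.74	nfkb
IL32	1	1	0	0	1.35	0	2.72	1	0.48	0.43	1.08	1.06	nfkb
NFKB1	1	1	0	0	2.10	1	3.31	1	0.72	0.66	1.08	1.13	nfkb
NFKB2	1	1	0	0	1.44	0	2.21	1	0.64	0.63	1.13	1.11	nfkb
NFKBIA	1	1	1	0	1.86	1	3.26	1	0.65	0.63	1.25	1.28	nfkb
NFKBIE	1	1	0	0	1.65	0	2.72	1	0.59	0.59	1.12	1.08	nfkb
RELB	1	1	0	0	2.60	1	4.44	1	0.66	0.65	1.06	0.99	nfkb
TNFAIP3	0	1	0	0	3.07	1	6.01	1	0.70	0.66	1.03	1.02	nfkb
TRAF1	0	1	0	0	2.42	1	7.14	1	0.47	0.39	2.97	2.06	nfkb
IL4I1	1	1	1	1	1.83	1	3.32	1	0.48	0.39	1.58	1.23	both
RRAD	1	0	0	1	1.66	1	3.56	1	0.68	0.65	0.68	0.49	both
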