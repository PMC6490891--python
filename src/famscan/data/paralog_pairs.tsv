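gene_a	gene_b	s_sites	n_sites	ka	ks	omega	selection	t_mya
CbABCG11	CbABCG40	127.23	406.77	0.23	0.21	1.06	positive	15.36
CaABCG2	CcABCG40	142.31	490.69	0.23	0.25	0.89	purifying	18.13
CaABCF8	CaABCF2	91.15	310.85	0.07	0.05	1.57	positive	3.25
CcABCC5	CcABCC22	88.18	256.82	0.11	0.15	0.72	purifying	11.12
CbABCB36	CaABCB9	260.28	843.72	0.00	0.02	0.06	purifying	1.40
CaABCB31	CcABCB3	326.66	996.34	0.07	0.08	0.82	purifying	6.00
CaABCG3	CaABCG34	49.75	166.25	0.10	0.09	1.13	positive	6.11
CaABCG30	CaABCG80	108.39	371.61	0.52	0.54	0.95	purifying	39.06
CbABCG89	CcABCG69	497.18	1704.82	0.02	0.08	0.31	purifying	5.47
CaABCG23	CaABCG33	401.44	1314.56	0.01	0.01	0.47	purifying	0.99
CbABCG7	CcABCG38	84.41	281.59	0.17	0.20	0.84	purifying	14.57
CbABCG72	CbABCG73	52.13	184.87	0.82	1.00	0.82	purifying	72.07
CbABCG29	CbABCG30	95.05	327.95	0.96	1.16	0.83	purifying	83.55
CbABCG58	CaABCG38	148.66	514.34	1.01	1.15	0.88	purifying	82.39
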