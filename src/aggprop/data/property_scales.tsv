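residue	hydrophobicity	hydrophilicity	mutability	volume	polarizability	steric	free_energy	asa_tripeptide
A	1.8	-0.5	100	52.6	0.046	0.52	-0.368	115
C	2.5	-1.0	20	68.3	0.128	0.62	4.53	135
D	-3.5	3.0	106	68.4	0.105	0.76	2.06	150
E	-3.5	3.0	102	84.7	0.151	0.68	1.77	190
F	2.8	-2.5	41	113.9	0.290	0.70	1.06	210
G	-0.4	0.0	49	36.3	0.000	0.00	-0.525	75
H	-3.2	-0.5	66	91.9	0.230	0.70	0.0	195
I	4.5	-1.8	96	102.0	0.186	1.02	0.791	175
K	-3.9	3.0	56	105.1	0.219	0.68	0.0	200
L	3.8	-1.8	40	102.0	0.186	0.98	1.07	170
M	1.9	-1.3	94	97.7	0.221	0.78	0.656	185
N	-3.5	0.2	134	75.7	0.134	0.76	0.0	160
P	-1.6	0.0	56	73.6	0.131	0.36	-2.24	145
Q	-3.5	0.2	93	89.7	0.180	0.68	0.731	180
R	-4.5	3.0	65	109.1	0.291	0.68	-1.03	225
S	-0.8	0.3	120	54.9	0.062	0.53	-0.524	115
T	-0.7	-0.4	97	71.2	0.108	0.50	0.0	140
V	4.2	-1.5	74	85.1	0.140	0.76	0.401	155
W	-0.9	-3.4	18	135.4	0.409	0.70	1.60	255
Y	-1.3	-2.3	41	116.2	0.298	0.70	4.91	230
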