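target	stoichiometry	taxonomy	technique	dockq95	ics95	category	capri	phase0	phase2
H1202	A2B2	Human	X-ray	0.86	0.84	Heteromer	Yes	No	Yes
H1204	A2B2C2	Nanobody-human	X-ray	0.2	0.11	Heteromer (NA)	Yes	No	Yes
H1208	A1B1	Bacteria	X-ray	0.85	0.87	Heteromer	Yes	Yes	Yes
H1213	A1B1C1D1E1	Virus	EM	0.79	0.79	Heteromer	Yes	No	Yes
H1215	A1B1	Nanobody-eukaryota	X-ray	0.88	0.88	Heteromer (NA)	Yes	Yes	Yes
H1217	A2B2C2D2E2F2	Virus	EM	0.73	0.73	Heteromer	Yes	Yes	Yes
H1220	A1B4	Virus	EM	0.76	0.75	Heteromer	Yes	Yes	Yes
H1222	A1B1C1	Antibody-virus	X-ray	0.58	0.58	Heteromer (AA)	Yes	Yes	Yes
H1223	A1B1C1	Antibody-virus	X-ray	0.25	0.28	Heteromer (AA)	Yes	Yes	Yes
H1225	A1B1C1	Antibody-virus	X-ray	0.16	0.11	Heteromer (AA)	Yes	Yes	Yes
H1227	A1B6	Bacteria	EM	0.67	0.7	Heteromer	Yes	Yes	Yes
H1229	A1B1	Virus-human	EM	0.54	0.61	Heteromer	Yes	Yes	Yes
H1230	A1B1	Virus-human	EM	0.66	0.77	Heteromer	Yes	Yes	Yes
H1232	A2B2	Antibody-virus	X-ray	0.12	0.15	Heteromer (AA)	Yes	Yes	Yes
H1233	A2B2C2	Antibody-virus	X-ray	0.91	0.89	Heteromer (AA)	Yes	Yes	Yes
H1236	A3B6	Virus	EM	0.33	0.48	Heteromer	Yes	Yes	Yes
H1244	A2B2C2	Nanobody-eukaryota	X-ray	0.03	0.02	Heteromer (NA)	Yes	Yes	Yes
H1245	A1B1	Eukaryota	X-ray	0.81	0.84	Heteromer	Yes	Yes	Yes
H1258	A1B2	Human	EM	0.4	0.64	Heteromer	No	Yes	Yes
H1265	A9B18	Human	EM	0.33	0.38	Heteromer	No	Yes	Yes
H1267	A2B2	Bacteria	X-ray	0.43	0.65	Heteromer	Yes	Yes	Yes
H1272	A1B1C1D1E1F1G1H1I1	Eukaryota	EM	0.58	0.73	Heteromer	No	Yes	Yes
T1201o	A2	Human	X-ray	0.79	0.84	Homomer	Yes	No	Yes
T1206o	A2	Virus	X-ray	0.95	0.95	Homomer	Yes	Yes	Yes
T1218o	A2	Bacteria	X-ray	0.44	0.5	Homomer	Yes	Yes	Yes
T1219o	An	Human	EM	0.82	0.78	Homomer	No	No	No
T1234o	A3	Virus	EM	0.32	0.4	Homomer	Yes	Yes	Yes
T1235o	A6	Virus	EM	0.78	0.74	Homomer	Yes	Yes	Yes
T1237o	A4	Bacteria	X-ray	0.78	0.78	Homomer	Yes	Yes	Yes
T1240o	A3	Bacteria	X-ray	0.43	0.87	Homomer	Yes	Yes	Yes
T1249v1o	A3	Virus	EM	0.49	0.44	Homomer	Yes	No	Yes
T1249v2o	A3	Virus	EM	0.26	0.23	Homomer	Yes	No	Yes
T1257o	A3	Virus	EM	0.79	0.89	Homomer	No	Yes	Yes
T1259o	A3	Bacteria	X-ray	0.89	0.9	Homomer	Yes	Yes	Yes
T1269o	A4	Human	EM	0.47	0.67	Homomer	No	No	No
T1270o	A6	Bacteria	EM	0.6	0.7	Homomer	Yes	Yes	Yes
T1292o	A2	Bacteria	X-ray	0.95	0.92	Homomer	No	No	No
T1294o	A2	Eukaryota	X-ray	0.9	0.86	Homomer	No	No	No
T1295o	A8	Bacteria	EM	0.78	0.68	Homomer	No	No	No
T1298o	A2	Bacteria	X-ray	0.7	0.88	Homomer	Yes	No	No
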