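target	stoichiometry	taxonomy	technique	ics95	capri	phase0	phase2
M1209	A1B1R1	Human-virus	X-ray	0.947	No	No	No
M1211	A2R1	Virus	X-ray	0.073	No	No	No
M1212	A1R1V1W1	Virus	EM	0.658	No	No	No
M1216	A4B4C4D4	Bacteria	EM	0.621	No	No	No
M1221	A1R1S1	Bacteria	EM	0.442	No	No	No
M1224	A1R1S1	Bacteria	EM	0.491	No	No	No
M1228v1	A4B2C2D2E2	Bacteria	EM	0.557	Yes	No	No
M1228v2	A4B2C2D2E2	Bacteria	EM	0.572	Yes	No	No
M1239v1	A4B2C2D2E2	Bacteria	EM	0.621	Yes	No	No
M1239v2	A4B2C2D2E2	Bacteria	EM	0.595	Yes	No	No
M1268	A8B8C8D8E1F1	Bacteria	EM	0.551	No	Yes	No
M1271	A1B1C1D1E1F2G2H1I1J5R1	Eukaryota	EM	0.239	No	No	No
M1276	A1B1	Eukaryota	X-ray	0.65	Yes	Yes	No
M1282	A1B1	Virus-synthetic	EM	0.048	Yes	No	No
M1287	A2D2	Bacteria	EM	0.488	Yes	Yes	No
M1293	A1B1R1	Virus	X-ray	0.923	No	No	No
M1296	A1B1C1	Human-virus	X-ray	0.894	No	No	No
M1297	A4B4C4D4E2R2	Human	EM	0.69	No	No	No
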