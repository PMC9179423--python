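gene	patient	ratio	p_value	printed_direction	printed_arrows
CCNA1	1	0.890	0.4366	none	0
CCNA1	2	2.343	0.0046	up	2
CCNA1	3	0.380	0.0088	down	2
CCND1	1	1.423	0.1843	none	0
CCND1	2	3.433	0.0031	up	2
CCND1	3	5.627	0.0001	up	3
CCND2	1	1.093	0.7726	none	0
CCND2	2	1.060	0.9889	none	0
CCND2	3	5.253	0.0003	up	3
CCND3	1	0.320	0.0260	down	2
CCND3	2	1.043	0.7505	none	0
CCND3	3	9.560	0.0001	up	4
CCNE1	1	1.050	0.9274	none	0
CCNE1	2	3.413	0.0036	up	2
CCNE1	3	0.800	0.0602	none	0
CDK2	1	3.480	0.0116	up	2
CDK2	2	4.187	0.0002	up	3
CDK2	3	2.527	0.0014	up	2
CDK4	1	2.360	0.0017	up	2
CDK4	2	3.170	0.0015	up	2
CDK4	3	2.380	0.0056	up	2
CDK6	1	2.330	0.0048	up	2
CDK6	2	3.870	0.0019	up	2
CDK6	3	6.717	0.0001	up	3
CDKN1A	1	1.060	0.6550	none	0
CDKN1A	2	1.250	0.2477	none	0
CDKN1A	3	1.333	0.1679	none	0
CDKN1B	1	1.707	0.0163	up	1
CDKN1B	2	1.177	0.3277	none	0
CDKN1B	3	5.533	0.0001	up	3
EGF	1	1.160	0.6528	none	0
EGF	2	4.600	0.0013	up	3
EGF	3	9.340	0.0002	up	4
EGFR	1	0.390	0.0216	down	2
EGFR	2	1.563	0.0047	up	1
EGFR	3	3.617	0.0001	up	2
FGFR1	1	2.690	0.0002	up	2
FGFR1	2	0.713	0.0767	none	0
FGFR1	3	3.490	0.0017	up	2
HRAS	1	0.280	0.0144	down	2
HRAS	2	1.157	0.3894	none	0
HRAS	3	1.560	0.0151	up	1
KRAS	1	0.373	0.0097	down	2
KRAS	2	1.230	0.3994	none	0
KRAS	3	8.313	0.0002	up	4
PIK3CA	1	0.297	0.0576	none	0
PIK3CA	2	1.557	0.0178	up	1
PIK3CA	3	9.830	0.0006	up	4
PIK3R3	1	5.847	0.0008	up	3
PIK3R3	2	1.130	0.1943	none	0
PIK3R3	3	10.26	0.0005	up	4
TGFB1	1	1.617	0.0728	none	0
TGFB1	2	1.917	0.0000	up	1
TGFB1	3	0.143	0.0060	down	3
TGFB3	1	0.807	0.2360	none	0
TGFB3	2	1.203	0.8063	none	0
TGFB3	3	2.830	0.0165	up	2
TGFBR2	1	0.913	0.2790	none	0
TGFBR2	2	0.567	0.0114	down	1
TGFBR2	3	5.737	0.0008	up	3
BAD	1	1.670	0.0052	up	1
BAD	2	10.07	0.0000	up	4
BAD	3	0.210	0.0135	down	3
BAX	1	0.870	0.4985	none	0
BAX	2	4.483	0.0098	up	3
BAX	3	0.387	0.0049	down	2
BCL2	1	0.543	0.1271	none	0
BCL2	2	0.210	0.0184	down	3
BCL2	3	1.253	0.0331	up	1
BCL2L1	1	2.430	0.0101	up	2
BCL2L1	2	8.863	0.0000	up	4
BCL2L1	3	1.097	0.3578	none	0
BID	1	7.500	0.0002	up	3
BID	2	6.157	0.0001	up	3
BID	3	7.463	0.0002	up	3
CREB1	1	1.563	0.1042	none	0
CREB1	2	2.363	0.0008	up	2
CREB1	3	13.94	0.0000	up	4
E2F3	1	2.600	0.0071	up	2
E2F3	2	1.100	0.7703	none	0
E2F3	3	4.443	0.0012	up	3
SMAD4	1	0.507	0.0035	down	1
SMAD4	2	1.083	0.4171	none	0
SMAD4	3	0.123	0.0023	down	4
STAT1	1	1.097	0.4855	none	0
STAT1	2	1.523	0.0456	up	1
STAT1	3	2.790	0.0370	up	2
CDH1	1	0.993	0.7830	none	0
CDH1	2	1.267	0.1972	none	0
CDH1	3	6.590	0.0001	up	3
CTNNB1	1	2.403	0.0008	up	2
CTNNB1	2	0.853	0.1334	none	0
CTNNB1	3	10.96	0.0001	up	4
FN1	1	3.673	0.0039	up	2
FN1	2	0.843	0.1443	none	0
FN1	3	2.403	0.0005	up	2
PDGFC	1	0.600	0.0110	down	1
PDGFC	2	3.247	0.0016	up	2
PDGFC	3	2.813	0.0033	up	2
PDGFRB	1	3.350	0.0028	up	2
PDGFRB	2	4.733	0.0002	up	3
PDGFRB	3	3.010	0.0069	up	2
VEGFC	1	1.583	0.0249	up	1
VEGFC	2	2.990	0.0007	up	2
VEGFC	3	0.237	0.0212	down	3
MAPK3	1	0.617	0.0947	none	0
MAPK3	2	2.313	0.0006	up	2
MAPK3	3	4.903	0.0044	up	3
SHC1	1	2.607	0.0062	up	2
SHC1	2	1.250	0.0030	up	1
SHC1	3	12.06	0.0002	up	4
IRS2	1	15.74	0.0001	up	4
IRS2	2	4.457	0.0001	up	3
IRS2	3	4.300	0.0003	up	3
TSC2	1	0.840	0.2096	none	0
TSC2	2	2.453	0.0034	up	2
TSC2	3	4.810	0.0012	up	3
MMP2	1	1.210	0.4724	none	0
MMP2	2	2.573	0.0057	up	2
MMP2	3	1.217	0.0097	up	1
TLR2	1	3.913	0.0045	up	2
TLR2	2	9.013	0.0000	up	4
TLR2	3	0.927	0.6464	none	0
MDM2	1	1.300	0.6030	none	0
MDM2	2	1.427	0.1993	none	0
MDM2	3	7.947	0.0001	up	3
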