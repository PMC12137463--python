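GENE	CASE_COUNT_HET	CASE_COUNT_CH	CASE_COUNT_HOM	CONTROL_COUNT_HET	CONTROL_COUNT_CH	CONTROL_COUNT_HOM	P_DOM
ABCA13	10	2	0	26	7	0	6.40E-08
CELSR1	5	0	0	2	0	0	5.11E-07
DAB2IP	8	0	0	8	0	0	6.50E-09
DNAH1	9	0	0	20	0	0	1.05E-07
DNAH2	7	0	0	13	0	0	1.21E-06
DNAH3	9	1	0	25	4	1	6.37E-07
SYNE2	7	0	0	14	0	0	1.77E-06
ABCA7	7	1	0	8	6	0	1.14E-07
AGRN	6	0	0	5	0	0	3.05E-07
AHNAK	8	2	0	21	0	0	1.56E-06
AP5Z1	5	0	0	3	0	0	1.33E-06
ARHGAP22	4	0	0	0	0	0	8.64E-07
ARID1B	5	0	0	3	0	0	1.33E-06
BAHCC1	9	0	0	5	0	0	3.08E-11
CACNA1A	5	1	0	3	1	0	1.33E-06
CACNA1D	6	0	0	8	0	0	1.84E-06
CFAP46	6	0	0	6	0	0	5.95E-07
CILP	4	0	0	0	0	0	8.64E-07
CMYA5	4	0	0	0	0	0	8.64E-07
COL12A1	5	0	0	2	0	0	5.11E-07
COL27A1	6	0	0	5	0	0	3.05E-07
COL7A1	8	0	0	9	0	0	1.20E-08
CSMD1	6	0	0	6	0	0	5.95E-07
DNAH10	7	0	0	5	0	0	1.51E-08
EPHB4	5	0	0	1	0	0	1.50E-07
FAT1	6	0	0	8	0	0	1.84E-06
FBXW5	6	2	0	2	1	0	1.99E-08
FIGNL1	6	0	0	7	0	0	1.08E-06
FLG	7	0	0	5	0	0	1.51E-08
HSPG2	11	1	0	25	0	0	4.29E-09
KMT2C	8	0	0	8	0	0	6.50E-09
KNTC1	5	0	0	2	0	0	5.11E-07
LAMA5	13	1	0	21	0	0	5.38E-12
LRP2	11	0	0	11	0	0	7.17E-12
MUC16	14	2	0	25	0	0	2.11E-12
MYH7B	5	0	0	2	0	0	5.11E-07
NEB	12	3	0	21	1	0	7.64E-11
NRAP	5	0	0	3	0	0	1.33E-06
NUP160	4	0	0	0	0	0	8.64E-07
OBSCN	11	1	0	14	0	0	4.20E-11
PABPC1L	4	0	0	0	0	0	8.64E-07
PKD1	7	1	0	4	0	0	6.46E-09
PKD1L2	8	1	0	19	10	2	1.56E-06
PKHD1L1	7	0	0	9	0	0	1.97E-07
PLEC	11	1	0	21	0	0	1.02E-09
PLXNA2	4	0	0	0	0	0	8.64E-07
RP1L1	6	0	0	8	1	0	1.84E-06
RYR1	8	0	0	5	0	0	7.02E-10
SACS	8	0	0	4	0	0	2.77E-10
SRRM2	5	0	0	2	0	0	5.11E-07
TG	6	0	0	5	0	0	3.05E-07
TTN	24	5	0	51	1	0	1.72E-19
USH2A	9	0	0	9	0	0	6.76E-10
XIRP2	6	0	0	7	0	0	1.08E-06
ZFHX3	6	0	0	6	0	0	5.95E-07
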