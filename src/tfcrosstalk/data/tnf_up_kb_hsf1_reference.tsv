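gene_symbol	hs_direction	ratio_hstnf_vs_tnf	label
CCL2	down	0.03	O
CCL20	down	0.01	O
CYR61	down	0.34	O
DUSP2	down	0.24	O
ETS1	down	0.52	O
IFNGR2	down	0.66	O
IL8	down	0.05	O
INHBA	down	0.28	O
KCTD11	down	0.40	O
EGR4	up	0.64	O
SLC12A7	up	0.76	O
BTG2	none	0.46	O
CD83	none	0.35	O
TNF	none	0.77	O
EGR1	up	1.66	A
EGR2	up	1.36	A
FOSB	up	2.61	A
MSX1	up	4.14	A
PPP1R15A	up	2.11	A
RRAD	up	19.23	A
ZFP36	up	1.80	A
ATF3	up	1.00
EPB41L2	up	0.97
GADD45B	up	0.87
NR4A1	up	0.85
AZIN1	none	0.93
BDKRB1	none	0.63
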