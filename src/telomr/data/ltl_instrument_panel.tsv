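rsid	chr	pos	gene	a1	a2	eaf	beta	se	pvalue
rs3219104	1	226562621	PARP1	C	A	0.83	-0.042	0.006	9.60E-11
rs55749605	3	101232093	SENP7	A	C	0.58	0.037	0.007	2.45E-08
rs10936600	3	169514585	TERC	T	A	0.24	0.086	0.006	7.18E-51
rs13137667	4	71774347	MOB1B	C	T	0.96	-0.077	0.014	2.43E-08
rs4691895	4	164048199	NAF1	C	G	0.78	-0.058	0.006	1.58E-21
rs7705526	5	1285974	TERT	A	C	0.33	-0.082	0.006	5.34E-45
rs34991172	6	25480328	CARMIL1	G	T	0.07	0.061	0.011	6.19E-09
rs2736176	6	31587561	PRRC2A	C	G	0.31	-0.035	0.006	3.53E-10
rs59294613	7	124554267	POT1	A	C	0.29	0.041	0.006	1.17E-13
rs9419958	10	105675946	OBFC1	C	T	0.86	0.064	0.007	5.05E-19
rs228595	11	108105593	ATM	A	G	0.42	0.029	0.005	1.43E-08
rs2302588	14	73404752	DCAF4	C	G	0.10	-0.048	0.008	1.68E-08
rs3785074	16	69406986	TERF2	G	A	0.26	-0.035	0.006	4.64E-10
rs62053580	16	74680074	RFWD3	G	A	0.17	0.039	0.007	4.08E-08
rs7194734	16	82199980	MPHOSPH6	T	C	0.78	0.037	0.006	6.94E-10
rs8105767	19	22215441	ZNF208	G	A	0.30	-0.039	0.005	5.42E-13
rs75691080	20	62269750	STMN3	T	C	0.09	0.067	0.009	5.99E-14
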