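snp	chr	pos	ea	nea	eaf	beta	se	pval	n	gene
rs6693447	1	2330190	T	G	0.551	0.039	0.006	6.25e-10	52018	RER1
rs13028225	2	220031255	T	C	0.857	0.102	0.009	2.38e-30	52018	SLC23A3
rs33972313	5	138715502	C	T	0.968	0.36	0.018	4.61e-90	52018	SLC23A1
rs10051765	5	176799992	C	T	0.342	0.039	0.007	3.64e-09	52018	RGS14
rs7740812	6	52725787	G	A	0.594	0.038	0.006	1.88e-09	52018	GSTA5
rs174547	11	61570783	C	T	0.328	0.036	0.007	3.84e-08	52018	FADS1
rs117885456	12	96249111	A	G	0.087	0.078	0.012	1.70e-11	52018	SNRPF
rs2559850	12	102093459	A	G	0.598	0.058	0.006	6.30e-20	52018	CHPT1
rs10136000	14	105253581	A	G	0.283	0.04	0.007	1.33e-08	52018	AKT1
rs56738967	16	79740541	C	G	0.321	0.041	0.007	7.62e-10	52018	MAF
rs9895661	17	59456589	T	C	0.817	0.063	0.008	1.05e-14	52018	BCAS3
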