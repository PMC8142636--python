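snp	chr	pos	ea	nea	eaf	beta	se	pval	n
rs10051765	5	176799992	C	T	0.342	0.013	0.019	0.477	482730
rs10136000	14	105253581	A	G	0.283	0.003	0.021	0.872	482730
rs117885456	12	96249111	A	G	0.087	-0.053	0.043	0.216	482730
rs13028225	2	220031255	T	C	0.857	0.055	0.025	0.024	482730
rs174547	11	61570783	C	T	0.328	0.003	0.018	0.853	482730
rs2559850	12	102093459	A	G	0.598	-0.026	0.023	0.247	482730
rs33972313	5	138715502	C	T	0.968	-0.006	0.052	0.903	482730
rs56738967	16	79740541	C	G	0.321	-0.034	0.019	0.063	482730
rs6693447	1	2330190	T	G	0.551	-0.034	0.019	0.066	482730
rs7740812	6	52725787	G	A	0.594	-0.034	0.023	0.135	482730
rs9895661	17	59456589	T	C	0.817	-0.002	0.023	0.931	482730
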