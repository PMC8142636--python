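snp	chr	pos	ea	nea	eaf	beta	se	pval	n
rs10051765	5	176799992	C	T	0.342	0.104	0.125	0.405	28568
rs10136000	14	105253581	A	G	0.283	0.100	0.141	0.478	28568
rs117885456	12	96249111	A	G	0.087	0.274	0.267	0.305	28568
rs13028225	2	220031255	T	C	0.857	-0.325	0.167	0.051	28568
rs174547	11	61570783	C	T	0.328	0.141	0.121	0.243	28568
rs2559850	12	102093459	A	G	0.598	0.013	0.141	0.929	28568
rs33972313	5	138715502	C	T	0.968	-0.751	0.353	0.033	28568
rs56738967	16	79740541	C	G	0.321	-0.003	0.125	0.980	28568
rs6693447	1	2330190	T	G	0.551	-0.049	0.125	0.697	28568
rs7740812	6	52725787	G	A	0.594	-0.238	0.143	0.096	28568
rs9895661	17	59456589	T	C	0.817	0.032	0.151	0.833	28568
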