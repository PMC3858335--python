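cyp	rsid	cdna_change	aa_change	global_frequency_percent
3A43	rs45450092	435G>T	M145I	1.5
3A43	rs45621431	825G>A	M275I	2.3
3A43	rs680055	1018C>G	P340A	13.4
3A43	rs78548296	389G>A	R130Q	1.0
4A11	rs1126743	1374C>G	I458M	42.6
4A11	rs4926581	553G>T	V185F	28.1
4A11	rs61736429	1525C>T	L509F	2.1
4A11	rs62618709	553G>T	V185F	1.1
4A22	rs112604161	181G>A	G61R	1.6
4A22	rs113777592	553G>T	V185F	29.6
4A22	rs2056900	388G>A	G130S	29.9
4A22	rs4926600	1525C>T	L509F	12.9
4A22	rs61507155	311A>T	Y104F	6.6
4A22	rs61736431	1154C>T	P385L	1.2
4B1	rs12094024	986A>C	Y329S	2.2
4B1	rs2297809	1123C>T	R375C	18.3
4B1	rs4646487	517C>T	R173W	16.8
4B1	rs59694031	1109G>C	C370S	4.0
4F2	rs2074900	515C>T	Thr172I	25.4
4F2	rs2108622	1297G>A	V433M	20.9
4F2	rs3093153	554G>T	G185V	3.7
4F2	rs3093200	1555C>A	L519M	8.4
5A1	rs13306050	1372C>T	R458C	3.3
5A1	rs13306052	679GA	V227M	1.4
5A1	rs6952940	544C>T	P182S	2.4
2A6	rs5031017	1436G>T	G479V	1.4
2A6	rs5031016	1412T>C	I471T	5.1
2A6	rs28399499	983T>C	I328T	2.3
2A6	rs8192709	64C>T	R22C	4.5
2A6	rs28399499	383T>C	I128T	2.3
2C8	rs11572103	805A>T	I269F	16.4
2C8	rs1058930	792C>G	I264M	4.1
2C8	rs11572103	805A>T	I269F	16.4
2C9	rs28371686	1080C>G	D360E	2.3
2C9	rs28371685	1003C>T	R335W	2.0
2C9	rs2256871	752A>G	H251R	4.0
2F1	rs144315434	1172T>C	L391P	5.4
2F1	rs146029724	1330A>C	M444L	6.5
2W1	rs61746347	557G>A	R186H	2.8
2W1	rs117826462	547C>G	L183V	1.4
4F11	rs1060463	1271G>A	R424Q	49.5
4F11	rs148197835	538C>T	R180C	4.2
4F11	rs57519667	436C>T	R146C	1.6
2C18	rs115091705	431G>A	R144H	1.7
2C18	rs117111102	370C>T	R124W	1.4
2C18	rs2281891	1154C>T	T385M	19.3
2C18	rs41286880	1004G>A	R335Q	2.5
2C18	rs79500998	1324C>T	R442C	1.0
7A1	rs8192875	1039G>A	D347N	1.6
4F12	rs16995378	47C>T	T16M	7.6
4F12	rs57578760	808G>C	V270L	3.7
4F12	rs76142062	88C>A	L30I	3.4
11B1	rs11775687	562C>T	P188S	5.7
11B1	rs9657020	593C>T	T198M	12.7
4F3	rs118159249	1420G>A	A474T	1.1
2A7	rs111390860	988C>T	R330W	1.0
2A7	rs184466431	1301G>T	R434L	1.2
2A7	rs3869579	778C>T	R260C	46.7
2A7	rs60711313	1259T>C	I420T	3.2
2A7	rs75152309	1106A>T	K369M	6.6
2A7	rs78754793	244G>C	A82P	2.4
2S1	rs34971233	1397C>T	P466L	1.1
2E1	rs6413419	535G>A	V179I	7.2
2E1	rs28969387	1370A>T	H457L	6.3
2C19	rs17884712	431G>A	R144H	1.4
8A1	rs5626	706C>T	R236C	3.7
2D6	rs2982054	986G>A	R329H	31.2
2D6	rs1058172	941G>A	R314H	7.9
2D6	rs59421388	859G>A	V287M	5.3
2D6	rs1065852	100C>T	P34S	25.9
1A1	rs4646422	134GA	G45D	6.7
1A1	rs17861094	233T>C	I78Thr	8.3
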