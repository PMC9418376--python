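molecule	position	base	guide
18S	28	A
18S	100	A
18S	420	A	snR52
18S	436	A
18S	541	A
18S	562	A
18S	619	A
18S	796	A
18S	974	A
18S	1007	C
18S	1126	U
18S	1271	G
18S	1280	A
18S	1415	C
18S	1428	G
18S	1572	G
18S	1583	A
18S	1639	C
25S	649	A
25S	650	C
25S	663	C
25S	805	G
25S	807	A
25S	817	C
25S	867	A
25S	876	G
25S	908	A
25S	1133	U
25S	1437	A
25S	1449	G
25S	1450	C
25S	1888	U
25S	2197	A
25S	2220	U
25S	2256	A
25S	2280	C
25S	2281	A
25S	2288	U
25S	2337	A
25S	2347	C
25S	2351	A
25S	2416	G
25S	2421	U
25S	2619	C
25S	2640	C
25S	2724	A
25S	2729	U
25S	2791	C
25S	2793	U
25S	2815	G
25S	2920	C
25S	2921	U	snR52
25S	2922	G
25S	2948	G
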