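case_id	role	line_id	breakpoints	males	females	printed_pct	printed_fold	printed_p	printed_comment	class_override
Df(2R)CX1	parent	Df(2R)CX1	49C1-4;50C23-D2	2	88	2	0.10	0	1
Df(2R)CX1	sub	Df(2R)Exel7123	49D5;49E6	6	202	3	0.14	0
Df(3R)p-XT103	parent	Df(3R)p-XT103	85A2;85C1-2	3	189	2	0.07	0	1
Df(3R)p-XT103	sub	Df(3R)Exel8143	85A5;85B3	27	322	8	0.36	0
Df(3R)by10	parent	Df(3R)by10	85D8-12;85E7-F1	19	170	10	0.46	0	1
Df(3R)by10	sub	Df(3R)Exel6153	85D19;85E1	4	249	2	0.09	0
Df(3L)fz-GF3b	parent	Df(3L)fz-GF3b	70C2;70D4-5	1	50	2	0.09	0	2
Df(3L)fz-GF3b	sub	Df(3L)Exel6122	70D4;70D7	109	257	30	1.4
Df(2L)E110	parent	Df(2L)E110	25F3-26A1;26D3-11	85	80	52	2.3	0	1
Df(2L)E110	sub	Df(2L)BSC5	26B1-2;26D1-2	77	95	45	2.0	0.02
Df(2L)E110	sub	Df(2L)BSC184	26B1;26B3	85	104	45	2.0	0.01
Df(2R)BSC18	parent	Df(2R)BSC18	50D1;50D2-7	101	120	46	2.1	0.02	1
Df(2R)BSC18	sub	Df(2R)50C-36	50C19-23;50C21-D5	111	152	42	1.9	0.01
Df(2R)BSC11	parent	Df(2R)BSC11	50E6-F1;51E2-4	47	36	57	2.6	< 0.0001	1
Df(2R)BSC11	sub	Df(2R)L48	50F6-F9;51B3	47	78	38	1.7	0.04		suppressor
Df(2L)JS17	parent	Df(2L)JS17	23C1-2;23E1-2	90	125	42	1.9	0.02	2
Df(2L)JS17	sub	Df(2L)Exel7015	23C5;23E3	59	143	29	1.3
Df(2L)BSC28	parent	Df(2L)BSC28	23C5-D1;23E2	98	129	43	2.0	0	2
Df(2L)BSC28	sub	Df(2L)Exel7015	23C5;23E3	59	143	29	1.3
Df(2R)cn9	parent	Df(2R)cn9	42E;44C	59	64	48	2.2	0	2
Df(2R)cn9	sub	Df(2R)Exel6053	43D3;43E9	75	138	35	1.6
Df(2R)X1	parent	Df(2R)X1	46C;47A1	84	72	54	2.4	0.01	1
Df(2R)X1	sub	Df(2R)BSC152	46C1;46D7	88	124	42	1.9	0.01
Df(2R)X1	sub	Df(2R)BSC298	46B2;46C7	131	207	39	1.8	0	1	suppressor
Df(2R)X1	sub	Df(2R)eve	46C7;46C9-46C11	31	74	30	1.4		2
Df(2R)vir130	parent	Df(2R)vir130	59B;59D8-E1	59	72	45	2.0	0	2
Df(2R)vir130	sub	Df(2R)twi	59C3-4;59D1-2	123	308	29	1.3
Df(3L)XG5	parent	Df(3L)XG5	71C2-3;72B1-C1	67	67	50	2.3	0
Df(3L)XG5	sub	Df(3L)brm11	72A3;72D5	72	278	21	1.0
Df(3R)mbc-30	parent	Df(3R)mbc-30	95A5-7;95C10-11	58	52	53	2.4	0.01
Df(3R)mbc-30	sub	Df(3R)Exel6195	95A4;95B1	45	55	45	2.0	0.02
Df(3R)mbc-30	sub	Df(3R)Exel9014	95B1;95D1	53	109	33	1.5
Df(2L)ast2	parent	Df(2L)ast2	21E2;22B2-3	12	128	9	0.39	0.1480	3
Df(2L)ast2	sub	Df(2L)Exel6004	21E4;21F1	60	80	43	2.0	0.01
Df(2L)TE35BC-24	parent	Df(2L)TE35BC-24	35B4-6;35F1-7	9	114	7	0.33	0	2
Df(2L)TE35BC-24	sub	Df(2L)TE35BC-7	35B2;35B10	55	99	36	1.6
Df(2L)TE35BC-24	sub	Df(2L)Exel7063	35D2;35D4	46	64	42	1.9	0.03	3
Df(2R)BSC49	parent	Df(2R)BSC49	53D9-E1;54B5-10	12	112	10	0.44	0.01	3
Df(2R)BSC49	sub	Df(2R)Exel6066	53F8;54B6	100	144	41	1.9	0
Df(2R)BSC49	sub	Df(2R)BSC154	54B2;54B7	3	93	3	0.14	0.01	1
Df(2R)AA21	parent	Df(2R)AA21	57B19-C1;57E1-6	1	75	1	0.06	0	2
Df(2R)AA21	sub	Df(2R)Exel6072	57B16;57D4	30	169	15	0.7
Df(2R)AA21	sub	Df(2R)Exel6076	57E1;57F3	77	89	46	2.1	0.03	3
Df(2R)Egfr5	parent	Df(2R)Egfr5	57D2-8;58D1	8	140	5	0.25	0	3
Df(2R)Egfr5	sub	Df(2R)Exel6076	57E1;57F3	77	89	46	2.1	0.03
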