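line_id	breakpoints	males	females	printed_total	printed_pct	printed_fold	printed_p	submapped
Df(3L)emc-E12	61A;61D3	0	115	115	0	0.00	0	No
Df(3L)ZN47	64C;65C	0	53	53	0	0.00	0	No
Df(3L)W10	75A6-7;75C1-2	0	217	217	0	0.00	0	No
Df(3L)fz2	75F10-11;76A1-5	0	77	77	0	0.00	0	No
Df(3R)crb-F89-4	95D7-D11;95F15	0	225	225	0	0.00	0	No
Df(3R)crb87-5	95F7;96A17-18	0	194	194	0	0.00	0	No
Df(2L)TW161	38A6-B1;40A4-B1	1	112	113	1	0.04	0	No
Df(2R)AA21	57B19-C1;57E1-6	1	75	76	1	0.06	0	Yes
Df(3R)p-XT103	85A2;85C1-2	3	189	192	2	0.07	< 0.0001	Yes
Df(3L)fz-GF3b	70C2;70D4-5	1	50	51	2	0.09	0	Yes
Df(2R)CX1	49C1-4;50C23-D2	2	88	90	2	0.10	0	Yes
Df(2R)M60E	60E6;60E11	5	140	145	3	0.16	0.02	No
Df(3L)GN24	63F6-7;64C13-15	4	97	101	4	0.18	< 0.0001	No
Df(3R)23D1	94A3-4;94D1-4	3	71	74	4	0.18	0	No
Df(2R)vg-C	49B2;49E2	6	128	134	4	0.20	0	No
Df(3R)e-R1	93B6-7;93D4	5	98	103	5	0.22	0.01	No
Df(2R)Egfr5	57D2-8;58D1	8	140	148	5	0.25	0	Yes
Df(3R)ea	88E7-13;89A1	13	175	188	7	0.31	0.01	No
Df(2R)BSC40	48E1-2;48E2-10	5	66	71	7	0.32	0.2390	No
Df(2R)BSC161	54B2;54B17	5	66	71	7	0.32	0.07	No
Df(2L)BSC32	32A1-2;32C5-D1	7	89	96	7	0.33	0	No
Df(2L)TE35BC-24	35B4-6;35F1-7	9	114	123	7	0.33	0	Yes
Df(2R)ED4065	60C8;60E8	30	332	362	8	0.38	0.01	No
Df(2L)ast2	21E2;22B2-3	12	128	140	9	0.39	0.1480	Yes
Df(2R)k10408	54B16,54B16	20	180	200	10	0.45	0	No
Df(2R)BSC49	53D9-E1;54B5-10	12	112	124	10	0.45	0.01	Yes
Df(3R)by10	85D8-12;85E7-F1	19	170	189	10	0.46	0	Yes
Df(3R)D605	97E2;98A5	18	152	170	11	0.50	0.01	No
Df(2R)M41A4	41A;41A	22	167	189	12	0.53		
Df(2R)Kr10	60F1;60F5	11	80	91	12	0.55		
Df(3R)Exel6144	83A6;83B6	19	136	155	12	0.56		
Df(2L)drm-P2	23F3-4;24A1-2	16	113	129	12	0.56		
Df(3L)66C-G28	66B8-9;66C9-10	19	129	148	13	0.58		
Df(2L)BSC30	34A3;34B7-9	19	129	148	13	0.58		
Df(3L)GN34	63E6-9;64A8-9	42	276	318	13	0.60		
Df(3R)Antp17	84A5;84D9	18	106	124	15	0.66		
Df(3R)e1025-14	82F8-10;83A1-3	34	196	230	15	0.67		
Df(3L)Aprt-1	62A10-B1;62D2-5	14	80	94	15	0.68		
Df(3R)BSC140	96F1;96F10	17	93	110	15	0.70		
Df(3L)ri-79c	77B-C;77F-78A	35	190	225	16	0.71		
Df(2R)or-BR6	59B;59D8-E1	18	94	112	16	0.73		
Df(2R)H3E1	44D1-4;44F12	38	196	234	16	0.74		
Df(2R)BSC19	56F12-14;57A4	14	71	85	16	0.75		
Df(3R)L127	99B5-6;99F1	51	254	305	17	0.76		
Df(3R)Exel6197	95D8;95E5	22	109	131	17	0.76		
Df(3R)B81	99D3;3Rt	41	197	238	17	0.78		
Df(2R)Exel7131	50E4;50F6	29	136	165	18	0.80		
Df(3R)Exel6202	96C9;96E2	32	150	182	18	0.80		
Df(3L)ME107	77F3;78C8-9	83	387	470	18	0.80		
Df(3L)BSC14	67E3-7;68A2-6	21	96	117	18	0.82		
Df(2R)en30	48A3-4;48C6-8	22	97	119	18	0.84		
Df(3R)Espl3	96F1;97B1	28	123	151	19	0.84		
Df(3R)Scr	84A1-2;84B1-2	26	114	140	19	0.84		
Df(3R)BSC47	83B7-C1;83C6-D1	32	140	172	19	0.85		
Df(2R)Jp1	51D3-8;52F5-9	27	118	145	19	0.85		
Df(3L)ED4978	78D5;79A2	93	390	483	19	0.88		
Df(2R)nap9	42A1-2;42E6-F1	28	116	144	19	0.88		
Df(3R)WIN11	83E1-2;84A5	19	78	97	20	0.89		
Df(2L)BSC41	28A4-B1;28D3-9	33	129	162	20	0.93		
Df(3L)brm11	72A3;72D5	72	278	350	21	0.94		
Df(3R)IR16	97F1-2;98A	46	176	222	21	0.94		
Df(2L)cl-h3	25D2-4;26B2-5	38	145	183	21	0.94		
Df(3L)Exel6087	62A2;62A7	103	389	492	21	1.0		
Df(2L)ed1	24A2;24D4	34	126	160	21	1.0		
Df(2R)robl-c	54B17-C4;54C1-4	34	126	160	21	1.0		
Df(3L)ri-XT1	77E2-4;78A2-4	44	163	207	21	1.0		
w1118	N/A	314	1123	1437	22	1.0		
Df(3L)81k19	73A3;74F	39	134	173	23	1.0		
Df(3R)Exel6203	96E2;96E6	37	127	164	23	1.0		
Df(3R)BSC137	95A2-4;95A8-B1	43	141	184	23	1.1		
Df(3R)Exel9012	94E9;94E13	37	118	155	24	1.1		
Df(2L)XE-3801	27E2;28D1	14	44	58	24	1.1		
Df(3R)Exel6196	95C12;95D8	52	155	207	25	1.1		
Df(2L)TE29Aa-11	28E4-7;29B2-C1	39	113	152	26	1.2		
Df(2L)FCK-20	32D1;32F1-3	32	91	123	26	1.2		
Df(2R)BSC44	54B1-2;54B7-10	47	133	180	26	1.2		
Df(2R)Px2	60C5-6;60D9-10	39	109	148	26	1.2		
Df(2L)ED611	29B4;29C3	45	125	170	26	1.2		
Df(3L)ZP1	66A17-20;66C1-5	23	62	85	27	1.2		
Df(3L)vin7	68C8-11;69B4-5	47	126	173	27	1.2		
Df(3R)M-Kx1	86C1;87B1-5	38	99	137	28	1.3		
Df(3L)rdgC-co2	77A1;77D1	58	150	208	28	1.3		
Df(3R)3450	98E3;99A6-8	140	358	498	28	1.3		
Df(3L)ED4782	75F2;76A1	31	79	110	28	1.3		
Df(2L)Prl	32F1-3;33F1-2	35	88	123	28	1.3		
Df(3L)eygC1	69A4-5;69D4-6	43	107	150	29	1.3		
Df(2R)X58-12	58D1-2;59A	40	92	132	30	1.4		
Df(2L)b87e25	34B12-C1;35B10-C1	43	96	139	31	1.4		
Df(2L)dp-79b	22A2-3;22D5-E1	48	106	154	31	1.4		
Df(2L)BSC36	32D1;32D4-E1	50	106	156	32	1.5		
Df(3R)ED5177	83B4;83B6	50	104	154	32	1.5		
Df(2R)PC4	55A;55F	71	147	218	33	1.5		
Df(3R)Exel9014	95B1;95D1	53	109	162	33	1.5		
Df(3L)BSC12	69F6-70A1;70A1-2	36	74	110	33	1.5		
Df(2R)P34	55E2-4;56C1-11	53	108	161	33	1.5		
Df(2L)BSC31	23E5;23F4-5	68	138	206	33	1.5		
Df(2R)BSC132	45F6;46B12	43	86	129	33	1.5		
Df(3R)Tl-P	97A;98A1-2	90	176	266	34	1.5		
Df(3L)pbl-X1	65F3;66B10	41	79	120	34	1.6		
Df(2R)BSC26	56C4;56D6-10	48	88	136	35	1.6		
Df(3L)st-f13	72C1-D1;73A3-4	58	106	164	35	1.6		
Df(2L)BSC4	21B7-C1;21C2-3	81	142	223	36	1.7		
Df(3L)R-G7	62B4-7;62D5-E5	51	89	140	36	1.7		
Df(2R)B5	46A;46C	50	86	136	37	1.7		
Df(2R)14H10Y-53	54D1-2;54E5-7	58	99	157	37	1.7		
Df(2R)w45-30n	45A6-7;45E2-3	83	140	223	37	1.7		
Df(2R)Exel7162	56F11;56F16	56	94	150	37	1.7		
Df(2L)BSC111	28F5;29B1	58	97	155	37	1.7		
Df(2R)ST1	42B3-5;43E15-18	56	91	147	38	1.7		
Df(2L)pr-A16	37B2-12;38D2-5	47	75	122	39	1.8		
Df(3L)XS533	76B4;77B	42	67	109	39	1.8		
Df(3L)BSC8	74D3-75A1;75B2-5	53	84	137	39	1.8		
Df(3L)vin5	68A2-3;69A1-3	38	60	98	39	1.8		
Df(2R)BSC39	48C5-D1;48D5-E1	67	102	169	40	1.8		
Df(2R)CB21	48E;49A	56	85	141	40	1.8		
Df(3R)3-4	82F3-4;82F10-11	59	87	146	40	1.8		
Df(3R)Tpl10	83C1-2;84B1-2	41	59	100	41	1.9	0.08	No
Df(3R)BSC24	85B7;85D15	61	85	146	42	1.9	0	No
Df(2L)JS17	23C1-2;23E1-2	90	125	215	42	1.9	0.02	Yes
Df(2R)BSC22	56D7-E3;56F9-12	67	92	159	42	1.9	0	No
Df(3L)BSC35	66F1-2;67B2-3	192	262	454	42	1.9	0.01	No
Df(2R)BSC155	60B8;60C4	76	103	179	42	1.9	0.01	No
Df(3L)BSC20	76A7-B1;76B4-5	61	81	142	43	2.0	0.03	No
Df(3R)Exel6193	94D3;94E4	58	78	136	43	2.0	0.01	No
Df(2L)BSC28	23C5-D1;23E2	98	129	227	43	2.0	0	Yes
Df(3R)BSC42	98B1-2;98B3-5	129	169	298	43	2.0	0.01	No
Df(2R)Np5	44F12;45DE3	48	60	108	44	2.0	0.05	No
Df(3L)h-i22	66D10-11;66E1-2	51	63	114	45	2.0	0.05	No
Df(3L)AC1	67A2;67D11-13	47	58	105	45	2.0	0.02	No
Df(2L)BSC5	26B1-2;26D1-2	77	95	172	45	2.0	0.02	Yes
Df(3R)Exel6195	95A4;95B1	45	55	100	45	2.0	0.0020	Yes
Df(2R)vir130	59B;59D8-E1	59	72	131	45	2.0	0	Yes
Df(2L)TW203	36E-36E3;37B10	46	55	101	46	2.1	0	No
Df(2R)BSC18	50D1;50D2-7	101	120	221	46	2.1	0.02	Yes
Df(2R)BSC29	45D3-4;45F2-6	64	75	139	46	2.1	0	No
Df(2R)Exel7130	50D4;50E4	105	120	225	47	2.1	0.03	No
Df(3R)mbc-R1	95A5-7;95D6-11	99	111	210	47	2.1	0.0050	No
Df(2R)BSC3	48E12-F4;49A11-B6	79	88	167	47	2.2	0.0180	No
Df(2R)BSC45	54C8-D1;54E2-7	98	109	207	47	2.2	0	No
Df(2R)cn9	42E;44C	59	64	123	48	2.2	0	Yes
Df(3L)BSC10	69D4-5;69F5-7	62	67	129	48	2.2	0.01	No
Df(3L)Scf-R6	66E1-6;66F1-6	43	45	88	49	2.2	0	No
Df(3L)XG5	71C2-3;72B1-C1	67	67	134	50	2.3	0	Yes
Df(3L)BSC21	79E5-F1;80A2-3	32	31	63	51	2.3	0.28	No
Df(2L)E110	25F3-26A1;26D3-11	85	80	165	52	2.3	0	Yes
Df(3R)mbc-30	95A5-7;95C10-11	58	52	110	53	2.4	0.01	Yes
Df(2L)spd[j2]	27B2-27F2	64	55	119	54	2.4	0.02	No
Df(2R)X1	46C;47A1	84	72	156	54	2.4	0.01	Yes
Df(2R)BSC11	50E6-F1;51E2-4	47	36	83	57	2.6	< 0.0001	Yes
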