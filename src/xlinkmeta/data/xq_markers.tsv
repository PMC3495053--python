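marker_id	bp_start	bp_end	decode_cm	published_cm	gws
DXS1216	66597577	66597945	82.98	82.98	1
DXS6800	76721582	76721893	86.84	86.84	1
DXS986	77422288	77422628	86.84	86.84	1
DXS990	91036325	91036548	94.92	94.92	1
DXS6789	93484970	93485285	96.95	96.95	1
DXS1106	100764898	100765284		101.56	1
DXS6797	105514006	105514365	104.57	104.57	1
GATA172D05	111199673	111199793	110.42	110.42	1
DXS8055	112690834	112691203		112.66	1
DXS1001	117811961	117812315	120.35	120.35	1
GATA165B12	118830243	118830577	122.11	122.11	1
DXS1047	127020308	127020598		131.44	1
DXS1192	136312813	136313015	142.03	142.03	0
DXS1232	137224883	137225141		144.25	0
DXS984	137576507	137576708	145.8	145.8	1
GATA31E08	138167161	138167460		147.38	1
DXS1205	138195175	138195518	147.46	147.46	0
DXS1227	138735290	138735546	150.37	150.37	1
DXS6751	138961389	138961667		151.02	1
DXS6798	139563750	139564153		152.76	1
DXS8106	140116944	140117293	154.35	154.35	0
DXS7127	140874035	140874578		156.62	1
DXS6806	141366644	141366944	158.09	158.09	1
DXS8043	141885707	141885926		159.62	1
MXMAFMA113ZF5	142386616	142387004		161.1	0
DXS1200	143602429	143602828	164.69	164.69	1
DXS297	143861118	143861312		165.05	0
DXS731	145029666	145029754		166.65	0
MXMAFM323YF1	145482291	145482634		167.28	0
DXS8091	145497860	145498194	167.3	167.3	1
MXMAFM136YB10	146107588	146107837		168.95	1
MXMAFMA107XF5	146244529	146244891		169.32	0
DXS1193	146275270	146275535	169.4	169.4	1
DXS1123	146381305	146381484		169.78	0
DXS8069	147408020	147408348	173.44	173.44	1
DXS8011	147637858	147638200		176	0
DXS8103	147886112	147886447	178.77	178.77	0
MXMAFMA225XH9	148302283	148302628		179.88	0
MXMAFMA082XA5	148619715	148620129		180.74	0
DXS1073	151414197	151414518	188.22	188.22	1
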