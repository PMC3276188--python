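marker	H1	H2	H3	H4	H5	H6	H7
D6S2972	129	121	123	121	121	123	123
D6S2970	303,307	307,303	295	315	311	353	311
D6S2854	173,193	173,193	173,193	173,193,197	213	173,193,197	173,193
D6S2704	163	163	145	147	153	147	161
D6S2847	321	321	321	321	321	323	323
C4-2-25	235	237	235	235	235	235	235
MICA	203	200	200	200	206	194	203
D6S2793	276	268	246	246	246	246	278
D6S2782	324	343	337	341	341	337	337
D6S2669	130	112	143	130	110	97	110
D6S2892	208	202	206	202	205	208	202
DRACA	237	268	272	266	266	268	270
D6S2876	215	211	217	211	204	211	211
D6S2747	208	203	194	191	206	210	191
D6S2745	299	311	303	303	299	299	303
D6S2771	398	399	399	395	398	399	395
D6S2741	266	276	256	258	268	272	258
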