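specificity	type1_plus	type1_minus	type1_all	type2_plus	type2_minus	type2_all	type3
default	512	381	893	1364	1374	2738	8001
0.70	235	176	411	645	689	1334	3552
0.80	135	102	237	413	431	844	2053
0.90	34	45	79	194	203	397	760
0.95	9	12	21	75	88	163	220
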