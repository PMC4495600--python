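residue	hydrophobicity_kd	hydrophilicity_hw	volume	polarity	isoelectric_point	mass	charge
A	1.8	-0.5	88.6	8.1	6.00	71.08	0.0
R	-4.5	3.0	173.4	10.5	10.76	156.19	1.0
N	-3.5	0.2	114.1	11.6	5.41	114.10	0.0
D	-3.5	3.0	111.1	13.0	2.77	115.09	-1.0
C	2.5	-1.0	108.5	5.5	5.07	103.14	0.0
Q	-3.5	0.2	143.8	10.5	5.65	128.13	0.0
E	-3.5	3.0	138.4	12.3	3.22	129.12	-1.0
G	-0.4	0.0	60.1	9.0	5.97	57.05	0.0
H	-3.2	-0.5	153.2	10.4	7.59	137.14	0.1
I	4.5	-1.8	166.7	5.2	6.02	113.16	0.0
L	3.8	-1.8	166.7	4.9	5.98	113.16	0.0
K	-3.9	3.0	168.6	11.3	9.74	128.17	1.0
M	1.9	-1.3	162.9	5.7	5.74	131.19	0.0
F	2.8	-2.5	189.9	5.2	5.48	147.18	0.0
P	-1.6	0.0	112.7	8.0	6.30	97.12	0.0
S	-0.8	0.3	89.0	9.2	5.68	87.08	0.0
T	-0.7	-0.4	116.1	8.6	5.60	101.10	0.0
W	-0.9	-3.4	227.8	5.4	5.89	186.21	0.0
Y	-1.3	-2.3	193.6	6.2	5.66	163.18	0.0
V	4.2	-1.5	140.0	5.9	5.96	99.13	0.0
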