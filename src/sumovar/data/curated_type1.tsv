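gene	protein_id	token	site_pos	peptide	group
TP53	P04637	Lys386Asn	386	STSRHKKLMFKTEGPDSD	I-
NPM1	P06748	Lys263Arg	263	ASIEKGGSLPKVEAKFINYVK	I-
CBS	P35520	Lys211Arg	211	ESHVGVAWRLKNEIPNSHILD	I-
NR1H3	Q13133	Lys434Asn	434	QVFALRLQDKKLPPLLSEIWD	I-
ZNF221	Q9UK13	Lys423Ile	423	QQVHSGQKSFKCEECGKGFYT	I-
FOSL2	P15408	Lys222Asn	222	GGGSVGAVVVKQEPLEEDSPS	I-
NR1H3	Q13133	Lys328Gln	328	DFSYNREDFAKAGLQVEFINP	I-
INO80B	Q9C086	Lys168Asn	168	KGELDDNGDLKKEINERLLTA	I-
HIF1A	Q16665	Lys477T	477	DPALNQEVALKLEPNPESLEL	I-
PML;MYL	P29590	Lys487Asn	487	RKCSQTQCPRKVIKMESEEGK	I-
SALL1	Q9NSC2	Lys1086Asn	1086	IPANSLSSLIKTEVNGFVHVS	I-
IRF2	P14316	Lys166Ile	166	PEYAVLTSTIKNEVDSTVNII	I-
RSBN1	Q5VWQ0	Lys313Asn	313	GLNKESFRYLKDEQLCRLNLG	I-
SREBF1	P36956	Lys123Gln	123	MPAFSPGPGIKEESVPLSILQ	I-
ARID5B	Q14865	Lys629Asn	629	MADYIANCTVKVDQLGSDDIH	I-
ACTB	P60709	Lys68Gln	68	AQSKRGILTLKYPIEHGIVTN	I-
SCIN	Q9Y6U3	Lys299Gln	299	AAKQIFVWKGKDANPQERKAA	I-
ZBTB1	Q9Y2K1	Lys328Gln	328	RAAERKRIIIKMEPEDIPTDE	I-
VHL	P40337	Lys171Asn	171	RCLQVVRSLVKPENYRRLDIV	I-
PIAS4	Q8N2W9	Lys128Met	128	GLGRLPAKTLKPEVRLVKLPF	I-
HIST1H4A	P62805	Lys13Ile	13	GRGKGGKGLGKGGAKRHRKVL	I-
HIST1H4A	P62805	Lys13Asn	13	GRGKGGKGLGKGGAKRHRKVL	I-
SNCA	P37840	Lys96Arg	96	GSIAAATGFVKKDQLGKNEEG	I-
IGF1R	P08069	Lys1150Arg	1150	NCMVAEDFTVKIGDFGMTRDI	I-
BLM	P54132	Lys347Asn	347	TSKDLLSKPEKMSMQELNPET	I-
HDAC1	Q13547	Lys476Gln	476	KEEKPEAKGVKEFEVKLA	I-
PDE4D	Q08499	Lys387Asn	387	TNSSIPRFGVKTEQEDVLAKE	I-
UBA2	Q9UBT2	Lys257Asn	257	TGYDPVKLFTKLFKDDIRYLL	I-
BLM	P54132	Lys344Asn	344	VLSTSKDLLSKPEKMSMQELN	I-
MAPKAPK2	P49137	Lys353Arg	353	KEDKERWEDVKEEMTSALATM	I-
CHD7	Q9P2D1	Lys1196Asn	1196	MLRRLKEDVEKNLAPKEETII	I-
XRCC4	Q13426	Lys210Arg	210	NAAQEREKDIKQEGETAICSE	I-
USP25	Q9UHP3	Lys141Thr	141	RVLEASIAENKACLKRTPTEV	I-
RLF	Q13129	Lys1561Thr	1561	CMVQGCLSVVKLESSIVRHYK	I-
TBX22	Q9Y458	Lys63Asn	63	GKSEPLEKQPKTEPSTSASSG	I-
SUMO1	P63165	Lys16Asn	16	AKPSTEDLGDKKEGEYIKLKV	I-
KCNIP3	Q9Y2W7	Lys90Gln	90	DQLQAQTKFTKKELQSLYRGF	I-
HIF1A	Q16665	Lys391Arg	391	EDTSSLFDKLKKEPDALTLLA	I-
RANBP2	P49792	Lys2725Gln	2725	EKKPTVEEKAKADTLKLPPTF	I-
IRF2	P14316	Lys137Gln	137	TEKEDKVKHIKQEPVESSLGL	I-
POLD3	Q15054	Lys433Gln	433	SVHRPPAMTVKKEPREERKGP	I-
ZNF462	Q96JM2	Lys2482Asn	2482	DEAIGIDFSLKNETVAICVVT	I-
MDM4	O15151	Lys254Asn	254	SVSEQLGVGIKVEAADTEQTS	I-
APP;A4	P05067	Lys670Asn	670	NIKTEEISEVKMDAEFRHDSG	I-
UBA2	Q9UBT2	Lys623Asn	623	KLDEKENLSAKRSRIEQKEEL	I-
SUMO1	P63165	Lys7Gln	7	MSDQEAKPSTEDLGDKK	I-
HSF1	Q00613	Lys298Asn	298	PLSSSPLVRVKEEPPSPPQSP	I-
USP25	Q9UHP3	Lys99Gln	99	TNVIDLTGDDKDDLQRAIALS	I-
NF2	P35240	Lys76Arg	76	YTIKDTVAWLKMDKKVLDHDV	I-
AGO2	Q9UKV8	Lys402Arg	402	PYVREFGIMVKDEMTDVTGRV	I-
RARA	P10276	Lys399Arg	399	AKGAERVITLKMEIPGSMPPL	I-
ATF7	P17544	Lys118Arg	118	SLPSTPDIKIKEEEPVEVDSS	I-
RARA	P10276	Lys166Arg	166	ESVRNDRNKKKKEVPKPECSE	I-
RARA	P10276	Lys171Arg	171	DRNKKKKEVPKPECSESYTLT	I-
ZIC3	O60481	Lys248Arg	248	AFFRYMRQPIKQELSCKWIDE	I-
CASP8AP2	Q9UKL3	Gln1792Lys	1792	ANRPLKCIVEETYIDLTTESP	I+
BHLHE41	Q9C0J8	Leu240Lys	240	DFLRCHEERILRGHGADVKCV	I+
BHLHE42	Q9C0J8	Thr255Lys	255	ADVKCVDWHPTKGLVVSGSKD	I+
NPM1	P06748	Arg101Lys	101	GFEITPPVVLRLKCGSGPVHI	I+
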