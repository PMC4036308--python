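symbol	chrom	start	stop
ADAM17	11	87798074	88040943
AREGB	6	91026256	91238391
BMP4	10	66651296	66855026
BMPR1A	28	41717915	41975988
CSN2	6	87079502	87288025
CCND1	29	47444380	47653820
DKK1	26	6752970	6955647
EDAR	11	44351547	44567795
EGF	6	16465618	16768065
EGFR	22	792005	1169280
ESR1	9	89869586	90355801
FGF1	7	55408007	55701836
FGF10	20	30510292	30719199
FGFR1	27	33150508	33400219
GH1	19	48668618	48872014
GHR	20	31790736	32299996
GLI2	2	72877209	73268370
GLI3	4	79344243	79858476
IGF1	5	66432877	66704734
IGF1R	21	8108822	8368093
IRS1	2	115690540	115894253
IRS2	12	88564525	88769181
LEF1	6	18235031	18550774
MFGE8	21	20789913	21004968
MMP14	10	21706054	21914533
MMP2	18	23728638	23955657
MMP3	15	5928011	6134595
MMP9	13	75366513	75573824
MSX1	6	105961463	106165759
MSX2	20	6260600	6465489
NRG1	27	27523938	27933470
NRG3	28	38201492	38451092
NTN1	19	28984419	29369338
PGR	15	8004485	8322755
PCBD1/TCF1	28	27126795	27331724
PRL	23	35005135	35213759
PRLR	20	38973246	39237480
PTHLH	5	82146522	82358858
PTH1R	22	53061302	53324114
PTH	15	39628332	39830868
TNFRSF11A	24	61139109	61375194
TNFSF11	12	12641069	12882474
RELN	4	44792394	45389293
SIRPA	13	53567570	53810792
SLIT2	6	41136589	41740789
SOCS1	25	9875299	10075970
SOCS2	5	23423981	23628860
SOCS3	19	54358856	54559555
STAT5A	19	42933597	43154075
STAT5B	19	42860226	43096671
TBX2	19	11843185	12051411
TBX3	17	62252245	62463636
TCF3	7	45499593	45730734
TCF4	24	54956409	55261459
TGFA	11	13772149	14086616
TGFB1	18	50671354	50885924
TGFBR1	8	64470093	64741796
TGFBR2	22	5041232	5333083
WAP	4	77111371	77312672
WNT10B	5	30913104	31114446
WNT11	15	56284700	56504335
WNT3	19	45921803	46171153
WNT5A	22	45996228	46212683
WNT6	2	107444683	107656681
N = 64			
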