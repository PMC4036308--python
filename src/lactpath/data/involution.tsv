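symbol	chrom	start	stop
AKT1	21	70778138	70995537
ATF4	5	111362845	111564936
BAK1	23	7555892	7758885
BAX	18	55885202	56089378
BCL2L1	13	61666806	61917383
CASP3	27	13984622	14210610
CEBPA	18	43828610	44029840
CEBPD	14	20638814	20840407
CEBPG	18	43905707	44112657
CISH	22	50220205	50425617
CTNNA1	7	51588098	51980519
CTNNA2	11	54622279	56182035
E2F1	13	63605710	63814008
FOXO3	9	41908606	42218673
IGFBP5	2	105278991	105497646
IL11	18	62461915	62664977
IL6	4	31478311	31682667
IL6ST	20	23112633	23370316
IRF1	7	23135653	23343697
JAK1	3	80675557	81015026
JAK2	8	39531342	39850796
LEF1	6	18235031	18550774
LIF	17	71313855	71518166
LIFR	20	35817479	36066671
MMP2	18	23728638	23955657
MMP3	15	5928011	6134595
MMP9	13	75366513	75573824
MYC	14	13669244	13874438
OSM	17	71334468	71537372
OSMR	20	35421410	35688186
TP53	19	27885495	28097841
PTEN	26	9398226	9695849
PTK2	14	3770893	4165010
RAF1	22	57022412	57304951
SFRP4	4	49909882	50120466
SOCS3	19	54358856	54559555
STAT3	19	42956660	43232624
STAT5A	19	42933597	43154075
STAT5B	19	42860226	43096671
TIMP3	5	71651415	71909052
N = 40			
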