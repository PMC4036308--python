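symbol	chrom	start	stop
AKT2	18	49804012	50050072
CSN1S1	6	87041556	87259096
CSN2	6	87079502	87288025
CISH	22	50220205	50425617
RAF1	22	57022412	57304951
ELF5	15	65724442	65954386
ERBB4	2	99560620	100097642
ESR1	9	89869586	90355801
GAL	29	46659818	46865617
GATA3	13	15884602	16102940
IGF2	29	49946626	50165230
IL6	4	31478311	31682667
IRS1	2	115690540	115894253
JAK2	8	39531342	39850796
NR3C1	7	56131970	56450496
PRL	23	35005135	35213759
PRLR	20	38973246	39237480
PTH	15	39628332	39830868
SOCS1	25	9875299	10075970
SOCS2	5	23423981	23628860
SOCS3	19	54358856	54559555
GH1	19	48668618	48872014
STAT3	19	42956660	43232624
STAT5A	19	42933597	43154075
STAT5B	19	42860226	43096671
TNFRSF11A	24	61139109	61375194
TNFSF11	12	12641069	12882474
N = 27			
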