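name	signal	site_id	annotation
ABRELATERD1	ACGTG	S000414	ABRE, etiolation, erd
GCN4OSGLUB1	TGAGTCA	S000277	GluB-1, glutelin, endosperm, seed, storage protein, GCN4 motif
TATABOX4	TATATAA	S000111	TATA, sporamin, phaseolin
CATATGGMSAUR	CATATG	S000370	SAUR, NDE, auxin
ASF1MOTIFCAMV	TGACG	S000024	TGACG, root, leaf, CaMV, 35S, promoter, auxin, salicylic acid
NTBBF1ARROLB	ACTTTA	S000273	rolB, Dof, auxin, domain B, root, shoot, meristem, vascular
ARFAT	TGTCTC	S000270	auxin, AuxRE, ARF, ARF1, Aux/IAA, SAUR, NDE, GH3, D1, D4
CAATBOX1	CAAT	S000028	CAAT, legA, seed
CCAATBOX1	CCAAT	S000030	HSE (Heat shock element), CCAAT box
HEXMOTIFTAH3H4	ACGTCA	S000053	hexamer, HBP-1A, HBP-1B, histone H3, CaMV, 35S, NOS, HBP-1
T/GBOXATPIN2	AACGTG	S000458	T/G-box, JA, pin2, LAP, MYC, wounding
TATCCAYMOTIFOSRAMY3D	TATCCAY	S000256	GATA, amylase, sugar, repression
LTRE1HVBLT49	CCGAAA	S000250	low temperature, LTRE
GT1CONSENSUS	GRWAAW	S000198	GT-1, light, TATA, TFIIA, TBP, HR, SAR, TMV, leaf, shoot
INRNTPSADB	YTCANTYY	S000395	initiater, light-responsive transcription, TATA-less promoter
TATCCAOSAMY	TATCCA	S000403	alpha-amylase, MYB proteins, gibberellin, GA, sugar starvation
TGACGTVMAMY	TGACGT	S000377	alpha-Amylase, cotyledon, seed germination, seed
ABREATCONSENSUS	YACGTGGC	S000406	ABA, ABF, bZIP factors
BOXIIPCCHS	ACGTGGC	S000229	Box II, Box 2, CHS, chs, light regulation
LRENPCABE	ACGTGGCA	S000231	CAB, cab, cab-E, CABE, light, leaf, shoot
WRKY71OS	TGAC	S000447	WRKY, GA, MYB, W box, TGAC, PR proteins
LTRECOREATCOR15	CCGAC	S000153	low temperature, cold, LTRE, drought, ABA, cor15a, BN115, leaf
TBOXATGAPB	ACTTTG	S000383	GAPB, glyceraldehyde-3-phosphate dehydrogenase, light-activated
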