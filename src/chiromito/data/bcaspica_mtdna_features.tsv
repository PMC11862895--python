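# Feature annotation of the Barbastella caspica mitochondrial genome (GenBank PP963575, 16933 bp, circular)
# Columns: Gene Category Strand Start End Anticodon StartCodon StopCodon ("-" = not applicable; StopCodon "T"/"TA" = truncated)
Gene	Category	Strand	Start	End	Anticodon	StartCodon	StopCodon
tRNA-Phe	tRNA	H	1	72	GAA	-	-
12S rRNA	rRNA	H	72	1031	-	-	-
tRNA-Val	tRNA	H	1032	1100	TAC	-	-
16S rRNA	rRNA	H	1101	2668	-	-	-
tRNA-Leu2	tRNA	H	2669	2743	TAA	-	-
ND1	PCG	H	2749	3705	-	ATG	TAA
tRNA-Ile	tRNA	H	3705	3772	GAT	-	-
tRNA-Gln	tRNA	L	3770	3843	TTG	-	-
tRNA-Met	tRNA	H	3844	3911	CAT	-	-
ND2	PCG	H	3912	4953	-	ATA	T
tRNA-Trp	tRNA	H	4954	5020	TCA	-	-
tRNA-Ala	tRNA	L	5028	5095	TGC	-	-
tRNA-Asn	tRNA	L	5096	5168	GTT	-	-
tRNA-Cys	tRNA	L	5200	5266	GCA	-	-
tRNA-Tyr	tRNA	L	5267	5332	GTA	-	-
COX1	PCG	H	5334	6878	-	ATG	TAA
tRNA-Ser2	tRNA	L	6882	6950	TGA	-	-
tRNA-Asp	tRNA	H	6958	7024	GTC	-	-
COX2	PCG	H	7025	7708	-	ATG	TAA
tRNA-Lys	tRNA	H	7711	7779	TTT	-	-
ATP8	PCG	H	7780	7983	-	ATG	TAA
ATP6	PCG	H	7941	8621	-	ATG	TAA
COX3	PCG	H	8621	9404	-	ATG	T
tRNA-Gly	tRNA	H	9404	9472	TCC	-	-
ND3	PCG	H	9472	9818	-	ATA	TA
tRNA-Arg	tRNA	H	9819	9889	TCG	-	-
ND4L	PCG	H	9891	10187	-	ATG	TAA
ND4	PCG	H	10181	11558	-	ATG	T
tRNA-His	tRNA	H	11559	11627	GTG	-	-
tRNA-Ser1	tRNA	H	11628	11686	GCT	-	-
tRNA-Leu1	tRNA	H	11688	11758	TAG	-	-
ND5	PCG	H	11759	13579	-	ATA	TAA
ND6	PCG	L	13563	14090	-	ATG	TAA
tRNA-Glu	tRNA	L	14091	14158	TTC	-	-
Cytb	PCG	H	14164	15303	-	ATG	AGA
tRNA-Thr	tRNA	H	15304	15375	TGT	-	-
tRNA-Pro	tRNA	L	15373	15441	TGG	-	-
D-loop	control	H	15442	16933	-	-	-
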