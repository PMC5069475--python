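name	kind	strand	start	end	anticodon	start_codon	stop_codon
tRNA-Ile	tRNA	J	1	65	GAT
tRNA-Gln	tRNA	N	63	131	TTG
tRNA-Met	tRNA	J	131	198	CAT
ND2	PCG	J	199	1170		ATT	TAA
tRNA-Trp	tRNA	J	1248	1310	TCA
tRNA-Cys	tRNA	N	1311	1372	GCA
tRNA-Tyr	tRNA	N	1373	1434	GTA
CO1	PCG	J	1436	2974		TTG	TAA
tRNA-Leu	tRNA	J	2970	3034	TAA
CO2	PCG	J	3035	3701		ATT	T-
tRNA-Lys	tRNA	J	3702	3772	CTT
tRNA-Asp	tRNA	J	3772	3834	GTC
ATPase8	PCG	J	3835	3990		ATT	TAA
ATPase6	PCG	J	3984	4658		ATG	TAA
CO3	PCG	J	4645	5431		ATG	T-
tRNA-Gly	tRNA	J	5432	5498	TCC
ND3	PCG	J	5499	5849		ATA	TAG
tRNA-Ala	tRNA	J	5848	5910	TGC
tRNA-Arg	tRNA	J	5910	5971	TCG
tRNA-Asn	tRNA	J	5972	6042	GTT
tRNA-Ser	tRNA	J	6042	6110	GCT
tRNA-Glu	tRNA	J	6110	6174	TTC
tRNA-Phe	tRNA	N	6174	6237	GAA
ND5	PCG	N	6237	7943		ATT	TAA
tRNA-His	tRNA	N	7944	8005	GTG
ND4	PCG	N	8006	9317		ATG	T-
ND4L	PCG	N	9311	9586		GTG	TAA
tRNA-Thr	tRNA	J	9589	9651	TGT
tRNA-Pro	tRNA	N	9652	9714	TGG
ND6	PCG	J	9717	10190		ATC	TAA
Cytb	PCG	J	10183	11316		ATG	TAG
tRNA-Ser	tRNA	J	11315	11384	TGA
ND1	PCG	N	11365	12321		ATT	TAA
tRNA-Leu	tRNA	N	12322	12386	TAG
16S	rRNA	N	12387	13637
tRNA-Val	tRNA	N	13638	13705	TAC
12S	rRNA	N	13706	14492
control_region	control_region	J	14493	16345
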