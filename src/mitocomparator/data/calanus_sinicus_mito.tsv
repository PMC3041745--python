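# topology: linear
# total_length: 20460
name	kind	strand	start	end	start_codon	stop_codon
rrnL	rRNA	H	2244	3382	.	.
trnV	tRNA	H	3383	3447	.	.
trnD	tRNA	H	3457	3518	.	.
trnT	tRNA	H	3531	3593	.	.
trnS2	tRNA	L	3594	3650	.	.
cox1	PCG	L	3660	5207	ATA	TAA
nad4L	PCG	H	5336	5671	ATA	TAG
cytb	PCG	L	5751	6887	ATG	TAA
nad6	PCG	L	6898	7377	ATT	TAG
rrnS	rRNA	L	7429	8082	.	.
trnG	tRNA	L	8083	8146	.	.
nad1	PCG	L	8147	9063	ATA	TA
trnF	tRNA	L	9064	9126	.	.
trnI	tRNA	L	9131	9193	.	.
nad5	PCG	H	9231	10954	ATT	TA
trnH	tRNA	H	10955	11017	.	.
trnA	tRNA	H	12788	12851	.	.
trnY	tRNA	H	12852	12912	.	.
trnE	tRNA	L	12908	12971	.	.
trnQ	tRNA	L	13002	13067	.	.
trnL1	tRNA	L	13080	13143	.	.
trnP	tRNA	L	13178	13240	.	.
trnM	tRNA	L	13246	13309	.	.
trnK	tRNA	L	13312	13374	.	.
trnW	tRNA	L	13376	13439	.	.
trnS1	tRNA	L	13439	13498	.	.
trnN	tRNA	L	13498	13565	.	.
cox2	PCG	L	13571	14275	ATT	TAA
nad3	PCG	H	14338	14691	ATT	TAA
cox3	PCG	L	14794	15585	ATG	TAA
nad4	PCG	H	16357	17658	ATA	TAA
trnL2	tRNA	H	17663	17728	.	.
nad2	PCG	H	17729	18697	ATA	TAA
atp8	PCG	H	18870	19031	ATT	TAA
atp6	PCG	H	19034	19744	ATG	TAG
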