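# Printed per-row annotation bookkeeping of the C. sinicus mitogenome contig:
# declared gene lengths, upstream intergenic spacers (negative = overlap) and
# per-gene composition, exactly as published. "intergenic" is the spacer
# immediately upstream (5' on the reference strand) of the named feature;
# ">2959(LNR1)" for rrnL marks the open, incompletely sequenced region split
# across the contig head and tail. Used by validate_table audits.
name	length	intergenic	lnr	at_pct	gc_skew	at_skew
rrnL	1139	open:2959	LNR1	71.7	0.0567	0.0126
trnV	65	3	.	83.1	-0.0888	0.0734
trnD	62	9	.	80.6	0.165	0.000
trnT	63	12	.	74.6	-0.126	-0.0643
trnS2	57	0	.	73.7	0.202	0.0475
cox1	1548	9	.	59.0	0.0439	-0.190
nad4L	336	128	LNR2	61.9	0.0919	-0.202
cytb	1137	79	.	60.2	-0.0050	-0.249
nad6	480	10	.	62.3	0.0822	-0.149
rrnS	654	51	.	73.1	0.264	0.0369
trnG	64	3	.	87.6	0.000	0.000
nad1	917	0	.	62.5	0.000	-0.174
trnF	63	0	.	66.6	0.237	0.000
trnI	63	4	.	58.7	0.153	0.0801
nad5	1724	37	.	59.5	0.0272	-0.109
trnH	63	0	.	69.8	0.369	0.0917
trnA	64	1770	LNR3	67.2	0.0488	-0.164
trnY	61	0	.	60.6	0.000	-0.0264
trnE	64	-5	.	68.7	0.000	0.0451
trnQ	66	30	.	77.5	0.604	-0.102
trnL1	64	12	.	80.1	0.431	0.104
trnP	63	34	.	76.2	0.202	-0.0420
trnM	64	5	.	68.7	-0.0990	0.0917
trnK	63	2	.	68.2	-0.101	0.0235
trnW	64	1	.	78.1	-0.142	0.0807
trnS1	60	-1	.	77.0	-0.144	-0.0208
trnN	68	-1	.	61.8	-0.154	0.0485
cox2	705	5	.	62.6	0.0749	-0.166
nad3	354	62	.	61.3	0.183	-0.318
cox3	792	102	LNR4	57.1	0.0536	-0.208
nad4	1302	771	LNR5	59.9	-0.0697	-0.142
trnL2	66	4	.	69.7	0.102	0.174
nad2	969	0	.	61.9	-0.0761	-0.202
atp8	162	172	LNR6	70.4	-0.0811	-0.122
atp6	711	2	.	59.5	-0.0963	-0.126
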