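# Published per-gene divergence of mitochondrial genes among five copepod
# species (between-group: DB, omega_B) and 11 C. sinicus individuals
# (within-group: DW, omega_W). "NA" = not computable for that cell
# (atp8 omega_B: saturated; RNA genes: no codons).
gene	DB	omegaB	DW	omegaW
atp6	0.557	0.0736	0.00102	0.157
atp8	0.519	NA	0.00314	0.000
cox1	0.238	0.0283	0.00115	0.000
cox2	0.488	0.0369	0.00098	0.885
cox3	0.372	0.0074	0.00211	0.000
cytb	0.395	0.0026	0.00070	0.000
nad1	0.528	0.0926	0.00115	0.159
nad2	0.753	0.0100	0.00255	0.222
nad3	0.581	0.0923	0.00103	0.358
nad4	0.668	0.0534	0.00184	0.914
nad4L	0.768	0.0617	0.000	0.000
nad5	0.625	0.0306	0.00173	0.279
nad6	0.732	0.0087	0.00333	0.435
rrnS	0.405	NA	0.00078	NA
rrnL	0.409	NA	0.00163	NA
tRNA	NA	NA	0.00060	NA
overall	0.525	0.0490	0.00150	0.203
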