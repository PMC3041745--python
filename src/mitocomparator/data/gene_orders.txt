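# Signed circular mitochondrial gene orders, one genome per line:
#   name: gene1 -gene2 gene3 ...       (leading '-' = opposite strand)
# "arthropod_ground" is the putative ancestral arthropod arrangement
# (Limulus-like); "arthropod_ground_major" restricts it to protein-coding
# and rRNA genes for tRNA-free comparisons.
arthropod_ground: trnI -trnQ trnM nad2 trnW -trnC -trnY cox1 trnL2 cox2 trnK trnD atp8 atp6 cox3 trnG nad3 trnA trnR trnN trnS1 trnE -trnF -nad5 -trnH -nad4 -nad4L trnT -trnP nad6 cytb trnS2 -nad1 -trnL1 -rrnL -trnV -rrnS
arthropod_ground_major: cox1 cox2 atp8 atp6 cox3 nad3 -nad5 -nad4 -nad4L nad6 cytb -nad1 -rrnL -rrnS
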