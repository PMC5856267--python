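# Putative ancestral organisations of the mitochondrial protein-coding and
# ribosomal RNA genes at deep bilaterian nodes (hypothetical taxonomic
# units inferred from gene-order parsimony).
ancestral_01	cox1 cox2 atp8 atp6 cox3 nad3 -nad5 -nad4 -nad4L nad6 cob rrnS rrnL nad1 nad2
ancestral_02	cox1 cox2 atp8 atp6 -nad5 -nad4 -nad4L nad6 cob rrnS rrnL nad1 cox3 nad3 nad2
ancestral_03	cox1 cox2 atp8 atp6 -nad5 -nad4 -nad4L nad6 cob -nad3 -cox3 rrnS rrnL nad1 nad2
ancestral_04	cox1 cox2 atp8 atp6 nad6 cob nad4L nad4 nad5 -nad3 -cox3 rrnS rrnL nad1 nad2
ancestral_05	cox1 cox2 atp8 atp6 cox3 nad3 -nad5 -nad4 -nad4L -cob -nad6 -nad1 -rrnL -rrnS nad2
ancestral_06	cox1 cox2 atp8 atp6 cox3 nad3 nad4L nad4 nad5 -nad6 cob -nad1 -rrnL -rrnS nad2
ancestral_07	cox1 cox2 atp8 atp6 -nad5 -nad4 -nad4L nad6 cob -nad1 -rrnL -rrnS cox3 nad3 nad2
ancestral_08	cox1 cox2 atp8 atp6 cox3 nad3 -nad5 -nad4 -nad4L -cob nad6 rrnS rrnL nad1 nad2
ancestral_09	cox1 cox2 atp8 atp6 cox3 nad3 rrnS rrnL nad1 -cob nad6 -nad5 -nad4 -nad4L nad2
ancestral_10	cox1 cox2 atp8 atp6 cox3 nad3 rrnS rrnL nad1 nad6 cob nad4L nad4 nad5 nad2
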