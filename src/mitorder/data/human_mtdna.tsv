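# Human mitochondrial protein-coding and rRNA gene order (tRNAs omitted),
# written in canonical linear representation (anchored at cox1, + strand).
Homo_sapiens	cox1 cox2 atp8 atp6 cox3 nad3 nad4L nad4 nad5 -nad6 cob rrnS rrnL nad1 nad2
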