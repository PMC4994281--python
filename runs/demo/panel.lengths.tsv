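chrom	length_morgan
chr1	0.640000
chr2	0.122000
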