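# Restriction enzymes used for CAPS genotyping of the two desaturase loci.
# cut_offset: 0-based offset of the top-strand cut from the first site base.
# BssSI (= BssSalphaI): C^ACGAG; HinfI: G^ANTC.
name	recognition	cut_offset
BssSI	CACGAG	1
HinfI	GANTC	1
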