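# Genotype-class oleic-acid (C18:1, % of total fatty acids) means for the
# F2 progeny of a high-oleic (aabb) x normal (AABB) rapeseed cross grown at
# two field sites. Locus 1 = chromosome-A5 desaturase (A/a), locus 2 = C5 (B/b).
trial	location	genotype	n_lines	c18_1_mean	c18_1_sd
F2-1	Nanjing	AABB	16	63.1	2.0
F2-1	Nanjing	AABb	28	66.8	1.0
F2-1	Nanjing	AaBB	30	66.9	1.6
F2-1	Nanjing	AAbb	15	69.8	2.4
F2-1	Nanjing	aaBB	15	69.5	1.8
F2-1	Nanjing	AaBb	58	73.7	2.0
F2-1	Nanjing	aaBb	27	77.6	1.8
F2-1	Nanjing	Aabb	29	78.1	2.3
F2-1	Nanjing	aabb	14	84.9	1.5
F2-1	Wuhan	AABB	15	63.3	1.9
F2-1	Wuhan	AABb	26	67.1	1.7
F2-1	Wuhan	AaBB	26	67.0	1.9
F2-1	Wuhan	AAbb	12	70.0	2.0
F2-1	Wuhan	aaBB	13	70.3	1.9
F2-1	Wuhan	AaBb	60	74.2	2.0
F2-1	Wuhan	aaBb	30	78.2	1.9
F2-1	Wuhan	Aabb	27	79.0	2.2
F2-1	Wuhan	aabb	15	85.1	1.4
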