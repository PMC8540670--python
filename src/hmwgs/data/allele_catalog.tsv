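locus	subunits	symbol	display	reference_count
Glu-A1	1Ax1	Glu-A1a	1	418
Glu-A1	1Ax2*	Glu-A1b	2*	774
Glu-A1		Glu-A1c	Null	595
Glu-B1	1Bx6	Glu-B1-1d	6	8
Glu-B1	1Bx6;1By8*	Glu-B1ca	6 + 8*	65
Glu-B1	1Bx7	Glu-B1a	7	64
Glu-B1	1Bx7;1By8	Glu-B1b	7 + 8	473
Glu-B1	1Bx7;1By8*	Glu-B1ce	7 + 8*	219
Glu-B1	1Bx7;1By9	Glu-B1c	7 + 9	503
Glu-B1	1Bx7OE;1By8*	Glu-B1al	7OE + 8*	33
Glu-B1	1Bx7OE;1By9	unknown	7OE + 9	2
Glu-B1	1By8	Glu-B1aj	8	1
Glu-B1	1By8*	Glu-B1-2o	8*	1
Glu-B1	1By9	Glu-B1-2b	9	1
Glu-B1	1Bx13;1By16	Glu-B1f	13 + 16	67
Glu-B1	1Bx14;1By15	Glu-B1h	14 + 15	2
Glu-B1	1By15	Glu-B1-2e	15	7
Glu-B1	1Bx17;1By18	Glu-B1i	17 + 18	219
Glu-B1	1By20y	Glu-B1-2z	20y	2
Glu-B1	1Bx20x;1By20y	Glu-B1e	20 + 20	120
Glu-D1	1Dx2;1Dy12	Glu-D1a	2 + 12	758
Glu-D1	1Dx2	Glu-D1k	2	1
Glu-D1	1Dx2.2;1Dy12	Glu-D1f	2.2 + 12	150
Glu-D1	1Dx4;1Dy12	Glu-D1c	4 + 12	38
Glu-D1	1Dx5	Glu-D1-1d	5	2
Glu-D1	1Dx5;1Dy10	Glu-D1d	5 + 10	837
Glu-D1	1Dy12	Glu-D1l	12	1
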