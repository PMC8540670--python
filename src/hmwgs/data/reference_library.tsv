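subunit	locus	family	mean_rt_min	rsd_pct
1Ax1	Glu-A1	Ax	5.373	0.25
1Ax2*	Glu-A1	Ax	5.240	0.22
1Bx6	Glu-B1	Bx	4.560	0.19
1Bx7	Glu-B1	Bx	4.670	0.42
1Bx7OE	Glu-B1	Bx	4.630	0.35
1Bx13	Glu-B1	Bx	4.230	0.10
1Bx14	Glu-B1	Bx	4.670	0.16
1Bx17	Glu-B1	Bx	4.710	0.27
1Bx20x	Glu-B1	Bx	5.090	0.11
1By8	Glu-B1	By	4.110	0.24
1By8*	Glu-B1	By	3.740	0.31
1By9	Glu-B1	By	3.750	0.12
1By15	Glu-B1	By	3.720	0.17
1By16	Glu-B1	By	3.960	0.14
1By18	Glu-B1	By	3.730	0.23
1By20y	Glu-B1	By	3.700	0.07
1Dx2	Glu-D1	Dx	4.440	0.26
1Dx2.2	Glu-D1	Dx	4.310	0.11
1Dx4	Glu-D1	Dx	4.480	0.12
1Dx5	Glu-D1	Dx	4.340	0.32
1Dy10	Glu-D1	Dy	3.000	0.39
1Dy12	Glu-D1	Dy	2.970	0.33
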