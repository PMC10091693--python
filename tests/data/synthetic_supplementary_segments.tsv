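sample	chrom	start	end	call	mean_logr	mcf	n_probes	gene
CDKN2A_P8	chr7	85000001	87000000	loss	-1.0	1.0	40	MAGI2
CDKN2A_P8	chr9	25000001	27500000	gain	0.58	1.0	50	CNTLN
CDKN2A_P8	chr1	1	249000000	neutral	0.0		4980
CDKN2A_P16	chr7	85000001	87000000	loss	-1.0	1.0	40	MAGI2
CDKN2A_P16	chr9	25000001	27500000	gain	0.58	1.0	50	CNTLN
CDKN2A_P24	chr7	85050001	87000000	loss	-1.0	1.0	39	MAGI2
CDKN2A_P24	chr9	25000001	27450000	gain	0.58	1.0	49	CNTLN
RB1_P8	chr3	158000001	158800000	loss	-1.0	1.0	16	RSRC1
RB1_P8	chr16	78000001	78600000	gain	0.58	1.0	12	WWOX
RB1_P16	chr3	158000001	158800000	loss	-1.0	1.0	16	RSRC1
RB1_P16	chr16	78000001	78600000	gain	0.58	1.0	12	WWOX
RB1_P24	chr3	158000001	158800000	loss	-1.0	1.0	16	RSRC1
RB1_P24	chr16	78050001	78600000	gain	0.58	1.0	11	WWOX
RB1_P24	chr2	1	242000000	neutral	0.0		4840
TP53_P8	chr3	158000001	158800000	loss	-1.0	1.0	16	RSRC1
TP53_P8	chr16	78000001	78600000	gain	0.58	1.0	12	WWOX
TP53_P8	chr6	60000001	66000000	complex	0.2		120
TP53_P16	chr3	158000001	158800000	loss	-1.0	1.0	16	RSRC1
TP53_P16	chr16	78000001	78600000	gain	0.58	1.0	12	WWOX
TP53_P16	chr6	60000001	66000000	complex	0.2		120
TP53_P16	chr4	10000001	35000000	loss	-0.3	0.45	500
TP53_P24	chr3	158000001	158800000	loss	-1.0	1.0	16	RSRC1
TP53_P24	chr16	78000001	78600000	gain	0.58	1.0	12	WWOX
TP53_P24	chr6	60000001	66000000	complex	0.2		120
TP53_P24	chr4	10000001	35000000	loss	-0.45	0.72	500
TP53_P24	chr11	40000001	48000000	gain	0.26	0.35	160
WT_P5	chr12	50000001	53000000	loss	-0.9	0.95	60
WT_P45	chr12	50000001	53000000	loss	-0.9	0.97	60
WT_P45	chr20	1000001	4000000	gain	0.55	0.93	60
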