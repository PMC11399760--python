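trait	gene	mask	n_var	p_burden	p_skat
FG	G6PC	NSbroad	9	1.41e-6	1.32e-5
FG	G6PC	NSstrict	3	1.41e-3	7.43e-4
FI	G6PC	NSbroad	8	1.62e-6	8.58e-6
FI	G6PC	NSstrict	3	1.85e-3	7.80e-3
HbA1c	TF	NSbroad	10	2.15e-6	5.98e-3
HbA1c	TF	NSstrict	3	5.48e-2	5.48e-2
FG	MAP3K15	NSbroad	18	1.86e-25	1.07e-18
FG	MAP3K15	NSstrict	7	1.34e-14	4.01e-11
HbA1c	MAP3K15	NSbroad	18	1.27e-7	1.53e-4
HbA1c	MAP3K15	NSstrict	7	2.65e-4	9.46e-3
FG	G6PC2	NSbroad	18	4.09e-67	5.38e-58
FG	G6PC2	NSstrict	7	7.8e-69	3.83e-56
HbA1c	G6PC2	NSbroad	18	6.18e-30	4.65e-27
HbA1c	G6PC2	NSstrict	7	1.04e-31	1.92e-26
FG	SLC30A8	NSbroad	13	5.69e-4	6.42e-11
FG	SLC30A8	NSstrict	7	6.55e-11	3.74e-10
HbA1c	SLC30A8	NSbroad	12	7.20e-8	2.18e-5
HbA1c	SLC30A8	NSstrict	6	5.66e-8	3.22e-6
FG	VPS13C	NSbroad	52	9.66e-6	3.73e-7
FG	VPS13C	NSstrict	26	1.27e-5	1.44e-5
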