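abbrev	d_alleles	nd_alleles
Nterm	1	1
TM1	4	5
Ic1	3	2
TM2	16	2
Ec1	0	1
TM3	7	6
Ic2	4	0
TM4	1	0
Ec2	0	0
TM5	9	0
Ic3	2	1
TM6	2	0
Ec3	1	1
TM7	11	2
Cterm	2	1
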