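name	abbrev	start	end	compartment
N-terminus	Nterm	1	37	extracellular
Transmembrane 1	TM1	38	63	transmembrane
Intracellular 1	Ic1	64	72	intracellular
Transmembrane 2	TM2	73	100	transmembrane
Extracellular 1	Ec1	101	115	extracellular
Transmembrane 3	TM3	116	143	transmembrane
Intracellular 2	Ic2	144	162	intracellular
Transmembrane 4	TM4	163	183	transmembrane
Extracellular 2	Ec2	184	192	extracellular
Transmembrane 5	TM5	193	218	transmembrane
Intracellular 3	Ic3	219	236	intracellular
Transmembrane 6	TM6	237	265	transmembrane
Extracellular 3	Ec3	266	276	extracellular
Transmembrane 7	TM7	277	299	transmembrane
C-terminus	Cterm	300	317	intracellular
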