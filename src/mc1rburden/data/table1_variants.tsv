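cdna	protein	case_alleles	control_alleles	predicted_damaging	rare	novel
c.100C>T	p.R34W	0	1	no	yes	yes
c.104G>A	p.C35Y	1	0	yes	yes	no
c.112G>A	p.V38M	2	3	no	yes	no
c.122C>G	p.S41C	0	2	yes	yes	yes
c.133T>C	p.F45L	2	0	yes	yes	no
c.178G>T	p.V60L	359	254	yes	no	no
c.199C>T	p.R67W	0	2	yes	yes	no
c.200G>A	p.R67Q	1	1	no	yes	no
c.205C>G	p.L69V	0	1	yes	yes	yes
c.241G>C	p.A81P	1	0	yes	yes	no
c.247T>C	p.S83P	5	1	yes	yes	no
c.252C>A	p.D84E	23	13	rhc	no	no
c.274G>A	p.V92M	188	113	yes	no	no
c.284C>T	p.T95M	6	2	yes	yes	no
c.296T>C	p.L99P	1	0	yes	yes	yes
c.310G>A	p.G104S	0	1	yes	yes	no
c.350A>T	p.D117V	1	0	yes	yes	yes
c.359T>C	p.I120T	1	0	yes	yes	no
c.364G>A	p.V122M	1	4	no	yes	no
c.373T>C	p.C125R	1	0	yes	yes	no
c.389C>T	p.S130F	1	0	yes	yes	yes
c.415G>A	p.A139T	1	0	yes	yes	no
c.417G>A	p.V140M	1	0	no	yes	yes
c.419T>G	p.V140G	0	1	yes	yes	yes
c.424C>T	p.R142C	1	0	yes	yes	no
c.425G>A	p.R142H	29	13	rhc	no	no
c.451C>T	p.R151C	211	76	rhc	no	no
c.456C>A	p.Y152X	1	0	yes	yes	no
c.464T>C	p.I155T	35	14	yes	no	no
c.467T>C	p.V156A	0	1	yes	yes	no
c.478C>T	p.R160W	152	59	rhc	no	no
c.479G>A	p.R160Q	2	0	yes	yes	no
c.488G>A	p.R163Q	75	57	yes	no	no
c.512C>A	p.A171D	0	1	yes	yes	no
c.613G>C	p.V205L	1	0	yes	yes	yes
c.637C>T	p.R213W	3	4	yes	yes	no
c.652G>A	p.A218T	0	1	yes	yes	no
c.664G>T	p.A222S	1	0	no	yes	yes
c.667C>T	p.R223W	1	0	yes	yes	yes
c.707G>A	p.G236D	1	0	yes	yes	yes
c.766C>T	p.P256S	1	1	yes	yes	no
c.801C>A	p.C267X	1	0	yes	yes	yes
c.820G>A	p.G274S	1	0	no	yes	no
c.832A>G	p.K278E	3	1	yes	yes	no
c.842A>G	p.N281S	0	1	yes	yes	no
c.853G>A	p.A285T	1	0	no	yes	yes
c.854C>G	p.A285G	1	0	yes	yes	yes
c.861C>G	p.I287M	2	0	yes	yes	no
c.865T>C	p.C289R	0	1	yes	yes	no
c.880G>C	p.D294H	85	35	rhc	no	no
c.892T>C	p.Y298H	1	0	yes	yes	no
c.895G>A	p.A299T	1	0	yes	yes	no
c.917G>A	p.R306H	1	0	yes	yes	no
c.928A>C	p.K310Q	1	0	no	yes	yes
c.951G>T	p.W317C	0	1	yes	yes	yes
c.86_87insA		4	0	yes	yes	no
c.481_482insG		1	0	yes	yes	yes
c.524_525insT		1	0	yes	yes	yes
c.366G>A	p.V122V	1	0	no	yes	no
c.414C>T	p.I138I	0	1	no	yes	no
c.426C>A	p.R142R	0	2	no	yes	yes
c.471C>T	p.T157T	0	1	no	yes	yes
c.477G>C	p.P159P	0	1	no	yes	yes
c.478C>A	p.R160R	1	0	no	yes	no
c.483G>A	p.A161A	0	1	no	yes	no
c.504C>T	p.I168I	0	1	no	yes	no
c.531G>A	p.T177T	1	1	no	yes	no
c.537C>T	p.F179F	0	1	no	yes	yes
c.621C>T	p.Y207Y	0	1	no	yes	no
c.690G>C	p.P230P	0	3	no	yes	no
c.699G>A	p.Q233Q	6	10	no	yes	no
c.792C>T	p.I264I	0	4	no	yes	no
c.828C>T	p.I276I	0	1	no	yes	no
c.873C>T	p.A291A	1	0	no	yes	yes
c.894C>T	p.Y298Y	0	2	no	yes	no
c.900C>T	p.F300F	1	4	no	yes	no
c.927C>G	p.L309L	1	0	no	yes	yes
c.942A>G	p.T314T	249	170	no	no	no
c.948C>T	p.S316S	5	5	no	yes	no
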