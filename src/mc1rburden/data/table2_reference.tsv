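case_chromosomes	control_chromosomes	reference_case	reference_control
2262	1738	936	976
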