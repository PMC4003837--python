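# Example cohort specification mirroring the observed study structure:
# 1131 melanoma cases, 869 controls; pooled variant classes at their
# estimated control-population frequencies with their estimated allele
# odds ratios.  Covariate levels are ordinal probabilities (codes 1..k).

n_cases = 1131
n_controls = 869
baseline_prevalence = 0.10
genetic_coding = "dosage"

[[allele]]
variant_id = "R_pool"
class = "R"
control_frequency = 0.11
codon = 151

[[allele]]
variant_id = "r_pool"
class = "frequent_r"
control_frequency = 0.39
codon = 60

[[allele]]
variant_id = "D_pool"
class = "rare_r_D"
control_frequency = 0.012
codon = 95

[[allele]]
variant_id = "nD_pool"
class = "rare_r_nD"
control_frequency = 0.006
codon = 122

[class_odds_ratios]
R = 2.66
frequent_r = 1.51
rare_r_D = 2.38
rare_r_nD = 1.0

[covariate_levels]
hair_colour = [0.15, 0.45, 0.30, 0.10]
eye_colour = [0.35, 0.35, 0.30]
skin_type = [0.10, 0.30, 0.40, 0.20]
nevus_count = [0.40, 0.35, 0.18, 0.07]

[age_class_means]
rare_r_D = 45.0
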