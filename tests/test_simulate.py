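import numpy as np
import pytest

from mc1rburden.association import odds_ratio, paf
from mc1rburden.multivariate import SubjectRecord
from mc1rburden.simulate import (
    AlleleSpec,
    SimulationSpec,
    class_contingencies,
    counts_from_subjects,
    null_spec,
    simulate_cohort,
    table2_spec,
)


class TestSpecValidation:
    def test_frequencies_summing_past_one_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            SimulationSpec(
                n_cases=10,
                n_controls=10,
                allele_catalog=(
                    AlleleSpec("a", "R", 0.6, 10),
                    AlleleSpec("b", "frequent_r", 0.5, 20),
                ),
                class_odds_ratios={},
            )

    def test_negative_or_rejected(self):
        with pytest.raises(ValueError):
            SimulationSpec(
                n_cases=10,
                n_controls=10,
                allele_catalog=(AlleleSpec("a", "R", 0.1, 10),),
                class_odds_ratios={"R": -2.0},
            )

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            SimulationSpec(
                n_cases=0,
                n_controls=10,
                allele_catalog=(),
                class_odds_ratios={},
            )


class TestSimulateCohort:
    def test_exact_group_sizes(self):
        spec = table2_spec(n_cases=150, n_controls=100)
        subjects = simulate_cohort(spec, seed=5)
        assert sum(s.is_case for s in subjects) == 150
        assert sum(not s.is_case for s in subjects) == 100

    def test_seed_makes_output_identical(self):
        spec = table2_spec(n_cases=120, n_controls=90, seed=17)
        assert simulate_cohort(spec) == simulate_cohort(spec)

    def test_different_seeds_differ(self):
        spec = table2_spec(n_cases=120, n_controls=90)
        assert simulate_cohort(spec, seed=1) != simulate_cohort(spec, seed=2)

    def test_at_most_one_variant_per_haplotype(self):
        spec = table2_spec(n_cases=200, n_controls=200)
        for s in simulate_cohort(spec, seed=8):
            assert len(s.haplotype1) <= 1 and len(s.haplotype2) <= 1

    def test_cases_get_diagnosis_age_controls_do_not(self):
        spec = table2_spec(n_cases=50, n_controls=50)
        for s in simulate_cohort(spec, seed=9):
            assert (s.age_at_diagnosis is not None) == s.is_case


class TestCountsFromSubjects:
    def test_hand_countable_example(self):
        subjects = [
            SubjectRecord("c1", "case", haplotype1=("R151C",)),
            SubjectRecord("c2", "case", haplotype1=("R151C",)),
            SubjectRecord("k1", "control"),
            SubjectRecord("k2", "control"),
        ]
        counts, cohort = counts_from_subjects(subjects, {"R151C": "R"})
        assert counts.loc[0, "case_alleles"] == 2
        assert cohort.reference_case == 2  # the two variant-free case haplotypes
        assert cohort.reference_control == 4

    def test_synonymous_only_haplotypes_count_as_reference(self):
        subjects = [
            SubjectRecord("c1", "case", haplotype1=("T314T",)),
            SubjectRecord("k1", "control", haplotype2=("T314T",)),
        ]
        _, cohort = counts_from_subjects(
            subjects, {"T314T": "synonymous_frequent"}
        )
        assert cohort.reference_case == 2
        assert cohort.reference_control == 2

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            counts_from_subjects([], {})

    def test_unknown_variant_id_rejected(self):
        subjects = [SubjectRecord("c1", "case", haplotype1=("mystery",))]
        with pytest.raises(ValueError, match="mystery"):
            counts_from_subjects(subjects, {"R151C": "R"})


class TestCalibration:
    def test_simulate_then_count_recovers_frequencies(self):
        spec = table2_spec(n_cases=600, n_controls=600)
        class_of = {a.variant_id: a.klass for a in spec.allele_catalog}
        subjects = simulate_cohort(spec, seed=23)
        counts, cohort = counts_from_subjects(subjects, class_of)
        by_id = counts.set_index("variant_id")
        for allele in spec.allele_catalog:
            f = allele.control_frequency
            sd = np.sqrt(f * (1 - f) / cohort.control_chromosomes)
            observed = (
                by_id.loc[allele.variant_id, "control_alleles"]
                / cohort.control_chromosomes
                if allele.variant_id in by_id.index
                else 0.0
            )
            assert observed == pytest.approx(f, abs=4 * sd + 1e-3)

    def test_control_frequency_estimator_unbiased(self):
        """Mean absolute error of the control-side frequency over many
        seeds stays below twice the binomial standard deviation."""
        spec = table2_spec(n_cases=300, n_controls=300)
        class_of = {a.variant_id: a.klass for a in spec.allele_catalog}
        f = 0.11  # generating R-class frequency
        errors = []
        for seed in range(100):
            subjects = simulate_cohort(spec, seed=seed)
            counts, cohort = counts_from_subjects(subjects, class_of)
            row = counts.set_index("variant_id")
            obs = row.loc["R_pool", "control_alleles"] / cohort.control_chromosomes
            errors.append(abs(obs - f))
        assert np.mean(errors) < 2 * np.sqrt(f * (1 - f) / 600)

    def test_null_spec_odds_ratios_near_one(self):
        """Under a null spec the common-class OR estimates stay inside
        [0.8, 1.25] in at least 90% of seeds.  (The rare classes carry only
        a couple of dozen alleles at this cohort size, so their log-OR
        sampling deviation ~0.3 makes that band unattainable for them by
        binomial arithmetic; they are checked for symmetry around 1.)"""
        spec = null_spec(2000, 2000)
        class_of = {a.variant_id: a.klass for a in spec.allele_catalog}
        hits = 0
        seeds = 50
        rare_log_ors = []
        for seed in range(seeds):
            subjects = simulate_cohort(spec, seed=seed)
            counts, cohort = counts_from_subjects(subjects, class_of)
            ts = class_contingencies(counts, cohort)
            common = [odds_ratio(ts[k]) for k in ("R", "frequent_r")]
            hits += all(0.8 <= o <= 1.25 for o in common)
            if "rare_r_D" in ts:
                rare_log_ors.append(np.log(odds_ratio(ts["rare_r_D"])))
        assert hits / seeds >= 0.9
        assert abs(np.mean(rare_log_ors)) < 0.15

    def test_paf_distribution_covers_generating_value(self):
        """Simulating at the generating (p = 0.11, OR = 2.66) R class, the
        estimated PAF distribution covers 0.158 inside its central 90%."""
        spec = table2_spec(n_cases=400, n_controls=300)
        class_of = {a.variant_id: a.klass for a in spec.allele_catalog}
        pafs = []
        for seed in range(40):
            subjects = simulate_cohort(spec, seed=seed)
            counts, cohort = counts_from_subjects(subjects, class_of)
            t = class_contingencies(counts, cohort)["R"]
            pafs.append(paf(t.b / cohort.control_chromosomes, odds_ratio(t)))
        lo, hi = np.quantile(pafs, [0.05, 0.95])
        assert lo <= 0.158 <= hi
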