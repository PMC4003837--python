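import math
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mc1rburden.association import (
    AlleleContingency,
    adjust_pvalues,
    associate,
    fisher_exact_two_sided,
    odds_ratio,
    paf,
    pool_counts,
    woolf_ci,
)
from mc1rburden.classify import NON_RHC_CLASSES, RARE_R_CLASSES, VariantClass
from mc1rburden.pipeline import PAPER_CLASS_OVERRIDES, apply_class_overrides


def enumerate_fisher_p(a: int, b: int, c: int, d: int) -> float:
    """Independent oracle: exhaustive enumeration over all 2x2 tables with
    the observed margins, summing hypergeometric probabilities no larger
    than the observed table's (exact integer arithmetic throughout)."""
    r1, r2, m = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, m)
    lo, hi = max(0, m - r2), min(r1, m)
    weights = {k: comb(r1, k) * comb(r2, m - k) for k in range(lo, hi + 1)}
    obs = weights[a]
    return sum(w for w in weights.values() if w <= obs) / denom


class TestOddsRatio:
    @pytest.mark.parametrize(
        "table, expected",
        [
            ((500, 196, 936, 976), 2.66),
            ((35, 14, 936, 976), 2.61),
            ((10, 10, 100, 100), 1.0),
        ],
    )
    def test_cross_product_examples(self, table, expected):
        assert odds_ratio(AlleleContingency(*table)) == pytest.approx(
            expected, abs=0.005
        )

    def test_zero_reference_undefined(self):
        with pytest.raises(ValueError):
            odds_ratio(AlleleContingency(5, 5, 0, 0))

    def test_haldane_correction_on_zero_cell(self):
        t = AlleleContingency(5, 0, 100, 100)
        assert t.needs_correction
        assert odds_ratio(t) == pytest.approx((5.5 * 100.5) / (0.5 * 100.5))


class TestWoolfCI:
    def test_matches_closed_form(self):
        t = AlleleContingency(500, 196, 936, 976)
        lo, hi = woolf_ci(t, 0.95)
        log_or = math.log((500 * 976) / (196 * 936))
        se = math.sqrt(1 / 500 + 1 / 196 + 1 / 936 + 1 / 976)
        assert lo == pytest.approx(math.exp(log_or - 1.959963984540054 * se))
        assert hi == pytest.approx(math.exp(log_or + 1.959963984540054 * se))
        # frozen evaluation of the formula
        assert (lo, hi) == (pytest.approx(2.204, abs=1e-3), pytest.approx(3.210, abs=1e-3))

    def test_d_class_interval(self):
        lo, hi = woolf_ci(AlleleContingency(48, 21, 936, 976), 0.95)
        assert (lo, hi) == (pytest.approx(1.416, abs=1e-3), pytest.approx(4.011, abs=1e-3))

    def test_symmetric_table_contains_one(self):
        lo, hi = woolf_ci(AlleleContingency(10, 10, 100, 100), 0.95)
        assert lo < 1 < hi

    def test_bad_level_rejected(self):
        with pytest.raises(ValueError):
            woolf_ci(AlleleContingency(1, 1, 1, 1), 1.5)


class TestFisherExact:
    def test_rare_r_row(self):
        p = fisher_exact_two_sided(AlleleContingency(57, 31, 936, 976))
        assert p == pytest.approx(0.004, abs=0.001)

    def test_identical_margins(self):
        assert fisher_exact_two_sided(AlleleContingency(5, 5, 50, 50)) == 1.0

    def test_never_exactly_zero(self):
        assert fisher_exact_two_sided(AlleleContingency(500, 0, 0, 500)) > 0.0

    @given(
        a=st.integers(0, 12),
        b=st.integers(0, 12),
        c=st.integers(0, 12),
        d=st.integers(0, 12),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_enumeration_oracle(self, a, b, c, d):
        if a + b < 1 or (c == 0 and d == 0):
            return
        t = AlleleContingency(a, b, c, d)
        assert fisher_exact_two_sided(t) == pytest.approx(
            enumerate_fisher_p(a, b, c, d), rel=1e-9, abs=1e-12
        )


class TestPaf:
    def test_pooled_r_class(self):
        assert 100 * paf(196 / 1738, 2.66) == pytest.approx(15.8, abs=0.05)

    def test_null_odds_ratio(self):
        assert paf(0.37, 1.0) == 0.0

    def test_d_class(self):
        assert 100 * paf(21 / 1738, 2.38) == pytest.approx(1.6, abs=0.05)

    def test_preventive_allele_negative(self):
        assert paf(0.2, 0.5) < 0

    @given(
        p1=st.floats(0.01, 0.9),
        p2=st.floats(0.01, 0.9),
        or1=st.floats(1.01, 50),
        or2=st.floats(1.01, 50),
    )
    @settings(max_examples=100, deadline=None)
    def test_strictly_increasing_and_bounded(self, p1, p2, or1, or2):
        lo_p, hi_p = sorted((p1, p2))
        lo_or, hi_or = sorted((or1, or2))
        assert paf(hi_p, hi_or) < 1
        if hi_p > lo_p:
            assert paf(hi_p, hi_or) > paf(lo_p, hi_or)
        if hi_or > lo_or:
            assert paf(hi_p, hi_or) > paf(hi_p, lo_or)


class TestPoolCounts:
    def test_rhc_pool(self, assignments, cohort):
        t = pool_counts(assignments, {VariantClass.R}, cohort)
        assert (t.a, t.b, t.c, t.d) == (500, 196, 936, 976)

    def test_all_r_pool_includes_synonymous(self, assignments, cohort):
        t = pool_counts(assignments, NON_RHC_CLASSES, cohort)
        assert (t.a, t.b) == (980, 678)

    def test_rare_r_pool_excludes_synonymous(self, assignments, cohort):
        t = pool_counts(assignments, RARE_R_CLASSES, cohort)
        assert (t.a, t.b) == (57, 31)

    def test_explicit_variant_list(self, assignments, cohort):
        t = pool_counts(assignments, {"V60L", "V92M"}, cohort)
        assert (t.a, t.b) == (359 + 188, 254 + 113)

    def test_empty_members_rejected(self, assignments, cohort):
        with pytest.raises(ValueError):
            pool_counts(assignments, set(), cohort)

    def test_unknown_member_rejected(self, assignments, cohort):
        with pytest.raises(ValueError, match="Q999Z"):
            pool_counts(assignments, {"Q999Z"}, cohort)


class TestAssociate:
    def test_d_class_bundle(self, cohort):
        r = associate(AlleleContingency(48, 21, 936, 976), cohort)
        assert round(r.odds_ratio, 2) == 2.38
        assert 100 * paf(r.maf_controls, round(r.odds_ratio, 2)) == pytest.approx(
            1.6, abs=0.05
        )
        assert r.p_two_sided < 0.005

    def test_nd_class_is_null(self, cohort):
        r = associate(AlleleContingency(9, 10, 936, 976), cohort)
        assert round(r.odds_ratio, 2) == 0.94
        assert r.preventive
        assert r.p_two_sided > 0.5

    def test_ci_brackets_estimate(self, cohort):
        r = associate(AlleleContingency(57, 31, 936, 976), cohort)
        assert r.ci_low <= r.odds_ratio <= r.ci_high

    def test_single_variant_rows_match_printed_ors(
        self, assignments, cohort
    ):
        # printed two-decimal ORs; D84E prints 1.85 while the cross-product
        # gives 1.8449, hence the one-hundredth tolerance
        printed = {
            "D84E": 1.85,
            "R142H": 2.33,
            "R151C": 2.90,
            "R160W": 2.69,
            "D294H": 2.53,
            "V60L": 1.47,
            "V92M": 1.73,
            "I155T": 2.61,
            "R163Q": 1.37,
        }
        for key, expected in printed.items():
            t = pool_counts(assignments, {key}, cohort)
            r = associate(t, cohort)
            assert r.odds_ratio == pytest.approx(expected, abs=0.011), key

    def test_mafs_match_printed_columns(self, assignments, cohort):
        printed = {
            frozenset({VariantClass.R}): (0.22, 0.11),
            frozenset(NON_RHC_CLASSES): (0.43, 0.39),
            frozenset(RARE_R_CLASSES): (0.025, 0.017),
        }
        for members, (maf_case, maf_control) in printed.items():
            r = associate(pool_counts(assignments, members, cohort), cohort)
            assert r.maf_cases == pytest.approx(maf_case, abs=0.005)
            assert r.maf_controls == pytest.approx(maf_control, abs=0.005)


class TestClassOverrides:
    def test_published_d_nd_pools_need_the_g104s_override(
        self, assignments, cohort
    ):
        pooled = apply_class_overrides(assignments, PAPER_CLASS_OVERRIDES)
        d = pool_counts(pooled, {VariantClass.RARE_R_D}, cohort)
        nd = pool_counts(pooled, {VariantClass.RARE_R_ND}, cohort)
        assert (d.a, d.b) == (48, 21)
        assert (nd.a, nd.b) == (9, 10)
        # without the override the strict rule-based split differs by the
        # single G104S control allele
        d_strict = pool_counts(assignments, {VariantClass.RARE_R_D}, cohort)
        assert (d_strict.a, d_strict.b) == (48, 22)


class TestAdjustPvalues:
    def test_default_is_no_correction(self):
        assert adjust_pvalues([0.01, 0.5]) == [0.01, 0.5]

    def test_bonferroni_caps_at_one(self):
        assert adjust_pvalues([0.04, 0.6], "bonferroni") == [0.08, 1.0]
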