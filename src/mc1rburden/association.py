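"""Allele-level association statistics against a reference haplotype pool.

Every comparison is a 2x2 allele-count table: variant (or pooled class)
alleles in cases/controls against the count of reference haplotypes — that
is, chromosomes carrying no nonsynonymous variant (wild-type or
synonymous-only).  The cross-product odds ratio, a Woolf (log-OR, normal
quantile) confidence interval, a two-sided Fisher exact p-value, and the
population attributable fraction

    PAF = p (OR - 1) / (p (OR - 1) + 1)

with ``p`` the control-side allele frequency, are bundled per comparison.
No multiple-testing correction is applied by default; a Bonferroni/FDR
helper is provided but off by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .classify import ClassAssignment, VariantClass
from .variants import CohortCounts


@dataclass(frozen=True)
class AlleleContingency:
    """2x2 allele/haplotype table: class vs reference, cases vs controls.

    ``a``/``b`` are class allele counts in cases/controls, ``c``/``d`` the
    reference haplotype counts in cases/controls.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")
        if self.a + self.b < 1:
            raise ValueError("class allele count a+b must be >= 1")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def needs_correction(self) -> bool:
        return self.b == 0 or self.c == 0


@dataclass(frozen=True)
class AssociationResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_two_sided: float
    paf: float
    maf_cases: float
    maf_controls: float
    level: float = 0.95
    haldane_corrected: bool = False
    preventive: bool = False  # OR < 1, PAF reported negative


def odds_ratio(t: AlleleContingency) -> float:
    """Cross-product odds ratio (a*d)/(b*c).

    A zero in ``b`` or ``c`` triggers the Haldane–Anscombe +0.5 correction
    (flagged through :attr:`AlleleContingency.needs_correction`); a table
    with no reference counts at all is undefined.
    """
    if t.c == 0 and t.d == 0:
        raise ValueError("odds ratio undefined: no reference haplotypes")
    if t.needs_correction:
        return ((t.a + 0.5) * (t.d + 0.5)) / ((t.b + 0.5) * (t.c + 0.5))
    return (t.a * t.d) / (t.b * t.c)


def woolf_ci(
    t: AlleleContingency, level: float = 0.95
) -> tuple[float, float]:
    """Woolf confidence interval: exp(ln OR ± z * sqrt(1/a+1/b+1/c+1/d)).

    Zero cells fall back to the +0.5-corrected table (the same correction
    the point estimate uses).
    """
    if not 0 < level < 1:
        raise ValueError(f"confidence level must be in (0, 1), got {level}")
    if t.c == 0 and t.d == 0:
        raise ValueError("confidence interval undefined: no reference haplotypes")
    cells = (t.a, t.b, t.c, t.d)
    if min(cells) == 0:
        cells = tuple(x + 0.5 for x in cells)
    a, b, c, d = cells
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.5 + level / 2)
    return math.exp(log_or - z * se), math.exp(log_or + z * se)


def fisher_exact_two_sided(t: AlleleContingency) -> float:
    """Two-sided Fisher exact p: sum of hypergeometric probabilities no
    larger than the observed table's, with margins fixed.

    Delegates to :func:`scipy.stats.fisher_exact`; the result is floored at
    the smallest positive float so a p-value of exactly zero is never
    returned.
    """
    p = stats.fisher_exact([[t.a, t.b], [t.c, t.d]], alternative="two-sided")[1]
    return max(float(p), 5e-324)


def paf(p_exposed_controls: float, odds_ratio: float) -> float:
    """Population attributable fraction p(OR-1)/(p(OR-1)+1).

    ``p_exposed_controls`` is the control allele frequency of the risk
    class.  For OR < 1 the value is negative (preventive exposure); callers
    flag this through :attr:`AssociationResult.preventive`.
    """
    if not 0 <= p_exposed_controls <= 1:
        raise ValueError("exposure proportion must lie in [0, 1]")
    if odds_ratio < 0:
        raise ValueError("odds ratio must be non-negative")
    excess = p_exposed_controls * (odds_ratio - 1.0)
    return excess / (excess + 1.0)


def pool_counts(
    assignments: Sequence[ClassAssignment],
    members: Iterable[VariantClass] | Iterable[str],
    reference: CohortCounts | tuple[int, int],
) -> AlleleContingency:
    """Pool case/control allele counts over a class set or explicit variants.

    ``members`` is either a collection of :class:`VariantClass` values or a
    collection of variant identifiers (protein change, else cDNA change).
    Reference counts come from the cohort description — they are an input
    in count-mode, never re-derived from the pooled rows, because haplotype
    multiplicity makes allele counts non-additive over chromosomes.
    """
    members = set(members)
    if not members:
        raise ValueError("empty member set")
    if all(isinstance(m, VariantClass) for m in members):
        chosen = [a for a in assignments if a.klass in members]
    else:
        ids = {str(m).removeprefix("p.") for m in members}
        chosen = [
            a
            for a in assignments
            if a.variant.key.removeprefix("p.") in ids or a.variant.cdna in ids
        ]
        found = {a.variant.key.removeprefix("p.") for a in chosen} | {
            a.variant.cdna for a in chosen
        }
        missing = ids - found
        if missing:
            raise ValueError(f"unknown pool members: {sorted(missing)}")
    if isinstance(reference, CohortCounts):
        c, d = reference.reference_case, reference.reference_control
    else:
        c, d = reference
    return AlleleContingency(
        a=sum(x.variant.case_alleles for x in chosen),
        b=sum(x.variant.control_alleles for x in chosen),
        c=c,
        d=d,
    )


def associate(
    t: AlleleContingency, cohort: CohortCounts, level: float = 0.95
) -> AssociationResult:
    """Full association bundle for one contingency table."""
    or_ = odds_ratio(t)
    lo, hi = woolf_ci(t, level)
    p = fisher_exact_two_sided(t)
    p_ctrl = t.b / cohort.control_chromosomes
    return AssociationResult(
        odds_ratio=or_,
        ci_low=lo,
        ci_high=hi,
        p_two_sided=p,
        paf=paf(p_ctrl, or_),
        maf_cases=t.a / cohort.case_chromosomes,
        maf_controls=p_ctrl,
        level=level,
        haldane_corrected=t.needs_correction,
        preventive=or_ < 1.0,
    )


def adjust_pvalues(pvalues: Sequence[float], method: Optional[str] = None) -> list[float]:
    """Optional multiple-testing adjustment (default: none, matching the
    single-cohort design).  ``method`` may be 'bonferroni' or 'fdr_bh'."""
    p = np.asarray(pvalues, dtype=float)
    if method is None:
        return p.tolist()
    m = len(p)
    if method == "bonferroni":
        return np.minimum(p * m, 1.0).tolist()
    if method == "fdr_bh":
        order = np.argsort(p)
        ranked = p[order] * m / (np.arange(m) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty(m)
        out[order] = np.minimum(ranked, 1.0)
        return out.tolist()
    raise ValueError(f"unknown adjustment method {method!r}")
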