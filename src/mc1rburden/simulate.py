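"""Synthetic case-control cohorts with class-labelled MC1R-like alleles.

The generator emulates the sampling design of a melanoma case-control
resequencing study: diploid subjects whose haplotypes carry at most one
nonsynonymous variant each (matching the reference-haplotype counting
model, which treats a chromosome as "reference" only when it carries no
nonsynonymous variant), disease status assigned by a logistic model whose
class coefficients are ln(class odds ratio), and four ordinal pigmentation
covariates.  Case-control sampling is by rejection: population subjects
are drawn until the requested numbers of cases and controls are reached,
so class effects are recovered by the allele-level estimators regardless
of the baseline prevalence.

Defaults mirror the observed cohort: 1131 cases / 869 controls, pooled
class frequencies and odds ratios as estimated from the study's count
tables (R 0.11 / OR 2.66, frequent r 0.39 / OR 1.51, rare D 0.012 /
OR 2.38, rare nD 0.006 / OR 1.0).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .multivariate import SubjectRecord
from .variants import CohortCounts

SYNONYMOUS_CLASSES = frozenset({"synonymous_frequent", "synonymous_rare"})

#: Default ordinal covariate level probabilities (levels coded 1..k).
DEFAULT_COVARIATE_LEVELS: Mapping[str, tuple[float, ...]] = {
    "hair_colour": (0.15, 0.45, 0.30, 0.10),
    "eye_colour": (0.35, 0.35, 0.30),
    "skin_type": (0.10, 0.30, 0.40, 0.20),
    "nevus_count": (0.40, 0.35, 0.18, 0.07),
}


@dataclass(frozen=True)
class AlleleSpec:
    variant_id: str
    klass: str
    control_frequency: float
    codon: int

    def __post_init__(self) -> None:
        if not 0 < self.control_frequency < 1:
            raise ValueError(f"{self.variant_id}: frequency must lie in (0, 1)")
        if self.codon < 1:
            raise ValueError(f"{self.variant_id}: codon must be positive")


@dataclass(frozen=True)
class SimulationSpec:
    n_cases: int
    n_controls: int
    allele_catalog: tuple[AlleleSpec, ...]
    class_odds_ratios: Mapping[str, float]
    covariate_levels: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_LEVELS)
    )
    covariate_effects: Mapping[str, float] = field(default_factory=dict)
    genotype_covariate_corr: float = 0.0
    baseline_prevalence: float = 0.10
    genetic_coding: str = "dosage"  # per-haplotype effects; "carriage" available
    multi_variant_haplotypes: bool = False
    age_mean: float = 54.0
    age_sd: float = 12.0
    age_class_means: Mapping[str, float] = field(default_factory=dict)
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("n_cases and n_controls must be >= 1")
        total_freq = sum(a.control_frequency for a in self.allele_catalog)
        if not self.multi_variant_haplotypes and total_freq > 1:
            raise ValueError(
                f"allele frequencies sum to {total_freq:.3f} > 1 per haplotype"
            )
        for k, v in self.class_odds_ratios.items():
            if v < 0:
                raise ValueError(f"class odds ratio for {k!r} must be >= 0")
        if self.genetic_coding not in ("dosage", "carriage"):
            raise ValueError(f"unknown genetic coding {self.genetic_coding!r}")
        if not 0 < self.baseline_prevalence < 1:
            raise ValueError("baseline_prevalence must lie in (0, 1)")


def table2_spec(
    n_cases: int = 1131,
    n_controls: int = 869,
    seed: Optional[int] = None,
    **overrides,
) -> SimulationSpec:
    """A specification mirroring the study's pooled class structure."""
    catalog = (
        AlleleSpec("R_pool", "R", 0.11, 151),
        AlleleSpec("r_pool", "frequent_r", 0.39, 60),
        AlleleSpec("D_pool", "rare_r_D", 0.012, 95),
        AlleleSpec("nD_pool", "rare_r_nD", 0.006, 122),
    )
    ors = {"R": 2.66, "frequent_r": 1.51, "rare_r_D": 2.38, "rare_r_nD": 1.0}
    return SimulationSpec(
        n_cases=n_cases,
        n_controls=n_controls,
        allele_catalog=catalog,
        class_odds_ratios=ors,
        seed=seed,
        **overrides,
    )


def null_spec(
    n_cases: int, n_controls: int, seed: Optional[int] = None
) -> SimulationSpec:
    """Same catalog as :func:`table2_spec` but every class effect null."""
    spec = table2_spec(n_cases, n_controls, seed=seed)
    return replace(
        spec, class_odds_ratios={k: 1.0 for k in spec.class_odds_ratios}
    )


def _tilted(probs: np.ndarray, corr: float) -> np.ndarray:
    levels = np.arange(1, len(probs) + 1)
    w = probs * np.exp(corr * levels)
    return w / w.sum()


def simulate_cohort(
    spec: SimulationSpec, seed: Optional[int] = None
) -> list[SubjectRecord]:
    """Draw a cohort of exactly ``n_cases`` cases and ``n_controls`` controls.

    Haplotypes are independent draws (no linkage) from the catalog's
    control-population frequencies with at most one variant per haplotype;
    status follows a logistic model with class coefficients ln(OR); the
    run is reproducible given a seed (argument wins over ``spec.seed``).
    """
    rng = np.random.default_rng(seed if seed is not None else spec.seed)
    catalog = spec.allele_catalog
    n_alleles = len(catalog)
    freqs = np.array([a.control_frequency for a in catalog])
    probs = np.append(freqs, 1.0 - freqs.sum())  # last index = wild-type
    classes = sorted({a.klass for a in catalog})
    class_idx = {k: i for i, k in enumerate(classes)}
    allele_class = np.array([class_idx[a.klass] for a in catalog])
    beta = np.array(
        [np.log(spec.class_odds_ratios.get(k, 1.0)) for k in classes]
    )
    beta0 = float(logit(spec.baseline_prevalence))
    cov_names = list(spec.covariate_levels)
    gamma = np.array([spec.covariate_effects.get(c, 0.0) for c in cov_names])

    kept_cases: list[SubjectRecord] = []
    kept_controls: list[SubjectRecord] = []
    batch = max(2048, 2 * (spec.n_cases + spec.n_controls))
    next_id = 0
    while (
        len(kept_cases) < spec.n_cases or len(kept_controls) < spec.n_controls
    ):
        haps = rng.choice(n_alleles + 1, size=(batch, 2), p=probs)
        is_variant = haps < n_alleles
        # per-class haplotype dosage
        dosage = np.zeros((batch, len(classes)))
        for h in range(2):
            m = is_variant[:, h]
            np.add.at(dosage, (np.nonzero(m)[0], allele_class[haps[m, h]]), 1)
        x = dosage if spec.genetic_coding == "dosage" else np.minimum(dosage, 1)

        nonsyn_classes = [
            i for k, i in class_idx.items() if k not in SYNONYMOUS_CLASSES
        ]
        carrier = dosage[:, nonsyn_classes].sum(axis=1) > 0

        covs = np.empty((batch, len(cov_names)), dtype=int)
        for j, name in enumerate(cov_names):
            p = np.asarray(spec.covariate_levels[name], dtype=float)
            p = p / p.sum()
            draw = rng.choice(len(p), size=batch, p=p) + 1
            if spec.genotype_covariate_corr != 0.0:
                tilted = (
                    rng.choice(
                        len(p), size=batch, p=_tilted(p, spec.genotype_covariate_corr)
                    )
                    + 1
                )
                draw = np.where(carrier, tilted, draw)
            covs[:, j] = draw

        eta = beta0 + x @ beta + covs @ gamma
        case = rng.random(batch) < expit(eta)
        ages = np.clip(rng.normal(spec.age_mean, spec.age_sd, size=batch), 15, 95)
        if spec.age_class_means:
            for k, mean in spec.age_class_means.items():
                in_class = dosage[:, class_idx[k]] > 0
                shifted = np.clip(
                    rng.normal(mean, spec.age_sd, size=batch), 15, 95
                )
                ages = np.where(in_class, shifted, ages)

        need_cases = spec.n_cases - len(kept_cases)
        need_controls = spec.n_controls - len(kept_controls)
        case_rows = np.nonzero(case)[0][:need_cases]
        control_rows = np.nonzero(~case)[0][:need_controls]
        for rows, bucket in ((case_rows, kept_cases), (control_rows, kept_controls)):
            for i in rows:
                h1 = (catalog[haps[i, 0]].variant_id,) if is_variant[i, 0] else ()
                h2 = (catalog[haps[i, 1]].variant_id,) if is_variant[i, 1] else ()
                bucket.append(
                    SubjectRecord(
                        id=f"S{next_id:06d}",
                        status="case" if case[i] else "control",
                        haplotype1=h1,
                        haplotype2=h2,
                        hair_colour=int(covs[i, 0]),
                        eye_colour=int(covs[i, 1]),
                        skin_type=int(covs[i, 2]),
                        nevus_count=int(covs[i, 3]),
                        age_at_diagnosis=(
                            round(float(ages[i]), 1) if case[i] else None
                        ),
                    )
                )
                next_id += 1
    return kept_cases + kept_controls


def counts_from_subjects(
    subjects: Sequence[SubjectRecord],
    class_of_variant: Mapping[str, str],
) -> tuple[pd.DataFrame, CohortCounts]:
    """Collapse subject haplotypes to per-variant counts and cohort totals.

    The reference count per group is the number of haplotypes carrying no
    nonsynonymous variant (wild-type or synonymous-only chromosomes).
    """
    if not subjects:
        raise ValueError("empty cohort")
    nonsyn = {
        v for v, k in class_of_variant.items() if k not in SYNONYMOUS_CLASSES
    }
    case_counts: dict[str, int] = {}
    control_counts: dict[str, int] = {}
    ref = {"case": 0, "control": 0}
    n = {"case": 0, "control": 0}
    for s in subjects:
        n[s.status] += 1
        tally = case_counts if s.is_case else control_counts
        for hap in (s.haplotype1, s.haplotype2):
            for v in hap:
                if v not in class_of_variant:
                    raise ValueError(f"{s.id}: unknown variant id {v!r}")
                tally[v] = tally.get(v, 0) + 1
            if not any(v in nonsyn for v in hap):
                ref[s.status] += 1
    ids = sorted(set(case_counts) | set(control_counts))
    counts = pd.DataFrame(
        {
            "variant_id": ids,
            "klass": [class_of_variant[v] for v in ids],
            "case_alleles": [case_counts.get(v, 0) for v in ids],
            "control_alleles": [control_counts.get(v, 0) for v in ids],
        }
    )
    cohort = CohortCounts(
        case_chromosomes=2 * n["case"],
        control_chromosomes=2 * n["control"],
        reference_case=ref["case"],
        reference_control=ref["control"],
    )
    return counts, cohort


def class_contingencies(
    counts: pd.DataFrame, cohort: CohortCounts
) -> dict[str, "AlleleContingency"]:
    """Pooled class-vs-reference tables from a subject-derived count table."""
    from .association import AlleleContingency

    out = {}
    for klass, grp in counts.groupby("klass"):
        a = int(grp["case_alleles"].sum())
        b = int(grp["control_alleles"].sum())
        if a + b == 0:
            continue
        out[str(klass)] = AlleleContingency(
            a, b, cohort.reference_case, cohort.reference_control
        )
    return out
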