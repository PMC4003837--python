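"""Rule-based assignment of MC1R variants to risk classes.

Classes follow the standard red-hair-colour nomenclature: ``R`` (strong
red-hair-associated alleles, an input list, not an inference), frequent
``r`` (other nonsynonymous variants at >=1% allele frequency), and rare
``r`` split into predicted-damaging ``D`` and non-damaging ``nD``.
Nonsense and frameshift variants are always damaging.  Synonymous variants
are kept in their own frequent/rare classes: they are never D/nD members
but they do count toward pooled "all r" burden (and toward the reference
haplotype definition elsewhere).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

from .variants import CohortCounts, Consequence, VariantRecord

#: Red-hair-colour alleles as designated in the MC1R literature.
RHC_ALLELES = frozenset({"D84E", "R142H", "R151C", "R160W", "D294H"})


class VariantClass(str, Enum):
    R = "R"
    FREQUENT_R = "frequent_r"
    RARE_R_D = "rare_r_D"
    RARE_R_ND = "rare_r_nD"
    SYNONYMOUS_FREQUENT = "synonymous_frequent"
    SYNONYMOUS_RARE = "synonymous_rare"


#: Classes whose members are nonsynonymous rare r variants.
RARE_R_CLASSES = frozenset({VariantClass.RARE_R_D, VariantClass.RARE_R_ND})
#: Classes counted as "rare" in the variant census (includes synonymous).
RARE_CLASSES = RARE_R_CLASSES | {VariantClass.SYNONYMOUS_RARE}
#: Every non-RHC class — the pooled "all r" membership.
NON_RHC_CLASSES = frozenset(VariantClass) - {VariantClass.R}


class UnclassifiableVariantError(ValueError):
    """A rare nonsynonymous variant with no prediction and no truncation."""


def _strip_p(protein: str) -> str:
    return protein[2:] if protein.startswith("p.") else protein


@dataclass(frozen=True)
class RuleSet:
    """Configurable classification rules.

    ``rare_threshold`` is an allele frequency; the denominator defaults to
    the combined cohorts because that choice reproduces the rare/frequent
    split used throughout the source tables (e.g. R142H at 42/4000 = 1.05%
    is frequent).  ``min_damaging_votes`` applies when per-tool verdicts are
    supplied; the packaged count table carries a pre-aggregated >=1-vote
    consensus flag instead.
    """

    rhc_alleles: frozenset[str] = RHC_ALLELES
    rare_threshold: float = 0.01
    frequency_denominator: str = "combined"  # combined | cases | controls
    min_damaging_votes: int = 1
    truncating_is_damaging: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.rare_threshold < 1:
            raise ValueError("rare_threshold must lie in (0, 1)")
        if self.frequency_denominator not in ("combined", "cases", "controls"):
            raise ValueError(
                f"unknown frequency denominator {self.frequency_denominator!r}"
            )
        if self.min_damaging_votes < 1:
            raise ValueError("min_damaging_votes must be >= 1")
        object.__setattr__(
            self, "rhc_alleles", frozenset(_strip_p(a) for a in self.rhc_alleles)
        )

    def is_rhc(self, record: VariantRecord) -> bool:
        return bool(record.protein) and _strip_p(record.protein) in self.rhc_alleles


@dataclass(frozen=True)
class ClassAssignment:
    variant: VariantRecord
    klass: VariantClass
    frequency: float  # the frequency used for the rarity decision


def allele_frequency(
    record: VariantRecord, cohort: CohortCounts, denominator: str = "combined"
) -> float:
    """Allele frequency of a variant under the chosen denominator."""
    if denominator == "combined":
        num, den = record.total_alleles, cohort.total_chromosomes
    elif denominator == "cases":
        num, den = record.case_alleles, cohort.case_chromosomes
    elif denominator == "controls":
        num, den = record.control_alleles, cohort.control_chromosomes
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if record.case_alleles > cohort.case_chromosomes:
        raise ValueError(f"{record.cdna}: case alleles exceed case chromosomes")
    if record.control_alleles > cohort.control_chromosomes:
        raise ValueError(f"{record.cdna}: control alleles exceed control chromosomes")
    return num / den


def damaging_votes_consensus(
    votes: Mapping[str, bool], min_votes: int = 1
) -> bool:
    """Aggregate per-tool in-silico verdicts into a single damaging flag."""
    return sum(bool(v) for v in votes.values()) >= min_votes


def classify_variant(
    record: VariantRecord, rules: RuleSet, cohort: CohortCounts
) -> ClassAssignment:
    """Assign a single variant to its class.

    Precedence: (1) RHC list membership → R regardless of frequency;
    (2) synonymous → synonymous_frequent / synonymous_rare; (3) frequency at
    or above the threshold → frequent_r; (4) below it → rare_r_D when
    truncating or predicted damaging, rare_r_nD when predicted benign.
    A rare nonsynonymous variant with no prediction and no clear functional
    impact raises :class:`UnclassifiableVariantError` — it is never silently
    called non-damaging.
    """
    freq = allele_frequency(record, cohort, rules.frequency_denominator)
    if rules.is_rhc(record):
        return ClassAssignment(record, VariantClass.R, freq)
    rare = freq < rules.rare_threshold
    if record.consequence is Consequence.SYNONYMOUS:
        klass = (
            VariantClass.SYNONYMOUS_RARE if rare else VariantClass.SYNONYMOUS_FREQUENT
        )
        return ClassAssignment(record, klass, freq)
    if not rare:
        return ClassAssignment(record, VariantClass.FREQUENT_R, freq)
    if rules.truncating_is_damaging and record.truncating:
        return ClassAssignment(record, VariantClass.RARE_R_D, freq)
    if record.predicted_damaging is None:
        raise UnclassifiableVariantError(
            f"{record.key}: rare nonsynonymous variant with no damaging "
            "prediction and no truncating consequence"
        )
    klass = (
        VariantClass.RARE_R_D if record.predicted_damaging else VariantClass.RARE_R_ND
    )
    return ClassAssignment(record, klass, freq)


@dataclass(frozen=True)
class ClassSummary:
    """Distinct-variant tallies over a classified variant set."""

    by_class: Mapping[VariantClass, int]
    n_total: int
    n_rare: int  # non-RHC variants below the rarity threshold, any consequence
    n_rare_damaging: int
    n_rare_novel: int


def classify_all(
    records: Sequence[VariantRecord], rules: RuleSet, cohort: CohortCounts
) -> tuple[list[ClassAssignment], ClassSummary]:
    """Classify every record and summarize distinct-variant counts per class."""
    assignments = [classify_variant(r, rules, cohort) for r in records]
    by_class = Counter(a.klass for a in assignments)
    rare = [a for a in assignments if a.klass in RARE_CLASSES]
    summary = ClassSummary(
        by_class=dict(by_class),
        n_total=len(assignments),
        n_rare=len(rare),
        n_rare_damaging=by_class[VariantClass.RARE_R_D],
        n_rare_novel=sum(1 for a in rare if a.variant.novel),
    )
    return assignments, summary
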