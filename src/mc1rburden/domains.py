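"""Mapping variants onto MC1R protein domains and per-domain association.

MC1R is a seven-transmembrane G-protein-coupled receptor of 317 residues.
The domain table partitions residues 1..317 into the N-terminus, seven
transmembrane helices, three intracellular and three extracellular loops,
and the C-terminal tail.  Per-domain burden pools the alleles of *every*
variant whose codon lies in the domain — missense, nonsense, synonymous
and indel alike — against the reference haplotypes.  The D-vs-nD
enrichment compares how damaging and non-damaging rare-variant alleles
distribute over a chosen domain set.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .association import (
    AlleleContingency,
    AssociationResult,
    associate,
    fisher_exact_two_sided,
)
from .variants import CohortCounts, VariantRecord

COMPARTMENTS = ("extracellular", "transmembrane", "intracellular")


@dataclass(frozen=True)
class Domain:
    name: str
    abbrev: str
    start: int
    end: int
    compartment: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.name}: start {self.start} > end {self.end}")
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"{self.name}: unknown compartment {self.compartment!r}")

    def __contains__(self, codon: int) -> bool:
        return self.start <= codon <= self.end


class DomainTable:
    """Ordered, contiguous, non-overlapping residue partition of a protein."""

    def __init__(self, domains: Sequence[Domain]):
        domains = tuple(domains)
        if not domains:
            raise ValueError("domain table is empty")
        expected = domains[0].start
        for d in domains:
            if d.start != expected:
                raise ValueError(
                    f"domains must be contiguous; {d.name} starts at {d.start}, "
                    f"expected {expected}"
                )
            expected = d.end + 1
        self.domains = domains
        self._starts = [d.start for d in domains]

    @property
    def first_residue(self) -> int:
        return self.domains[0].start

    @property
    def last_residue(self) -> int:
        return self.domains[-1].end

    def __iter__(self):
        return iter(self.domains)

    def __len__(self) -> int:
        return len(self.domains)

    def __getitem__(self, key: int | str) -> Domain:
        if isinstance(key, str):
            for d in self.domains:
                if key in (d.name, d.abbrev):
                    return d
            raise KeyError(f"no domain named {key!r}")
        return self.domains[key]

    def assign(self, codon: int) -> Domain:
        """The unique domain containing a residue index."""
        if not self.first_residue <= codon <= self.last_residue:
            raise ValueError(
                f"codon {codon} outside residue range "
                f"{self.first_residue}..{self.last_residue}"
            )
        return self.domains[bisect_right(self._starts, codon) - 1]


def assign_domain(codon: int, table: DomainTable) -> str:
    """Name of the domain containing ``codon``."""
    return table.assign(codon).name


@dataclass(frozen=True)
class DomainAssociation:
    domain: Domain
    n_variants: int
    contingency: AlleleContingency | None
    result: AssociationResult | None

    @property
    def empty(self) -> bool:
        return self.contingency is None


def domain_association(
    records: Sequence[VariantRecord],
    domain: Domain | str,
    cohort: CohortCounts,
    table: DomainTable | None = None,
) -> DomainAssociation:
    """Pooled association of all variant alleles falling in one domain.

    A domain harbouring no variant yields a flagged empty result rather
    than an error (several extracellular loops are variant-free).
    """
    if isinstance(domain, str):
        if table is None:
            raise ValueError("a DomainTable is required to look up domain names")
        domain = table[domain]
    members = [r for r in records if r.codon in domain]
    if not members:
        return DomainAssociation(domain, 0, None, None)
    t = AlleleContingency(
        a=sum(r.case_alleles for r in members),
        b=sum(r.control_alleles for r in members),
        c=cohort.reference_case,
        d=cohort.reference_control,
    )
    return DomainAssociation(domain, len(members), t, associate(t, cohort))


@dataclass(frozen=True)
class DomainEnrichment:
    """D-vs-nD allele clustering in a domain set versus the rest."""

    in_set_D: int
    out_set_D: int
    in_set_nD: int
    out_set_nD: int
    fraction_D: float
    fraction_nD: float
    p: float


def domain_set_enrichment(
    domain_counts: Mapping[str, tuple[int, int]],
    domain_set: Iterable[str],
) -> DomainEnrichment:
    """Compare the D and nD allele fractions falling in a domain set.

    ``domain_counts`` maps a domain key to its (D alleles, nD alleles)
    tally; ``domain_set`` names the in-set domains.  The p-value is the
    two-sided Fisher exact test on the in/out x D/nD table.
    """
    wanted = set(domain_set)
    if not wanted:
        raise ValueError("empty domain set")
    unknown = wanted - set(domain_counts)
    if unknown:
        raise ValueError(f"unknown domains in set: {sorted(unknown)}")
    in_d = sum(domain_counts[k][0] for k in wanted)
    in_nd = sum(domain_counts[k][1] for k in wanted)
    all_d = sum(v[0] for v in domain_counts.values())
    all_nd = sum(v[1] for v in domain_counts.values())
    if all_d == 0 or all_nd == 0:
        raise ValueError("no D or no nD alleles in the domain counts")
    out_d, out_nd = all_d - in_d, all_nd - in_nd
    p = fisher_exact_two_sided(AlleleContingency(in_d, in_nd, out_d, out_nd))
    return DomainEnrichment(
        in_set_D=in_d,
        out_set_D=out_d,
        in_set_nD=in_nd,
        out_set_nD=out_nd,
        fraction_D=in_d / all_d,
        fraction_nD=in_nd / all_nd,
        p=p,
    )


def recompute_domain_class_counts(
    records: Sequence[VariantRecord],
    assignments,
    table: DomainTable,
    include_indels: bool = False,
) -> dict[str, tuple[int, int]]:
    """Per-domain (D, nD) allele counts recomputed from classified records.

    Provided as a cross-check against transcribed per-domain tallies; the
    published tally excludes indels and reassigns one predicted-damaging
    variant, so the two routes are documented to disagree in a few cells.
    """
    from .classify import VariantClass

    counts = {d.abbrev: [0, 0] for d in table}
    for a in assignments:
        r = a.variant
        if not include_indels and not r.protein:
            continue
        if a.klass is VariantClass.RARE_R_D:
            counts[table.assign(r.codon).abbrev][0] += r.total_alleles
        elif a.klass is VariantClass.RARE_R_ND:
            counts[table.assign(r.codon).abbrev][1] += r.total_alleles
    return {k: (v[0], v[1]) for k, v in counts.items()}


def compartment_rollup(
    records: Sequence[VariantRecord], table: DomainTable
) -> dict[str, float]:
    """Fraction of distinct variants per receptor compartment.

    Reported for orientation only; compartment percentages depend on the
    membership convention and are not pinned to any published roll-up.
    """
    tally = {c: 0 for c in COMPARTMENTS}
    for r in records:
        tally[table.assign(r.codon).compartment] += 1
    total = len(records)
    return {c: (n / total if total else 0.0) for c, n in tally.items()}
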