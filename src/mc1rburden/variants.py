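"""Coding-variant notation, consequence typing, and per-variant allele counts.

Variants are held as :class:`VariantRecord` objects parsed from the cDNA
(``c.478C>T``) and protein (``p.R160W``) change strings used in MC1R
resequencing studies.  Coordinates are 1-based on the coding sequence
(NM_002386.3 numbering); the affected codon is the ceiling of the first
affected cDNA position divided by three.  When a protein change is printed
alongside the cDNA change, the protein residue number is taken as the
authoritative codon and any disagreement with the cDNA-derived codon is
flagged (``codon_mismatch``) rather than silently repaired.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence


class HgvsParseError(ValueError):
    """Raised when a cDNA or protein change string cannot be parsed."""


class Consequence(str, Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    SYNONYMOUS = "synonymous"


class CdnaKind(str, Enum):
    SUBSTITUTION = "substitution"
    INSERTION = "insertion"
    DELETION = "deletion"


_SUB_RE = re.compile(r"^c\.(\d+)([ACGT])>([ACGT])$")
_INS_RE = re.compile(r"^c\.(\d+)_(\d+)ins([ACGT]+)$")
_DEL_RE = re.compile(r"^c\.(\d+)(?:_(\d+))?del([ACGT]*)$")
_PROT_RE = re.compile(r"^p\.([A-Z])(\d+)([A-Z*])$")


@dataclass(frozen=True)
class ParsedCdna:
    """A parsed coding-sequence change.

    ``position`` is the 1-based coordinate of the first affected nucleotide.
    For substitutions ``ref``/``alt`` hold the two bases; for insertions
    ``end`` is the 3'-flanking position and ``seq`` the inserted bases; for
    deletions ``end`` is the last deleted position (or ``None`` for a
    single-base deletion) and ``seq`` the deleted bases if stated.
    """

    position: int
    kind: CdnaKind
    ref: Optional[str] = None
    alt: Optional[str] = None
    end: Optional[int] = None
    seq: Optional[str] = None

    def __str__(self) -> str:
        if self.kind is CdnaKind.SUBSTITUTION:
            return f"c.{self.position}{self.ref}>{self.alt}"
        if self.kind is CdnaKind.INSERTION:
            return f"c.{self.position}_{self.end}ins{self.seq}"
        span = f"{self.position}" if self.end is None else f"{self.position}_{self.end}"
        return f"c.{span}del{self.seq or ''}"

    @property
    def length_change(self) -> int:
        """Signed change in coding-sequence length (0 for substitutions)."""
        if self.kind is CdnaKind.INSERTION:
            return len(self.seq or "")
        if self.kind is CdnaKind.DELETION:
            if self.seq:
                return -len(self.seq)
            end = self.end if self.end is not None else self.position
            return -(end - self.position + 1)
        return 0


def _normalize_cdna(change: str) -> str:
    # Tolerate two typographic artefacts seen in printed tables: a stray
    # space before "ins"/"del" and "<" printed in place of ">".
    return change.replace(" ", "").replace("<", ">")


def parse_cdna(change: str) -> ParsedCdna:
    """Parse a cDNA change string into position, kind and event payload.

    Supports the substitution (``c.<pos><ref>><alt>``), range-insertion
    (``c.<p1>_<p2>ins<seq>``) and deletion (``c.<p1>[_<p2>]del[<seq>]``)
    grammars.  Raises :class:`HgvsParseError` naming the offending token for
    anything else, and ``ValueError`` for non-positive coordinates.
    """
    if not isinstance(change, str) or not change.startswith("c."):
        raise HgvsParseError(f"cDNA change must start with 'c.': {change!r}")
    text = _normalize_cdna(change)
    m = _SUB_RE.match(text)
    if m:
        pos = int(m.group(1))
        if pos <= 0:
            raise ValueError(f"cDNA position must be positive: {change!r}")
        return ParsedCdna(pos, CdnaKind.SUBSTITUTION, ref=m.group(2), alt=m.group(3))
    m = _INS_RE.match(text)
    if m:
        p1, p2 = int(m.group(1)), int(m.group(2))
        if p1 <= 0:
            raise ValueError(f"cDNA position must be positive: {change!r}")
        if p2 != p1 + 1:
            raise HgvsParseError(
                f"insertion must be between adjacent positions: {change!r}"
            )
        return ParsedCdna(p1, CdnaKind.INSERTION, end=p2, seq=m.group(3))
    m = _DEL_RE.match(text)
    if m:
        p1 = int(m.group(1))
        if p1 <= 0:
            raise ValueError(f"cDNA position must be positive: {change!r}")
        end = int(m.group(2)) if m.group(2) else None
        return ParsedCdna(p1, CdnaKind.DELETION, end=end, seq=m.group(3) or None)
    token = text[2:] if len(text) > 2 else text
    raise HgvsParseError(f"unrecognized cDNA change token: {token!r} in {change!r}")


def codon_of(cdna_position: int) -> int:
    """Codon (residue) index of a 1-based coding-sequence position."""
    if cdna_position < 1:
        raise ValueError(f"cDNA position must be >= 1, got {cdna_position}")
    return (cdna_position + 2) // 3


def parse_protein(change: str) -> tuple[str, int, str]:
    """Parse ``p.<ref><N><alt>`` into (reference residue, codon, alternate)."""
    m = _PROT_RE.match(change.replace(" ", ""))
    if not m:
        raise HgvsParseError(f"unrecognized protein change: {change!r}")
    return m.group(1), int(m.group(2)), m.group(3)


def derive_consequence(cdna: str | ParsedCdna, protein: Optional[str]) -> Consequence:
    """Classify a variant as missense / nonsense / frameshift / synonymous.

    Substitutions require a protein change; the consequence is read off its
    residues (stop ``X`` → nonsense, identical residues → synonymous).
    Indels carry no protein notation here and are typed from the cDNA token
    alone: a length change that is not a multiple of three is a frameshift.
    """
    parsed = cdna if isinstance(cdna, ParsedCdna) else parse_cdna(cdna)
    if parsed.kind is CdnaKind.SUBSTITUTION:
        if not protein:
            raise ValueError(
                f"substitution {parsed} lacks protein notation; cannot type"
            )
        ref, _, alt = parse_protein(protein)
        if alt == "X" or alt == "*":
            return Consequence.NONSENSE
        if ref == alt:
            return Consequence.SYNONYMOUS
        return Consequence.MISSENSE
    if parsed.length_change % 3 != 0:
        return Consequence.FRAMESHIFT
    raise ValueError(f"in-frame indel {parsed} is outside the supported model")


@dataclass(frozen=True)
class VariantRecord:
    """One coding variant with parsed notation and per-group allele counts."""

    cdna: str
    protein: str  # empty string for indels
    consequence: Consequence
    codon: int
    case_alleles: int
    control_alleles: int
    predicted_damaging: Optional[bool]  # None when no prediction is available
    rhc: bool = False
    novel: bool = False
    codon_mismatch: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if self.case_alleles < 0 or self.control_alleles < 0:
            raise ValueError(f"{self.cdna}: negative allele count")
        if self.case_alleles + self.control_alleles < 1:
            raise ValueError(f"{self.cdna}: variant observed on no chromosome")
        if self.codon < 1:
            raise ValueError(f"{self.cdna}: codon must be positive")

    @classmethod
    def from_changes(
        cls,
        cdna: str,
        protein: str = "",
        *,
        case_alleles: int,
        control_alleles: int,
        predicted_damaging: Optional[bool] = None,
        rhc: bool = False,
        novel: bool = False,
    ) -> "VariantRecord":
        """Build a record, deriving consequence and codon from the notation.

        The protein residue number wins for codon assignment when present;
        a cDNA-vs-protein codon disagreement sets ``codon_mismatch``.
        """
        parsed = parse_cdna(cdna)
        consequence = derive_consequence(parsed, protein or None)
        cdna_codon = codon_of(parsed.position)
        if protein:
            _, prot_codon, _ = parse_protein(protein)
            mismatch = prot_codon != cdna_codon
            codon = prot_codon
        else:
            mismatch = False
            codon = cdna_codon
        return cls(
            cdna=str(parsed),
            protein=protein,
            consequence=consequence,
            codon=codon,
            case_alleles=case_alleles,
            control_alleles=control_alleles,
            predicted_damaging=predicted_damaging,
            rhc=rhc,
            novel=novel,
            codon_mismatch=mismatch,
        )

    @property
    def key(self) -> str:
        """Stable identifier: protein change when present, else cDNA change."""
        return self.protein or self.cdna

    @property
    def total_alleles(self) -> int:
        return self.case_alleles + self.control_alleles

    @property
    def truncating(self) -> bool:
        return self.consequence in (Consequence.NONSENSE, Consequence.FRAMESHIFT)


@dataclass(frozen=True)
class CohortCounts:
    """Chromosome totals and reference (variant-free) haplotype counts."""

    case_chromosomes: int
    control_chromosomes: int
    reference_case: int
    reference_control: int

    def __post_init__(self) -> None:
        for name in (
            "case_chromosomes",
            "control_chromosomes",
            "reference_case",
            "reference_control",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.reference_case > self.case_chromosomes:
            raise ValueError("reference_case exceeds case chromosomes")
        if self.reference_control > self.control_chromosomes:
            raise ValueError("reference_control exceeds control chromosomes")

    @property
    def total_chromosomes(self) -> int:
        return self.case_chromosomes + self.control_chromosomes


@dataclass(frozen=True)
class VariantCensus:
    total: int
    missense: int
    nonsense: int
    frameshift: int
    synonymous: int


def census(records: Sequence[VariantRecord]) -> VariantCensus:
    """Count distinct variants overall and per consequence.

    Records must be unique by cDNA change; duplicates raise a ``ValueError``
    listing the offending keys.
    """
    keys = Counter(r.cdna for r in records)
    dups = sorted(k for k, n in keys.items() if n > 1)
    if dups:
        raise ValueError(f"duplicate cDNA keys: {', '.join(dups)}")
    by_csq = Counter(r.consequence for r in records)
    return VariantCensus(
        total=len(records),
        missense=by_csq[Consequence.MISSENSE],
        nonsense=by_csq[Consequence.NONSENSE],
        frameshift=by_csq[Consequence.FRAMESHIFT],
        synonymous=by_csq[Consequence.SYNONYMOUS],
    )
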