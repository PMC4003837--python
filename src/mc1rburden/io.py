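"""TSV readers/writers and packaged fixture access.

All tables are UTF-8 TSV with explicit headers.  The packaged fixtures
transcribe the study's printed count tables: the 79-variant count table,
the cohort/reference chromosome totals, the 15-domain residue partition of
the receptor, and the per-domain damaging/non-damaging allele tallies.
"""

from __future__ import annotations

import sys
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .classify import ClassAssignment
from .domains import Domain, DomainTable
from .multivariate import SubjectRecord
from .simulate import AlleleSpec, SimulationSpec
from .variants import CohortCounts, VariantRecord

_COUNT_COLUMNS = (
    "cdna",
    "protein",
    "case_alleles",
    "control_alleles",
    "predicted_damaging",
    "rare",
    "novel",
)

_FLAGS = {"yes": True, "no": False}


def _data_path(name: str):
    return resources.files("mc1rburden.data") / name


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def read_variant_counts(path) -> list[VariantRecord]:
    """Read a variant-count table into validated records.

    Columns: cdna, protein, case_alleles, control_alleles,
    predicted_damaging {yes,no,rhc,''}, rare {yes,no}, novel {yes,no}.
    Any malformed row raises with its 1-based data line number.
    """
    df = _read_tsv(path)
    unknown = set(df.columns) - set(_COUNT_COLUMNS)
    if unknown:
        raise ValueError(f"unknown column(s): {sorted(unknown)}")
    missing = set(_COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"missing column(s): {sorted(missing)}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            counts = {}
            for col in ("case_alleles", "control_alleles"):
                raw = getattr(row, col).strip()
                counts[col] = int(raw) if raw else 0
                if counts[col] < 0:
                    raise ValueError(f"negative count in {col}")
            pred_raw = row.predicted_damaging.strip().lower()
            rhc = pred_raw == "rhc"
            if rhc or pred_raw == "":
                predicted = None
            elif pred_raw in _FLAGS:
                predicted = _FLAGS[pred_raw]
            else:
                raise ValueError(
                    f"predicted_damaging must be yes/no/rhc/'', got {pred_raw!r}"
                )
            for col in ("rare", "novel"):
                val = getattr(row, col).strip().lower()
                if val not in _FLAGS:
                    raise ValueError(f"{col} must be yes/no, got {val!r}")
            records.append(
                VariantRecord.from_changes(
                    row.cdna.strip(),
                    row.protein.strip(),
                    case_alleles=counts["case_alleles"],
                    control_alleles=counts["control_alleles"],
                    predicted_damaging=predicted,
                    rhc=rhc,
                    novel=_FLAGS[row.novel.strip().lower()],
                )
            )
        except ValueError as exc:
            raise ValueError(f"line {i}: {exc}") from exc
    return records


def write_variant_counts(records: Sequence[VariantRecord], path) -> None:
    rows = []
    for r in records:
        if r.rhc:
            pred = "rhc"
        elif r.predicted_damaging is None:
            pred = ""
        else:
            pred = "yes" if r.predicted_damaging else "no"
        rows.append(
            {
                "cdna": r.cdna,
                "protein": r.protein,
                "case_alleles": r.case_alleles,
                "control_alleles": r.control_alleles,
                "predicted_damaging": pred,
                # the written rare flag restates the fixture convention:
                # non-RHC variants below 1% combined frequency
                "rare": "yes" if (not r.rhc and r.total_alleles < 40) else "no",
                "novel": "yes" if r.novel else "no",
            }
        )
    pd.DataFrame(rows, columns=list(_COUNT_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


def read_cohort_counts(path) -> CohortCounts:
    df = _read_tsv(path)
    row = df.iloc[0]
    return CohortCounts(
        case_chromosomes=int(row["case_chromosomes"]),
        control_chromosomes=int(row["control_chromosomes"]),
        reference_case=int(row["reference_case"]),
        reference_control=int(row["reference_control"]),
    )


def read_domain_table(path) -> DomainTable:
    df = _read_tsv(path)
    return DomainTable(
        [
            Domain(
                name=r["name"],
                abbrev=r["abbrev"],
                start=int(r["start"]),
                end=int(r["end"]),
                compartment=r["compartment"],
            )
            for _, r in df.iterrows()
        ]
    )


def read_domain_class_counts(path) -> dict[str, tuple[int, int]]:
    df = _read_tsv(path)
    return {
        r["abbrev"]: (int(r["d_alleles"]), int(r["nd_alleles"]))
        for _, r in df.iterrows()
    }


# -- packaged fixtures ------------------------------------------------------

def load_variant_counts() -> list[VariantRecord]:
    """The packaged 79-variant MC1R count table."""
    return read_variant_counts(_data_path("table1_variants.tsv"))


def load_cohort_counts() -> CohortCounts:
    """Cohort chromosome totals (2262/1738) and reference counts (936/976)."""
    return read_cohort_counts(_data_path("table2_reference.tsv"))


def load_domain_table() -> DomainTable:
    """The 15-domain MC1R residue partition (residues 1..317)."""
    return read_domain_table(_data_path("table4_domains.tsv"))


def load_domain_class_counts() -> dict[str, tuple[int, int]]:
    """Transcribed per-domain damaging/non-damaging allele tallies.

    These are the published per-domain tallies (indels excluded; one
    predicted-damaging extracellular variant tallied as non-damaging);
    see :func:`mc1rburden.domains.recompute_domain_class_counts` for the
    recompute-from-records route and its documented discrepancies.
    """
    return read_domain_class_counts(_data_path("table4_class_alleles.tsv"))


# -- classification / association / subject tables --------------------------

def write_classification(assignments: Sequence[ClassAssignment], path) -> None:
    pd.DataFrame(
        [
            {
                "cdna": a.variant.cdna,
                "protein": a.variant.protein,
                "class": a.klass.value,
                "frequency": f"{a.frequency:.6f}",
            }
            for a in assignments
        ]
    ).to_csv(path, sep="\t", index=False)


def write_association_report(rows: Sequence[dict], path) -> None:
    """Write an association report (one row per variant/class/domain)."""
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")


_SUBJECT_COLUMNS = (
    "id",
    "status",
    "hap1",
    "hap2",
    "hair",
    "eye",
    "skin",
    "nevus",
    "age",
)


def write_subjects(subjects: Sequence[SubjectRecord], path) -> None:
    rows = []
    for s in subjects:
        rows.append(
            {
                "id": s.id,
                "status": s.status,
                "hap1": ";".join(s.haplotype1),
                "hap2": ";".join(s.haplotype2),
                "hair": "" if s.hair_colour is None else s.hair_colour,
                "eye": "" if s.eye_colour is None else s.eye_colour,
                "skin": "" if s.skin_type is None else s.skin_type,
                "nevus": "" if s.nevus_count is None else s.nevus_count,
                "age": "" if s.age_at_diagnosis is None else s.age_at_diagnosis,
            }
        )
    pd.DataFrame(rows, columns=list(_SUBJECT_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


def read_subjects(path) -> list[SubjectRecord]:
    df = _read_tsv(path)
    missing = set(_SUBJECT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"missing column(s): {sorted(missing)}")
    subjects = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            subjects.append(
                SubjectRecord(
                    id=row.id,
                    status=row.status,
                    haplotype1=tuple(v for v in row.hap1.split(";") if v),
                    haplotype2=tuple(v for v in row.hap2.split(";") if v),
                    hair_colour=int(row.hair) if row.hair else None,
                    eye_colour=int(row.eye) if row.eye else None,
                    skin_type=int(row.skin) if row.skin else None,
                    nevus_count=int(row.nevus) if row.nevus else None,
                    age_at_diagnosis=float(row.age) if row.age else None,
                )
            )
        except ValueError as exc:
            raise ValueError(f"line {i}: {exc}") from exc
    return subjects


def read_simulation_spec(path) -> SimulationSpec:
    """Read a simulation specification from a TOML file.

    See the packaged ``example_simulation.toml`` for the expected layout.
    """
    import tomllib

    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    catalog = tuple(
        AlleleSpec(
            variant_id=a["variant_id"],
            klass=a["class"],
            control_frequency=float(a["control_frequency"]),
            codon=int(a["codon"]),
        )
        for a in doc.get("allele", [])
    )
    kwargs = {}
    for key in (
        "genotype_covariate_corr",
        "baseline_prevalence",
        "genetic_coding",
        "age_mean",
        "age_sd",
        "seed",
    ):
        if key in doc:
            kwargs[key] = doc[key]
    if "covariate_levels" in doc:
        kwargs["covariate_levels"] = {
            k: tuple(v) for k, v in doc["covariate_levels"].items()
        }
    if "covariate_effects" in doc:
        kwargs["covariate_effects"] = dict(doc["covariate_effects"])
    if "age_class_means" in doc:
        kwargs["age_class_means"] = dict(doc["age_class_means"])
    return SimulationSpec(
        n_cases=int(doc["n_cases"]),
        n_controls=int(doc["n_controls"]),
        allele_catalog=catalog,
        class_odds_ratios=dict(doc["class_odds_ratios"]),
        **kwargs,
    )


def example_simulation_spec_path():
    """Path of the packaged example simulation spec (TOML)."""
    return _data_path("example_simulation.toml")
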