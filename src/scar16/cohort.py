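"""Typed data model for the SCAR16 patient cohort and mutant-CHIP biochemistry.

Two small tables drive the whole analysis: one row per patient (demographics,
clinical phenotypes, the mutation on each allele) and one row per
biochemically characterized mutant CHIP protein.  This module validates
them on load, writes them back losslessly, and expands patients to
per-allele records for allele-level association tests.
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass, fields as dc_fields
from importlib import resources as importlib_resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "PatientRecord",
    "AlleleRecord",
    "BiochemRecord",
    "CohortLoadError",
    "load_cohort",
    "load_biochem",
    "write_cohort",
    "write_biochem",
    "explode_alleles",
    "load_domain_map",
    "domain_for_mutation",
    "cohort_frame",
    "biochem_frame",
    "allele_frame",
]

SEX_LEVELS = ("male", "female")
ANCESTRY_LEVELS = ("AMR", "SAS", "MENA", "EUR", "EAS")
YN_LEVELS = ("Y", "N")
DOMAIN_LEVELS = ("TPR", "CC", "Ubox")
OLIGOMER_LEVELS = ("dimer", "higher_order")

SARA_MIN, SARA_MAX = 0.0, 40.0

# residue ranges delimiting CHIP's three functional domains
_DOMAIN_RANGES = (("TPR", 1, 126), ("CC", 127, 229), ("Ubox", 230, 303))

_SUBSTITUTION_RE = re.compile(r"^[A-Z](\d+)[A-Z]$")


class CohortLoadError(ValueError):
    """Raised when a table row violates the data model; names row and field."""


@dataclass(frozen=True)
class PatientRecord:
    """One SCAR16 patient: demographics, allele annotations, phenotypes.

    ``aoo`` (age of onset, years) and ``hypogonadism`` may be missing
    (``None``); every other field is required.  ``sara`` is the 0-40 ataxia
    severity score.
    """

    patient_id: str
    sex: str
    ancestry: str
    homozygous: bool
    allele1: str
    allele2: str
    aoo: float | None
    sara: float
    cd: str
    tr: str
    hypogonadism: str | None

    def __post_init__(self):
        _check_level("sex", self.sex, SEX_LEVELS)
        _check_level("ancestry", self.ancestry, ANCESTRY_LEVELS)
        _check_level("cd", self.cd, YN_LEVELS)
        _check_level("tr", self.tr, YN_LEVELS)
        if self.hypogonadism is not None:
            _check_level("hypogonadism", self.hypogonadism, YN_LEVELS)
        if not (SARA_MIN <= self.sara <= SARA_MAX):
            raise CohortLoadError(
                f"field 'sara': {self.sara} outside [{SARA_MIN}, {SARA_MAX}]"
            )
        if self.aoo is not None and not self.aoo > 0:
            raise CohortLoadError(f"field 'aoo': {self.aoo} must be > 0")
        if self.homozygous and self.allele1 != self.allele2:
            raise CohortLoadError(
                f"field 'homozygous': patient marked homozygous but alleles "
                f"differ ({self.allele1!r} vs {self.allele2!r})"
            )


@dataclass(frozen=True)
class AlleleRecord:
    """One substitution allele of one patient, carrying the patient phenotypes."""

    patient_id: str
    mutation: str
    domain: str
    copies: int
    cd: str
    tr: str
    sara: float
    aoo: float | None

    def __post_init__(self):
        _check_level("domain", self.domain, DOMAIN_LEVELS)
        if self.copies not in (1, 2):
            raise CohortLoadError(f"field 'copies': {self.copies} not in {{1, 2}}")


@dataclass(frozen=True)
class BiochemRecord:
    """Biophysical/biochemical profile of one CHIP variant.

    kd: binding affinity to the HSP70 EEVD peptide (uM); bmax: binding
    capacity (umol/min); pct_hsp70_ub: % of HSP70 ubiquitinated;
    pct_chain: E2-dependent ubiquitin chain formation relative to WT (%);
    tm: melting temperature (degC); oligomer: dimer vs higher-order;
    pct_e: relative cellular protein stability (%).
    """

    mutation: str
    domain: str
    kd: float
    bmax: float
    pct_hsp70_ub: float
    pct_chain: float
    tm: float
    oligomer: str
    pct_e: float

    def __post_init__(self):
        _check_level("domain", self.domain, DOMAIN_LEVELS)
        _check_level("oligomer", self.oligomer, OLIGOMER_LEVELS)
        if not self.kd > 0:
            raise CohortLoadError(f"field 'kd': {self.kd} must be > 0")
        for name in ("pct_hsp70_ub", "pct_chain", "pct_e", "bmax"):
            val = getattr(self, name)
            if val < 0:
                raise CohortLoadError(f"field {name!r}: {val} must be >= 0")
        if not (20.0 <= self.tm <= 100.0):
            raise CohortLoadError(
                f"field 'tm': {self.tm} outside the plausible 20-100 degC range"
            )


def _check_level(field: str, value, levels: Sequence[str]) -> None:
    if value not in levels:
        raise CohortLoadError(
            f"field {field!r}: unknown level {value!r} (allowed: {list(levels)})"
        )


# --------------------------------------------------------------------- io

_PATIENT_FIELDS = [f.name for f in dc_fields(PatientRecord)]
_BIOCHEM_FIELDS = [f.name for f in dc_fields(BiochemRecord)]
_ALLELE_FIELDS = [f.name for f in dc_fields(AlleleRecord)]

_MISSING = {"", "NA", "NaN", "nan", "None", "."}


def _parse_float(value: str, field: str, row: int, optional: bool = False):
    if value is None or value.strip() in _MISSING:
        if optional:
            return None
        raise CohortLoadError(f"row {row}: field {field!r} is missing")
    try:
        out = float(value)
    except ValueError:
        raise CohortLoadError(
            f"row {row}: field {field!r}: {value!r} is not numeric"
        ) from None
    if math.isnan(out):
        if optional:
            return None
        raise CohortLoadError(f"row {row}: field {field!r} is missing")
    return out


def _parse_bool(value: str, field: str, row: int) -> bool:
    v = value.strip().lower()
    if v in {"true", "1", "yes", "y"}:
        return True
    if v in {"false", "0", "no", "n"}:
        return False
    raise CohortLoadError(f"row {row}: field {field!r}: {value!r} is not boolean")


def _read_rows(path, required: Sequence[str]) -> list[dict]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(row for row in fh if not row.startswith("#"))
        header = reader.fieldnames or []
        missing = [c for c in required if c not in header]
        if missing:
            raise CohortLoadError(f"missing column(s): {missing}")
        return list(reader)


def load_cohort(path) -> list[PatientRecord]:
    """Read a patient table (CSV with header); validate every row.

    Row order is preserved.  A header-only file yields an empty list.
    Errors name the offending row (1-based, excluding header) and field.
    """
    records: list[PatientRecord] = []
    for i, row in enumerate(_read_rows(path, _PATIENT_FIELDS), start=1):
        try:
            hypo = row["hypogonadism"]
            hypo = None if hypo is None or hypo.strip() in _MISSING else hypo.strip()
            records.append(
                PatientRecord(
                    patient_id=row["patient_id"].strip(),
                    sex=row["sex"].strip(),
                    ancestry=row["ancestry"].strip(),
                    homozygous=_parse_bool(row["homozygous"], "homozygous", i),
                    allele1=row["allele1"].strip(),
                    allele2=row["allele2"].strip(),
                    aoo=_parse_float(row["aoo"], "aoo", i, optional=True),
                    sara=_parse_float(row["sara"], "sara", i),
                    cd=row["cd"].strip(),
                    tr=row["tr"].strip(),
                    hypogonadism=hypo,
                )
            )
        except CohortLoadError as err:
            raise CohortLoadError(f"row {i}: {err}" if "row" not in str(err) else str(err)) from None
    return records


def load_biochem(path) -> list[BiochemRecord]:
    """Read a mutant-protein biochemistry table; validate every row."""
    records: list[BiochemRecord] = []
    for i, row in enumerate(_read_rows(path, _BIOCHEM_FIELDS), start=1):
        try:
            records.append(
                BiochemRecord(
                    mutation=row["mutation"].strip(),
                    domain=row["domain"].strip(),
                    kd=_parse_float(row["kd"], "kd", i),
                    bmax=_parse_float(row["bmax"], "bmax", i),
                    pct_hsp70_ub=_parse_float(row["pct_hsp70_ub"], "pct_hsp70_ub", i),
                    pct_chain=_parse_float(row["pct_chain"], "pct_chain", i),
                    tm=_parse_float(row["tm"], "tm", i),
                    oligomer=row["oligomer"].strip(),
                    pct_e=_parse_float(row["pct_e"], "pct_e", i),
                )
            )
        except CohortLoadError as err:
            raise CohortLoadError(f"row {i}: {err}" if "row" not in str(err) else str(err)) from None
    return records


def _frame(records: Iterable, columns: Sequence[str]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) if not isinstance(r, dict) else r for r in records],
                        columns=columns)


def cohort_frame(records: Iterable[PatientRecord]) -> pd.DataFrame:
    return _frame(records, _PATIENT_FIELDS)


def biochem_frame(records: Iterable[BiochemRecord]) -> pd.DataFrame:
    return _frame(records, _BIOCHEM_FIELDS)


def allele_frame(records: Iterable[AlleleRecord]) -> pd.DataFrame:
    return _frame(records, _ALLELE_FIELDS)


def write_cohort(records: Iterable[PatientRecord], path) -> None:
    cohort_frame(records).to_csv(path, index=False)


def write_biochem(records: Iterable[BiochemRecord], path) -> None:
    biochem_frame(records).to_csv(path, index=False)


# ------------------------------------------------------------ domain map

def load_domain_map(path=None) -> dict[str, str]:
    """Mutation -> domain map; defaults to the packaged resource file."""
    if path is None:
        ref = importlib_resources.files("scar16.resources") / "domain_map.csv"
        text = ref.read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    reader = csv.DictReader(lines)
    out = {}
    for row in reader:
        _check_level("domain", row["domain"].strip(), DOMAIN_LEVELS)
        out[row["mutation"].strip()] = row["domain"].strip()
    return out


def is_substitution(mutation: str) -> bool:
    """True for simple substitutions; stop (``*``) and frameshift alleles are not."""
    return bool(_SUBSTITUTION_RE.match(mutation.strip()))


def domain_for_mutation(mutation: str, domain_map: Mapping[str, str] | None = None) -> str:
    """Resolve a substitution's domain, via the map or residue-range fallback."""
    mutation = mutation.strip()
    if domain_map and mutation in domain_map:
        return domain_map[mutation]
    m = _SUBSTITUTION_RE.match(mutation)
    if not m:
        raise CohortLoadError(f"{mutation!r} is not a substitution mutation")
    pos = int(m.group(1))
    for name, lo, hi in _DOMAIN_RANGES:
        if lo <= pos <= hi:
            return name
    raise CohortLoadError(f"{mutation!r}: residue {pos} outside CHIP (1-303)")


# ------------------------------------------------------- allele expansion

def explode_alleles(
    patients: Iterable[PatientRecord],
    domain_map: Mapping[str, str] | None = None,
    copy_policy: str = "per_allele_copy",
) -> list[AlleleRecord]:
    """Expand patients to per-allele records for allele-level association tests.

    Stop-codon and frameshift alleles are dropped (no protein to
    characterize).  For a homozygous patient, ``per_allele_copy`` yields one
    record with ``copies=2``; ``per_distinct_mutation`` yields one record
    with ``copies=1``.  Compound heterozygotes contribute one record per
    substitution allele.
    """
    if copy_policy not in ("per_allele_copy", "per_distinct_mutation"):
        raise ValueError(f"unknown copy_policy {copy_policy!r}")
    if domain_map is None:
        domain_map = load_domain_map()
    out: list[AlleleRecord] = []
    for patient in patients:
        alleles = [patient.allele1] if patient.homozygous else [
            patient.allele1, patient.allele2
        ]
        subs = [a for a in alleles if is_substitution(a)]
        for mut in subs:
            copies = 2 if (patient.homozygous and copy_policy == "per_allele_copy") else 1
            out.append(
                AlleleRecord(
                    patient_id=patient.patient_id,
                    mutation=mut,
                    domain=domain_for_mutation(mut, domain_map),
                    copies=copies,
                    cd=patient.cd,
                    tr=patient.tr,
                    sara=patient.sara,
                    aoo=patient.aoo,
                )
            )
    return out
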