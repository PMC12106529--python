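"""Occupational cohort summary tables.

Each cohort is a single summary row: average exposure duration and
intensity, cumulative exposure, age at exposure onset, mesothelioma case
count, total expected mortality, and the excess mesothelioma mortality
fraction with its complement, the "survival rate function"
``S = 1 - excess``.  The built-in table holds the six non-textile
chrysotile cohorts (mining and general-industry) on which every analysis
in this package is exercised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

from .errors import DataSchemaError, DataValidationError

__all__ = [
    "CohortRecord",
    "CohortTable",
    "Finding",
    "builtin_table1",
    "load_cohorts",
    "save_cohorts",
    "validate_consistency",
    "CSV_COLUMNS",
]

#: Canonical CSV column order (one column per CohortRecord field).
CSV_COLUMNS = (
    "name",
    "duration_years",
    "intensity_fcc",
    "cumulative_fcc_years",
    "onset_age",
    "meso_cases",
    "expected_mortality",
    "excess_rate",
    "survival",
)


@dataclass(frozen=True)
class CohortRecord:
    """One cohort's exposure and mortality summary.

    Parameters
    ----------
    name : str
        Cohort label.
    duration_years : float
        Average exposure duration D (years, > 0).
    intensity_fcc : float
        Average exposure intensity E (PCM f/cc, >= 0).
    cumulative_fcc_years : float
        Cumulative exposure CE (f/cc-years, >= 0); nominally E * D.
    onset_age : float
        Average age at exposure onset Y (years, > 0).
    meso_cases : int
        Observed mesothelioma cases M (>= 0).
    expected_mortality : float
        Total expected mortality TM from all causes (> 0).
    excess_rate : float
        Excess mesothelioma mortality fraction, in [0, 1].
    survival : float
        Survival rate function S = 1 - excess_rate, in [0, 1].
    """

    name: str
    duration_years: float
    intensity_fcc: float
    cumulative_fcc_years: float
    onset_age: float
    meso_cases: int
    expected_mortality: float
    excess_rate: float
    survival: float

    def __post_init__(self) -> None:
        if not self.name:
            raise DataValidationError("cohort name must be non-empty")
        if self.duration_years <= 0:
            raise DataValidationError(f"{self.name}: duration_years must be > 0")
        if self.intensity_fcc < 0:
            raise DataValidationError(f"{self.name}: intensity_fcc must be >= 0")
        if self.cumulative_fcc_years < 0:
            raise DataValidationError(f"{self.name}: cumulative exposure must be >= 0")
        if self.onset_age <= 0:
            raise DataValidationError(f"{self.name}: onset_age must be > 0")
        if self.meso_cases < 0 or self.meso_cases != int(self.meso_cases):
            raise DataValidationError(f"{self.name}: meso_cases must be a non-negative integer")
        if self.expected_mortality <= 0:
            raise DataValidationError(f"{self.name}: expected_mortality must be > 0")
        if not 0.0 <= self.excess_rate <= 1.0:
            raise DataValidationError(f"{self.name}: excess_rate must lie in [0, 1]")
        if not 0.0 <= self.survival <= 1.0:
            raise DataValidationError(f"{self.name}: survival must lie in [0, 1]")
        if self.meso_cases > self.expected_mortality:
            raise DataValidationError(f"{self.name}: meso_cases exceeds expected_mortality")


class CohortTable:
    """Ordered, uniquely named collection of :class:`CohortRecord`."""

    def __init__(self, records: Iterable[CohortRecord], label: str = "") -> None:
        self.records = tuple(records)
        self.label = label
        if not self.records:
            raise DataValidationError("a cohort table must contain at least one record")
        names = [r.name for r in self.records]
        if len(set(names)) != len(names):
            raise DataValidationError("cohort names must be unique")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[CohortRecord]:
        return iter(self.records)

    def __getitem__(self, key: int | str) -> CohortRecord:
        if isinstance(key, str):
            for r in self.records:
                if r.name == key:
                    return r
            raise KeyError(key)
        return self.records[key]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CohortTable):
            return NotImplemented
        return self.records == other.records

    def __repr__(self) -> str:
        return f"CohortTable({self.label!r}, n={len(self)})"

    def to_dataframe(self) -> pd.DataFrame:
        """Return the table as a pandas DataFrame in canonical column order."""
        return pd.DataFrame([
            {f.name if f.name != "name" else "name": getattr(r, f.name) for f in fields(CohortRecord)}
            for r in self.records
        ]).rename(columns=_FIELD_TO_CSV)[list(CSV_COLUMNS)]

    def column(self, field: str) -> list:
        """Values of one record field across all cohorts, in table order."""
        return [getattr(r, field) for r in self.records]


_FIELD_TO_CSV = {f: c for f, c in zip(
    ("name", "duration_years", "intensity_fcc", "cumulative_fcc_years",
     "onset_age", "meso_cases", "expected_mortality", "excess_rate", "survival"),
    CSV_COLUMNS,
)}


# The six non-textile chrysotile cohorts (mining and general industry),
# as printed: Québec and Balangero miners/millers, Quinghai miners,
# New Orleans asbestos-cement workers, Connecticut friction-product
# workers, and the Russian (Asbest) miners/millers cohort.
_TABLE1_ROWS = (
    ("Québec", 35.0, 17.14, 600.0, 23.0, 33, 5913.0, 0.0054, 0.995),
    ("Balangero", 16.95, 42.5, 721.0, 27.0, 7, 549.0, 0.0128, 0.987),
    ("Quinghai", 27.3, 4.39, 120.0, 21.7, 0, 366.0, 0.0, 1.0),
    ("New Orleans", 3.9, 5.64, 22.0, 27.0, 0, 500.0, 0.0, 1.0),
    ("Connecticut", 8.04, 5.72, 46.0, 31.0, 2, 274.0, 0.00072, 0.999),
    ("Russian", 15.0, 2.24, 33.6, 24.0, 13, 10351.0, 0.0012, 0.998),
)


def builtin_table1() -> CohortTable:
    """The built-in six-cohort non-textile chrysotile table.

    The ``excess_rate`` column is stored exactly as published, not
    recomputed from ``meso_cases / expected_mortality``; the two disagree
    for some cohorts (see :func:`validate_consistency`).
    """
    return CohortTable(
        (CohortRecord(*row) for row in _TABLE1_ROWS),
        label="non-textile chrysotile cohorts",
    )


def save_cohorts(table: CohortTable, path: str | Path) -> None:
    """Write a cohort table as UTF-8, comma-separated CSV."""
    # pandas' default float formatting is shortest-round-trip: lossless
    table.to_dataframe().to_csv(path, index=False)


def load_cohorts(path: str | Path) -> CohortTable:
    """Read a cohort table from CSV written by :func:`save_cohorts`.

    Raises
    ------
    DataSchemaError
        If the file is empty or a required column is missing.
    DataValidationError
        If a cell fails to parse or a record violates its invariants;
        parse failures name the offending row.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise DataSchemaError(f"{path}: empty file, expected columns {CSV_COLUMNS}") from None
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise DataSchemaError(f"{path}: missing column(s) {missing}")
    records = []
    for i, row in df.iterrows():
        values: list = [row["name"]]
        for col in CSV_COLUMNS[1:]:
            cell = row[col]
            try:
                values.append(int(cell) if col == "meso_cases" else float(cell))
            except ValueError:
                raise DataValidationError(
                    f"{path}: row {i} ({row['name']!r}): cannot parse {col}={cell!r}"
                ) from None
        records.append(CohortRecord(*values))
    return CohortTable(records, label=path.stem)


@dataclass(frozen=True)
class Finding:
    """One internal-consistency warning for a cohort record."""

    cohort: str
    check: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.check}] {self.cohort}: {self.message}"


def validate_consistency(
    table: CohortTable,
    tol_ce: float = 0.02,
    tol_rate: float = 0.001,
) -> list[Finding]:
    """Cross-check each record's redundant columns; return warnings.

    Three checks per record: cumulative exposure against intensity x
    duration (relative tolerance ``tol_ce``); survival against
    ``1 - excess_rate`` (absolute tolerance ``tol_rate``); and the raw
    case rate ``M/TM`` against the stored ``excess_rate`` (relative
    tolerance ``tol_rate`` where the stored rate is nonzero).
    Inconsistencies are reported, never raised: published tables can
    legitimately disagree with their own marginals (rounding, differing
    reference populations), and silently "fixing" them would change
    every downstream fit.
    """
    if not (0 < tol_ce < 1 and 0 < tol_rate < 1):
        raise ValueError("tolerances must lie in (0, 1)")
    findings: list[Finding] = []
    for r in table:
        prod = r.intensity_fcc * r.duration_years
        if r.cumulative_fcc_years > 0 and not math.isclose(
            prod, r.cumulative_fcc_years, rel_tol=tol_ce
        ):
            findings.append(Finding(
                r.name, "ce_vs_product",
                f"CE={r.cumulative_fcc_years} but E*D={prod:.4g}",
            ))
        if abs(r.survival - (1.0 - r.excess_rate)) > tol_rate:
            findings.append(Finding(
                r.name, "survival_vs_excess",
                f"S={r.survival} but 1-excess={1.0 - r.excess_rate:.6g}",
            ))
        raw = r.meso_cases / r.expected_mortality
        if r.excess_rate > 0:
            if not math.isclose(raw, r.excess_rate, rel_tol=tol_rate):
                findings.append(Finding(
                    r.name, "cases_vs_excess",
                    f"M/TM={raw:.6g} but excess_rate={r.excess_rate}",
                ))
        elif r.meso_cases > 0:
            findings.append(Finding(
                r.name, "cases_vs_excess",
                f"M={r.meso_cases} but excess_rate=0",
            ))
    return findings


def with_excess(record: CohortRecord, excess_rate: float) -> CohortRecord:
    """Copy of *record* with a new excess rate and matching survival."""
    return replace(record, excess_rate=excess_rate, survival=1.0 - excess_rate)
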