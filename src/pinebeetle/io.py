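"""CSV schemas and input validation.

All files are UTF-8, comma-separated, with a header row and "." as the
decimal mark.  Schemas:

* ``trials.csv`` — stage, year, species, host_class, tree_id, unit_id,
  n_exposed, n_success, phloem_mm (optional), paired_male (optional)
* ``traps.csv`` — site, week, year, treatment, count
* ``chem.csv`` — species, tree_id, compound, mg_per_g
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .anova import ChemRecord, TRANSFORM_REGISTRY, TrapRecord
from .proportions import Stage, TrialRecord, trials_to_frame

__all__ = [
    "ValidationIssue",
    "ValidationReport",
    "read_trials",
    "write_trials",
    "read_traps",
    "write_traps",
    "read_chem",
    "write_chem",
    "validate_input",
]

SCHEMAS = {
    "trials": ["stage", "year", "species", "host_class", "tree_id", "unit_id",
               "n_exposed", "n_success"],
    "traps": ["site", "week", "year", "treatment", "count"],
    "chem": ["species", "tree_id", "compound", "mg_per_g"],
}


@dataclass(frozen=True)
class ValidationIssue:
    row: int | None  # 1-based data row; None for file-level issues
    severity: str    # "error" | "warning"
    message: str


@dataclass(frozen=True)
class ValidationReport:
    schema: str
    path: str
    issues: tuple[ValidationIssue, ...]

    @property
    def errors(self) -> tuple[ValidationIssue, ...]:
        return tuple(i for i in self.issues if i.severity == "error")

    @property
    def ok(self) -> bool:
        return not self.errors


# ---------------------------------------------------------------------------
# readers / writers


def write_trials(records: Iterable[TrialRecord], path) -> None:
    trials_to_frame(records).to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, "trials", path)
    return df


def write_traps(records: Iterable[TrapRecord], path) -> None:
    pd.DataFrame(
        [{"site": r.site, "week": r.week, "year": r.year,
          "treatment": r.treatment, "count": r.count} for r in records],
        columns=SCHEMAS["traps"],
    ).to_csv(path, index=False)


def read_traps(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, "traps", path)
    return df


def write_chem(records: Iterable[ChemRecord], path) -> None:
    pd.DataFrame(
        [{"species": r.species, "tree_id": r.tree_id,
          "compound": r.compound, "mg_per_g": r.mg_per_g} for r in records],
        columns=SCHEMAS["chem"],
    ).to_csv(path, index=False)


def read_chem(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, "chem", path)
    return df


def _require_columns(df: pd.DataFrame, schema: str, path) -> None:
    missing = [c for c in SCHEMAS[schema] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


# ---------------------------------------------------------------------------
# validation


def validate_input(path, schema: str) -> ValidationReport:
    """Row-level validation of a CSV against one of the known schemas.

    Count violations (``n_success > n_exposed``), negative counts or
    concentrations, and unknown stage labels are errors; an unregistered
    compound label is only a warning (the transform registry falls back
    to identity).
    """
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; expected one of {sorted(SCHEMAS)}")
    path = Path(path)
    issues: list[ValidationIssue] = []
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # unreadable file is a hard error
        raise OSError(f"cannot read {path}: {exc}") from exc
    missing = [c for c in SCHEMAS[schema] if c not in df.columns]
    if missing:
        issues.append(ValidationIssue(None, "error", f"missing column(s) {missing}"))
        return ValidationReport(schema, str(path), tuple(issues))

    stage_values = {s.value for s in Stage}
    for idx, row in df.iterrows():
        rownum = int(idx) + 1
        if schema == "trials":
            if row["stage"] not in stage_values:
                issues.append(ValidationIssue(
                    rownum, "error", f"unknown stage {row['stage']!r}"))
            if row["n_exposed"] < 0 or row["n_success"] < 0:
                issues.append(ValidationIssue(rownum, "error", "negative count"))
            elif row["n_success"] > row["n_exposed"]:
                issues.append(ValidationIssue(
                    rownum, "error",
                    f"n_success ({row['n_success']}) exceeds n_exposed "
                    f"({row['n_exposed']})"))
            if "phloem_mm" in df.columns and pd.notna(row.get("phloem_mm")):
                if row["phloem_mm"] <= 0:
                    issues.append(ValidationIssue(
                        rownum, "error", "phloem_mm must be positive"))
        elif schema == "traps":
            if row["count"] < 0:
                issues.append(ValidationIssue(rownum, "error", "negative count"))
        elif schema == "chem":
            if row["mg_per_g"] < 0:
                issues.append(ValidationIssue(
                    rownum, "error", "negative concentration"))
            if row["compound"] not in TRANSFORM_REGISTRY:
                issues.append(ValidationIssue(
                    rownum, "warning",
                    f"compound {row['compound']!r} not in transform registry"))
    return ValidationReport(schema, str(path), tuple(issues))
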