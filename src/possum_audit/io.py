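"""Cohort file input/output.

Cohorts travel as delimited text (RFC-4180 CSV by default, tab accepted):
a header row and the columns ``ps, os, urgency, specialty, died_30d,
directly_admitted, data_complete``.  Urgency accepts the synonyms
``emergency``, ``non-elective``, ``non_elective``, ``ne`` and ``1`` for
non-elective surgery.  Unknown columns are preserved but ignored.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd

from .errors import SchemaError, ValidationError
from .models import (
    Cohort,
    COHORT_COLUMNS,
    ELECTIVE,
    NON_ELECTIVE,
    OS_MAX,
    OS_MIN,
    PS_MAX,
    PS_MIN,
    SPECIALTIES,
)

__all__ = ["read_cohort", "write_cohort"]

REQUIRED_COLUMNS = tuple(COHORT_COLUMNS)

_URGENCY_SYNONYMS = {
    "elective": ELECTIVE,
    "0": ELECTIVE,
    "emergency": NON_ELECTIVE,
    "non-elective": NON_ELECTIVE,
    "non_elective": NON_ELECTIVE,
    "nonelective": NON_ELECTIVE,
    "ne": NON_ELECTIVE,
    "1": NON_ELECTIVE,
}

_SPECIALTY_SYNONYMS = {s: s for s in SPECIALTIES}
_SPECIALTY_SYNONYMS.update(
    {"general surgery": "general_surgery", "general": "general_surgery",
     "gynecology": "gynaecology"}
)


def _row_errors(df: pd.DataFrame) -> list[str]:
    """Collect per-row validation problems, 1-based data line numbers."""
    errors = []
    for col in ("ps", "os", "died_30d", "directly_admitted", "data_complete"):
        bad = pd.to_numeric(df[col], errors="coerce").isna()
        for i in df.index[bad]:
            errors.append(f"row {i + 1}: column {col!r} is not numeric ({df.at[i, col]!r})")
    if errors:
        return errors
    ps = pd.to_numeric(df["ps"])
    os_ = pd.to_numeric(df["os"])
    for i in df.index[(ps < PS_MIN) | (ps > PS_MAX)]:
        errors.append(
            f"row {i + 1}: ps={ps[i]} outside the valid range [{PS_MIN}, {PS_MAX}]"
        )
    for i in df.index[(os_ < OS_MIN) | (os_ > OS_MAX)]:
        errors.append(
            f"row {i + 1}: os={os_[i]} outside the valid range [{OS_MIN}, {OS_MAX}]"
        )
    for col in ("died_30d", "directly_admitted", "data_complete"):
        vals = pd.to_numeric(df[col])
        for i in df.index[~vals.isin((0, 1))]:
            errors.append(f"row {i + 1}: column {col!r} must be 0 or 1 ({vals[i]!r})")
    urg = df["urgency"].astype(str).str.strip().str.lower()
    for i in df.index[~urg.isin(_URGENCY_SYNONYMS)]:
        errors.append(f"row {i + 1}: unrecognised urgency {df.at[i, 'urgency']!r}")
    spec = df["specialty"].astype(str).str.strip().str.lower()
    for i in df.index[~spec.isin(_SPECIALTY_SYNONYMS)]:
        errors.append(f"row {i + 1}: unrecognised specialty {df.at[i, 'specialty']!r}")
    return errors


def read_cohort(path, sep: str | None = None, skip_bad: bool = False) -> Cohort:
    """Read a cohort file, validating schema and every row.

    ``sep=None`` sniffs comma vs tab from the header line.  Row-level
    problems fail fast with line numbers; with ``skip_bad`` the offending
    rows are dropped with a warning instead.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"cohort file not found: {path}")
    if sep is None:
        header = path.open(encoding="utf-8").readline()
        sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep, dtype=str, encoding="utf-8")
    df.columns = [str(c).strip().lower() for c in df.columns]
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort file {path} is missing required column(s): {missing}")
    errors = _row_errors(df)
    if errors:
        if not skip_bad:
            raise ValidationError(
                f"{len(errors)} invalid row(s) in {path}:\n  " + "\n  ".join(errors[:20])
            )
        bad_rows = sorted({int(e.split()[1].rstrip(":")) - 1 for e in errors})
        warnings.warn(f"dropping {len(bad_rows)} invalid row(s) from {path}", stacklevel=2)
        df = df.drop(index=bad_rows)
        if df.empty:
            raise ValidationError(f"no valid rows remain in {path}")
    out = df.copy()
    for col in ("ps", "os", "died_30d", "directly_admitted", "data_complete"):
        out[col] = pd.to_numeric(out[col]).astype(int)
    out["urgency"] = (
        out["urgency"].astype(str).str.strip().str.lower().map(_URGENCY_SYNONYMS)
    )
    out["specialty"] = (
        out["specialty"].astype(str).str.strip().str.lower().map(_SPECIALTY_SYNONYMS)
    )
    return Cohort(out, provenance=str(path))


def write_cohort(cohort: Cohort, path, sep: str = ",") -> None:
    """Write a cohort back to delimited text (round-trips with read_cohort)."""
    cohort.episodes.to_csv(path, sep=sep, index=False, encoding="utf-8")
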