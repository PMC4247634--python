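"""POSSUM-family risk models, patient episodes and cohort containers.

The POSSUM system grades 12 physiological factors (summed to the
physiological score, PS) and 6 operative factors (summed to the operative
severity score, OS), each factor graded 1, 2, 4 or 8.  The toolkit consumes
PS and OS as integers; grading raw physiology is out of scope.  Predicted
30-day mortality risk comes from a linear-logistic model

    ln[R / (1 - R)] = intercept + b_ps * PS + b_os * OS + b_ne * NE

where NE indicates non-elective (emergency) surgery and is only present in
recalibrated models such as S-POSSUM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ValidationError

__all__ = [
    "PS_MIN",
    "PS_MAX",
    "OS_MIN",
    "OS_MAX",
    "ELECTIVE",
    "NON_ELECTIVE",
    "SPECIALTIES",
    "RiskModel",
    "POSSUM",
    "P_POSSUM",
    "S_POSSUM",
    "PREDEFINED_MODELS",
    "PatientEpisode",
    "Cohort",
    "ExclusionReport",
    "predicted_risk",
    "score_cohort",
    "apply_eligibility",
]

# Arithmetic bounds of the score sums: 12 factors * grade 1..8 and
# 6 factors * grade 1..8.
PS_MIN, PS_MAX = 12, 96
OS_MIN, OS_MAX = 6, 48

ELECTIVE = "elective"
NON_ELECTIVE = "non_elective"
URGENCIES = (ELECTIVE, NON_ELECTIVE)

SPECIALTIES = ("general_surgery", "urology", "gynaecology", "other")


@dataclass(frozen=True)
class RiskModel:
    """A linear-logistic 30-day mortality model on PS, OS and urgency.

    Parameters
    ----------
    name
        Human-readable model label, carried into reports.
    intercept
        Constant term on the log-odds scale.
    coef_ps, coef_os
        Log-odds increment per PS / OS point.
    coef_nonelective
        Log-odds increment for non-elective surgery; 0 for models without
        an urgency term (POSSUM, P-POSSUM).
    """

    name: str
    intercept: float
    coef_ps: float
    coef_os: float
    coef_nonelective: float = 0.0

    @property
    def has_urgency_term(self) -> bool:
        return self.coef_nonelective != 0.0

    def linear_predictor(self, ps, os, nonelective=0) -> np.ndarray | float:
        """Log-odds of death for the given scores (vectorised)."""
        return (
            self.intercept
            + self.coef_ps * np.asarray(ps, dtype=float)
            + self.coef_os * np.asarray(os, dtype=float)
            + self.coef_nonelective * np.asarray(nonelective, dtype=float)
        )

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "intercept": self.intercept,
            "coef_ps": self.coef_ps,
            "coef_os": self.coef_os,
            "coef_nonelective": self.coef_nonelective,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RiskModel":
        return cls(
            name=d["name"],
            intercept=float(d["intercept"]),
            coef_ps=float(d["coef_ps"]),
            coef_os=float(d["coef_os"]),
            coef_nonelective=float(d.get("coef_nonelective", 0.0)),
        )


#: Original exponential-analysis mortality equation.
POSSUM = RiskModel("POSSUM", intercept=-7.04, coef_ps=0.13, coef_os=0.16)

#: Portsmouth refinement; predicts lower mortality at most score pairs.
P_POSSUM = RiskModel("P-POSSUM", intercept=-9.065, coef_ps=0.1692, coef_os=0.155)

#: Recalibration for level 1 critical care, adding an urgency term
#: (NE = 1 for non-elective surgery).
S_POSSUM = RiskModel(
    "S-POSSUM", intercept=-6.505, coef_ps=0.144, coef_os=0.03, coef_nonelective=1.057
)

PREDEFINED_MODELS = {
    "possum": POSSUM,
    "pposum": P_POSSUM,
    "p-possum": P_POSSUM,
    "sposum": S_POSSUM,
    "s-possum": S_POSSUM,
}


def _check_scores(ps, os, strict: bool = True) -> None:
    """Validate PS/OS against the arithmetic grading bounds.

    With ``strict=False`` out-of-range scores raise only a warning, for
    research inputs scored under non-standard conventions.
    """
    ps = np.asarray(ps)
    os_ = np.asarray(os)
    problems = []
    if np.any((ps < PS_MIN) | (ps > PS_MAX)):
        bad = np.asarray(ps)[(ps < PS_MIN) | (ps > PS_MAX)]
        problems.append(
            f"physiological_score out of bounds [{PS_MIN}, {PS_MAX}]: "
            f"{np.unique(bad)[:5].tolist()}"
        )
    if np.any((os_ < OS_MIN) | (os_ > OS_MAX)):
        bad = np.asarray(os_)[(os_ < OS_MIN) | (os_ > OS_MAX)]
        problems.append(
            f"operative_score out of bounds [{OS_MIN}, {OS_MAX}]: "
            f"{np.unique(bad)[:5].tolist()}"
        )
    if problems:
        msg = "; ".join(problems)
        if strict:
            raise ValidationError(msg)
        warnings.warn(msg, stacklevel=3)


@dataclass(frozen=True)
class PatientEpisode:
    """One post-operative admission to the level 1 care ward."""

    physiological_score: int
    operative_score: int
    urgency: str
    specialty: str
    died_30d: int
    directly_admitted: bool = True
    data_complete: bool = True

    def __post_init__(self):
        _check_scores(self.physiological_score, self.operative_score)
        if self.urgency not in URGENCIES:
            raise ValidationError(f"urgency must be one of {URGENCIES}, got {self.urgency!r}")
        if self.specialty not in SPECIALTIES:
            raise ValidationError(
                f"specialty must be one of {SPECIALTIES}, got {self.specialty!r}"
            )
        if self.died_30d not in (0, 1):
            raise ValidationError(f"died_30d must be 0 or 1, got {self.died_30d!r}")


#: Cohort DataFrame column schema (dtype-coerced on construction).
COHORT_COLUMNS = {
    "ps": int,
    "os": int,
    "urgency": str,
    "specialty": str,
    "died_30d": int,
    "directly_admitted": int,
    "data_complete": int,
}


@dataclass
class Cohort:
    """An ordered collection of patient episodes backed by a DataFrame.

    The frame always carries the columns ``ps, os, urgency, specialty,
    died_30d, directly_admitted, data_complete``; extra columns are
    preserved but ignored by the analyses.
    """

    episodes: pd.DataFrame
    provenance: str = "unspecified"
    strict: bool = field(default=True, repr=False)

    def __post_init__(self):
        df = self.episodes
        missing = [c for c in COHORT_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"cohort frame missing columns: {missing}")
        df = df.copy()
        for col, typ in COHORT_COLUMNS.items():
            if typ is int:
                df[col] = df[col].astype(int)
        self.episodes = df.reset_index(drop=True)
        self._validate()

    def _validate(self):
        df = self.episodes
        _check_scores(df["ps"].to_numpy(), df["os"].to_numpy(), strict=self.strict)
        bad_urg = ~df["urgency"].isin(URGENCIES)
        if bad_urg.any():
            rows = df.index[bad_urg][:5].tolist()
            raise ValidationError(f"invalid urgency at rows {rows}")
        bad_out = ~df["died_30d"].isin((0, 1))
        if bad_out.any():
            rows = df.index[bad_out][:5].tolist()
            raise ValidationError(f"died_30d must be 0/1; offending rows {rows}")

    def __len__(self) -> int:
        return len(self.episodes)

    def __iter__(self) -> Iterator[PatientEpisode]:
        for row in self.episodes.itertuples(index=False):
            yield PatientEpisode(
                physiological_score=row.ps,
                operative_score=row.os,
                urgency=row.urgency,
                specialty=row.specialty,
                died_30d=row.died_30d,
                directly_admitted=bool(row.directly_admitted),
                data_complete=bool(row.data_complete),
            )

    @property
    def ps(self) -> np.ndarray:
        return self.episodes["ps"].to_numpy()

    @property
    def os(self) -> np.ndarray:
        return self.episodes["os"].to_numpy()

    @property
    def nonelective(self) -> np.ndarray:
        """0/1 indicator for non-elective surgery (the NE covariate)."""
        return (self.episodes["urgency"] == NON_ELECTIVE).to_numpy().astype(int)

    @property
    def outcomes(self) -> np.ndarray:
        return self.episodes["died_30d"].to_numpy()

    @property
    def n_deaths(self) -> int:
        return int(self.outcomes.sum())

    def subset(self, mask, provenance: str | None = None) -> "Cohort":
        return Cohort(
            self.episodes.loc[np.asarray(mask)],
            provenance=provenance or self.provenance,
            strict=self.strict,
        )

    def with_provenance(self, provenance: str) -> "Cohort":
        return replace(self, provenance=provenance)


def predicted_risk(model: RiskModel, ps, os, urgency=None, strict: bool = True):
    """Predicted mortality risk for given scores under ``model``.

    ``urgency`` may be a string (``elective``/``non_elective``), a 0/1
    indicator, or an array of either; it is required only for models with a
    non-zero urgency coefficient and treated as elective when absent.
    Returns a float for scalar inputs, an array otherwise; risks are kept at
    full precision (rounding is a presentation concern only).
    """
    _check_scores(ps, os, strict=strict)
    if urgency is None:
        if model.has_urgency_term:
            raise ValidationError(
                f"model {model.name!r} has an urgency term; urgency is required"
            )
        ne = 0
    else:
        ne = _coerce_nonelective(urgency)
    lp = model.linear_predictor(ps, os, ne)
    risk = expit(lp)
    if np.isscalar(ps) or np.asarray(ps).ndim == 0:
        return float(risk)
    return risk


def _coerce_nonelective(urgency) -> np.ndarray | int:
    """Normalise urgency input to a 0/1 NE indicator."""
    if isinstance(urgency, str):
        if urgency not in URGENCIES:
            raise ValidationError(f"urgency must be one of {URGENCIES}, got {urgency!r}")
        return int(urgency == NON_ELECTIVE)
    arr = np.asarray(urgency)
    if arr.dtype.kind in "US":
        bad = ~np.isin(arr, URGENCIES)
        if bad.any():
            raise ValidationError(f"invalid urgency values: {np.unique(arr[bad])[:5].tolist()}")
        return (arr == NON_ELECTIVE).astype(int)
    if not np.isin(arr, (0, 1)).all():
        raise ValidationError("numeric urgency indicator must be 0/1")
    return arr.astype(int)


def score_cohort(model: RiskModel, cohort: Cohort):
    """Predicted risk and observed outcome per episode, order preserved.

    Returns ``(risks, outcomes)`` as aligned arrays; ``risks.sum()`` is the
    model-expected number of deaths in the cohort.
    """
    if len(cohort) == 0:
        raise ValidationError("cannot score an empty cohort")
    risks = predicted_risk(
        model, cohort.ps, cohort.os, cohort.nonelective, strict=cohort.strict
    )
    return np.asarray(risks, dtype=float), cohort.outcomes.copy()


@dataclass(frozen=True)
class ExclusionReport:
    """Counts from the eligibility filter, one reason per excluded episode."""

    n_input: int
    n_eligible: int
    n_incomplete: int
    n_indirect: int

    def __post_init__(self):
        assert self.n_input == self.n_eligible + self.n_incomplete + self.n_indirect

    @property
    def empty_output(self) -> bool:
        return self.n_eligible == 0

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_eligible": self.n_eligible,
            "excluded_insufficient_data": self.n_incomplete,
            "excluded_not_directly_admitted": self.n_indirect,
        }


def apply_eligibility(raw: Cohort) -> tuple[Cohort, ExclusionReport]:
    """Drop episodes with incomplete data or indirect admission.

    An episode failing both checks is counted once, under insufficient
    data, so reason counts sum exactly to the number excluded.
    """
    df = raw.episodes
    incomplete = df["data_complete"] == 0
    indirect = (df["directly_admitted"] == 0) & ~incomplete
    eligible_mask = ~incomplete & ~indirect
    report = ExclusionReport(
        n_input=len(df),
        n_eligible=int(eligible_mask.sum()),
        n_incomplete=int(incomplete.sum()),
        n_indirect=int(indirect.sum()),
    )
    if report.empty_output:
        warnings.warn("eligibility filter removed every episode", stacklevel=2)
    eligible = raw.subset(eligible_mask, provenance=f"{raw.provenance} [eligible]")
    return eligible, report
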