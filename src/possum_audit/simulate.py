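"""Seeded synthetic surgical cohorts for exercising the validation pipeline.

No patient-level POSSUM dataset is publicly deposited, so the pipeline is
tested against simulated level 1 care cohorts with the statistical
structure the analyses assume: integer PS/OS drawn from right-skewed
discrete distributions, an elective/non-elective mix, a true logistic
mortality model, and a controllable calibration distortion.  The distortion
acts on the log-odds scale,

    true ln-odds = ln(lambda) + slope * (truth-model ln-odds),

so ``lambda`` is a uniform odds multiplier (calibration-in-the-large) and
``slope`` a logit slope (risk spread); ``lambda = slope = 1`` makes the
truth model perfectly calibrated.

The packaged default spec emulates the observable margins of a ~2552
episode level 1 care ward cohort: 24.5% non-elective surgery, overall
30-day mortality near 3.45% splitting to roughly 1.7% elective / 8.7%
emergency, and mean POSSUM / P-POSSUM predicted risks near 13.8% / 6.4%
so that validating those models yields overall O:E ratios near 0.25 and
0.54.  Score distributions are discretised log-normals over the valid
ranges (no score histogram is available to fit, so shapes were chosen to
reproduce those margins and are config-exposed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import lognorm, norm

from .errors import ValidationError
from .models import (
    Cohort,
    ELECTIVE,
    NON_ELECTIVE,
    OS_MAX,
    OS_MIN,
    PS_MAX,
    PS_MIN,
    RiskModel,
    SPECIALTIES,
)

__all__ = ["CohortSpec", "generate", "default_cohort_spec", "lognormal_score_weights"]

PS_GRID = np.arange(PS_MIN, PS_MAX + 1)
OS_GRID = np.arange(OS_MIN, OS_MAX + 1)

# Default-cohort constants (see module docstring for the margins they hit).
_DEFAULT_PS_SHAPE = (0.276, 20.4)  # lognormal (sigma, median) for PS
_DEFAULT_OS_SHAPE = (0.658, 7.85)  # lognormal (sigma, median) for OS
_DEFAULT_LAMBDA = 0.0581
_DEFAULT_BETA_NE = 2.1635
_DEFAULT_SPECIALTY_MIX = {
    "general_surgery": 0.563,
    "urology": 0.317,
    "gynaecology": 0.117,
    "other": 0.003,
}
_DEFAULT_SEED = 20081
#: Truth behind the default cohort: POSSUM's PS/OS weights plus an urgency
#: effect, so elective and emergency mortality separate as observed.
DEFAULT_TRUTH = RiskModel(
    "level1-truth",
    intercept=-7.04,
    coef_ps=0.13,
    coef_os=0.16,
    coef_nonelective=_DEFAULT_BETA_NE,
)


def lognormal_score_weights(grid: np.ndarray, sigma: float, median: float) -> np.ndarray:
    """Discretised, truncated log-normal weights over an integer score grid."""
    w = lognorm.pdf(grid, s=sigma, scale=median)
    total = w.sum()
    if total <= 0:
        raise ValidationError("degenerate score distribution (all-zero weights)")
    return w / total


def _check_weights(w, grid, name):
    w = np.asarray(w, dtype=float)
    if w.shape != grid.shape:
        raise ValidationError(f"{name} must have {grid.size} weights, got {w.size}")
    if (w < 0).any():
        raise ValidationError(f"{name} weights must be non-negative")
    if not np.isclose(w.sum(), 1.0, atol=1e-8):
        raise ValidationError(f"{name} weights must sum to 1 (got {w.sum():.6f})")
    return w / w.sum()


@dataclass(frozen=True)
class CohortSpec:
    """Full parameterisation of one synthetic cohort draw.

    ``odds_multiplier`` (lambda) and ``logit_slope`` define the calibration
    distortion applied to ``truth_model``; ``score_correlation`` couples the
    PS and OS draws through a Gaussian copula on ranks (0 = independent).
    ``n_incomplete`` / ``n_indirect`` episodes are flagged (disjointly) for
    the eligibility filter to remove.
    """

    n: int
    ps_weights: np.ndarray
    os_weights: np.ndarray
    p_nonelective: float
    specialty_mix: dict[str, float]
    truth_model: RiskModel
    odds_multiplier: float = 1.0
    logit_slope: float = 1.0
    seed: int = 0
    n_incomplete: int = 0
    n_indirect: int = 0
    score_correlation: float = 0.0
    label: str = "synthetic"

    def __post_init__(self):
        if self.n <= 0:
            raise ValidationError(f"cohort size must be positive, got {self.n}")
        object.__setattr__(self, "ps_weights", _check_weights(self.ps_weights, PS_GRID, "ps"))
        object.__setattr__(self, "os_weights", _check_weights(self.os_weights, OS_GRID, "os"))
        if not 0.0 <= self.p_nonelective <= 1.0:
            raise ValidationError("p_nonelective must lie in [0, 1]")
        mix = np.array([self.specialty_mix.get(s, 0.0) for s in SPECIALTIES], dtype=float)
        if (mix < 0).any() or not np.isclose(mix.sum(), 1.0, atol=1e-8):
            raise ValidationError("specialty_mix must be non-negative and sum to 1")
        if self.odds_multiplier <= 0 or self.logit_slope <= 0:
            raise ValidationError("odds_multiplier and logit_slope must be positive")
        if self.n_incomplete < 0 or self.n_indirect < 0:
            raise ValidationError("exclusion counts must be non-negative")
        if self.n_incomplete + self.n_indirect > self.n:
            raise ValidationError("cannot flag more episodes than the cohort holds")
        if not -1.0 < self.score_correlation < 1.0:
            raise ValidationError("score_correlation must lie in (-1, 1)")

    def with_seed(self, seed: int) -> "CohortSpec":
        return replace(self, seed=seed)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ps_weights"] = self.ps_weights.tolist()
        d["os_weights"] = self.os_weights.tolist()
        d["truth_model"] = self.truth_model.to_dict()
        return d


def _draw_scores(rng: np.random.Generator, spec: CohortSpec):
    """Draw (PS, OS) pairs, optionally rank-correlated via a Gaussian copula."""
    if spec.score_correlation == 0.0:
        ps = rng.choice(PS_GRID, size=spec.n, p=spec.ps_weights)
        os_ = rng.choice(OS_GRID, size=spec.n, p=spec.os_weights)
        return ps, os_
    rho = spec.score_correlation
    z = rng.multivariate_normal([0.0, 0.0], [[1.0, rho], [rho, 1.0]], size=spec.n)
    u = norm.cdf(z)
    ps_cdf = np.cumsum(spec.ps_weights)
    os_cdf = np.cumsum(spec.os_weights)
    ps = PS_GRID[np.searchsorted(ps_cdf, u[:, 0], side="left").clip(0, PS_GRID.size - 1)]
    os_ = OS_GRID[np.searchsorted(os_cdf, u[:, 1], side="left").clip(0, OS_GRID.size - 1)]
    return ps, os_


def generate(spec: CohortSpec) -> Cohort:
    """Draw one cohort from the spec; identical seeds give identical cohorts."""
    rng = np.random.default_rng(spec.seed)
    ps, os_ = _draw_scores(rng, spec)
    ne = (rng.random(spec.n) < spec.p_nonelective).astype(int)
    mix = np.array([spec.specialty_mix.get(s, 0.0) for s in SPECIALTIES], dtype=float)
    specialty = rng.choice(np.array(SPECIALTIES), size=spec.n, p=mix / mix.sum())
    lp = spec.truth_model.linear_predictor(ps, os_, ne)
    true_risk = expit(np.log(spec.odds_multiplier) + spec.logit_slope * lp)
    died = rng.binomial(1, true_risk)
    flagged = rng.choice(spec.n, size=spec.n_incomplete + spec.n_indirect, replace=False)
    data_complete = np.ones(spec.n, dtype=int)
    directly_admitted = np.ones(spec.n, dtype=int)
    data_complete[flagged[: spec.n_incomplete]] = 0
    directly_admitted[flagged[spec.n_incomplete:]] = 0
    frame = pd.DataFrame(
        {
            "ps": ps,
            "os": os_,
            "urgency": np.where(ne == 1, NON_ELECTIVE, ELECTIVE),
            "specialty": specialty,
            "died_30d": died,
            "directly_admitted": directly_admitted,
            "data_complete": data_complete,
        }
    )
    return Cohort(frame, provenance=f"{spec.label} (seed {spec.seed})")


def default_cohort_spec(seed: int = _DEFAULT_SEED, raw: bool = False) -> CohortSpec:
    """The packaged level 1 care ward cohort spec (see module docstring).

    2552 eligible episodes, 24.5% non-elective; the truth model carries
    POSSUM's score weights plus an urgency term, under a strong uniform
    odds shrinkage (lambda ~ 0.058 against that urgency-augmented truth)
    so cohort mortality sits near 3.45% overall, 1.7% elective and 8.7%
    emergency.  With ``raw=True`` the spec instead describes the cohort
    before eligibility filtering: 3741 episodes of which 690 are flagged
    incomplete and 499 (disjointly) indirectly admitted, leaving 2552.
    """
    n, n_incomplete, n_indirect = (3741, 690, 499) if raw else (2552, 0, 0)
    return CohortSpec(
        n=n,
        ps_weights=lognormal_score_weights(PS_GRID, *_DEFAULT_PS_SHAPE),
        os_weights=lognormal_score_weights(OS_GRID, *_DEFAULT_OS_SHAPE),
        p_nonelective=0.245,
        specialty_mix=dict(_DEFAULT_SPECIALTY_MIX),
        truth_model=DEFAULT_TRUTH,
        odds_multiplier=_DEFAULT_LAMBDA,
        logit_slope=1.0,
        seed=seed,
        n_incomplete=n_incomplete,
        n_indirect=n_indirect,
        label="synthetic level 1 care ward cohort",
    )
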