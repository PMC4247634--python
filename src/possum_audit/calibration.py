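"""Calibration of predicted against observed mortality across risk bands.

A model can rank patients well yet still mispredict absolute risk.
Calibration is assessed by partitioning episodes into risk bands — either
equal-width bands of predicted risk (deciles of risk) or bands holding
equal expected numbers of deaths — and comparing, within each band, the
observed deaths O against the model-expected deaths E = sum of predicted
risks.  Each band contributes a two-cell chi-square term

    (O - E)^2 / E + ((N - O) - (N - E))^2 / (N - E)

and the Hosmer-Lemeshow statistic is the sum over non-empty bands, referred
to a chi-square with g - 2 degrees of freedom.  Observed-to-expected (O:E)
mortality ratios with exact Poisson confidence intervals summarise
calibration-in-the-large: an O:E below 1 means the model overpredicts
death.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.stats import beta, chi2

from .errors import DegenerateBandError, StatisticalError, ValidationError
from .models import Cohort, RiskModel, score_cohort

__all__ = [
    "RiskBand",
    "HLResult",
    "band_equal_width",
    "band_equal_expected",
    "hl_component",
    "hl_test",
    "oe_ratio",
    "poisson_exact_ci",
    "calibration_table",
    "calibration_curve",
]

OE_CI_METHOD = "poisson-exact-garwood"


@dataclass(frozen=True)
class RiskBand:
    """One calibration band: a predicted-risk range and its O/E summary."""

    lower: float
    upper: float
    n_patients: int
    observed_deaths: int
    expected_deaths: float
    mean_risk: float
    oe_ratio: float
    oe_ci: tuple[float, float]
    hl_component: float

    @property
    def empty(self) -> bool:
        return self.n_patients == 0

    @property
    def observed_rate(self) -> float:
        return self.observed_deaths / self.n_patients if self.n_patients else float("nan")

    @property
    def label(self) -> str:
        """Percent-range label in the style of a deciles-of-risk table."""
        return f"{100 * self.lower:g}-{100 * self.upper:g}"

    def to_dict(self) -> dict:
        return {
            "risk_band": self.label,
            "lower": self.lower,
            "upper": self.upper,
            "n_patients": self.n_patients,
            "observed_deaths": self.observed_deaths,
            "expected_deaths": self.expected_deaths,
            "mean_risk": self.mean_risk,
            "oe_ratio": self.oe_ratio,
            "oe_ci_low": self.oe_ci[0],
            "oe_ci_high": self.oe_ci[1],
            "hl_component": self.hl_component,
        }


@dataclass(frozen=True)
class HLResult:
    """Hosmer-Lemeshow goodness-of-fit summary over a set of risk bands."""

    bands: tuple[RiskBand, ...]
    statistic: float
    df: int
    p_value: float
    scheme: str  # equal_width | equal_expected

    @property
    def poor_fit(self) -> bool:
        """Calibration is considered poor when p <= 0.05."""
        return self.p_value <= 0.05

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "poor_fit": self.poor_fit,
            "bands": [b.to_dict() for b in self.bands],
        }


def hl_component(n: int, o: int, e: float) -> float:
    """Two-cell Hosmer-Lemeshow chi-square term for one band.

    ``(o - e)^2/e + ((n - o) - (n - e))^2/(n - e)``, algebraically equal to
    ``(o - e)^2 / (e (1 - e/n))``.  Requires ``0 < e < n``.
    """
    if not 0 <= o <= n:
        raise ValidationError(f"observed deaths {o} outside [0, {n}]")
    if not 0 < e < n:
        raise DegenerateBandError(
            f"expected deaths must satisfy 0 < E < N; got E={e}, N={n} "
            "(merge the band into a neighbour)"
        )
    return (o - e) ** 2 / e + ((n - o) - (n - e)) ** 2 / (n - e)


def poisson_exact_ci(count: int, level: float = 0.95) -> tuple[float, float]:
    """Exact (Garwood) confidence interval for a Poisson mean.

    Lower bound is 0 when the count is 0.
    """
    if count < 0:
        raise ValidationError("count must be non-negative")
    alpha = 1.0 - level
    lo = chi2.ppf(alpha / 2, 2 * count) / 2.0 if count > 0 else 0.0
    hi = chi2.ppf(1 - alpha / 2, 2 * count + 2) / 2.0
    return float(lo), float(hi)


def oe_ratio(o: int, e: float, level: float = 0.95) -> tuple[float, float, float]:
    """Observed:expected mortality ratio with an exact Poisson CI.

    The observed count is treated as Poisson and the expected total as
    fixed, as for a standardised mortality ratio; the interval is the
    Garwood exact interval for the count, divided by ``e``.
    """
    if e <= 0:
        raise StatisticalError(f"expected deaths must be positive, got {e}")
    if o < 0:
        raise ValidationError("observed deaths must be non-negative")
    lo, hi = poisson_exact_ci(o, level)
    return o / e, lo / e, hi / e


def _make_band(lower, upper, band_risks, band_outcomes, level=0.95) -> RiskBand:
    n = band_risks.size
    o = int(band_outcomes.sum())
    e = float(band_risks.sum())
    if n == 0:
        return RiskBand(lower, upper, 0, 0, 0.0, float("nan"), float("nan"),
                        (float("nan"), float("nan")), float("nan"))
    ratio, lo, hi = oe_ratio(o, e, level) if e > 0 else (float("nan"),) * 3
    comp = hl_component(n, o, e) if 0 < e < n else float("nan")
    return RiskBand(
        lower=lower,
        upper=upper,
        n_patients=n,
        observed_deaths=o,
        expected_deaths=e,
        mean_risk=float(band_risks.mean()),
        oe_ratio=ratio,
        oe_ci=(lo, hi),
        hl_component=comp,
    )


def _as_pairs(pairs):
    risks = np.asarray([p[0] for p in pairs], dtype=float)
    outcomes = np.asarray([p[1] for p in pairs], dtype=int)
    return risks, outcomes


def band_equal_width(pairs, k: int = 10, level: float = 0.95) -> list[RiskBand]:
    """Partition episodes into k equal-width bands of predicted risk.

    Bands are half-open ``[i/k, (i+1)/k)`` with the final band closed at 1,
    so the classic "deciles of risk" are ``k=10``.  Empty bands are kept as
    zero rows (they are excluded from the HL sum and df downstream).
    """
    if k < 2:
        raise ValidationError(f"need at least 2 bands, got k={k}")
    risks, outcomes = _as_pairs(pairs)
    if risks.size == 0:
        raise ValidationError("no episodes to band")
    idx = np.minimum((risks * k).astype(int), k - 1)
    bands = []
    for i in range(k):
        in_band = idx == i
        bands.append(
            _make_band(i / k, (i + 1) / k, risks[in_band], outcomes[in_band], level)
        )
    return bands


def band_equal_expected(pairs, k: int = 4, level: float = 0.95) -> list[RiskBand]:
    """Partition episodes into k bands of (near-)equal expected deaths.

    Episodes are sorted by ascending risk and cut where the cumulative
    expected deaths first reach ``j * total / k``; a tie group (episodes
    sharing one risk value) is never split — when a cut would fall inside
    one, the whole group stays in the earlier band.  A warning (not an
    error) is raised when bands hold fewer than 5 expected deaths each.
    """
    if k < 2:
        raise ValidationError(f"need at least 2 bands, got k={k}")
    risks, outcomes = _as_pairs(pairs)
    if risks.size == 0:
        raise ValidationError("no episodes to band")
    n_distinct = np.unique(risks).size
    if k > n_distinct:
        raise StatisticalError(
            f"k={k} exceeds the {n_distinct} distinct risk values"
        )
    order = np.argsort(risks, kind="stable")
    r = risks[order]
    y = outcomes[order]
    total_e = r.sum()
    if total_e < 5 * k:
        warnings.warn(
            f"total expected deaths {total_e:.2f} < 5 per band for k={k}; "
            "band chi-square terms may be unstable",
            stacklevel=2,
        )
    cum = np.cumsum(r)
    cuts = []  # index of first episode of each new band
    for j in range(1, k):
        thr = j * total_e / k
        i = int(np.searchsorted(cum, thr))  # first index with cum >= thr
        # never split a tie group: push the boundary past it
        while 0 < i < r.size and r[i] == r[i - 1]:
            i += 1
        if i >= r.size:
            break
        if cuts and i <= cuts[-1]:
            continue
        cuts.append(i)
    edges = [0] + cuts + [r.size]
    bands = []
    for a, b in zip(edges[:-1], edges[1:]):
        lower = float(r[a]) if a > 0 else 0.0
        upper = float(r[b]) if b < r.size else 1.0
        bands.append(_make_band(lower, upper, r[a:b], y[a:b], level))
    return bands


def hl_test(
    bands: Sequence[RiskBand], scheme: str = "equal_width", df: int | None = None
) -> HLResult:
    """Hosmer-Lemeshow chi-square over the non-empty bands.

    By default df = (non-empty bands) - 2, the convention of the original
    test for a model fitted on the same data (10 occupied deciles give
    df 8); printed validation tables use the same convention, so it is the
    default here too.  For a model specified *externally* (not refitted on
    the cohort) the statistic's null reference is chi-square with g
    degrees of freedom, not g - 2; pass ``df`` explicitly (e.g. the number
    of occupied bands) to use that calibrated reference.  p is the upper
    chi-square tail.
    """
    occupied = [b for b in bands if not b.empty]
    if len(occupied) < 3:
        raise StatisticalError(
            f"Hosmer-Lemeshow test needs >= 3 non-empty bands, got {len(occupied)}"
        )
    components = [b.hl_component for b in occupied]
    if any(np.isnan(c) for c in components):
        raise DegenerateBandError(
            "a non-empty band has a degenerate chi-square term (E <= 0 or E >= N); "
            "merge bands before testing"
        )
    statistic = float(np.sum(components))
    if df is None:
        df = len(occupied) - 2
    elif df < 1:
        raise ValidationError(f"df must be a positive integer, got {df}")
    p = float(chi2.sf(statistic, df))
    return HLResult(
        bands=tuple(bands), statistic=statistic, df=df, p_value=p, scheme=scheme
    )


def merge_degenerate_bands(bands: list[RiskBand]) -> list[RiskBand]:
    """Merge any band with a degenerate chi-square term into its neighbour.

    Degenerate means occupied but with E <= 0 or E >= N (all-certain
    predictions); the merge is into the preceding band when one exists.
    """
    out: list[RiskBand] = []
    for band in bands:
        if not band.empty and np.isnan(band.hl_component) and out:
            prev = out.pop()
            n = prev.n_patients + band.n_patients
            o = prev.observed_deaths + band.observed_deaths
            e = prev.expected_deaths + band.expected_deaths
            mean_risk = (
                prev.mean_risk * prev.n_patients + band.mean_risk * band.n_patients
            ) / n
            ratio, lo, hi = oe_ratio(o, e) if e > 0 else (float("nan"),) * 3
            comp = hl_component(n, o, e) if 0 < e < n else float("nan")
            warnings.warn("merged a degenerate risk band into its neighbour", stacklevel=2)
            out.append(
                RiskBand(prev.lower, band.upper, n, o, e, mean_risk, ratio, (lo, hi), comp)
            )
        else:
            out.append(band)
    return out


def calibration_table(
    model: RiskModel,
    cohort: Cohort,
    scheme: str = "equal_width",
    k: int = 10,
    level: float = 0.95,
) -> tuple[list[RiskBand], HLResult, RiskBand]:
    """Full calibration table for a model on a cohort.

    Returns the per-band rows, the Hosmer-Lemeshow result over them, and a
    pooled 0-100% total row with the overall O, E and O:E ratio.  Values
    are unrounded; table renderers round for presentation.
    """
    if scheme not in ("equal_width", "equal_expected"):
        raise ValidationError(f"unknown banding scheme {scheme!r}")
    risks, outcomes = score_cohort(model, cohort)
    pairs = list(zip(risks, outcomes))
    if scheme == "equal_width":
        bands = band_equal_width(pairs, k, level)
    else:
        bands = band_equal_expected(pairs, k, level)
    bands = merge_degenerate_bands(bands)
    hl = hl_test(bands, scheme)
    overall = _make_band(0.0, 1.0, risks, outcomes, level)
    overall = replace(overall, hl_component=hl.statistic)
    return bands, hl, overall


def calibration_curve(bands: Sequence[RiskBand], level: float = 0.95):
    """Observed mortality rate per band with exact binomial CIs.

    Returns a list of ``(mean_risk, observed_rate, ci_low, ci_high)``; a
    perfectly calibrated model lies on the line of unity.  Empty bands are
    skipped with a warning.
    """
    if len(bands) == 0:
        raise ValidationError("no bands supplied")
    alpha = 1.0 - level
    out = []
    for band in bands:
        if band.empty:
            warnings.warn(f"skipping empty band {band.label}", stacklevel=2)
            continue
        n, o = band.n_patients, band.observed_deaths
        # Clopper-Pearson
        lo = beta.ppf(alpha / 2, o, n - o + 1) if o > 0 else 0.0
        hi = beta.ppf(1 - alpha / 2, o + 1, n - o) if o < n else 1.0
        out.append((band.mean_risk, o / n, float(lo), float(hi)))
    return out
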