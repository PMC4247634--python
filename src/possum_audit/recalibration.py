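"""Logistic recalibration of POSSUM-family models.

When an externally validated model is miscalibrated, refitting the same
predictors on the local cohort yields a recalibrated equation.  Here the
refit regresses the 30-day outcome on PS and OS (continuous) and an
indicator NE for non-elective surgery, by maximum likelihood on the
binomial log-likelihood.  Fitting uses Newton-Raphson with step-halving:
given current coefficients b, risks p = expit(Xb), gradient X'(y - p) and
observed information X'WX with W = diag(p(1-p)), the update solves the
normal equations, halving the step until the log-likelihood does not
decrease.  Standard errors come from the inverse information at the
optimum; Wald z-tests give p-values and symmetric-in-log odds-ratio
confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .calibration import HLResult, band_equal_width, hl_test, merge_degenerate_bands
from .errors import ConvergenceError, SeparationError, StatisticalError, ValidationError
from .models import Cohort, RiskModel

__all__ = [
    "CoefficientEstimate",
    "FitResult",
    "fit_logistic",
    "coefficient_table",
    "derive_recalibrated_model",
]

MAX_ITER = 50
TOL = 1e-8
SEPARATION_BOUND = 30.0  # |b| beyond this during iteration implies separation


@dataclass(frozen=True)
class CoefficientEstimate:
    """One fitted-coefficient row: log-odds, Wald inference, odds ratio."""

    term: str
    b: float
    se: float
    p: float
    odds_ratio: float
    or_ci_low: float
    or_ci_high: float

    def to_dict(self) -> dict:
        return {
            "term": self.term,
            "B": self.b,
            "SE": self.se,
            "P": self.p,
            "ExpB": self.odds_ratio,
            "CI_low": self.or_ci_low,
            "CI_high": self.or_ci_high,
        }


@dataclass(frozen=True)
class FitResult:
    """Converged maximum-likelihood fit of a binary logistic model."""

    terms: tuple[str, ...]
    coef: np.ndarray
    cov: np.ndarray
    log_likelihood: float
    iterations: int
    converged: bool
    n_obs: int

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


def _log_likelihood(eta: np.ndarray, y: np.ndarray) -> float:
    # log L = sum y*eta - log(1 + exp(eta)), stable via logaddexp
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic(design, outcomes, add_intercept: bool = False) -> FitResult:
    """Maximum-likelihood logistic regression via Newton-Raphson.

    Parameters
    ----------
    design
        Predictor matrix with column labels (DataFrame) or a plain 2-D
        array (columns labelled x0, x1, ...).  Must already contain the
        intercept column unless ``add_intercept`` is set.
    outcomes
        Binary 0/1 response vector.

    Convergence requires |change in log-likelihood| < 1e-8 or a gradient
    max-norm below 1e-8, within 50 iterations; step-halving guarantees the
    log-likelihood never decreases.  Raises :class:`SeparationError` when
    coefficients diverge (perfect separation) and :class:`ConvergenceError`
    with an iteration trace otherwise.
    """
    if isinstance(design, pd.DataFrame):
        labels = [str(c) for c in design.columns]
        X = design.to_numpy(dtype=float)
    else:
        X = np.asarray(design, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        labels = [f"x{j}" for j in range(X.shape[1])]
    y = np.asarray(outcomes, dtype=float)
    if not np.isin(y, (0, 1)).all():
        raise ValidationError("outcomes must be binary 0/1")
    n, p = X.shape
    if y.shape != (n,):
        raise ValidationError("design and outcomes have mismatched lengths")
    if n <= p:
        raise StatisticalError(f"need more observations ({n}) than columns ({p})")
    if y.sum() == 0 or y.sum() == n:
        raise StatisticalError("outcomes contain a single class; fit is undefined")
    col_sd = X.std(axis=0)
    col_mean = np.abs(X.mean(axis=0))
    constant_cols = (col_sd == 0) & (col_mean != 1.0)
    if constant_cols.any():
        raise ValidationError(
            f"constant non-intercept column(s): {[labels[j] for j in np.flatnonzero(constant_cols)]}"
        )
    if add_intercept:
        X = np.column_stack([X, np.ones(n)])
        labels = labels + ["const"]
        p += 1

    b = np.zeros(p)
    ll = _log_likelihood(X @ b, y)
    trace = [ll]
    converged = False
    it = 0
    for it in range(1, MAX_ITER + 1):
        prob = expit(X @ b)
        grad = X.T @ (y - prob)
        w = prob * (1.0 - prob)
        info = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(
                "singular information matrix; data may be separated or collinear"
            ) from exc
        # step-halving: accept the first step that does not lower log L
        scale = 1.0
        for _ in range(30):
            b_new = b + scale * step
            ll_new = _log_likelihood(X @ b_new, y)
            if ll_new >= ll - 1e-12:
                break
            scale /= 2.0
        if np.max(np.abs(b_new)) > SEPARATION_BOUND:
            raise SeparationError(
                "coefficients diverging (|b| > 30); perfect separation suspected"
            )
        delta_ll = ll_new - ll
        b, ll = b_new, ll_new
        trace.append(ll)
        if abs(delta_ll) < TOL or np.max(np.abs(grad)) < TOL:
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"Newton-Raphson did not converge in {MAX_ITER} iterations", trace=trace
        )
    prob = expit(X @ b)
    w = prob * (1.0 - prob)
    info = (X * w[:, None]).T @ X
    cov = np.linalg.inv(info)
    return FitResult(
        terms=tuple(labels),
        coef=b,
        cov=cov,
        log_likelihood=ll,
        iterations=it,
        converged=True,
        n_obs=n,
    )


def coefficient_table(fit: FitResult, level: float = 0.95) -> list[CoefficientEstimate]:
    """Wald coefficient table: B, SE, p, odds ratio and its CI per term.

    OR = exp(B); CI = exp(B +/- z * SE) at the requested level; p is the
    two-sided normal tail of B/SE.
    """
    if not fit.converged:
        raise StatisticalError("coefficient table requires a converged fit")
    z = norm.ppf(0.5 + level / 2.0)
    rows = []
    for term, b, se in zip(fit.terms, fit.coef, fit.se):
        rows.append(
            CoefficientEstimate(
                term=term,
                b=float(b),
                se=float(se),
                p=float(2.0 * norm.sf(abs(b / se))),
                odds_ratio=float(np.exp(b)),
                or_ci_low=float(np.exp(b - z * se)),
                or_ci_high=float(np.exp(b + z * se)),
            )
        )
    return rows


def derive_recalibrated_model(
    cohort: Cohort,
    name: str = "recalibrated",
    reverse_urgency: bool = False,
    hl_bands: int = 10,
) -> tuple[RiskModel, FitResult, HLResult]:
    """Refit mortality on PS, OS and urgency; package as a new risk model.

    The design is outcome ~ PS + OS + NE + intercept with NE = 1 for
    non-elective surgery (``reverse_urgency`` flips the coding to indicate
    elective instead, for replication against reports that coded the
    category the other way round).  Also returns a Hosmer-Lemeshow test of
    the refit evaluated on its own training cohort; by construction the
    refit is calibrated-in-the-large there (overall O:E = 1).
    """
    if len(cohort) == 0:
        raise ValidationError("cannot refit on an empty cohort")
    ne = cohort.nonelective
    if reverse_urgency:
        ne = 1 - ne
    design = pd.DataFrame(
        {"PScore": cohort.ps, "OScore": cohort.os, "NE": ne, "Constant": 1.0}
    )
    fit = fit_logistic(design, cohort.outcomes)
    coef = dict(zip(fit.terms, fit.coef))
    b_ne = coef["NE"] if not reverse_urgency else -coef["NE"]
    intercept = coef["Constant"] if not reverse_urgency else coef["Constant"] + coef["NE"]
    model = RiskModel(
        name=name,
        intercept=float(intercept),
        coef_ps=float(coef["PScore"]),
        coef_os=float(coef["OScore"]),
        coef_nonelective=float(b_ne),
    )
    risks = expit(design.to_numpy() @ fit.coef)
    bands = band_equal_width(list(zip(risks, cohort.outcomes)), k=hl_bands)
    bands = merge_degenerate_bands(bands)
    hl = hl_test(bands, scheme="equal_width")
    return model, fit, hl
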