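"""ROC curves and the C-statistic for mortality risk models.

Discrimination — the ability to rank non-survivors above survivors — is
summarised by the area under the ROC curve (AUC, equivalently the
C-statistic): the probability that a randomly chosen death received a
higher predicted risk than a randomly chosen survivor, with ties counted
one half (the Mann-Whitney convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .errors import StatisticalError, ValidationError

__all__ = ["ROCResult", "roc_curve", "interpret_auc", "AUC_BANDS"]


@dataclass(frozen=True)
class ROCResult:
    """AUC with its standard error and the full threshold-sweep curve.

    ``points`` is an (m, 2) array of (false positive rate, true positive
    rate) pairs from (0, 0) to (1, 1), one interior point per distinct risk
    value, swept in descending risk order.  ``se_method`` records how
    ``auc_se`` was obtained.
    """

    auc: float
    auc_se: float
    points: np.ndarray
    n_deaths: int
    n_survivors: int
    se_method: str = "hanley-mcneil"

    @property
    def trapezoid_area(self) -> float:
        """Area under ``points`` by the trapezoid rule; equals ``auc``."""
        fpr, tpr = self.points[:, 0], self.points[:, 1]
        return float(np.trapezoid(tpr, fpr))

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "auc_se": self.auc_se,
            "se_method": self.se_method,
            "n_deaths": self.n_deaths,
            "n_survivors": self.n_survivors,
        }


def _validate_inputs(risks, outcomes):
    risks = np.asarray(risks, dtype=float)
    outcomes = np.asarray(outcomes)
    if risks.shape != outcomes.shape or risks.ndim != 1:
        raise ValidationError("risks and outcomes must be 1-D arrays of equal length")
    if not np.isin(outcomes, (0, 1)).all():
        raise ValidationError("outcomes must be binary 0/1")
    outcomes = outcomes.astype(int)
    n1 = int(outcomes.sum())
    n0 = outcomes.size - n1
    if n1 == 0:
        raise StatisticalError("no deaths in input; AUC undefined")
    if n0 == 0:
        raise StatisticalError("no survivors in input; AUC undefined")
    return risks, outcomes, n1, n0


def _hanley_mcneil_se(auc: float, n1: int, n0: int) -> float:
    # Binegative-exponential assumption of Hanley & McNeil (1982).
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1.0 - auc) + (n1 - 1) * (q1 - auc**2) + (n0 - 1) * (q2 - auc**2)
    ) / (n1 * n0)
    return float(np.sqrt(max(var, 0.0)))


def roc_curve(risks, outcomes) -> ROCResult:
    """ROC curve and AUC for predicted risks against binary outcomes.

    The AUC is computed as the Mann-Whitney concordance over all
    death/survivor pairs (ties score 0.5), via midranks, which equals the
    trapezoidal area under the threshold-sweep curve exactly.  The standard
    error uses the Hanley-McNeil formula.
    """
    risks, outcomes, n1, n0 = _validate_inputs(risks, outcomes)

    ranks = rankdata(risks)  # midranks handle ties
    auc = (ranks[outcomes == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)

    # Threshold sweep in descending risk: one point per distinct value.
    order = np.argsort(-risks, kind="stable")
    sorted_out = outcomes[order]
    sorted_risk = risks[order]
    tp = np.cumsum(sorted_out)
    fp = np.cumsum(1 - sorted_out)
    # collapse runs of tied risks to their last index
    last_of_run = np.r_[np.nonzero(np.diff(sorted_risk))[0], sorted_risk.size - 1]
    tpr = tp[last_of_run] / n1
    fpr = fp[last_of_run] / n0
    points = np.column_stack(
        [np.r_[0.0, fpr], np.r_[0.0, tpr]]
    )
    if points[-1, 0] != 1.0 or points[-1, 1] != 1.0:  # pragma: no cover
        points = np.vstack([points, [1.0, 1.0]])

    return ROCResult(
        auc=float(auc),
        auc_se=_hanley_mcneil_se(float(auc), n1, n0),
        points=points,
        n_deaths=n1,
        n_survivors=n0,
    )


#: Discrimination bands: lower edge (inclusive) -> label.
AUC_BANDS = (
    (0.9, "excellent"),
    (0.8, "good_to_excellent"),
    (0.7, "acceptable"),
)


def interpret_auc(auc: float) -> str:
    """Qualitative discrimination band for an AUC value.

    ``>= 0.9`` excellent, ``[0.8, 0.9)`` good to excellent, ``[0.7, 0.8)``
    acceptable, below that poor; exactly 0.5 carries no discriminating
    value at all.
    """
    if not 0.0 <= auc <= 1.0:
        raise ValidationError(f"AUC must lie in [0, 1], got {auc}")
    if auc == 0.5:
        return "none"
    for edge, label in AUC_BANDS:
        if auc >= edge:
            return label
    return "poor"
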