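"""Validation reports: the end-to-end audit of one model on one cohort.

``run_validation`` chains the pipeline — eligibility filter, scoring, ROC
discrimination, calibration under both banding schemes, overall O:E — and
packages the result with enough metadata to reproduce every rendered
number from the stored unrounded values.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
from dataclasses import dataclass, field

from . import __version__
from .calibration import OE_CI_METHOD, HLResult, RiskBand, calibration_table
from .discrimination import ROCResult, interpret_auc, roc_curve
from .models import Cohort, ExclusionReport, RiskModel, apply_eligibility, score_cohort

__all__ = ["ValidationReport", "run_validation", "render_markdown_table"]

log = logging.getLogger("possum_audit")

REPORT_SCHEMA_VERSION = 1


@dataclass
class ValidationReport:
    """All results of validating one risk model on one cohort."""

    model: RiskModel
    cohort_provenance: str
    exclusions: ExclusionReport
    roc: ROCResult
    calibrations: dict[str, HLResult]
    overall: RiskBand
    config: dict = field(default_factory=dict)
    timestamp: str = field(
        default_factory=lambda: _dt.datetime.now(_dt.timezone.utc).isoformat()
    )

    @property
    def poor_fit(self) -> bool:
        return any(hl.poor_fit for hl in self.calibrations.values())

    @property
    def poor_discrimination(self) -> bool:
        return interpret_auc(self.roc.auc) in ("poor", "none")

    def to_dict(self) -> dict:
        return {
            "schema_version": REPORT_SCHEMA_VERSION,
            "toolkit_version": __version__,
            "timestamp": self.timestamp,
            "model": self.model.to_dict(),
            "cohort": {
                "provenance": self.cohort_provenance,
                **self.exclusions.to_dict(),
            },
            "discrimination": {
                **self.roc.to_dict(),
                "interpretation": interpret_auc(self.roc.auc),
            },
            "calibration": {name: hl.to_dict() for name, hl in self.calibrations.items()},
            "overall": {**self.overall.to_dict(), "oe_ci_method": OE_CI_METHOD},
            "flags": {
                "poor_fit": self.poor_fit,
                "poor_discrimination": self.poor_discrimination,
            },
            "config": self.config,
        }

    def to_json(self, path=None, indent: int = 2):
        text = json.dumps(self.to_dict(), indent=indent)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text


def run_validation(
    cohort: Cohort,
    model: RiskModel,
    k_equal_width: int = 10,
    k_equal_expected: int = 4,
    filter_eligibility: bool = True,
    config: dict | None = None,
) -> ValidationReport:
    """Validate ``model`` on ``cohort``: filter, score, ROC, calibrate.

    Both banding schemes are always computed: equal-width deciles of risk
    (``k_equal_width``) and bands of equal expected deaths
    (``k_equal_expected``).  Deterministic given cohort and configuration.
    """
    if filter_eligibility:
        cohort, exclusions = apply_eligibility(cohort)
    else:
        exclusions = ExclusionReport(len(cohort), len(cohort), 0, 0)
    log.info(
        "eligibility: %d of %d episodes retained", exclusions.n_eligible, exclusions.n_input
    )
    risks, outcomes = score_cohort(model, cohort)
    log.info(
        "scored %d episodes with %s: %d deaths observed, %.2f expected",
        len(risks), model.name, int(outcomes.sum()), float(risks.sum()),
    )
    roc = roc_curve(risks, outcomes)
    log.info("AUC %.3f +/- %.3f (%s)", roc.auc, roc.auc_se, interpret_auc(roc.auc))
    calibrations = {}
    overall = None
    for scheme, k in (("equal_width", k_equal_width), ("equal_expected", k_equal_expected)):
        bands, hl, overall = calibration_table(model, cohort, scheme=scheme, k=k)
        calibrations[scheme] = hl
        log.info(
            "HL (%s, %d bands): chi2=%.2f df=%d p=%.3g", scheme, k, hl.statistic,
            hl.df, hl.p_value,
        )
    log.info(
        "overall O:E %.3f (%.3f-%.3f)", overall.oe_ratio, overall.oe_ci[0], overall.oe_ci[1]
    )
    return ValidationReport(
        model=model,
        cohort_provenance=cohort.provenance,
        exclusions=exclusions,
        roc=roc,
        calibrations=calibrations,
        overall=overall,
        config={
            "k_equal_width": k_equal_width,
            "k_equal_expected": k_equal_expected,
            "filter_eligibility": filter_eligibility,
            "oe_ci_method": OE_CI_METHOD,
            **(config or {}),
        },
    )


def _fmt(x, nd=2):
    import math

    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "-"
    # round-half-up at nd decimals, as in printed risk tables
    q = 10**nd
    return f"{math.floor(abs(x) * q + 0.5) / q * (1 if x >= 0 else -1):.{nd}f}"


def render_markdown_table(hl: HLResult, overall: RiskBand | None = None) -> str:
    """Markdown calibration table, one row per band plus an overall row."""
    lines = [
        "| Risk band (%) | N | Observed deaths | Expected deaths | Mean risk "
        "| O:E (95% CI) | HL component |",
        "|---|---|---|---|---|---|---|",
    ]
    for b in hl.bands:
        oe = f"{_fmt(b.oe_ratio)} ({_fmt(b.oe_ci[0])} - {_fmt(b.oe_ci[1])})" if not b.empty else "-"
        lines.append(
            f"| {b.label} | {b.n_patients} | {b.observed_deaths} | "
            f"{_fmt(b.expected_deaths)} | {_fmt(b.mean_risk)} | {oe} | "
            f"{_fmt(b.hl_component)} |"
        )
    if overall is not None:
        oe = f"{_fmt(overall.oe_ratio)} ({_fmt(overall.oe_ci[0])} - {_fmt(overall.oe_ci[1])})"
        lines.append(
            f"| 0-100 | {overall.n_patients} | {overall.observed_deaths} | "
            f"{_fmt(overall.expected_deaths)} | {_fmt(overall.mean_risk)} | {oe} | "
            f"**{_fmt(hl.statistic)}** |"
        )
    lines.append(
        f"\nHL chi-square = {_fmt(hl.statistic)}; df = {hl.df}; "
        f"p = {hl.p_value:.3g} ({'poor' if hl.poor_fit else 'adequate'} fit)"
    )
    return "\n".join(lines)
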