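"""Screening diagnostics of the high-risk classification.

The classification is a single rule (high-risk vs not), so its performance
against each binary outcome is a 2x2 table: sensitivity, specificity,
positive and negative predictive value.  Point estimates use the
survey-weighted cell totals; 95% intervals are simple proportion intervals
(Wald by default, Wilson optional) on the relevant margin's *unweighted*
head count — no design-effect adjustment is applied, and the report says so.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .cohort import (
    PRIMARY_OUTCOME,
    SECONDARY_OUTCOME_LABELS,
    Cohort,
)
from .profiles import HighRiskClassification

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


class DiagnosticsError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionTable:
    """Weighted and unweighted 2x2 cross-tabulation of flag x outcome."""

    tp: float
    fp: float
    fn: float
    tn: float
    tp_u: int
    fp_u: int
    fn_u: int
    tn_u: int

    @property
    def n_unweighted(self) -> int:
        return self.tp_u + self.fp_u + self.fn_u + self.tn_u


@dataclass(frozen=True)
class MetricEstimate:
    estimate: Optional[float]
    lower: Optional[float]
    upper: Optional[float]
    undefined: bool = False

    def as_percent(self, digits: int = 1) -> str:
        if self.undefined:
            return "undefined"
        return (
            f"{100 * self.estimate:.{digits}f} "
            f"({100 * self.lower:.{digits}f},{100 * self.upper:.{digits}f})"
        )


@dataclass
class DiagnosticResult:
    outcome_label: str
    cohort_label: str
    sensitivity: MetricEstimate
    specificity: MetricEstimate
    ppv: MetricEstimate
    npv: MetricEstimate
    table: ConfusionTable = field(repr=False, default=None)  # type: ignore[assignment]

    def to_row(self) -> dict:
        row = {"outcome": self.outcome_label, "cohort": self.cohort_label}
        for name in ("sensitivity", "specificity", "ppv", "npv"):
            m: MetricEstimate = getattr(self, name)
            row[name] = m.estimate
            row[f"{name}_lo"] = m.lower
            row[f"{name}_hi"] = m.upper
        return row


def confusion(
    classification: HighRiskClassification,
    outcome,
    weights,
) -> ConfusionTable:
    """Weighted and unweighted 2x2 table of high-risk flag against outcome."""
    flags = np.asarray(classification.flags, dtype=bool)
    y = np.asarray(outcome, dtype=bool)
    w = np.asarray(weights, dtype=float)
    if not (len(flags) == len(y) == len(w)):
        raise DiagnosticsError("classification, outcome and weights lengths differ")
    cells = {
        "tp": flags & y,
        "fp": flags & ~y,
        "fn": ~flags & y,
        "tn": ~flags & ~y,
    }
    return ConfusionTable(
        **{k: float(w[v].sum()) for k, v in cells.items()},
        **{f"{k}_u": int(v.sum()) for k, v in cells.items()},
    )


def _interval(p_hat: float, n: int, ci_method: str) -> tuple[float, float]:
    if ci_method == "wald":
        half = Z_95 * math.sqrt(p_hat * (1.0 - p_hat) / n)
        return max(0.0, p_hat - half), min(1.0, p_hat + half)
    if ci_method == "wilson":
        lo, hi = proportion_confint(p_hat * n, n, alpha=0.05, method="wilson")
        return float(lo), float(hi)
    raise DiagnosticsError(f"unknown ci_method {ci_method!r}")


def _metric(num_w: float, den_w: float, den_u: int, ci_method: str) -> MetricEstimate:
    if den_w <= 0 or den_u <= 0:
        return MetricEstimate(None, None, None, undefined=True)
    p_hat = num_w / den_w
    lo, hi = _interval(p_hat, den_u, ci_method)
    return MetricEstimate(float(p_hat), lo, hi)


def screening_metrics(
    table: ConfusionTable,
    ci_method: str = "wald",
    outcome_label: str = PRIMARY_OUTCOME,
    cohort_label: str = "discovery",
) -> DiagnosticResult:
    """Sensitivity, specificity, PPV and NPV with 95% intervals.

    A metric whose margin is empty is reported as undefined with an
    explicit flag rather than silently as zero.
    """
    return DiagnosticResult(
        outcome_label=outcome_label,
        cohort_label=cohort_label,
        sensitivity=_metric(table.tp, table.tp + table.fn, table.tp_u + table.fn_u, ci_method),
        specificity=_metric(table.tn, table.tn + table.fp, table.tn_u + table.fp_u, ci_method),
        ppv=_metric(table.tp, table.tp + table.fp, table.tp_u + table.fp_u, ci_method),
        npv=_metric(table.tn, table.tn + table.fn, table.tn_u + table.fn_u, ci_method),
        table=table,
    )


def evaluate_all_outcomes(
    classification: HighRiskClassification,
    cohort: Cohort,
    ci_method: str = "wald",
    cohort_label: str = "discovery",
) -> list[DiagnosticResult]:
    """Apply the SAME classification to the primary and all six secondary outcomes.

    Output order: primary first, then the secondary outcomes in canonical
    reporting order (antisocial, substance, physical, mental, risky
    behaviours, academic).
    """
    if len(cohort.secondary_outcomes.columns) != len(SECONDARY_OUTCOME_LABELS):
        raise DiagnosticsError(
            "cohort must carry all six secondary outcome columns; found "
            f"{list(cohort.secondary_outcomes.columns)}"
        )
    results = []
    columns = [PRIMARY_OUTCOME] + list(cohort.secondary_outcomes.columns)
    labels = ["suicidal_thoughts"] + list(SECONDARY_OUTCOME_LABELS)
    for column, label in zip(columns, labels):
        table = confusion(classification, cohort.outcome(column), cohort.weights)
        results.append(
            screening_metrics(table, ci_method, outcome_label=label, cohort_label=cohort_label)
        )
    return results


def results_to_frame(results: list[DiagnosticResult]) -> pd.DataFrame:
    """Long-format report: one row per outcome, metric columns with CI bounds."""
    return pd.DataFrame([r.to_row() for r in results])
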