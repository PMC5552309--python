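"""Model/Results front end for the risk-subgroup discovery pipeline.

`HighRiskTreeModel` is constructed from a cohort (or a plain DataFrame) and
`fit()` runs the full discovery procedure: grow the maximal weighted
classification tree under the minimum-node-size rule, designate every
node's risk level relative to the base rate (>2x base = high, <1/2 base =
low, else moderate), prune risk-homogeneous subtrees, and extract one
subgroup profile per remaining high-risk leaf.  The returned
`HighRiskTreeResults` carries the trees, the profiles and the screening
diagnostics, and can classify and evaluate new cohorts — including a
validation cohort reached through a closest-proxy predictor mapping.

`StepwiseLogisticModel` is the traditional comparator: stepwise-selected
weighted logistic regression dichotomized at a probability threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .cohort import Cohort
from .diagnostics import (
    DiagnosticResult,
    confusion,
    evaluate_all_outcomes,
    results_to_frame,
    screening_metrics,
)
from .logistic import (
    LogisticModel,
    StepwiseConfig,
    classify_by_probability,
    stepwise_select,
)
from .profiles import (
    HighRiskClassification,
    PredictorMapping,
    SubgroupProfile,
    classify,
    extract_high_risk_profiles,
    port_profiles,
)
from .risk import (
    RiskThresholds,
    annotate_tree,
    count_terminals_by_risk,
    prune_by_risk_homogeneity,
)
from .tree import GrowConfig, Tree, grow_maximal_tree


class HighRiskTreeModel:
    """Weighted classification-tree model of a binary outcome.

    Parameters
    ----------
    cohort : Cohort
        Weighted individual-level data.
    outcome : str
        Outcome column the tree predicts (default the primary outcome).
    n_min : int, optional
        Minimum unweighted individuals per child node.  Defaults to 1% of
        the cohort (at least 1), the convention of the motivating analysis.
    high_multiplier, low_multiplier : float
        Risk-designation cut-offs as multiples of the base rate.
    """

    def __init__(
        self,
        cohort: Cohort,
        outcome: str = "y_primary",
        n_min: Optional[int] = None,
        high_multiplier: float = 2.0,
        low_multiplier: float = 0.5,
        grow_config: Optional[GrowConfig] = None,
    ):
        self.cohort = cohort
        self.outcome = outcome
        if grow_config is None:
            if n_min is None:
                n_min = max(1, round(0.01 * cohort.n))
            grow_config = GrowConfig(n_min=n_min)
        self.grow_config = grow_config
        self.high_multiplier = high_multiplier
        self.low_multiplier = low_multiplier

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, **kwargs) -> "HighRiskTreeModel":
        return cls(Cohort.from_frame(frame), **kwargs)

    def fit(self, prune: bool = True) -> "HighRiskTreeResults":
        maximal = grow_maximal_tree(self.cohort, self.outcome, self.grow_config)
        thresholds = RiskThresholds(
            base_rate=maximal.base_rate,
            high_multiplier=self.high_multiplier,
            low_multiplier=self.low_multiplier,
        )
        annotated = annotate_tree(maximal, thresholds)
        pruned = prune_by_risk_homogeneity(annotated) if prune else annotated
        profiles = extract_high_risk_profiles(pruned)
        return HighRiskTreeResults(
            model=self,
            maximal_tree=annotated,
            tree=pruned,
            thresholds=thresholds,
            profiles=profiles,
        )


@dataclass
class HighRiskTreeResults:
    """Fitted discovery tree: risk-designated, pruned, with subgroup profiles."""

    model: HighRiskTreeModel
    maximal_tree: Tree
    tree: Tree
    thresholds: RiskThresholds
    profiles: list[SubgroupProfile]

    @property
    def base_rate(self) -> float:
        return self.thresholds.base_rate

    @property
    def risk_counts(self) -> dict[str, int]:
        return count_terminals_by_risk(self.tree)

    # -- application -------------------------------------------------------
    def classify(self, cohort: Optional[Cohort] = None) -> HighRiskClassification:
        return classify(self.profiles, cohort or self.model.cohort)

    def port(self, mapping: PredictorMapping, policy: str = "profile-never-fires"):
        """Profiles renamed for a second cohort, plus the coverage report."""
        return port_profiles(self.profiles, mapping, policy)

    def diagnostics(
        self,
        cohort: Optional[Cohort] = None,
        outcome: Optional[str] = None,
        mapping: Optional[PredictorMapping] = None,
        policy: str = "profile-never-fires",
        ci_method: str = "wald",
        cohort_label: str = "discovery",
    ) -> DiagnosticResult:
        """Screening metrics of the high-risk rule against one outcome."""
        cohort = cohort or self.model.cohort
        profiles = self.profiles
        if mapping is not None:
            profiles, _ = port_profiles(profiles, mapping, policy)
        cls = classify(profiles, cohort)
        table = confusion(cls, cohort.outcome(outcome or self.model.outcome), cohort.weights)
        return screening_metrics(
            table, ci_method, outcome_label=outcome or self.model.outcome,
            cohort_label=cohort_label,
        )

    def evaluate_outcomes(
        self,
        cohort: Optional[Cohort] = None,
        ci_method: str = "wald",
        cohort_label: str = "discovery",
    ) -> pd.DataFrame:
        """Primary plus all six secondary outcomes under the same rule."""
        cohort = cohort or self.model.cohort
        cls = classify(self.profiles, cohort)
        return results_to_frame(
            evaluate_all_outcomes(cls, cohort, ci_method, cohort_label=cohort_label)
        )

    # -- reporting ---------------------------------------------------------
    def summary(self) -> str:
        counts = self.risk_counts
        lines = [
            "High-risk subgroup discovery (weighted classification tree)",
            "=" * 62,
            f"n (unweighted):        {self.model.cohort.n}",
            f"outcome:               {self.model.outcome}",
            f"n_min per child node:  {self.model.grow_config.n_min}",
            f"base rate (weighted):  {100 * self.base_rate:.1f}%",
            f"high / low cut-offs:   >{100 * self.thresholds.high_cutoff:.1f}% / "
            f"<{100 * self.thresholds.low_cutoff:.1f}%",
            f"maximal tree leaves:   {len(self.maximal_tree.terminals())}",
            f"pruned tree leaves:    {len(self.tree.terminals())} "
            f"(high {counts['high']}, moderate {counts['moderate']}, low {counts['low']})",
            "",
            "High-risk subgroup profiles",
            "-" * 62,
        ]
        if not self.profiles:
            lines.append("(none)")
        for p in self.profiles:
            lines.append(
                f"{p.profile_id}: {100 * p.training_prevalence:.1f}%, n = {p.training_n}"
            )
            for name, level in p.conditions:
                lines.append(f"    - {name} = {level}")
        return "\n".join(lines)

    def profile_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "profile_id": [p.profile_id for p in self.profiles],
                "prevalence": [p.training_prevalence for p in self.profiles],
                "n": [p.training_n for p in self.profiles],
                "conditions": [
                    " & ".join(f"{n}={lv}" for n, lv in p.conditions)
                    for p in self.profiles
                ],
            }
        )


class StepwiseLogisticModel:
    """Stepwise-selected weighted logistic regression comparator."""

    def __init__(
        self,
        cohort: Cohort,
        outcome: str = "y_primary",
        config: StepwiseConfig = StepwiseConfig(),
        candidates: Optional[list[str]] = None,
    ):
        self.cohort = cohort
        self.outcome = outcome
        self.config = config
        self.candidates = candidates

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, **kwargs) -> "StepwiseLogisticModel":
        return cls(Cohort.from_frame(frame), **kwargs)

    def fit(self) -> "StepwiseLogisticResults":
        fitted = stepwise_select(self.cohort, self.candidates, self.config, self.outcome)
        return StepwiseLogisticResults(model=self, fitted=fitted)


@dataclass
class StepwiseLogisticResults:
    model: StepwiseLogisticModel
    fitted: LogisticModel

    def classify(
        self, cohort: Optional[Cohort] = None, threshold: Optional[float] = None
    ) -> HighRiskClassification:
        if threshold is None:
            threshold = self.model.config.classification_threshold
        return classify_by_probability(self.fitted, cohort or self.model.cohort, threshold)

    def diagnostics(
        self,
        cohort: Optional[Cohort] = None,
        threshold: Optional[float] = None,
        ci_method: str = "wald",
        cohort_label: str = "discovery",
    ) -> DiagnosticResult:
        cohort = cohort or self.model.cohort
        cls = self.classify(cohort, threshold)
        table = confusion(cls, cohort.outcome(self.model.outcome), cohort.weights)
        return screening_metrics(
            table, ci_method, outcome_label=self.model.outcome, cohort_label=cohort_label
        )

    def summary(self) -> str:
        f = self.fitted
        lines = [
            "Stepwise logistic regression (weighted)",
            "=" * 62,
            f"selected predictors:   {len(f.selected)}",
            f"log-likelihood:        {f.log_likelihood:.2f}",
            f"intercept:             {f.intercept:.4f}",
            "",
            f"{'term':<12} {'coef':>9} {'se':>8} {'p':>9} {'OR':>7} {'95% CI':>17}",
            "-" * 66,
        ]
        for name in f.selected:
            o = f.odds_ratios.loc[name]
            lines.append(
                f"{name:<12} {f.coefficients[name]:>9.4f} {f.standard_errors[name]:>8.4f} "
                f"{f.pvalues[name]:>9.2e} {o['or']:>7.2f} "
                f"({o['lower']:.2f},{o['upper']:.2f})".rjust(0)
            )
        if f.selection_trace:
            lines += ["", "selection trace: " + ", ".join(f.selection_trace)]
        return "\n".join(lines)
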