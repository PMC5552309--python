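"""Stepwise logistic-regression comparator.

The tree procedure is benchmarked against the traditional approach: a
weighted logistic regression with classical stepwise selection (Wald-p
entry below ``entry_alpha``, removal above ``stay_alpha``), dichotomized
into a high-risk flag at a fitted-probability threshold so the same
screening diagnostics apply.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import Cohort
from .profiles import HighRiskClassification

Z_95 = 1.959963984540054


class LogisticError(ValueError):
    pass


class SeparationError(LogisticError):
    """The likelihood is unbounded (perfect separation) or IRLS diverged."""


@dataclass(frozen=True)
class StepwiseConfig:
    entry_alpha: float = 0.05
    stay_alpha: float = 0.05
    max_iterations: int = 200
    convergence_tol: float = 1e-8
    classification_threshold: float = 0.5

    def __post_init__(self) -> None:
        for a in (self.entry_alpha, self.stay_alpha):
            if not 0 < a < 1:
                raise LogisticError("alphas must lie in (0, 1)")


@dataclass
class LogisticModel:
    selected: list[str]
    intercept: float
    coefficients: pd.Series
    standard_errors: pd.Series
    pvalues: pd.Series
    odds_ratios: pd.DataFrame  # columns: or, lower, upper
    fitted_probabilities: np.ndarray
    log_likelihood: float
    selection_trace: list[str] = field(default_factory=list)

    def predict(self, predictors: pd.DataFrame) -> np.ndarray:
        eta = np.full(len(predictors), self.intercept)
        for name in self.selected:
            if name not in predictors.columns:
                raise LogisticError(f"cohort is missing model predictor {name!r}")
            eta = eta + self.coefficients[name] * predictors[name].to_numpy(dtype=float)
        return 1.0 / (1.0 + np.exp(-eta))


def _design(predictors: pd.DataFrame, names: list[str]) -> pd.DataFrame:
    X = predictors[names].astype(float).copy() if names else pd.DataFrame(index=predictors.index)
    X.insert(0, "const", 1.0)
    return X


def fit_logistic(
    design: pd.DataFrame,
    outcome,
    weights,
    config: StepwiseConfig = StepwiseConfig(),
    trace: Optional[list[str]] = None,
) -> LogisticModel:
    """Weighted maximum-likelihood logistic fit (IRLS).

    Survey weights enter as variance weights, so the point estimates solve
    the weighted score equations.  Constant predictor columns, perfect
    separation and IRLS divergence raise explicit errors.
    """
    y = np.asarray(outcome, dtype=float)
    w = np.asarray(weights, dtype=float)
    names = [str(c) for c in design.columns]
    for name in names:
        if design[name].nunique() < 2:
            raise LogisticError(f"predictor {name!r} is constant in this sample")
    if len(design) <= len(names) + 1:
        raise LogisticError("more parameters than observations")
    X = _design(design, names)
    model = sm.GLM(y, X, family=sm.families.Binomial(), var_weights=w)
    try:
        res = model.fit(maxiter=config.max_iterations, tol=config.convergence_tol)
    except Exception as exc:  # statsmodels PerfectSeparation / LinAlg errors
        raise SeparationError(f"logistic fit failed: {exc}") from exc
    if not res.converged or np.any(np.abs(res.params) > 30) or np.any(res.bse > 1e3):
        raise SeparationError(
            "logistic fit did not converge to a finite maximum "
            "(possible perfect separation)"
        )
    params = res.params
    bse = res.bse
    coef = params.drop("const")
    or_table = pd.DataFrame(
        {
            "or": np.exp(coef),
            "lower": np.exp(coef - Z_95 * bse.drop("const")),
            "upper": np.exp(coef + Z_95 * bse.drop("const")),
        }
    )
    return LogisticModel(
        selected=names,
        intercept=float(params["const"]),
        coefficients=coef,
        standard_errors=bse.drop("const"),
        pvalues=res.pvalues.drop("const"),
        odds_ratios=or_table,
        fitted_probabilities=np.asarray(res.fittedvalues, dtype=float),
        log_likelihood=float(res.llf),
        selection_trace=list(trace or []),
    )


def stepwise_select(
    cohort: Cohort,
    candidates: Optional[list[str]] = None,
    config: StepwiseConfig = StepwiseConfig(),
    outcome: str = "y_primary",
) -> LogisticModel:
    """Classical stepwise selection by Wald p-values.

    Repeatedly: add the excluded candidate with the smallest Wald p below
    ``entry_alpha`` (p taken from the fit that includes it), then remove
    any included term whose p exceeds ``stay_alpha``.  Revisiting a model
    state already seen terminates the loop (anti-cycling), as does a pass
    with no entry.  Candidates that are constant or that break the fit are
    skipped.  The final model carries the full selection trace.
    """
    y = cohort.outcome(outcome)
    w = cohort.weights
    preds = cohort.predictors
    if candidates is None:
        candidates = [c for c in cohort.predictor_names if preds[c].nunique() > 1]
    selected: list[str] = []
    trace: list[str] = []
    seen = {frozenset()}

    def try_fit(names: list[str]) -> Optional[LogisticModel]:
        try:
            return fit_logistic(preds[names], y, w, config)
        except LogisticError:
            return None

    for _ in range(config.max_iterations):
        # entry step
        best_name, best_p = None, np.inf
        for name in candidates:
            if name in selected:
                continue
            fit = try_fit(selected + [name])
            if fit is None:
                continue
            p = float(fit.pvalues[name])
            if p < best_p:
                best_name, best_p = name, p
        if best_name is None or best_p >= config.entry_alpha:
            break
        state = frozenset(selected) | {best_name}
        if state in seen:
            break
        selected.append(best_name)
        seen.add(state)
        trace.append(f"+{best_name} (p={best_p:.3g})")
        # removal step
        while len(selected) > 0:
            fit = try_fit(selected)
            if fit is None:
                # the newly grown model is unstable; back out the last entry
                trace.append(f"-{selected[-1]} (unstable fit)")
                selected.pop()
                break
            worst = fit.pvalues[selected].astype(float).idxmax()
            if float(fit.pvalues[worst]) <= config.stay_alpha:
                break
            state = frozenset(selected) - {worst}
            if state in seen:
                break
            selected.remove(worst)
            seen.add(state)
            trace.append(f"-{worst} (p={float(fit.pvalues[worst]):.3g})")

    if selected:
        final = fit_logistic(preds[selected], y, w, config, trace=trace)
    else:
        # intercept-only model
        X = pd.DataFrame({"const": np.ones(cohort.n)})
        res = sm.GLM(np.asarray(y, float), X, family=sm.families.Binomial(), var_weights=w).fit()
        final = LogisticModel(
            selected=[],
            intercept=float(res.params["const"]),
            coefficients=pd.Series(dtype=float),
            standard_errors=pd.Series(dtype=float),
            pvalues=pd.Series(dtype=float),
            odds_ratios=pd.DataFrame(columns=["or", "lower", "upper"]),
            fitted_probabilities=np.asarray(res.fittedvalues, dtype=float),
            log_likelihood=float(res.llf),
            selection_trace=trace,
        )
    return final


def classify_by_probability(
    model: LogisticModel,
    cohort: Cohort,
    threshold: float = 0.5,
) -> HighRiskClassification:
    """Flag individuals whose fitted probability strictly exceeds the threshold."""
    p = model.predict(cohort.predictors)
    flags = p > threshold
    matched = ["logistic" if f else None for f in flags]
    return HighRiskClassification(flags=flags, matched_profile_id=matched)


def threshold_sweep(
    model: LogisticModel,
    cohort: Cohort,
    outcome: str = "y_primary",
) -> pd.DataFrame:
    """Sensitivity/specificity at every achievable probability threshold."""
    from .diagnostics import confusion, screening_metrics

    p = model.predict(cohort.predictors)
    rows = []
    for thr in np.unique(np.concatenate(([0.0, 1.0], p))):
        cls = HighRiskClassification(flags=p > thr, matched_profile_id=[None] * cohort.n)
        res = screening_metrics(confusion(cls, cohort.outcome(outcome), cohort.weights))
        rows.append(
            {
                "threshold": float(thr),
                "sensitivity": res.sensitivity.estimate,
                "specificity": res.specificity.estimate,
            }
        )
    return pd.DataFrame(rows)
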