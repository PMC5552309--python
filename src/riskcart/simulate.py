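"""Synthetic cohort generator with planted high-risk subgroups.

The real discovery and validation cohorts behind this kind of analysis are
restricted-access microdata, so every pipeline stage is exercised on
synthetic cohorts that emulate their statistical structure: ~75 correlated
dichotomized early-life predictors (item non-response folded into the
"no/missing" level), a ~12% weighted prevalence of the primary outcome,
six correlated secondary outcomes, right-skewed non-negative survey
weights, and planted high-risk subgroups defined by conjunctions of
predictor conditions.

Predictor co-occurrence is induced by a single shared latent "adversity"
factor per individual, thresholded per predictor — the simplest one-
parameter mechanism that reproduces the clustering of early-life stressors.
The primary outcome is drawn at each planted subgroup's configured
prevalence for its members (first matching subgroup wins, in declared
order) and at a background rate calibrated so the overall weighted
prevalence approaches the configured base rate.  Secondary outcomes are
elevated for subgroup members so they share predictors with the primary
outcome (multifinality).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from .cohort import Cohort, PRIMARY_OUTCOME, SECONDARY_OUTCOME_COLUMNS
from .profiles import PredictorMapping

#: Default secondary-outcome prevalences, in canonical reporting order
#: (antisocial, substance, physical, mental, risky behaviours, academic);
#: the endpoints of the emulated range are 11.4% and 26.4%.
DEFAULT_SECONDARY_PREVALENCES = (0.15, 0.264, 0.14, 0.16, 0.114, 0.18)

#: Multiplier applied to each secondary outcome's prevalence inside
#: planted subgroups (capped at 0.95).
SECONDARY_MEMBER_LIFT = 2.0


class SpecError(ValueError):
    pass


class CalibrationError(ValueError):
    """Planted subgroups so large or extreme that no background rate exists."""


@dataclass(frozen=True)
class PlantedSubgroup:
    """A high-risk cell: a conjunction of 1-9 predictor conditions."""

    conditions: tuple[tuple[int, str], ...]  # (predictor index, "yes"|"no")
    outcome_prevalence_in_group: float

    def __post_init__(self) -> None:
        if not 1 <= len(self.conditions) <= 9:
            raise SpecError("a planted subgroup needs 1-9 conditions")
        idx = [i for i, _ in self.conditions]
        if len(set(idx)) != len(idx):
            raise SpecError("subgroup predictor indices must be distinct")
        if any(level not in ("yes", "no") for _, level in self.conditions):
            raise SpecError("condition levels must be 'yes' or 'no'")
        if not 0 < self.outcome_prevalence_in_group < 1:
            raise SpecError("subgroup outcome prevalence must lie in (0, 1)")


@dataclass(frozen=True)
class CohortSpec:
    """Full description of one synthetic cohort; identical spec => identical cohort."""

    n_individuals: int
    n_predictors: int = 75
    base_prevalence: float = 0.12
    secondary_prevalences: tuple = DEFAULT_SECONDARY_PREVALENCES
    planted_subgroups: tuple = ()
    predictor_marginals: Optional[tuple] = None  # pre-fold "yes" rates
    missingness_rates: Optional[tuple] = None
    clustering_strength: float = 0.2  # latent correlation in [0, 1)
    weight_dispersion: float = 0.5  # CV of the gamma survey weights
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1 or self.n_predictors < 1:
            raise SpecError("counts must be positive")
        if not 0 < self.base_prevalence < 1:
            raise SpecError("base_prevalence must lie in (0, 1)")
        if len(self.secondary_prevalences) != 6 or any(
            not 0 < s < 1 for s in self.secondary_prevalences
        ):
            raise SpecError("need six secondary prevalences in (0, 1)")
        if not 0 <= self.clustering_strength < 1:
            raise SpecError("clustering_strength must lie in [0, 1)")
        if self.weight_dispersion < 0:
            raise SpecError("weight_dispersion must be >= 0")
        object.__setattr__(self, "planted_subgroups", tuple(self.planted_subgroups))
        for group in self.planted_subgroups:
            for i, _ in group.conditions:
                if not 0 <= i < self.n_predictors:
                    raise SpecError(f"subgroup references predictor index {i} out of range")
        for name, values, lo, hi in (
            ("predictor_marginals", self.predictor_marginals, 0.0, 1.0),
            ("missingness_rates", self.missingness_rates, -1e-12, 1.0),
        ):
            if values is not None:
                if len(values) != self.n_predictors:
                    raise SpecError(f"{name} must have one entry per predictor")
                if any(not lo < v < hi for v in values):
                    raise SpecError(f"{name} entries out of range")

    # resolved per-predictor parameters ------------------------------------
    def marginals(self) -> np.ndarray:
        if self.predictor_marginals is not None:
            return np.asarray(self.predictor_marginals, dtype=float)
        return np.linspace(0.10, 0.50, self.n_predictors)

    def missingness(self) -> np.ndarray:
        if self.missingness_rates is not None:
            return np.asarray(self.missingness_rates, dtype=float)
        return np.full(self.n_predictors, 0.15)

    def predictor_names(self) -> list[str]:
        return [f"x{i + 1:04d}" for i in range(self.n_predictors)]

    # -- config-file dialect ----------------------------------------------
    def to_dict(self) -> dict:
        return {
            "n_individuals": self.n_individuals,
            "n_predictors": self.n_predictors,
            "base_prevalence": self.base_prevalence,
            "secondary_prevalences": list(self.secondary_prevalences),
            "planted_subgroups": [
                {
                    "conditions": [[i, lv] for i, lv in g.conditions],
                    "outcome_prevalence_in_group": g.outcome_prevalence_in_group,
                }
                for g in self.planted_subgroups
            ],
            "predictor_marginals": (
                list(self.predictor_marginals) if self.predictor_marginals else None
            ),
            "missingness_rates": (
                list(self.missingness_rates) if self.missingness_rates else None
            ),
            "clustering_strength": self.clustering_strength,
            "weight_dispersion": self.weight_dispersion,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "CohortSpec":
        payload = dict(payload)
        groups = tuple(
            PlantedSubgroup(
                conditions=tuple((int(i), str(lv)) for i, lv in g["conditions"]),
                outcome_prevalence_in_group=float(g["outcome_prevalence_in_group"]),
            )
            for g in payload.get("planted_subgroups", [])
        )
        payload["planted_subgroups"] = groups
        for key in ("secondary_prevalences", "predictor_marginals", "missingness_rates"):
            if payload.get(key) is not None:
                payload[key] = tuple(payload[key])
        return cls(**payload)

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class ValidationReport:
    """Which discovery predictors made it into the validation cohort."""

    mapped: list[str] = field(default_factory=list)
    unmapped: list[str] = field(default_factory=list)

    @property
    def coverage(self) -> float:
        total = len(self.mapped) + len(self.unmapped)
        return len(self.mapped) / total if total else 0.0


# ---------------------------------------------------------------------------


def _draw_predictors(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    """Correlated binary predictors with missingness folded to 0."""
    n, p = spec.n_individuals, spec.n_predictors
    rho = spec.clustering_strength
    z = rng.standard_normal(n)
    eps = rng.standard_normal((n, p))
    latent = np.sqrt(rho) * z[:, None] + np.sqrt(1.0 - rho) * eps
    raw_yes = latent <= norm.ppf(spec.marginals())[None, :]
    observed_missing = rng.random((n, p)) < spec.missingness()[None, :]
    return (raw_yes & ~observed_missing).astype(int)


def subgroup_membership(
    X: np.ndarray, groups: Sequence[PlantedSubgroup]
) -> np.ndarray:
    """Index of the first matching planted subgroup per row, -1 for none."""
    member = np.full(len(X), -1, dtype=int)
    for g_idx, group in enumerate(groups):
        mask = np.ones(len(X), dtype=bool)
        for i, level in group.conditions:
            mask &= X[:, i] == (1 if level == "yes" else 0)
        member[(member == -1) & mask] = g_idx
    return member


def _background_rate(
    target: float, member_share: float, member_rate: float, what: str
) -> float:
    """Solve share*member_rate + (1-share)*q = target for q."""
    if member_share >= 1.0:
        return 0.0  # no non-members; q is never used
    q = (target - member_share * member_rate) / (1.0 - member_share)
    if not 0.0 <= q <= 1.0:
        raise CalibrationError(
            f"cannot calibrate {what}: required background rate {q:.4f} "
            "falls outside [0, 1] — planted subgroups too large or extreme"
        )
    return q


def generate_cohort(spec: CohortSpec, seed: Optional[int] = None) -> Cohort:
    """Generate one cohort per the spec; same spec (and seed) => same cohort."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n_individuals
    X = _draw_predictors(spec, rng)

    if spec.weight_dispersion > 0:
        shape = 1.0 / spec.weight_dispersion**2
        weights = rng.gamma(shape, scale=1.0 / shape, size=n)
    else:
        weights = np.ones(n)
    w_total = weights.sum()

    member = subgroup_membership(X, spec.planted_subgroups)
    group_share = np.array(
        [weights[member == g].sum() / w_total for g in range(len(spec.planted_subgroups))]
    )
    group_rates = np.array(
        [g.outcome_prevalence_in_group for g in spec.planted_subgroups]
    )
    member_share = float(group_share.sum())
    member_rate = (
        float((group_share * group_rates).sum() / member_share) if member_share > 0 else 0.0
    )
    q = _background_rate(spec.base_prevalence, member_share, member_rate, "primary outcome")

    prob = np.where(member >= 0, group_rates[member] if len(group_rates) else 0.0, q)
    y_primary = (rng.random(n) < prob).astype(int)

    secondary = {}
    is_member = member >= 0
    for col, target in zip(SECONDARY_OUTCOME_COLUMNS, spec.secondary_prevalences):
        r_member = min(0.95, SECONDARY_MEMBER_LIFT * target)
        b = _background_rate(target, member_share, r_member, f"secondary outcome {col}")
        p_sec = np.where(is_member, r_member, b)
        secondary[col] = (rng.random(n) < p_sec).astype(int)

    return Cohort(
        ids=np.arange(n),
        weights=weights,
        predictors=pd.DataFrame(X, columns=spec.predictor_names()),
        primary_outcome=y_primary,
        secondary_outcomes=pd.DataFrame(secondary),
    )


def make_validation_cohort(
    spec: CohortSpec,
    mapping: PredictorMapping,
    seed: Optional[int] = None,
) -> tuple[Cohort, ValidationReport]:
    """Second cohort whose predictors are noisy proxies of the discovery ones.

    The cohort is generated from the same structural spec (planted
    subgroups and outcomes are defined on the latent, pre-noise variables);
    each mapped predictor is then flipped independently with its entry's
    flip probability and renamed to its proxy, and unmapped variables are
    dropped.  The report lists mapped and unmapped source predictors.
    """
    names = spec.predictor_names()
    known = set(names)
    for entry in mapping.entries:
        if entry.source not in known:
            raise SpecError(f"mapping references unknown predictor {entry.source!r}")
    cohort = generate_cohort(spec, seed=seed)
    rng = np.random.default_rng(
        (spec.seed if seed is None else seed) + 1_000_003
    )
    report = ValidationReport()
    proxy = {}
    for name in names:
        try:
            entry = mapping.lookup(name)
        except Exception:
            entry = None
        if entry is None or entry.target is None:
            report.unmapped.append(name)
            continue
        x = cohort.predictors[name].to_numpy().copy()
        if entry.flip_probability > 0:
            flip = rng.random(len(x)) < entry.flip_probability
            x[flip] = 1 - x[flip]
        proxy[entry.target] = x
        report.mapped.append(name)
    validation = Cohort(
        ids=cohort.ids,
        weights=cohort.weights,
        predictors=pd.DataFrame(proxy, index=range(cohort.n)),
        primary_outcome=cohort.primary_outcome,
        secondary_outcomes=cohort.secondary_outcomes,
    )
    return validation, report
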