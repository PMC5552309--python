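"""High-risk subgroup profiles and their transport to a second cohort.

A profile is the conjunction of the yes/no path conditions that define one
high-risk terminal of the pruned tree.  Classifying a cohort by a profile
set flags anyone satisfying every condition of at least one profile; in
external validation the profiles are first ported through a mapping from
discovery-cohort predictors to the closest available proxies in the
validation cohort.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .cohort import Cohort
from .risk import HIGH
from .tree import Tree

#: Sentinel target meaning "no proxy exists in the validation cohort".
ABSENT = None

POLICY_DROP = "drop-condition"
POLICY_NEVER = "profile-never-fires"
POLICY_FAIL = "fail"
PORT_POLICIES = (POLICY_DROP, POLICY_NEVER, POLICY_FAIL)


class ProfileError(ValueError):
    pass


@dataclass(frozen=True)
class SubgroupProfile:
    """One high-risk terminal as a conjunction of predictor conditions."""

    profile_id: str
    conditions: tuple[tuple[str, str], ...]  # (predictor name, "yes"|"no")
    training_prevalence: float
    training_n: int

    def __post_init__(self) -> None:
        if len(self.conditions) < 1:
            raise ProfileError("a profile needs at least one condition")
        names = [c[0] for c in self.conditions]
        if len(set(names)) != len(names):
            raise ProfileError("a predictor may appear only once per profile")


@dataclass
class MappingEntry:
    source: str
    target: Optional[str] = None  # None = ABSENT (no usable proxy)
    flip_probability: float = 0.0  # proxy disagreement rate, for simulation
    note: str = ""


@dataclass
class PredictorMapping:
    """Closest-proxy predictor mapping between two cohorts."""

    entries: list[MappingEntry]

    def __post_init__(self) -> None:
        names = [e.source for e in self.entries]
        if len(set(names)) != len(names):
            raise ProfileError("mapping source names must be unique")
        self._by_source = {e.source: e for e in self.entries}

    def lookup(self, source: str) -> MappingEntry:
        if source not in self._by_source:
            raise ProfileError(f"mapping has no entry for predictor {source!r}")
        return self._by_source[source]

    @property
    def coverage(self) -> float:
        if not self.entries:
            return 0.0
        mapped = sum(e.target is not None for e in self.entries)
        return mapped / len(self.entries)

    @classmethod
    def identity(cls, names, flip_probability: float = 0.0) -> "PredictorMapping":
        return cls([MappingEntry(n, n, flip_probability) for n in names])

    # CSV dialect: columns source,target,flip_probability,note; empty target = ABSENT
    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "source": [e.source for e in self.entries],
                "target": [e.target if e.target is not None else "" for e in self.entries],
                "flip_probability": [e.flip_probability for e in self.entries],
                "note": [e.note for e in self.entries],
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PredictorMapping":
        frame = pd.read_csv(path, keep_default_na=False)
        entries = []
        for _, row in frame.iterrows():
            target = str(row["target"]) if str(row["target"]) else None
            flip = float(row["flip_probability"]) if "flip_probability" in frame.columns else 0.0
            entries.append(
                MappingEntry(str(row["source"]), target, flip, str(row.get("note", "")))
            )
        return cls(entries)


@dataclass
class HighRiskClassification:
    """Per-individual high-risk flag plus the first matching profile id."""

    flags: np.ndarray
    matched_profile_id: list[Optional[str]]

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=bool)

    @property
    def n_flagged(self) -> int:
        return int(self.flags.sum())


@dataclass
class CoverageReport:
    """What a mapping did to each profile when porting."""

    policy: str
    unmapped_by_profile: dict[str, list[str]] = field(default_factory=dict)
    per_profile_mapped_fraction: dict[str, float] = field(default_factory=dict)
    disabled_profiles: list[str] = field(default_factory=list)


def extract_high_risk_profiles(tree: Tree) -> list[SubgroupProfile]:
    """One profile per high-risk terminal, ordered by descending prevalence.

    Conditions are the terminal's path conditions in root-to-leaf order;
    profiles from distinct leaves are mutually exclusive conjunctions.
    Ties in prevalence break by node id for determinism.
    """
    leaves = []
    for node in tree.terminals():
        if node.risk_level is None:
            raise ProfileError(f"terminal {node.node_id} is not risk-annotated")
        if node.risk_level == HIGH:
            leaves.append(node)
    leaves.sort(key=lambda nd: (-nd.weighted_prevalence, nd.node_id))
    return [
        SubgroupProfile(
            profile_id=f"subgroup_{rank}",
            conditions=tuple(node.path_conditions),
            training_prevalence=node.weighted_prevalence,
            training_n=node.n_unweighted,
        )
        for rank, node in enumerate(leaves, start=1)
    ]


def _profile_mask(profile: SubgroupProfile, predictors: pd.DataFrame) -> np.ndarray:
    mask = np.ones(len(predictors), dtype=bool)
    for name, level in profile.conditions:
        if name not in predictors.columns:
            raise ProfileError(f"cohort is missing predictor column {name!r}")
        x = predictors[name].to_numpy()
        mask &= x == (1 if level == "yes" else 0)
    return mask


def classify(profiles: list[SubgroupProfile], cohort: Cohort) -> HighRiskClassification:
    """Flag individuals satisfying every condition of at least one profile.

    The matched profile id is the first satisfied profile in stored order
    (profiles are stored in descending training prevalence).
    """
    flags = np.zeros(cohort.n, dtype=bool)
    matched: list[Optional[str]] = [None] * cohort.n
    for profile in profiles:
        mask = _profile_mask(profile, cohort.predictors)
        fresh = mask & ~flags
        for i in np.flatnonzero(fresh):
            matched[i] = profile.profile_id
        flags |= mask
    return HighRiskClassification(flags=flags, matched_profile_id=matched)


def port_profiles(
    profiles: list[SubgroupProfile],
    mapping: PredictorMapping,
    policy: str = POLICY_NEVER,
) -> tuple[list[SubgroupProfile], CoverageReport]:
    """Rename profile conditions through a predictor mapping.

    Conditions on variables with no proxy (ABSENT target) follow ``policy``:

    - ``drop-condition``: the condition is removed (the profile can only
      match a superset of the individuals it matched before);
    - ``profile-never-fires``: the whole profile is disabled — nobody is
      classified high-risk on a condition that cannot be verified;
    - ``fail``: raise.
    """
    if policy not in PORT_POLICIES:
        raise ProfileError(f"unknown policy {policy!r}; choose from {PORT_POLICIES}")
    report = CoverageReport(policy=policy)
    ported: list[SubgroupProfile] = []
    for profile in profiles:
        new_conditions = []
        unmapped = []
        for name, level in profile.conditions:
            entry = mapping.lookup(name)
            if entry.target is None:
                unmapped.append(name)
            else:
                new_conditions.append((entry.target, level))
        report.unmapped_by_profile[profile.profile_id] = unmapped
        report.per_profile_mapped_fraction[profile.profile_id] = (
            len(new_conditions) / len(profile.conditions)
        )
        if unmapped:
            if policy == POLICY_FAIL:
                raise ProfileError(
                    f"profile {profile.profile_id!r} uses unmapped predictors: {unmapped}"
                )
            if policy == POLICY_NEVER:
                report.disabled_profiles.append(profile.profile_id)
                continue
        if not new_conditions:  # drop-condition removed everything
            report.disabled_profiles.append(profile.profile_id)
            continue
        ported.append(
            SubgroupProfile(
                profile_id=profile.profile_id,
                conditions=tuple(new_conditions),
                training_prevalence=profile.training_prevalence,
                training_n=profile.training_n,
            )
        )
    return ported, report


# -- JSON dialect -----------------------------------------------------------


def profiles_to_json(profiles: list[SubgroupProfile], path) -> None:
    payload = [
        {
            "profile_id": p.profile_id,
            "conditions": [{"predictor": n, "level": lv} for n, lv in p.conditions],
            "training_prevalence": p.training_prevalence,
            "training_n": p.training_n,
        }
        for p in profiles
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def profiles_from_json(path) -> list[SubgroupProfile]:
    with open(path) as fh:
        payload = json.load(fh)
    return [
        SubgroupProfile(
            profile_id=rec["profile_id"],
            conditions=tuple((c["predictor"], c["level"]) for c in rec["conditions"]),
            training_prevalence=rec["training_prevalence"],
            training_n=rec["training_n"],
        )
        for rec in payload
    ]
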