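"""Weighted cohort container and predictor encoding.

A cohort is one row per child: a survey weight, a binary primary outcome,
six binary secondary outcomes, and a block of dichotomized early-life
predictors coded 1 = yes, 0 = no/missing.  Item non-response is folded into
the "no" level before modelling, so the encoded table has no missing
entries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Secondary outcomes in canonical reporting order.
SECONDARY_OUTCOME_LABELS = (
    "antisocial_behaviour",
    "substance_misuse",
    "poor_physical_health",
    "poor_mental_health",
    "risky_health_behaviours",
    "poor_academic_performance",
)

PRIMARY_OUTCOME = "y_primary"
SECONDARY_OUTCOME_COLUMNS = tuple(f"y_sec{i}" for i in range(1, 7))


class CohortError(ValueError):
    """Invalid cohort structure (non-binary columns, bad weights, ...)."""


@dataclass
class Cohort:
    """Individual-level weighted cohort.

    Parameters
    ----------
    ids : array of unique identifiers
    weights : non-negative survey weights, at least one positive
    predictors : DataFrame of 0/1 predictor columns (1 = yes, 0 = no/missing)
    primary_outcome : 0/1 vector
    secondary_outcomes : DataFrame with the six 0/1 secondary-outcome columns
    """

    ids: np.ndarray
    weights: np.ndarray
    predictors: pd.DataFrame
    primary_outcome: np.ndarray
    secondary_outcomes: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.weights = np.asarray(self.weights, dtype=float)
        self.primary_outcome = np.asarray(self.primary_outcome)
        n = len(self.ids)
        if self.secondary_outcomes is None:
            self.secondary_outcomes = pd.DataFrame(index=range(n))
        if len(np.unique(self.ids)) != n:
            raise CohortError("ids must be unique")
        if len(self.weights) != n or len(self.predictors) != n:
            raise CohortError("weights/predictors length mismatch with ids")
        if len(self.primary_outcome) != n or len(self.secondary_outcomes) != n:
            raise CohortError("outcome length mismatch with ids")
        if np.any(self.weights < 0) or not np.any(self.weights > 0):
            raise CohortError("weights must be >= 0 with at least one positive")
        _check_binary(self.primary_outcome, PRIMARY_OUTCOME)
        for col in self.secondary_outcomes.columns:
            _check_binary(self.secondary_outcomes[col].to_numpy(), str(col))
        for col in self.predictors.columns:
            _check_binary(self.predictors[col].to_numpy(), str(col))

    # -- basic views -------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def predictor_names(self) -> list[str]:
        return [str(c) for c in self.predictors.columns]

    def outcome(self, name: str) -> np.ndarray:
        """Return an outcome column by name (primary or secondary)."""
        if name == PRIMARY_OUTCOME:
            return self.primary_outcome
        if name in self.secondary_outcomes.columns:
            return self.secondary_outcomes[name].to_numpy()
        raise CohortError(f"unknown outcome column: {name!r}")

    @property
    def outcome_names(self) -> list[str]:
        return [PRIMARY_OUTCOME] + [str(c) for c in self.secondary_outcomes.columns]

    # -- I/O ---------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame({"id": self.ids, "weight": self.weights})
        frame[PRIMARY_OUTCOME] = self.primary_outcome.astype(int)
        for col in self.secondary_outcomes.columns:
            frame[col] = self.secondary_outcomes[col].astype(int).to_numpy()
        for col in self.predictors.columns:
            frame[col] = self.predictors[col].astype(int).to_numpy()
        return frame

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Cohort":
        required = {"id", "weight", PRIMARY_OUTCOME}
        missing = required - set(map(str, frame.columns))
        if missing:
            raise CohortError(f"cohort table missing columns: {sorted(missing)}")
        sec_cols = [c for c in SECONDARY_OUTCOME_COLUMNS if c in frame.columns]
        reserved = {"id", "weight", PRIMARY_OUTCOME, *sec_cols}
        pred_cols = [c for c in frame.columns if str(c) not in reserved]
        return cls(
            ids=frame["id"].to_numpy(),
            weights=frame["weight"].to_numpy(dtype=float),
            predictors=frame[pred_cols].astype(int).reset_index(drop=True),
            primary_outcome=frame[PRIMARY_OUTCOME].to_numpy(dtype=int),
            secondary_outcomes=frame[sec_cols].astype(int).reset_index(drop=True),
        )

    @classmethod
    def from_csv(cls, path) -> "Cohort":
        return cls.from_frame(pd.read_csv(path))

    def subset(self, mask: np.ndarray) -> "Cohort":
        mask = np.asarray(mask, dtype=bool)
        return Cohort(
            ids=self.ids[mask],
            weights=self.weights[mask],
            predictors=self.predictors.loc[mask].reset_index(drop=True),
            primary_outcome=self.primary_outcome[mask],
            secondary_outcomes=self.secondary_outcomes.loc[mask].reset_index(drop=True),
        )


def _check_binary(values: np.ndarray, name: str) -> None:
    vals = np.asarray(values)
    if vals.size and not np.isin(vals, (0, 1)).all():
        raise CohortError(f"column {name!r} is not strictly 0/1")


def encode_predictors(raw_table: pd.DataFrame) -> pd.DataFrame:
    """Fold a three-level yes/no/missing table into the 0/1 modelling coding.

    ``yes`` maps to 1; ``no`` and ``missing`` both map to 0, so item
    non-response is absorbed into the reference level rather than dropping
    the individual.  Shape and column names are preserved.

    Raises
    ------
    CohortError
        If any cell holds a level other than ``yes``/``no``/``missing``,
        naming the offending row and column.
    """
    encoded = pd.DataFrame(index=raw_table.index)
    for col in raw_table.columns:
        values = raw_table[col].astype(str)
        bad = ~values.isin(("yes", "no", "missing"))
        if bad.any():
            row = raw_table.index[bad.to_numpy()][0]
            raise CohortError(
                f"unrecognized level {raw_table.loc[row, col]!r} "
                f"at row {row!r}, column {col!r}"
            )
        encoded[col] = (values == "yes").astype(int)
    return encoded
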