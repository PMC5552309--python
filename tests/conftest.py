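from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from riskcart.cohort import SECONDARY_OUTCOME_COLUMNS, Cohort
from riskcart.risk import HIGH, LOW, MODERATE
from riskcart.tree import GrowConfig, Tree, TreeNode


def make_cohort(X, y, w=None, secondary=None) -> Cohort:
    """Wrap plain arrays into a Cohort with x0001.. predictor names."""
    X = np.asarray(X, dtype=int)
    n, p = X.shape
    if w is None:
        w = np.ones(n)
    sec = pd.DataFrame(index=range(n))
    if secondary is not None:
        sec = pd.DataFrame(
            {c: np.asarray(v, dtype=int) for c, v in zip(SECONDARY_OUTCOME_COLUMNS, secondary)}
        )
    return Cohort(
        ids=np.arange(n),
        weights=np.asarray(w, dtype=float),
        predictors=pd.DataFrame(X, columns=[f"x{j + 1:04d}" for j in range(p)]),
        primary_outcome=np.asarray(y, dtype=int),
        secondary_outcomes=sec,
    )


def random_cohort(rng: np.random.Generator, n: int, p: int, weighted=True, y_rate=0.5) -> Cohort:
    X = rng.integers(0, 2, size=(n, p))
    y = (rng.random(n) < y_rate).astype(int)
    w = rng.gamma(4.0, 0.25, size=n) if weighted else None
    return make_cohort(X, y, w)


def random_annotated_tree(rng: np.random.Generator, max_nodes: int = 15) -> Tree:
    """Random risk-annotated tree with conservation-consistent pooled counts.

    Built top-down from integer (weight, positive-count) pairs so every
    parent's totals are exactly the sum of its children's; risk levels are
    drawn at random, so homogeneous subtrees occur often.
    """
    levels = [HIGH, MODERATE, LOW]
    nodes: dict[int, TreeNode] = {}
    counter = iter(range(10_000))

    def build(n_int: int, ones: int, depth: int, budget: list[int], path) -> int:
        nid = next(counter)
        node = TreeNode(
            node_id=nid,
            depth=depth,
            n_unweighted=n_int,
            weighted_n=float(n_int),
            weighted_prevalence=ones / n_int,
            unweighted_prevalence=ones / n_int,
            path_conditions=list(path),
            risk_level=levels[rng.integers(3)],
        )
        nodes[nid] = node
        can_split = n_int >= 2 and budget[0] >= 2 and rng.random() < 0.7
        if can_split:
            budget[0] -= 2
            nl = int(rng.integers(1, n_int))
            lo = max(0, ones - (n_int - nl))
            hi = min(ones, nl)
            ol = int(rng.integers(lo, hi + 1))
            name = f"x{depth + 1:04d}"
            node.split_predictor = name
            node.yes_child = build(nl, ol, depth + 1, budget, path + [(name, "yes")])
            node.no_child = build(n_int - nl, ones - ol, depth + 1, budget, path + [(name, "no")])
        return nid

    total = int(rng.integers(8, 40))
    ones = int(rng.integers(0, total + 1))
    budget = [max_nodes - 1]
    root_id = build(total, ones, 0, budget, [])
    return Tree(
        root_id=root_id,
        nodes=nodes,
        grow_config=GrowConfig(n_min=1),
        base_rate=nodes[root_id].weighted_prevalence,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
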