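"""Weighted classification-tree growth over binary predictors.

The tree is grown maximally: parent nodes are split recursively, by the
binary predictor whose yes/no partition gives the largest decrease in
(survey-weighted) Gini impurity, until no split remains that would leave at
least ``n_min`` unweighted individuals in each child.  ``n_min`` is a head
count — survey weights enter the impurity and prevalence computations but
the minimum-size rule counts individuals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .cohort import Cohort


class TreeError(ValueError):
    pass


@dataclass(frozen=True)
class GrowConfig:
    """Growth controls.

    n_min
        Minimum unweighted individuals required in *each child* for a split
        to be admissible (1% of the sample in the motivating analysis).
    min_impurity_decrease
        Splits must strictly exceed this weighted Gini decrease; the default
        0 grows the truly maximal tree under the node-size rule.
    max_depth
        Optional depth cap (None = unbounded).
    use_weights_in_splitting
        When off, impurity is computed on head counts instead of weights.
    """

    n_min: int = 64
    min_impurity_decrease: float = 0.0
    max_depth: Optional[int] = None
    use_weights_in_splitting: bool = True

    def __post_init__(self) -> None:
        if self.n_min < 1:
            raise TreeError("n_min must be >= 1")
        if self.min_impurity_decrease < 0:
            raise TreeError("min_impurity_decrease must be >= 0")


@dataclass(frozen=True)
class SplitCandidate:
    predictor_index: int
    impurity_decrease: float
    left_n: int   # predictor == 1 ("yes") side
    right_n: int  # predictor == 0 ("no") side
    left_w: float
    right_w: float


@dataclass
class TreeNode:
    node_id: int
    depth: int
    n_unweighted: int
    weighted_n: float
    weighted_prevalence: float
    unweighted_prevalence: float
    path_conditions: list[tuple[str, str]]  # (predictor name, "yes"|"no")
    split_predictor: Optional[str] = None
    yes_child: Optional[int] = None
    no_child: Optional[int] = None
    risk_level: Optional[str] = None

    @property
    def is_terminal(self) -> bool:
        return self.split_predictor is None


@dataclass
class Tree:
    root_id: int
    nodes: dict[int, TreeNode]
    grow_config: GrowConfig
    base_rate: float
    predictor_names: list[str] = field(default_factory=list)

    @property
    def root(self) -> TreeNode:
        return self.nodes[self.root_id]

    def terminals(self) -> list[TreeNode]:
        return [nd for nd in self.nodes.values() if nd.is_terminal]

    def children(self, node: TreeNode) -> list[TreeNode]:
        out = []
        if node.yes_child is not None:
            out.append(self.nodes[node.yes_child])
        if node.no_child is not None:
            out.append(self.nodes[node.no_child])
        return out

    def subtree_ids(self, node_id: int) -> list[int]:
        """Pre-order ids of the subtree rooted at node_id."""
        out, stack = [], [node_id]
        while stack:
            nid = stack.pop()
            out.append(nid)
            node = self.nodes[nid]
            for cid in (node.no_child, node.yes_child):
                if cid is not None:
                    stack.append(cid)
        return out

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "root_id": self.root_id,
            "base_rate": self.base_rate,
            "predictor_names": self.predictor_names,
            "grow_config": {
                "n_min": self.grow_config.n_min,
                "min_impurity_decrease": self.grow_config.min_impurity_decrease,
                "max_depth": self.grow_config.max_depth,
                "use_weights_in_splitting": self.grow_config.use_weights_in_splitting,
            },
            "nodes": [
                {
                    "node_id": nd.node_id,
                    "depth": nd.depth,
                    "split_predictor": nd.split_predictor,
                    "yes_child": nd.yes_child,
                    "no_child": nd.no_child,
                    "n_unweighted": nd.n_unweighted,
                    "weighted_n": nd.weighted_n,
                    "weighted_prevalence": nd.weighted_prevalence,
                    "unweighted_prevalence": nd.unweighted_prevalence,
                    "path_conditions": [list(c) for c in nd.path_conditions],
                    "risk_level": nd.risk_level,
                }
                for nd in sorted(self.nodes.values(), key=lambda d: d.node_id)
            ],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "Tree":
        cfg = GrowConfig(**payload["grow_config"])
        nodes = {}
        for rec in payload["nodes"]:
            rec = dict(rec)
            rec["path_conditions"] = [tuple(c) for c in rec["path_conditions"]]
            nodes[rec["node_id"]] = TreeNode(**rec)
        return cls(
            root_id=payload["root_id"],
            nodes=nodes,
            grow_config=cfg,
            base_rate=payload["base_rate"],
            predictor_names=list(payload.get("predictor_names", [])),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "Tree":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------


def weighted_prevalence(outcomes, weights) -> float:
    """Survey-weighted prevalence Σ(wᵢyᵢ)/Σwᵢ of a binary outcome."""
    y = np.asarray(outcomes, dtype=float)
    w = np.asarray(weights, dtype=float)
    if y.shape != w.shape:
        raise TreeError("outcomes and weights must have equal length")
    total = w.sum()
    if total <= 0:
        raise TreeError("total weight must be positive")
    return float((w * y).sum() / total)


def _gini(p: float) -> float:
    return 2.0 * p * (1.0 - p)


def evaluate_split(
    predictors: pd.DataFrame,
    outcome: np.ndarray,
    weights: np.ndarray,
    predictor_index: int,
    config: GrowConfig,
) -> SplitCandidate:
    """Gini impurity decrease of splitting a node on one binary predictor.

    The decrease is parent Gini minus the weight-share-weighted mean of the
    child Ginis; a one-sided (degenerate) split scores 0.
    """
    x = predictors.iloc[:, predictor_index].to_numpy()
    y = np.asarray(outcome, dtype=float)
    w = np.asarray(weights, dtype=float)
    m = w if config.use_weights_in_splitting else np.ones_like(w)

    yes = x == 1
    left_n = int(yes.sum())
    right_n = int(len(x) - left_n)
    left_w = float(w[yes].sum())
    right_w = float(w[~yes].sum())

    decrease = 0.0
    m_tot = m.sum()
    if left_n and right_n and m_tot > 0:
        m_l, m_r = m[yes].sum(), m[~yes].sum()
        if m_l > 0 and m_r > 0:
            p = (m * y).sum() / m_tot
            p_l = (m[yes] * y[yes]).sum() / m_l
            p_r = (m[~yes] * y[~yes]).sum() / m_r
            decrease = _gini(p) - (m_l / m_tot) * _gini(p_l) - (m_r / m_tot) * _gini(p_r)
    return SplitCandidate(
        predictor_index=predictor_index,
        impurity_decrease=max(float(decrease), 0.0),
        left_n=left_n,
        right_n=right_n,
        left_w=left_w,
        right_w=right_w,
    )


def _all_candidate_decreases(X, y, m):
    """Vectorized Gini decrease for every predictor column at once."""
    m_tot = m.sum()
    my = m * y
    m1 = m @ X          # weight mass on the "yes" side, per predictor
    my1 = my @ X
    m0 = m_tot - m1
    my0 = my.sum() - my1
    p = my.sum() / m_tot

    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = np.where(m1 > 0, my1 / np.where(m1 > 0, m1, 1.0), 0.0)
        p0 = np.where(m0 > 0, my0 / np.where(m0 > 0, m0, 1.0), 0.0)
    dec = _gini(p) - (m1 / m_tot) * _gini(p1) - (m0 / m_tot) * _gini(p0)
    dec = np.where((m1 > 0) & (m0 > 0), dec, 0.0)
    return np.maximum(dec, 0.0)


def best_split(
    predictors: pd.DataFrame,
    outcome: np.ndarray,
    weights: np.ndarray,
    config: GrowConfig,
) -> Optional[SplitCandidate]:
    """Best admissible split of a node, or None.

    Admissible: both children hold at least ``n_min`` unweighted individuals
    and the impurity decrease strictly exceeds ``min_impurity_decrease``.
    Ties break to the lowest predictor index, which makes growth
    deterministic for a fixed column order.
    """
    if len(predictors) == 0:
        raise TreeError("node has no rows")
    X = predictors.to_numpy(dtype=float)
    y = np.asarray(outcome, dtype=float)
    w = np.asarray(weights, dtype=float)
    m = w if config.use_weights_in_splitting else np.ones(len(y))

    n1 = X.sum(axis=0)
    n0 = len(y) - n1
    admissible = (n1 >= config.n_min) & (n0 >= config.n_min)
    if not admissible.any():
        return None
    dec = _all_candidate_decreases(X, y, m)
    dec = np.where(admissible, dec, -np.inf)
    j = int(np.argmax(dec))  # argmax returns the first (lowest) index on ties
    if not dec[j] > config.min_impurity_decrease:
        return None
    yes = X[:, j] == 1
    return SplitCandidate(
        predictor_index=j,
        impurity_decrease=float(dec[j]),
        left_n=int(n1[j]),
        right_n=int(n0[j]),
        left_w=float(w[yes].sum()),
        right_w=float(w[~yes].sum()),
    )


def grow_maximal_tree(cohort: Cohort, outcome: str, config: GrowConfig) -> Tree:
    """Grow the maximal weighted classification tree for one binary outcome.

    Depth-first, yes-branch first; node ids are assigned in visit order so
    the same cohort and config always produce the identical tree.
    """
    if cohort.n == 0:
        raise TreeError("cannot grow a tree on an empty cohort")
    y_all = np.asarray(cohort.outcome(outcome), dtype=float)
    w_all = cohort.weights
    X_all = cohort.predictors.to_numpy(dtype=float)
    names = cohort.predictor_names

    nodes: dict[int, TreeNode] = {}
    counter = iter(range(10**9))

    def build(rows: np.ndarray, depth: int, path: list[tuple[str, str]]) -> int:
        nid = next(counter)
        y, w = y_all[rows], w_all[rows]
        node = TreeNode(
            node_id=nid,
            depth=depth,
            n_unweighted=int(rows.size),
            weighted_n=float(w.sum()),
            weighted_prevalence=weighted_prevalence(y, w),
            unweighted_prevalence=float(y.mean()),
            path_conditions=list(path),
        )
        nodes[nid] = node
        if config.max_depth is not None and depth >= config.max_depth:
            return nid
        sub = pd.DataFrame(X_all[rows], columns=names)
        cand = best_split(sub, y, w, config)
        if cand is None:
            return nid
        name = names[cand.predictor_index]
        yes_rows = rows[X_all[rows, cand.predictor_index] == 1]
        no_rows = rows[X_all[rows, cand.predictor_index] == 0]
        node.split_predictor = name
        node.yes_child = build(yes_rows, depth + 1, path + [(name, "yes")])
        node.no_child = build(no_rows, depth + 1, path + [(name, "no")])
        return nid

    root_id = build(np.arange(cohort.n), 0, [])
    return Tree(
        root_id=root_id,
        nodes=nodes,
        grow_config=config,
        base_rate=nodes[root_id].weighted_prevalence,
        predictor_names=list(names),
    )


def descend(tree: Tree, row) -> TreeNode:
    """Follow yes/no children to the unique terminal for one predictor row.

    ``row`` is a mapping (or pandas Series) from predictor name to 0/1; it
    must provide every predictor the tree actually splits on along the path.
    """
    node = tree.root
    while not node.is_terminal:
        name = node.split_predictor
        try:
            value = row[name]
        except KeyError as exc:
            raise TreeError(f"row is missing required predictor {name!r}") from exc
        node = tree.nodes[node.yes_child if value == 1 else node.no_child]
    return node


def assign_terminals(tree: Tree, cohort: Cohort) -> np.ndarray:
    """Terminal node id for every cohort row (vectorized descent)."""
    out = np.full(cohort.n, tree.root_id, dtype=int)
    stack = [(tree.root_id, np.arange(cohort.n))]
    while stack:
        nid, rows = stack.pop()
        node = tree.nodes[nid]
        if node.is_terminal:
            out[rows] = nid
            continue
        if node.split_predictor not in cohort.predictors.columns:
            raise TreeError(f"cohort is missing required predictor {node.split_predictor!r}")
        x = cohort.predictors[node.split_predictor].to_numpy()[rows]
        stack.append((node.yes_child, rows[x == 1]))
        stack.append((node.no_child, rows[x == 0]))
    return out
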