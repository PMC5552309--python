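"""Risk designation relative to the base rate, and risk-homogeneity pruning.

Every node is labelled by comparing its prevalence with the cohort base
rate: strictly above twice the base rate is *high* risk, strictly below
half the base rate is *low* risk, anything between (boundaries included)
is *moderate*.  The maximal tree is then pruned bottom-up: any subtree in
which every node — internal nodes included — carries the same risk label
adds no differentiation in risk and is collapsed to a single terminal.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

from .tree import Tree, TreeNode

HIGH = "high"
MODERATE = "moderate"
LOW = "low"
RISK_LEVELS = (HIGH, MODERATE, LOW)


class RiskError(ValueError):
    pass


@dataclass(frozen=True)
class RiskThresholds:
    """Base rate and the multiplier cut-offs of the three-level designation."""

    base_rate: float
    high_multiplier: float = 2.0
    low_multiplier: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.base_rate < 1:
            raise RiskError("base_rate must lie in (0, 1)")
        if not 0 < self.low_multiplier < self.high_multiplier:
            raise RiskError("need 0 < low_multiplier < high_multiplier")
        if self.base_rate * self.high_multiplier > 1:
            raise RiskError("high cut-off exceeds 1; thresholds infeasible")

    @property
    def high_cutoff(self) -> float:
        return self.high_multiplier * self.base_rate

    @property
    def low_cutoff(self) -> float:
        return self.low_multiplier * self.base_rate


def designate_risk(node_prevalence: float, thresholds: RiskThresholds) -> str:
    """Three-level designation with strict boundaries.

    A prevalence exactly at a cut-off is moderate: the designation requires
    *greater than* twice, or *less than* half, the base rate.
    """
    if node_prevalence > thresholds.high_cutoff:
        return HIGH
    if node_prevalence < thresholds.low_cutoff:
        return LOW
    return MODERATE


def annotate_tree(tree: Tree, thresholds: RiskThresholds) -> Tree:
    """Return a copy with every node labelled from its weighted prevalence."""
    out = copy.deepcopy(tree)
    for node in out.nodes.values():
        node.risk_level = designate_risk(node.weighted_prevalence, thresholds)
    return out


def prune_by_risk_homogeneity(tree: Tree) -> Tree:
    """Collapse every risk-homogeneous subtree to its parent node.

    Post-order: an internal node whose entire subtree (itself and all
    descendants) shares one risk level becomes a terminal with its own
    pooled counts and prevalence — those are already the pooled values of
    its former leaves, so nothing is recomputed and totals are conserved.
    The result contains no internal node with a homogeneous subtree, and
    each pruned terminal is a union of original terminals.
    """
    out = copy.deepcopy(tree)

    def homogeneous(node: TreeNode) -> bool:
        """True iff the subtree at node shares node's risk level throughout."""
        if node.risk_level is None:
            raise RiskError(f"node {node.node_id} is not risk-annotated")
        if node.is_terminal:
            return True
        same = True
        for child in out.children(node):
            same &= homogeneous(child) and child.risk_level == node.risk_level
        if same:
            for cid in out.subtree_ids(node.node_id):
                if cid != node.node_id:
                    del out.nodes[cid]
            node.split_predictor = None
            node.yes_child = None
            node.no_child = None
        return same

    homogeneous(out.root)
    return out


def count_terminals_by_risk(tree: Tree) -> dict[str, int]:
    """Terminal counts per risk level; values sum to the number of leaves."""
    counts = {level: 0 for level in RISK_LEVELS}
    for node in tree.terminals():
        if node.risk_level is None:
            raise RiskError(f"terminal {node.node_id} is not risk-annotated")
        counts[node.risk_level] += 1
    return counts
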