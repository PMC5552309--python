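"""Independent brute-force reference implementations used as test oracles.

Deliberately naive: pure-Python loops and explicit sums, sharing no code
with the package. The reference partitioner mirrors the documented
contract — Gini decrease computed with survey weights, both children at
least n_min unweighted individuals, strict positive decrease, ties to the
lowest predictor index — via a completely separate code path.
"""

from __future__ import annotations


def ref_weighted_prevalence(y, w):
    num = 0.0
    den = 0.0
    for yi, wi in zip(y, w):
        num += wi * yi
        den += wi
    return num / den


def ref_gini(y, w):
    p = ref_weighted_prevalence(y, w)
    return 2.0 * p * (1.0 - p)


def ref_split_decrease(x, y, w):
    """Gini decrease of partitioning rows by x == 1 vs x == 0."""
    yl, wl, yr, wr = [], [], [], []
    for xi, yi, wi in zip(x, y, w):
        if xi == 1:
            yl.append(yi)
            wl.append(wi)
        else:
            yr.append(yi)
            wr.append(wi)
    if not yl or not yr:
        return 0.0, len(yl), len(yr)
    tot = sum(w)
    dec = (
        ref_gini(y, w)
        - (sum(wl) / tot) * ref_gini(yl, wl)
        - (sum(wr) / tot) * ref_gini(yr, wr)
    )
    return max(dec, 0.0), len(yl), len(yr)


def ref_best_split(X_cols, y, w, n_min):
    """(index, decrease) of the best admissible split, or None."""
    best = None
    for j, x in enumerate(X_cols):
        dec, nl, nr = ref_split_decrease(x, y, w)
        if nl < n_min or nr < n_min:
            continue
        if dec <= 0.0:
            continue
        if best is None or dec > best[1] + 1e-15:
            best = (j, dec)
    return best


def ref_grow(X_cols, y, w, n_min, names):
    """Nested-dict maximal tree: {'n', 'prev', 'split', 'yes', 'no'}."""
    node = {
        "n": len(y),
        "prev": ref_weighted_prevalence(y, w),
        "split": None,
        "yes": None,
        "no": None,
    }
    best = ref_best_split(X_cols, y, w, n_min)
    if best is None:
        return node
    j = best[0]
    yes_rows = [i for i in range(len(y)) if X_cols[j][i] == 1]
    no_rows = [i for i in range(len(y)) if X_cols[j][i] == 0]

    def take(rows):
        sub_X = [[col[i] for i in rows] for col in X_cols]
        sub_y = [y[i] for i in rows]
        sub_w = [w[i] for i in rows]
        return sub_X, sub_y, sub_w

    node["split"] = names[j]
    node["yes"] = ref_grow(*take(yes_rows), n_min, names)
    node["no"] = ref_grow(*take(no_rows), n_min, names)
    return node


def trees_equal(ref_node, tree, node_id, tol=1e-9):
    """Walk the reference dict and the package Tree in lockstep."""
    node = tree.nodes[node_id]
    if ref_node["n"] != node.n_unweighted:
        return False
    if abs(ref_node["prev"] - node.weighted_prevalence) > tol:
        return False
    if ref_node["split"] != node.split_predictor:
        return False
    if ref_node["split"] is None:
        return True
    return trees_equal(ref_node["yes"], tree, node.yes_child, tol) and trees_equal(
        ref_node["no"], tree, node.no_child, tol
    )
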