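"""Independent brute-force oracles used across test modules.

Each oracle recomputes a statistic by a different algorithm than the
implementation under test: explicit node counting over leaf sets for the
genealogical sorting index, dense grid search over the rotation angle for
the two-configuration Procrustes fit, and direct enumeration of label
assignments for the permutation tests.
"""

from __future__ import annotations

import itertools

import numpy as np


def gsi_node_count_oracle(tree, group: set[str]) -> float:
    """Genealogical sorting index by explicit node counting.

    Characterizes the uniting set through leaf sets: the group MRCA is the
    node with the smallest leaf set containing every group tip, and the
    uniting nodes are the internal nodes at or below the MRCA whose leaf
    set intersects the group.  gs = (k-1)/sum(d-1) over those nodes, with
    d the child count; min-max normalized against the all-internal-nodes
    denominator.
    """
    internal = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    leafsets = {}
    for node in internal:
        leafsets[id(node)] = {l.taxon.label for l in node.leaf_iter()}
    containing = [n for n in internal if group <= leafsets[id(n)]]
    mrca = min(containing, key=lambda n: len(leafsets[id(n)]))
    below = [mrca] + [
        n
        for n in mrca.preorder_iter()
        if not n.is_leaf() and n is not mrca and leafsets[id(n)] & group
    ]
    denom_obs = sum(len(n.child_nodes()) - 1 for n in below)
    denom_max = sum(len(n.child_nodes()) - 1 for n in internal)
    k = len(group)
    gs = (k - 1) / denom_obs
    gs_min = (k - 1) / denom_max
    if gs_min >= 1.0:
        return 1.0
    return (gs - gs_min) / (1.0 - gs_min)


def procrustes_distance_grid(a: np.ndarray, b: np.ndarray, n_theta: int = 200_000) -> float:
    """Two-configuration Procrustes distance by dense rotation search.

    Both configurations centered and scaled to unit centroid size, then
    the rotation angle minimized over a dense grid (2-D rotations are a
    one-parameter family, so a grid is an exhaustive oracle up to its
    resolution).
    """

    def norm(x):
        x = x - x.mean(axis=0)
        return x / np.sqrt((x**2).sum())

    a, b = norm(np.asarray(a, float)), norm(np.asarray(b, float))
    thetas = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
    cos, sin = np.cos(thetas), np.sin(thetas)
    # || a - b R(theta) ||^2 = 2 - 2 * (c1 cos + c2 sin)
    c1 = float((a * b).sum())
    c2 = float((a[:, 0] * -b[:, 1] + a[:, 1] * b[:, 0]).sum())
    obj = 2.0 - 2.0 * (c1 * cos + c2 * sin)
    return float(np.sqrt(max(obj.min(), 0.0)))


def exhaustive_two_group_pvalue(statistic, items: int, n_a: int, observed: float) -> float:
    """Exact permutation p-value by enumerating every size-preserving
    assignment of ``items`` observations into groups of ``n_a`` and the rest.

    ``statistic(mask)`` maps a boolean group-A mask to the test statistic.
    """
    hits = 0
    total = 0
    for combo in itertools.combinations(range(items), n_a):
        mask = np.zeros(items, dtype=bool)
        mask[list(combo)] = True
        total += 1
        if statistic(mask) >= observed - 1e-12:
            hits += 1
    return hits / total


def permanova_pseudo_f(x: np.ndarray, mask_a: np.ndarray) -> float:
    """Pseudo-F from first principles: explicit group mean squares of
    Euclidean distances (textbook two-group form)."""
    n = len(x)
    d2 = ((x[:, None, :] - x[None, :, :]) ** 2).sum(-1)
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for mask in (mask_a, ~mask_a):
        idx = np.flatnonzero(mask)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_among = ss_total - ss_within
    if ss_within == 0:
        return np.inf
    return (ss_among / 1) / (ss_within / (n - 2))
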