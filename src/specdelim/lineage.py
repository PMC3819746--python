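"""Genealogical evidence: haplotypes, gene trees, and exclusive ancestry.

The genealogical sorting index (gsi) quantifies the degree of exclusive
ancestry of a labeled group on a rooted gene tree.  Walking from each
group member toward the root, the set of "uniting" nodes is the smallest
set of internal nodes whose union of descendants contains every group
member — the internal nodes of the subtree spanning the group through its
most recent common ancestor.  With ``d(u)`` the number of child branches
of node ``u``::

    gs      = n_min / sum_u (d(u) - 1)        over uniting nodes u
    gsi     = (gs - gs_min) / (1 - gs_min)

where ``n_min = k - 1`` is the denominator value attained when the k
group members form a clade and ``gs_min`` is the value when every
internal node of the tree is required.  The index is 1 exactly at
monophyly, 0 at maximal dispersal, depends only on topology (never on
branch lengths), and handles polytomies through the node degrees.
Significance comes from permuting group labels across tips; the
multilocus statistic gsiT is the equal-weight mean of per-locus values,
with a joint permutation (one relabeling of individuals applied to all
loci) for its p-value.

The module also collapses identical sequences into haplotypes, builds
neighbor-joining trees from p-distances with pairwise deletion of
gap/ambiguous sites, and post-processes cluster-count scans with
Evanno's delta-K second-difference statistic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "HaplotypeTable",
    "GsiResult",
    "collapse_haplotypes",
    "allele_count_matrix",
    "nj_tree",
    "gsi",
    "gsi_test",
    "evanno_delta_k",
]


class LineageError(ValueError):
    pass


@dataclass
class HaplotypeTable:
    """Unique sequences with frequencies and the label -> haplotype map."""

    haplotypes: dict[str, str]  # id -> sequence
    assignment: dict[str, str]  # sequence label (individual/allele) -> id
    frequencies: dict[str, int]  # id -> count

    def genotype_codes(self, allele_sep: str = "_a") -> pd.DataFrame:
        """Individual x allele-slot haplotype ids, derived from labels of
        the form ``<individual><allele_sep><j>``."""
        rows: dict[str, dict[str, str]] = {}
        for label, hid in self.assignment.items():
            if allele_sep in label:
                ind, slot = label.rsplit(allele_sep, 1)
            else:
                ind, slot = label, "0"
            rows.setdefault(ind, {})[f"allele_{slot}"] = hid
        return pd.DataFrame.from_dict(rows, orient="index").sort_index()


@dataclass
class GsiResult:
    per_locus: pd.DataFrame  # columns: locus, gsi, p
    gsi_t: float
    p_t: float
    group: str
    n_permutations: int


def collapse_haplotypes(sequences: Mapping[str, str]) -> HaplotypeTable:
    """Collapse identical aligned sequences (case-insensitive) into
    haplotypes.

    Ids ``H1, H2, ...`` are assigned by descending frequency, ties broken
    lexicographically by sequence.  ``N`` and gap characters are literal:
    sequences differing only at an N site are distinct haplotypes.
    """
    if not sequences:
        return HaplotypeTable({}, {}, {})
    lengths = {len(s) for s in sequences.values()}
    if len(lengths) != 1:
        raise LineageError(f"sequences must be aligned (lengths {sorted(lengths)})")
    counts: dict[str, int] = {}
    for seq in sequences.values():
        key = seq.upper()
        counts[key] = counts.get(key, 0) + 1
    ordered = sorted(counts, key=lambda s: (-counts[s], s))
    ids = {seq: f"H{i + 1}" for i, seq in enumerate(ordered)}
    return HaplotypeTable(
        haplotypes={ids[s]: s for s in ordered},
        assignment={label: ids[seq.upper()] for label, seq in sequences.items()},
        frequencies={ids[s]: counts[s] for s in ordered},
    )


def allele_count_matrix(
    tables: Mapping[str, HaplotypeTable], allele_sep: str = "_a"
) -> pd.DataFrame:
    """Individuals x (locus, haplotype) allele counts across loci, the
    input DAPC and clustering methods expect."""
    pieces = []
    for locus, table in sorted(tables.items()):
        codes = table.genotype_codes(allele_sep)
        counts = (
            codes.stack()
            .groupby(level=0)
            .value_counts()
            .unstack(fill_value=0)
        )
        counts.columns = [f"{locus}:{h}" for h in counts.columns]
        pieces.append(counts)
    out = pd.concat(pieces, axis=1).fillna(0).astype(int)
    return out.sort_index()


# ---------------------------------------------------------------------------
# neighbor joining


def _pairwise_deletion_distances(
    alignment: Mapping[str, str],
) -> tuple[list[str], np.ndarray]:
    """p-distances ignoring, per pair, sites where either sequence has a
    gap or ambiguous base."""
    labels = sorted(alignment)
    arrays = {}
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) != 1:
        raise LineageError("alignment sequences must have equal length")
    for label in labels:
        arrays[label] = np.frombuffer(alignment[label].upper().encode(), dtype="S1")
    valid = {
        label: np.isin(arrays[label], [b"A", b"C", b"G", b"T"]) for label in labels
    }
    n = len(labels)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        a, b = labels[i], labels[j]
        both = valid[a] & valid[b]
        comparable = int(both.sum())
        if comparable == 0:
            raise LineageError(f"no comparable sites between {a!r} and {b!r}")
        diff = int((arrays[a][both] != arrays[b][both]).sum())
        d[i, j] = d[j, i] = diff / comparable
    return labels, d


def nj_tree(
    alignment: Mapping[str, str], outgroup: str | None = None
) -> dendropy.Tree:
    """Neighbor-joining tree from p-distances with pairwise deletion.

    Returns a dendropy tree; with ``outgroup`` given, the tree is rooted
    on the edge leading to that tip (and is then suitable for gsi).
    """
    if len(alignment) < 3:
        raise LineageError("neighbor joining needs at least 3 sequences")
    from skbio import DistanceMatrix
    from skbio.tree import nj as skbio_nj

    labels, d = _pairwise_deletion_distances(alignment)
    newick = str(skbio_nj(DistanceMatrix(d, ids=labels)))
    tree = dendropy.Tree.get(
        data=newick,
        schema="newick",
        preserve_underscores=True,
        rooting="force-unrooted",
    )
    if outgroup is not None:
        node = tree.find_node_with_taxon_label(outgroup)
        if node is None:
            raise LineageError(f"outgroup {outgroup!r} not found in tree")
        tree.to_outgroup_position(node, update_bipartitions=False)
        tree.is_rooted = True
    return tree


# ---------------------------------------------------------------------------
# genealogical sorting index


def _require_rooted(tree: dendropy.Tree) -> None:
    root = tree.seed_node
    if len(root.child_nodes()) > 2 and not tree.is_rooted:
        raise LineageError(
            "gsi is defined on a rooted gene tree; root the input "
            "(e.g. via an outgroup) before computing it"
        )


def _uniting_nodes(group_leaves) -> set:
    """Internal nodes on the paths from group tips to their MRCA."""
    # ancestors of the first leaf, leaf-to-root order
    first_path = []
    node = group_leaves[0].parent_node
    while node is not None:
        first_path.append(node)
        node = node.parent_node
    rank = {id(n): i for i, n in enumerate(first_path)}
    mrca_rank = 0
    visited: set[int] = set()
    nodes = []
    for leaf in group_leaves[1:]:
        node = leaf.parent_node
        while id(node) not in rank:
            if id(node) not in visited:
                visited.add(id(node))
                nodes.append(node)
            node = node.parent_node
        mrca_rank = max(mrca_rank, rank[id(node)])
    nodes.extend(first_path[: mrca_rank + 1])
    return nodes


def gsi(tree: dendropy.Tree, group: Iterable[str]) -> float:
    """Genealogical sorting index of ``group`` (tip labels) on a rooted tree.

    1.0 exactly iff the group is monophyletic; 0 when the group is
    maximally dispersed; branch lengths are ignored.
    """
    group = set(group)
    if len(group) < 2:
        raise LineageError("gsi needs a group of at least 2 tips")
    _require_rooted(tree)
    leaves = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}
    missing = group - set(leaves)
    if missing:
        raise LineageError(f"group tips absent from tree: {sorted(missing)}")
    if len(group) >= len(leaves):
        raise LineageError("group must be a proper subset of the tips")

    group_leaves = [leaves[label] for label in sorted(group)]
    uniting = _uniting_nodes(group_leaves)
    denom_obs = sum(len(u.child_nodes()) - 1 for u in uniting)
    denom_max = sum(
        len(v.child_nodes()) - 1
        for v in tree.preorder_node_iter()
        if not v.is_leaf()
    )
    n_min = len(group) - 1
    gs = n_min / denom_obs
    gs_min = n_min / denom_max
    if gs_min >= 1.0:
        return 1.0  # degenerate: a single internal node (star tree)
    return (gs - gs_min) / (1.0 - gs_min)


def _individual_of(label: str, allele_sep: str = "_a") -> str:
    return label.rsplit(allele_sep, 1)[0] if allele_sep in label else label


def _group_tips_on_tree(tree: dendropy.Tree, group: set[str], allele_sep: str) -> set[str]:
    tips = set()
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label
        if label in group or _individual_of(label, allele_sep) in group:
            tips.add(label)
    return tips


def gsi_test(
    trees: Sequence[dendropy.Tree] | dendropy.Tree,
    group: Iterable[str],
    n_permutations: int = 10_000,
    seed: int | None = None,
    method: str = "monte-carlo",
    allele_sep: str = "_a",
    group_label: str = "",
) -> GsiResult:
    """Permutation test of exclusive ancestry, per locus and combined.

    ``group`` may name tips directly or individuals (tips
    ``<individual>_a<j>`` are matched by prefix).  Per locus the p-value
    is the proportion of label permutations with gsi at least the
    observed value (+1 convention); gsiT is the equal-weight mean of
    per-locus observed values and its permutations relabel individuals
    once per replicate, jointly across loci.  ``method="exact"``
    enumerates all distinct individual subsets (small cases only; exact
    tail proportion, no +1).
    """
    if isinstance(trees, dendropy.Tree):
        trees = [trees]
    group = set(group)
    rng = np.random.default_rng(seed)

    per_tree_tips = []
    per_tree_individuals = []
    for tree in trees:
        tips = _group_tips_on_tree(tree, group, allele_sep)
        if len(tips) < 2:
            raise LineageError(
                f"group has fewer than 2 tips on tree {tree.label or '?'}"
            )
        per_tree_tips.append(tips)
        per_tree_individuals.append(
            sorted({_individual_of(l.taxon.label, allele_sep) for l in tree.leaf_node_iter()})
        )

    observed = [gsi(tree, tips) for tree, tips in zip(trees, per_tree_tips)]
    gsi_t_obs = float(np.mean(observed))

    all_individuals = sorted(set().union(*map(set, per_tree_individuals)))
    group_individuals = sorted(
        {_individual_of(t, allele_sep) for tips in per_tree_tips for t in tips}
    )
    k_ind = len(group_individuals)

    def replicate_values(chosen: set[str]) -> list[float] | None:
        values = []
        for tree in trees:
            tips = _group_tips_on_tree(tree, chosen, allele_sep)
            if len(tips) < 2 or len(tips) >= sum(1 for _ in tree.leaf_node_iter()):
                return None
            values.append(gsi(tree, tips))
        return values

    if method == "exact":
        combos = list(itertools.combinations(all_individuals, k_ind))
        per_locus_hits = np.zeros(len(trees))
        joint_hits = 0
        used = 0
        for combo in combos:
            values = replicate_values(set(combo))
            if values is None:
                continue
            used += 1
            for i, v in enumerate(values):
                if v >= observed[i] - 1e-12:
                    per_locus_hits[i] += 1
            if np.mean(values) >= gsi_t_obs - 1e-12:
                joint_hits += 1
        if used == 0:
            raise LineageError("no valid permutations")
        p_locus = per_locus_hits / used
        p_t = joint_hits / used
        n_used = used
    else:
        per_locus_hits = np.zeros(len(trees))
        joint_hits = 0
        for _ in range(n_permutations):
            for _retry in range(100):
                chosen = set(rng.choice(all_individuals, size=k_ind, replace=False))
                values = replicate_values(chosen)
                if values is not None:
                    break
            else:
                raise LineageError("could not draw a valid permutation")
            for i, v in enumerate(values):
                if v >= observed[i] - 1e-12:
                    per_locus_hits[i] += 1
            if np.mean(values) >= gsi_t_obs - 1e-12:
                joint_hits += 1
        p_locus = (per_locus_hits + 1) / (n_permutations + 1)
        p_t = (joint_hits + 1) / (n_permutations + 1)
        n_used = n_permutations

    per_locus = pd.DataFrame(
        {
            "locus": [t.label or f"locus{i + 1}" for i, t in enumerate(trees)],
            "gsi": observed,
            "p": p_locus,
        }
    )
    return GsiResult(
        per_locus=per_locus,
        gsi_t=gsi_t_obs,
        p_t=float(p_t),
        group=group_label or ",".join(sorted(group)[:3]),
        n_permutations=n_used,
    )


# ---------------------------------------------------------------------------
# Evanno delta-K


def evanno_delta_k(summary: pd.DataFrame) -> pd.DataFrame:
    """Evanno's second-difference statistic over a cluster-count scan.

    ``summary`` needs columns ``K``, ``run`` (or any run identifier) and
    ``lnP`` (log probability of the data).  For every interior K with both
    neighbors present::

        delta_K = |mean lnP(K+1) - 2 mean lnP(K) + mean lnP(K-1)| / sd(lnP(K))

    where the sd is across runs at K (ddof=1).  An sd of zero raises an
    error; a scan with a single K yields an empty frame with a warning.
    """
    import warnings

    required = {"K", "lnP"}
    if not required <= set(summary.columns):
        raise LineageError(f"summary needs columns {sorted(required)}")
    stats = (
        summary.groupby("K")["lnP"].agg(["mean", "std", "count"]).sort_index()
    )
    ks = stats.index.to_list()
    if len(ks) < 3:
        warnings.warn("need at least 3 consecutive K values for delta-K")
        return pd.DataFrame(columns=["K", "mean_lnP", "sd_lnP", "delta_K"])
    rows = []
    for i, k in enumerate(ks[1:-1], start=1):
        if ks[i - 1] != k - 1 or ks[i + 1] != k + 1:
            continue
        if stats.loc[k, "count"] < 2:
            raise LineageError(f"K={k}: need >= 2 runs for the sd divisor")
        sd = stats.loc[k, "std"]
        if sd == 0 or np.isnan(sd):
            raise LineageError(
                f"K={k}: sd of lnP across runs is zero; delta-K undefined "
                "(division by zero)"
            )
        second = (
            stats.loc[k + 1, "mean"] - 2 * stats.loc[k, "mean"] + stats.loc[k - 1, "mean"]
        )
        rows.append(
            {
                "K": k,
                "mean_lnP": stats.loc[k, "mean"],
                "sd_lnP": sd,
                "delta_K": abs(second) / sd,
            }
        )
    return pd.DataFrame(rows)
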