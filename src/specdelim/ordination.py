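"""Between-group ordination and permutation inference.

Between-group PCA (bgPCA) ordinates the matrix of group means — weighted
by group size — and projects individuals onto those axes; unlike a
discriminant analysis it stays well behaved with more variables than
cases.  The companion variance decomposition reports the fraction of
total variance that lies between groups, with significance from a
group-label randomization test.  PERMANOVA partitions squared Euclidean
distances (by default on the leading bgPCA scores) into among- and
within-group components and tests the pseudo-F statistic by label
permutation.  Benjamini-Hochberg FDR correction, greedy pruning of
collinear variables, and DAPC (PCA reduction followed by linear
discriminant analysis, with the a-score guard against overfitting)
round out the toolbox.

All permutation p-values use the (b+1)/(B+1) convention, so the smallest
attainable value with B randomizations is 1/(B+1).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupedFeatureTable",
    "BgpcaResult",
    "PermanovaResult",
    "DapcResult",
    "prune_correlated",
    "bgpca",
    "permanova",
    "bh_fdr",
    "dapc",
]


class OrdinationError(ValueError):
    pass


@dataclass
class GroupedFeatureTable:
    """Individuals x continuous variables, plus a group label per row."""

    data: pd.DataFrame
    groups: pd.Series

    def __post_init__(self):
        self.groups = self.groups.reindex(self.data.index)
        if self.groups.isna().any():
            missing = list(self.data.index[self.groups.isna()])
            raise OrdinationError(f"rows without a group label: {missing}")
        if self.data.isna().any().any():
            raise OrdinationError("feature table contains missing values")
        if self.data.columns.duplicated().any():
            raise OrdinationError("duplicate column names")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, group_col: str = "group"):
        groups = frame[group_col].astype(str)
        data = frame.drop(columns=[group_col]).astype(float)
        return cls(data=data, groups=groups)

    @classmethod
    def from_measurements(
        cls,
        frame: pd.DataFrame,
        id_col: str,
        group_col: str = "group",
    ):
        """Aggregate repeated measurements (e.g. calls) to individual means."""
        grouped = frame.groupby(id_col)
        data = grouped[[c for c in frame.columns if c not in (id_col, group_col)]].mean()
        groups = grouped[group_col].first().astype(str)
        return cls(data=data, groups=groups)

    @classmethod
    def from_csv(cls, path, sep: str = "\t", group_col: str = "group"):
        frame = pd.read_csv(path, sep=sep, index_col=0)
        return cls.from_frame(frame, group_col=group_col)

    @property
    def n_groups(self) -> int:
        return self.groups.nunique()


@dataclass
class BgpcaResult:
    axes: np.ndarray  # p x n_components
    scores: pd.DataFrame  # individuals x components
    group_means: pd.DataFrame  # groups x variables (centered space)
    between_share: float
    p_randomization: float | None
    n_randomizations: int
    columns: list[str] = field(default_factory=list)


@dataclass
class PermanovaResult:
    pseudo_F: float
    p: float
    n_permutations: int
    n_components_used: int | None = None
    pairwise: pd.DataFrame | None = None


@dataclass
class DapcResult:
    n_pc_retained: int
    n_df_retained: int
    assignment: pd.DataFrame  # individuals x groups, rows sum to 1
    coordinates: pd.DataFrame  # individuals x discriminant functions
    a_score: float | None = None
    a_score_grid: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# variable pruning


def prune_correlated(
    table: GroupedFeatureTable, threshold: float = 0.8
) -> GroupedFeatureTable:
    """Greedy left-to-right pruning of collinear variables.

    A column is dropped if its absolute Pearson correlation with any
    already-retained column exceeds ``threshold``; constant columns are
    dropped with a warning (their correlation is undefined).  Deterministic
    given the column order.
    """
    if table.data.shape[1] < 2:
        raise OrdinationError("pruning needs at least 2 variables")
    kept: list[str] = []
    values = table.data
    for col in values.columns:
        x = values[col].to_numpy()
        if np.std(x) == 0:
            warnings.warn(f"column {col!r} is constant; dropped")
            continue
        ok = True
        for other in kept:
            r = np.corrcoef(x, values[other].to_numpy())[0, 1]
            if abs(r) > threshold:
                ok = False
                break
        if ok:
            kept.append(col)
    return GroupedFeatureTable(data=values[kept].copy(), groups=table.groups.copy())


# ---------------------------------------------------------------------------
# between-group PCA


def _between_share(x: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """Size-weighted between-group sum of squares over total, x centered."""
    total = float((x**2).sum())
    if total == 0:
        return 0.0
    between = 0.0
    for g in range(n_groups):
        rows = x[codes == g]
        if len(rows):
            m = rows.mean(axis=0)
            between += len(rows) * float((m**2).sum())
    return between / total


def bgpca(
    table: GroupedFeatureTable,
    n_randomizations: int = 999,
    seed: int | None = None,
    standardize: bool = True,
) -> BgpcaResult:
    """Between-group principal component analysis with a randomization test.

    Variables are centered (and, by default, scaled to unit variance —
    appropriate for heterogeneous units; disable for Procrustes
    coordinates, which are already commensurate).  Principal axes are
    those of the size-weighted group-means matrix; individuals are
    projected onto them.  ``between_share`` is the size-weighted variance
    of group means over the total variance; its null distribution is
    obtained by permuting group labels.
    """
    if table.n_groups < 2:
        raise OrdinationError("bgPCA needs at least 2 groups")
    if table.n_groups > len(table.data):
        raise OrdinationError("more groups than rows")
    x = table.data.to_numpy(dtype=float)
    x = x - x.mean(axis=0)
    if standardize:
        sd = x.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        x = x / sd
    labels, codes = np.unique(table.groups.to_numpy(), return_inverse=True)
    g = len(labels)
    counts = np.bincount(codes, minlength=g).astype(float)
    means = np.vstack([x[codes == i].mean(axis=0) for i in range(g)])

    weighted = means * np.sqrt(counts / counts.sum())[:, None]
    _, svals, vt = np.linalg.svd(weighted, full_matrices=False)
    n_comp = min(g - 1, x.shape[1])
    axes = vt[:n_comp].T  # p x n_comp
    scores = x @ axes

    observed = _between_share(x, codes, g)
    p_rand = None
    if n_randomizations:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_randomizations):
            perm = rng.permutation(codes)
            if _between_share(x, perm, g) >= observed:
                hits += 1
        p_rand = (hits + 1) / (n_randomizations + 1)

    comp_cols = [f"PC{i + 1}" for i in range(n_comp)]
    return BgpcaResult(
        axes=axes,
        scores=pd.DataFrame(scores, index=table.data.index, columns=comp_cols),
        group_means=pd.DataFrame(means, index=labels, columns=table.data.columns),
        between_share=observed,
        p_randomization=p_rand,
        n_randomizations=n_randomizations,
        columns=list(table.data.columns),
    )


# ---------------------------------------------------------------------------
# PERMANOVA


def _ss_partition(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float]:
    """(SS_total, SS_within) from a squared-distance matrix (Gower)."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    return float(ss_total), float(ss_within)


def _permanova_single(
    d2: np.ndarray,
    codes: np.ndarray,
    n_groups: int,
    n_permutations: int,
    rng: np.random.Generator | None,
    method: str,
) -> tuple[float, float]:
    n = d2.shape[0]
    ss_total, ss_within = _ss_partition(d2, codes, n_groups)
    ss_among = ss_total - ss_within
    df_among = n_groups - 1
    df_within = n - n_groups
    if df_within <= 0:
        raise OrdinationError("PERMANOVA needs more observations than groups")
    if ss_within > 0:
        pseudo_f = (ss_among / df_among) / (ss_within / df_within)
    else:
        pseudo_f = np.inf
    # SS_among is a monotone-equivalent statistic (SS_total is permutation
    # invariant), and stays finite when within-group variance is zero.
    if method == "exact":
        masks = _distinct_two_group_masks(codes)
        hits = sum(
            1
            for m in masks
            if ss_total - _ss_partition(d2, m, n_groups)[1] >= ss_among - 1e-12
        )
        p = hits / len(masks)
    else:
        hits = 0
        for _ in range(n_permutations):
            perm = rng.permutation(codes)
            if ss_total - _ss_partition(d2, perm, n_groups)[1] >= ss_among - 1e-12:
                hits += 1
        p = (hits + 1) / (n_permutations + 1)
    return pseudo_f, p


def _distinct_two_group_masks(codes: np.ndarray) -> list[np.ndarray]:
    """All distinct relabelings preserving group sizes (2 groups only)."""
    if len(np.unique(codes)) != 2:
        raise OrdinationError("exact enumeration implemented for 2 groups")
    n = len(codes)
    n_a = int((codes == 0).sum())
    masks = []
    for combo in itertools.combinations(range(n), n_a):
        m = np.ones(n, dtype=int)
        m[list(combo)] = 0
        masks.append(m)
    return masks


def permanova(
    data,
    groups: Sequence[str] | pd.Series,
    n_permutations: int = 999,
    seed: int | None = None,
    pairwise: bool = False,
    is_distance: bool = False,
    n_components: int | None = None,
    method: str = "monte-carlo",
) -> PermanovaResult:
    """Permutational MANOVA on Euclidean distances (or a supplied
    distance matrix).

    ``data`` is either an observations x variables array (for instance
    the first ``n_components`` bgPCA scores) or, with
    ``is_distance=True``, a square distance matrix.  The pseudo-F is the
    among-group mean square over the within-group mean square of the
    partitioned squared distances; the global p-value comes from label
    permutation with the +1 convention (or exhaustive enumeration with
    ``method="exact"``, two groups only).  With ``pairwise=True`` every
    group pair is retested and the raw p-values are FDR-adjusted; pairs
    involving a singleton group are skipped with a warning.
    """
    groups = pd.Series(list(groups))
    x = np.asarray(data, dtype=float)
    if is_distance:
        d2 = x**2
    else:
        if x.ndim != 2:
            raise OrdinationError("data must be 2-D")
        if n_components is not None:
            x = x[:, :n_components]
        diff = x[:, None, :] - x[None, :, :]
        d2 = (diff**2).sum(axis=-1)
    if d2.shape[0] != len(groups):
        raise OrdinationError("group labels do not match observations")
    labels, codes = np.unique(groups.to_numpy(), return_inverse=True)
    rng = np.random.default_rng(seed)
    pseudo_f, p = _permanova_single(
        d2, codes, len(labels), n_permutations, rng, method
    )

    pairwise_table = None
    if pairwise:
        counts = pd.Series(codes).value_counts()
        rows = []
        for a, b in itertools.combinations(range(len(labels)), 2):
            if counts.get(a, 0) < 2 or counts.get(b, 0) < 2:
                warnings.warn(
                    f"pair ({labels[a]}, {labels[b]}): singleton group; skipped"
                )
                continue
            idx = np.flatnonzero((codes == a) | (codes == b))
            sub_codes = (codes[idx] == b).astype(int)
            f_ab, p_ab = _permanova_single(
                d2[np.ix_(idx, idx)], sub_codes, 2, n_permutations, rng, method
            )
            rows.append(
                {
                    "group_1": labels[a],
                    "group_2": labels[b],
                    "pseudo_F": f_ab,
                    "p": p_ab,
                }
            )
        pairwise_table = pd.DataFrame(rows)
        if len(pairwise_table):
            pairwise_table["p_adjusted"] = bh_fdr(pairwise_table["p"].to_numpy())
    return PermanovaResult(
        pseudo_F=pseudo_f,
        p=p,
        n_permutations=n_permutations,
        n_components_used=n_components,
        pairwise=pairwise_table,
    )


# ---------------------------------------------------------------------------
# FDR


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise OrdinationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# DAPC


def _reassignment_proportion(pcs, labels, n_df, seed=None):
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    lda = LinearDiscriminantAnalysis(n_components=n_df)
    z = lda.fit_transform(pcs, labels)
    post = LinearDiscriminantAnalysis().fit(z, labels)
    return float((post.predict(z) == labels).mean())


def dapc(
    matrix,
    groups: Sequence[str] | pd.Series,
    n_pc: int = 6,
    n_df: int = 5,
    optimize_by_a_score: bool = False,
    seed: int | None = None,
    n_a_score_permutations: int = 20,
) -> DapcResult:
    """Discriminant analysis of principal components.

    The data are reduced to ``n_pc`` principal components, then a linear
    discriminant analysis with ``n_df`` discriminant functions is fit on
    the retained components; posterior group memberships come from a
    Gaussian (equal-covariance) classifier in the discriminant space, so
    each individual's memberships sum to 1.  The a-score — observed
    correct-reassignment proportion minus its mean under group-label
    permutation — measures overfitting; with ``optimize_by_a_score`` the
    number of retained components is chosen to maximize it over a grid.
    """
    from sklearn.decomposition import PCA
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    groups = pd.Series(list(groups)).astype(str)
    x = np.asarray(matrix, dtype=float)
    index = (
        matrix.index if isinstance(matrix, pd.DataFrame) else pd.RangeIndex(len(x))
    )
    if groups.nunique() < 2:
        raise OrdinationError("DAPC needs at least 2 groups")
    n, p = x.shape
    labels = groups.to_numpy()
    rng = np.random.default_rng(seed)

    def a_score_for(k: int) -> float:
        pcs_k = PCA(n_components=k, random_state=0).fit_transform(x)
        df_k = min(n_df, k, groups.nunique() - 1)
        observed = _reassignment_proportion(pcs_k, labels, df_k)
        rand = [
            _reassignment_proportion(pcs_k, rng.permutation(labels), df_k)
            for _ in range(n_a_score_permutations)
        ]
        return observed - float(np.mean(rand))

    grid = None
    if optimize_by_a_score:
        candidates = [k for k in range(1, min(n - 1, p) + 1)]
        scored = [(k, a_score_for(k)) for k in candidates]
        grid = pd.DataFrame(scored, columns=["n_pc", "a_score"])
        n_pc = int(grid.loc[grid["a_score"].idxmax(), "n_pc"])

    n_pc = min(n_pc, n - 1, p)
    n_df = min(n_df, n_pc, groups.nunique() - 1)
    pca = PCA(n_components=n_pc, random_state=0)
    pcs = pca.fit_transform(x)
    lda = LinearDiscriminantAnalysis(n_components=n_df)
    z = lda.fit_transform(pcs, labels)
    posterior_model = LinearDiscriminantAnalysis().fit(z, labels)
    proba = posterior_model.predict_proba(z)
    assignment = pd.DataFrame(proba, index=index, columns=posterior_model.classes_)
    coords = pd.DataFrame(
        z, index=index, columns=[f"LD{i + 1}" for i in range(z.shape[1])]
    )
    a_val = a_score_for(n_pc) if optimize_by_a_score else None
    return DapcResult(
        n_pc_retained=n_pc,
        n_df_retained=n_df,
        assignment=assignment,
        coordinates=coords,
        a_score=a_val,
        a_score_grid=grid,
    )
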