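"""Generalized Procrustes analysis of 2-D landmark configurations.

Superimposition removes the nuisance similarity parameters (position,
scale, orientation) from raw landmark coordinates: every configuration is
centered, scaled to unit centroid size, and rotated (proper rotations
only, the morphometric convention) to best fit a consensus that is itself
re-estimated until convergence.  What remains is shape in Kendall's sense;
group differences in mean shape are then tested by permuting specimen
labels within a pair of groups and comparing squared Procrustes distances
between group means.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LandmarkConfiguration",
    "ShapeSet",
    "read_tps",
    "gpa",
    "procrustes_distance",
    "pairwise_mean_shape_test",
]


class TpsParseError(ValueError):
    pass


class ShapeDataError(ValueError):
    pass


@dataclass
class LandmarkConfiguration:
    specimen_id: str
    group: str
    coordinates: np.ndarray  # k x 2

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 2:
            raise ShapeDataError(
                f"{self.specimen_id}: coordinates must be a k x 2 matrix"
            )
        if np.isnan(self.coordinates).any():
            raise ShapeDataError(f"{self.specimen_id}: missing coordinates")


@dataclass
class ShapeSet:
    """Procrustes-aligned configurations with centroid sizes and consensus."""

    aligned: np.ndarray  # n x k x 2
    centroid_sizes: np.ndarray  # n
    mean_shape: np.ndarray  # k x 2
    specimen_ids: list[str]
    groups: pd.Series  # specimen_id -> group
    iterations: int
    converged: bool

    def flattened(self) -> pd.DataFrame:
        """Aligned coordinates as n x 2k variables for ordination."""
        n, k, _ = self.aligned.shape
        cols = [f"{ax}{i + 1}" for i in range(k) for ax in ("x", "y")]
        return pd.DataFrame(
            self.aligned.reshape(n, 2 * k), index=self.specimen_ids, columns=cols
        )


# ---------------------------------------------------------------------------
# TPS input


def read_tps(
    path, group_map: Mapping[str, str] | None = None
) -> list[LandmarkConfiguration]:
    """Parse a TPS-dialect landmark file.

    Records are ``LM=k`` followed by k coordinate lines and an ``ID=...``
    line (``IMAGE=``/``SCALE=`` lines are ignored).  The group label comes
    from ``group_map`` keyed by specimen id, or, failing that, from the id
    prefix before the first underscore.
    """
    configs: list[LandmarkConfiguration] = []
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    i = 0
    record = 0
    while i < len(lines):
        if not lines[i].upper().startswith("LM="):
            raise TpsParseError(f"record {record}: expected LM=, got {lines[i]!r}")
        k = int(lines[i].split("=", 1)[1])
        i += 1
        coords = []
        while i < len(lines) and not ("=" in lines[i]):
            parts = lines[i].split()
            if len(parts) != 2:
                raise TpsParseError(f"record {record}: bad coordinate line {lines[i]!r}")
            coords.append([float(parts[0]), float(parts[1])])
            i += 1
        if len(coords) != k:
            raise TpsParseError(
                f"record {record}: LM={k} but {len(coords)} coordinate lines"
            )
        specimen_id = f"record{record}"
        while i < len(lines) and "=" in lines[i] and not lines[i].upper().startswith("LM="):
            key, value = lines[i].split("=", 1)
            if key.upper() == "ID":
                specimen_id = value.strip()
            i += 1
        if group_map is not None and specimen_id in group_map:
            group = group_map[specimen_id]
        else:
            group = specimen_id.split("_")[0]
        configs.append(LandmarkConfiguration(specimen_id, group, np.array(coords)))
        record += 1
    return configs


# ---------------------------------------------------------------------------
# superimposition


def centroid_size(coords: np.ndarray) -> float:
    centered = coords - coords.mean(axis=0)
    return float(np.sqrt((centered**2).sum()))


def _normalize(coords: np.ndarray, label: str = "") -> tuple[np.ndarray, float]:
    centered = coords - coords.mean(axis=0)
    size = np.sqrt((centered**2).sum())
    if size <= 0:
        raise ShapeDataError(f"degenerate configuration (coincident landmarks): {label}")
    return centered / size, float(size)


def _optimal_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Proper rotation R minimizing ||target - source @ R||_F."""
    u, _, vt = np.linalg.svd(source.T @ target)
    r = u @ vt
    if np.linalg.det(r) < 0:
        u[:, -1] *= -1
        r = u @ vt
    return r


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Procrustes distance between two configurations: both centered and
    scaled to unit centroid size, one rotated (properly) onto the other."""
    a_n, _ = _normalize(np.asarray(a, float), "a")
    b_n, _ = _normalize(np.asarray(b, float), "b")
    r = _optimal_rotation(b_n, a_n)
    return float(np.linalg.norm(a_n - b_n @ r))


def gpa(
    configs: Sequence[LandmarkConfiguration],
    tol: float = 1e-10,
    max_iter: int = 100,
) -> ShapeSet:
    """Generalized Procrustes superimposition (full Procrustes: unit
    centroid size retained throughout).

    Iterates rotation of every configuration to the current consensus and
    re-estimation of the consensus until the consensus moves less than
    ``tol`` (Frobenius norm) or ``max_iter`` is reached.
    """
    if len(configs) < 2:
        raise ShapeDataError("GPA needs at least 2 configurations")
    k = configs[0].coordinates.shape[0]
    if any(c.coordinates.shape[0] != k for c in configs):
        raise ShapeDataError("all configurations must share the landmark count")
    sizes = np.empty(len(configs))
    aligned = np.empty((len(configs), k, 2))
    for i, c in enumerate(configs):
        aligned[i], sizes[i] = _normalize(c.coordinates, c.specimen_id)

    mean = aligned[0].copy()
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        for i in range(len(configs)):
            aligned[i] = aligned[i] @ _optimal_rotation(aligned[i], mean)
        new_mean = aligned.mean(axis=0)
        new_mean, _ = _normalize(new_mean, "consensus")
        if np.linalg.norm(new_mean - mean) < tol:
            mean = new_mean
            converged = True
            break
        mean = new_mean
    # final rotation onto the converged consensus
    for i in range(len(configs)):
        aligned[i] = aligned[i] @ _optimal_rotation(aligned[i], mean)
    mean = aligned.mean(axis=0)

    ids = [c.specimen_id for c in configs]
    groups = pd.Series([c.group for c in configs], index=ids)
    return ShapeSet(
        aligned=aligned,
        centroid_sizes=sizes,
        mean_shape=mean,
        specimen_ids=ids,
        groups=groups,
        iterations=iterations,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# pairwise mean-shape tests


def _mean_shape_stat(aligned: np.ndarray, mask_a: np.ndarray) -> float:
    """Squared Procrustes distance between the two group mean shapes."""
    mean_a = aligned[mask_a].mean(axis=0)
    mean_b = aligned[~mask_a].mean(axis=0)
    return procrustes_distance(mean_a, mean_b) ** 2


def pairwise_mean_shape_test(
    shapes: ShapeSet,
    n_perm: int = 999,
    seed: int | None = None,
    method: str = "monte-carlo",
) -> pd.DataFrame:
    """Permutation tests of mean-shape difference for every group pair.

    The statistic is the squared Procrustes distance between group mean
    shapes computed from the jointly aligned coordinates; the null
    permutes specimen labels within the pair.  With
    ``method="monte-carlo"`` (default) the p-value uses the
    (b+1)/(B+1) convention; with ``method="exact"`` all distinct label
    assignments are enumerated (small pairs only) and p is the exact tail
    proportion.  Groups with fewer than 2 specimens are excluded with a
    warning column in the result.
    """
    import warnings

    rng = np.random.default_rng(seed)
    counts = shapes.groups.value_counts()
    usable = sorted(counts[counts >= 2].index)
    for g in sorted(set(shapes.groups) - set(usable)):
        warnings.warn(f"group {g!r} has <2 specimens; excluded from pairwise tests")
    group_arr = shapes.groups.to_numpy()
    rows = []
    for ga, gb in itertools.combinations(usable, 2):
        idx = np.flatnonzero((group_arr == ga) | (group_arr == gb))
        sub = shapes.aligned[idx]
        mask_a = group_arr[idx] == ga
        n_a = int(mask_a.sum())
        observed = _mean_shape_stat(sub, mask_a)
        if method == "exact":
            combos = list(itertools.combinations(range(len(idx)), n_a))
            hits = 0
            for combo in combos:
                m = np.zeros(len(idx), dtype=bool)
                m[list(combo)] = True
                if _mean_shape_stat(sub, m) >= observed - 1e-12:
                    hits += 1
            p = hits / len(combos)
            b = len(combos)
        else:
            hits = 0
            for _ in range(n_perm):
                m = np.zeros(len(idx), dtype=bool)
                m[rng.choice(len(idx), size=n_a, replace=False)] = True
                if _mean_shape_stat(sub, m) >= observed:
                    hits += 1
            p = (hits + 1) / (n_perm + 1)
            b = n_perm
        rows.append(
            {
                "group_1": ga,
                "group_2": gb,
                "statistic": observed,
                "p": p,
                "n_permutations": b,
            }
        )
    return pd.DataFrame(rows)
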