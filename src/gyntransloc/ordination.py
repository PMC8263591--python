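"""Principal coordinates, permutation PERMANOVA, and correlation/FDR helpers.

PCoA is classical scaling: double-center -D^2/2, eigendecompose, scale
eigenvectors by the square roots of the positive eigenvalues.  Negative
eigenvalues (non-Euclidean input) are reported in the result and their axes
dropped, never silently clipped into coordinates.

PERMANOVA uses the Gower-centered pseudo-F with full-dataset label shuffles
and the add-one permutation p-value, so p is never exactly zero and has
resolution 1/(n_permutations + 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from skbio import DistanceMatrix
from statsmodels.stats.multitest import multipletests

__all__ = [
    "OrdinationResult",
    "PermanovaResult",
    "pcoa",
    "permanova",
    "pearson_with_age",
    "bh_adjust",
]


@dataclass
class OrdinationResult:
    sample_ids: list[str]
    coordinates: np.ndarray  # samples x axes
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives included)
    proportion_explained: np.ndarray  # per retained axis, over positive eigs


@dataclass
class PermanovaResult:
    pseudo_f: float
    p_value: float
    n_permutations: int
    group_sizes: dict[str, int]


def _as_distance(d, ids=None) -> DistanceMatrix:
    if isinstance(d, DistanceMatrix):
        return d
    d = np.asarray(d, dtype=float)
    if ids is None:
        ids = [str(i) for i in range(d.shape[0])]
    return DistanceMatrix(d, ids=list(map(str, ids)))


def pcoa(d, n_axes: int = 2, ids=None) -> OrdinationResult:
    """Classical-scaling principal coordinates of a distance matrix."""
    dm = _as_distance(d, ids)
    if n_axes < 1:
        raise ValueError("n_axes must be >= 1")
    d2 = dm.data ** 2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ d2 @ j
    g = (g + g.T) / 2
    eigvals, eigvecs = np.linalg.eigh(g)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    tol = max(abs(eigvals[0]), 1.0) * 1e-12 if n else 0.0
    pos = eigvals > tol
    n_pos = int(pos.sum())
    k = min(n_axes, n_pos)
    if n_axes > n_pos:
        warnings.warn(
            f"requested {n_axes} axes but only {n_pos} positive eigenvalues; "
            f"returning {k}",
            stacklevel=2,
        )
    coords = eigvecs[:, :k] * np.sqrt(eigvals[:k]) if k else np.zeros((n, 0))
    total_pos = eigvals[pos].sum()
    prop = eigvals[:k] / total_pos if total_pos > 0 else np.zeros(k)
    return OrdinationResult(list(dm.ids), coords, eigvals, prop)


def _group_masks(labels: np.ndarray):
    groups, codes = np.unique(labels, return_inverse=True)
    return groups, codes


def _pseudo_f_many(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> np.ndarray:
    """Pseudo-F for one or many label vectors (codes shape (..., n))."""
    codes = np.atleast_2d(codes)
    n = d2.shape[0]
    ss_total = d2.sum() / (2 * n)
    ssw = np.zeros(codes.shape[0])
    for g in range(n_groups):
        m = (codes == g).astype(np.float64)  # (P, n)
        n_g = m.sum(axis=1)
        within = np.einsum("pi,ij,pj->p", m, d2, m) / 2.0
        ssw += within / n_g
    ssb = ss_total - ssw
    df_b = n_groups - 1
    df_w = n - n_groups
    return (ssb / df_b) / (ssw / df_w)


def permanova(
    d,
    labels,
    n_permutations: int = 999,
    seed: int | None = None,
    ids=None,
) -> PermanovaResult:
    """Permutation PERMANOVA (the adonis-style one-factor test).

    ``labels`` is a sequence of group labels aligned with the distance-matrix
    ids (or a mapping id -> label).  Requires >= 2 groups of >= 2 samples and
    >= 99 permutations.
    """
    dm = _as_distance(d, ids)
    if isinstance(labels, dict):
        labels = [labels[i] for i in dm.ids]
    labels = np.asarray(labels)
    if labels.shape[0] != dm.shape[0]:
        raise ValueError("labels length must match distance matrix size")
    groups, codes = _group_masks(labels)
    if len(groups) < 2:
        raise ValueError("PERMANOVA needs at least 2 groups (constant labels)")
    sizes = {str(g): int((codes == i).sum()) for i, g in enumerate(groups)}
    if min(sizes.values()) < 2:
        small = min(sizes, key=sizes.get)
        raise ValueError(f"group {small!r} has fewer than 2 members")
    if n_permutations < 99:
        raise ValueError("n_permutations must be >= 99")

    d2 = dm.data ** 2
    f_obs = float(_pseudo_f_many(d2, codes, len(groups))[0])
    rng = np.random.default_rng(seed)
    perms = rng.permuted(
        np.tile(codes, (n_permutations, 1)), axis=1
    )
    f_perm = _pseudo_f_many(d2, perms, len(groups))
    p = (1 + int((f_perm >= f_obs).sum())) / (1 + n_permutations)
    return PermanovaResult(f_obs, p, n_permutations, sizes)


def pearson_with_age(values, ages) -> tuple[float, float]:
    """Pearson r between a per-sample quantity and age, with the two-sided
    t-based p-value."""
    x = np.asarray(values, dtype=float)
    y = np.asarray(ages, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("values and ages must be 1-D and paired")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite input")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Pearson r undefined for a constant vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D vector of p-values")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]
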