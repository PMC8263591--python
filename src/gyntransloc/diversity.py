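"""Alpha diversity, Good's coverage, Bray-Curtis and unweighted UniFrac.

Shannon entropy is reported in nats (natural log) throughout.  Unweighted
UniFrac treats a branch as observed for a sample if any descendant tip is
present (count >= 1); the edge above the root belongs to no split of the tip
set and is excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .cohort_io import AbundanceTable, CohortError, PhyloTree, to_relative

__all__ = [
    "DiversityResult",
    "observed_taxa",
    "shannon",
    "chao1",
    "goods_coverage",
    "alpha_diversity_table",
    "bray_curtis",
    "pairwise_bray_curtis",
    "unweighted_unifrac",
    "pairwise_unifrac",
]


@dataclass
class DiversityResult:
    sample_id: str
    shannon: float
    chao1: float
    observed: int
    goods: float


def _as_vector(counts: Iterable[float]) -> np.ndarray:
    x = np.asarray(list(counts) if not isinstance(counts, np.ndarray) else counts,
                   dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D vector of abundances")
    if np.any(x < 0) or not np.all(np.isfinite(x)):
        raise ValueError("abundances must be finite and non-negative")
    return x


def observed_taxa(counts: Iterable[float]) -> int:
    """Number of taxa with abundance >= 1 count (presence threshold 1)."""
    x = _as_vector(counts)
    return int(np.count_nonzero(x >= 1))


def shannon(counts: Iterable[float]) -> float:
    """Shannon entropy H = -sum p_i ln p_i in nats over taxa with p_i > 0."""
    x = _as_vector(counts)
    total = x.sum()
    if total == 0:
        raise ValueError("shannon undefined for an all-zero sample")
    p = x[x > 0] / total
    return float(-(p * np.log(p)).sum())


def _require_integer(x: np.ndarray, what: str) -> np.ndarray:
    if not np.allclose(x, np.round(x), rtol=0, atol=1e-9):
        raise ValueError(f"{what} requires integer counts")
    return np.round(x).astype(np.int64)


def chao1(counts: Iterable[float]) -> float:
    """Chao1 richness: S_obs + F1^2/(2 F2), or the bias-corrected
    S_obs + F1(F1-1)/2 when there are no doubletons."""
    x = _require_integer(_as_vector(counts), "chao1")
    s_obs = int(np.count_nonzero(x))
    f1 = int(np.count_nonzero(x == 1))
    f2 = int(np.count_nonzero(x == 2))
    if f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / 2.0


def goods_coverage(counts: Iterable[float]) -> float:
    """Good's coverage C = 1 - F1/N (F1 singletons, N total reads)."""
    x = _require_integer(_as_vector(counts), "goods_coverage")
    n = int(x.sum())
    if n == 0:
        raise ValueError("goods_coverage undefined for an empty sample")
    f1 = int(np.count_nonzero(x == 1))
    return 1.0 - f1 / n


def alpha_diversity_table(table: AbundanceTable) -> pd.DataFrame:
    """Per-sample Shannon, Chao1, observed richness and Good's coverage.

    Requires counts mode (Chao1 and Good's coverage are count-based).
    """
    if table.mode != "counts":
        raise CohortError("alpha_diversity_table requires counts mode")
    rows = []
    for j, sid in enumerate(table.sample_ids):
        col = table.values[:, j]
        rows.append(
            {
                "sample_id": sid,
                "shannon": shannon(col),
                "chao1": chao1(col),
                "observed": observed_taxa(col),
                "goods": goods_coverage(col),
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


# ---------------------------------------------------------------------------
# beta diversity


def bray_curtis(x: Iterable[float], y: Iterable[float]) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y)."""
    xv, yv = _as_vector(x), _as_vector(y)
    if xv.shape != yv.shape:
        raise ValueError("vectors must have equal length")
    denom = (xv + yv).sum()
    if denom == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero vectors")
    return float(np.abs(xv - yv).sum() / denom)


def pairwise_bray_curtis(
    table: AbundanceTable, use_relative: bool = True
) -> DistanceMatrix:
    """All-pairs Bray-Curtis.  By default counts are normalized per sample
    first (the analysis convention); pass ``use_relative=False`` for raw
    counts."""
    tab = table
    if use_relative and table.mode == "counts":
        tab = to_relative(table)
    vals = tab.values
    sums = vals.sum(axis=0)
    if np.any(sums == 0):
        j = int(np.flatnonzero(sums == 0)[0])
        raise CohortError(f"all-zero sample column: {tab.sample_ids[j]!r}")
    # sum|x-y| = sum(x)+sum(y) - 2*sum(min(x,y)); vectorize via minima
    n = tab.n_samples
    d = np.zeros((n, n))
    for j in range(n):
        mins = np.minimum(vals[:, j][:, None], vals[:, j + 1:]).sum(axis=0)
        num = sums[j] + sums[j + 1:] - 2 * mins
        den = sums[j] + sums[j + 1:]
        d[j, j + 1:] = num / den
    d = d + d.T
    return DistanceMatrix(d, ids=tab.sample_ids)


def _node_arrays(tree: PhyloTree, taxon_ids: Sequence[str]):
    """Branch lengths and per-branch tip membership (bool over taxon_ids),
    one row per non-root node in postorder."""
    pos = {t: i for i, t in enumerate(taxon_ids)}
    lengths: list[float] = []
    members: list[np.ndarray] = []
    memo: dict[int, np.ndarray] = {}
    for node in tree.tree.postorder(include_self=True):
        if node.is_tip():
            m = np.zeros(len(taxon_ids), dtype=bool)
            if node.name in pos:
                m[pos[node.name]] = True
        else:
            m = np.zeros(len(taxon_ids), dtype=bool)
            for child in node.children:
                m |= memo[id(child)]
        memo[id(node)] = m
        if node is not tree.tree:  # the root edge belongs to no split
            lengths.append(float(node.length))
            members.append(m)
    return np.array(lengths), np.array(members)


def unweighted_unifrac(
    presence_x: Iterable[str], presence_y: Iterable[str], tree: PhyloTree
) -> float:
    """Unweighted UniFrac between two presence sets of taxon ids.

    (branch length unique to one side's observed subtree) / (branch length of
    the union subtree)."""
    tips = set(tree.tip_names)
    sx, sy = set(presence_x), set(presence_y)
    for s in (sx, sy):
        missing = s - tips
        if missing:
            raise CohortError(f"taxa not on tree: {sorted(missing)}")
    if not sx or not sy:
        raise CohortError("each sample must have at least one present taxon")
    taxa = sorted(sx | sy)
    lengths, members = _node_arrays(tree, taxa)
    px = np.array([t in sx for t in taxa])
    py = np.array([t in sy for t in taxa])
    in_x = members @ px > 0
    in_y = members @ py > 0
    union = lengths[in_x | in_y].sum()
    unique = lengths[in_x ^ in_y].sum()
    if union == 0:
        return 0.0
    return float(unique / union)


def pairwise_unifrac(
    table: AbundanceTable, tree: PhyloTree, presence_threshold: float = 1.0
) -> DistanceMatrix:
    """All-pairs unweighted UniFrac over table samples.

    Presence = abundance >= ``presence_threshold`` (default one count; for
    relative-mode tables pass a suitable fraction or use > 0 via a tiny
    threshold)."""
    tips = set(tree.tip_names)
    missing = [t for t in table.taxon_ids if t not in tips]
    if missing:
        raise CohortError(f"taxa not on tree: {missing[:10]}")
    lengths, members = _node_arrays(tree, table.taxon_ids)
    presence = table.values >= presence_threshold  # taxa x samples
    if np.any(~presence.any(axis=0)):
        j = int(np.flatnonzero(~presence.any(axis=0))[0])
        raise CohortError(
            f"sample {table.sample_ids[j]!r} has no present taxon at this threshold"
        )
    # branch observed per sample: any member tip present
    obs = (members.astype(np.float64) @ presence.astype(np.float64)) > 0
    w = obs.astype(np.float64) * lengths[:, None]  # length-weighted flags
    per_sample = w.sum(axis=0)
    both = w.T @ obs.astype(np.float64)  # shared branch length, pairwise
    union = per_sample[:, None] + per_sample[None, :] - both
    unique = union - both
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(union > 0, unique / union, 0.0)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2  # enforce exact symmetry against fp noise
    return DistanceMatrix(d, ids=table.sample_ids)
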