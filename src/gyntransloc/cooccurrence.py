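"""Compositional (SparCC-style) co-occurrence between uterine and vaginal taxa.

Relative abundances are compositions, so naive correlations are confounded by
the constant-sum constraint.  The SparCC estimator works from log-ratio
variances t_ij = var(log(x_i/x_j)) across subjects: under a sparsity
assumption (most pairs uncorrelated) the basis variances w_i solve a linear
system in the row sums of t, and the correlation follows as

    r_ij = (w_i + w_j - t_ij) / (2 sqrt(w_i w_j)).

The strongest pair is then iteratively excluded from the system and the
basis re-solved, for a fixed number of rounds.

Cross-site correlation is realized by concatenating each subject's uterine
and vaginal taxon vectors into one site-namespaced composition, so the
compositional treatment stays coherent across body sites; only the
uterus x vagina block is reported by default.

Two fraction conventions are provided.  The deterministic estimator
(``n_inner_iterations=1``) normalizes each subject to fractions and applies a
fixed zero-replacement fraction, which makes the estimate exactly invariant
to per-subject scalar rescaling (the defining property of log-ratio methods).
The resampling mode (``n_inner_iterations>1``) draws fractions from
Dirichlet(counts + pseudocount) per subject and takes the median across
draws; it is depth-aware and therefore only asymptotically scale-invariant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import AbundanceTable, CohortError, SampleRecord

__all__ = [
    "CrossSiteCorrelation",
    "sparcc_correlation",
    "spearman_correlation",
    "bootstrap_pvalues",
    "sign_conservation",
    "strong_pairs",
    "paired_joint_table",
    "cross_site_block",
]

#: zero-replacement fraction for the deterministic estimator
ZERO_REPLACEMENT = 1e-6
#: SparCC-convention pseudocount for the Dirichlet resampling mode
PSEUDOCOUNT = 1.0
#: correlation magnitude below which pairs are not excluded
EXCLUSION_THRESHOLD = 0.1


@dataclass
class CrossSiteCorrelation:
    taxon: str
    rho_healthy: float
    rho_disease: float
    p_healthy: float
    p_disease: float
    sign_conserved: bool
    strong: bool


def _as_matrix(table) -> tuple[np.ndarray, list[str]]:
    """Return (taxa x subjects) float matrix plus taxon ids."""
    if isinstance(table, AbundanceTable):
        return table.values, list(table.taxon_ids)
    if isinstance(table, pd.DataFrame):
        return table.to_numpy(dtype=float), list(map(str, table.index))
    x = np.asarray(table, dtype=float)
    return x, [str(i) for i in range(x.shape[0])]


def _basis_correlation(
    frac: np.ndarray,
    n_exclusion_rounds: int,
    exclusion_threshold: float,
) -> np.ndarray:
    """One SparCC estimate from a (subjects x taxa) fraction matrix."""
    log_f = np.log(frac)
    cov = np.cov(log_f, rowvar=False, ddof=1)
    var = np.diag(cov)
    t = var[:, None] + var[None, :] - 2 * cov  # log-ratio variances
    n = t.shape[0]

    include = np.ones((n, n), dtype=bool)
    np.fill_diagonal(include, False)

    def solve_basis() -> np.ndarray:
        deg = include.sum(axis=1).astype(float)
        a = include.astype(float)
        np.fill_diagonal(a, deg)
        rhs = (t * include).sum(axis=1)
        try:
            w = np.linalg.solve(a, rhs)
        except np.linalg.LinAlgError:
            w, *_ = np.linalg.lstsq(a, rhs, rcond=None)
        return np.maximum(w, 1e-12)

    w = solve_basis()

    def corr_from(w: np.ndarray) -> np.ndarray:
        denom = 2 * np.sqrt(np.outer(w, w))
        r = (w[:, None] + w[None, :] - t) / denom
        r = np.clip(r, -1.0, 1.0)
        np.fill_diagonal(r, 1.0)
        return (r + r.T) / 2

    r = corr_from(w)
    for _ in range(n_exclusion_rounds):
        masked = np.where(include, np.abs(r), -1.0)
        i, j = np.unravel_index(int(np.argmax(masked)), masked.shape)
        if masked[i, j] <= exclusion_threshold:
            break
        include[i, j] = include[j, i] = False
        if include.sum(axis=1).min() < 2:  # system would degenerate
            include[i, j] = include[j, i] = True
            break
        w = solve_basis()
        r = corr_from(w)
    return r


def sparcc_correlation(
    table,
    n_inner_iterations: int = 20,
    n_exclusion_rounds: int = 10,
    exclusion_threshold: float = EXCLUSION_THRESHOLD,
    pseudocount: float = PSEUDOCOUNT,
    zero_replacement: float = ZERO_REPLACEMENT,
    seed: int | None = None,
) -> pd.DataFrame:
    """SparCC correlation matrix over the rows of a taxa x subjects table.

    Subjects are the observations.  Fewer than 5 subjects is an error; fewer
    than 25 draws a warning (the estimator is unstable at small n).
    """
    x, taxa = _as_matrix(table)
    n_taxa, n_subj = x.shape
    if n_taxa < 2:
        raise CohortError("need at least 2 taxa")
    if n_subj < 5:
        raise CohortError(f"SparCC needs at least 5 subjects, got {n_subj}")
    if n_subj < 25:
        warnings.warn(
            f"SparCC estimate from only {n_subj} subjects is unstable",
            stacklevel=2,
        )
    if np.any(x.sum(axis=0) <= 0):
        raise CohortError("every subject needs a positive total")

    xt = x.T  # subjects x taxa
    if n_inner_iterations <= 1:
        frac = xt / xt.sum(axis=1, keepdims=True)
        frac = (frac + zero_replacement) / (1 + n_taxa * zero_replacement)
        r = _basis_correlation(frac, n_exclusion_rounds, exclusion_threshold)
    else:
        rng = np.random.default_rng(seed)
        draws = np.empty((n_inner_iterations, n_taxa, n_taxa))
        alpha = xt + pseudocount
        for it in range(n_inner_iterations):
            frac = np.vstack([rng.dirichlet(alpha[s]) for s in range(n_subj)])
            frac = np.maximum(frac, 1e-12)
            frac /= frac.sum(axis=1, keepdims=True)
            draws[it] = _basis_correlation(
                frac, n_exclusion_rounds, exclusion_threshold
            )
        r = np.median(draws, axis=0)
        r = np.clip((r + r.T) / 2, -1.0, 1.0)
        np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=taxa, columns=taxa)


def spearman_correlation(table) -> pd.DataFrame:
    """Plain Spearman rank correlation between taxa (cross-check estimator)."""
    x, taxa = _as_matrix(table)
    r = stats.spearmanr(x.T).statistic
    r = np.atleast_2d(r)
    return pd.DataFrame(r, index=taxa, columns=taxa)


def bootstrap_pvalues(
    table,
    observed: pd.DataFrame | np.ndarray,
    n_boot: int = 100,
    seed: int | None = None,
    method: str = "sparcc",
    **sparcc_kwargs,
) -> pd.DataFrame:
    """Permutation-bootstrap p-values for pairwise correlations.

    Each replicate independently shuffles every taxon's values across
    subjects (destroying all pairwise association while keeping marginals),
    recomputes the correlation matrix, and the add-one two-sided p is the
    rank of |r_obs| among the |r_boot|.
    """
    if n_boot < 20:
        raise CohortError("n_boot must be >= 20")
    x, taxa = _as_matrix(table)
    obs = observed.to_numpy() if isinstance(observed, pd.DataFrame) else np.asarray(observed)
    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(obs, dtype=np.int64)
    for _ in range(n_boot):
        shuffled = np.vstack([rng.permutation(row) for row in x])
        if method == "sparcc":
            rb = sparcc_correlation(
                shuffled,
                seed=int(rng.integers(2**31)),
                **sparcc_kwargs,
            ).to_numpy()
        else:
            rb = spearman_correlation(shuffled).to_numpy()
        exceed += np.abs(rb) >= np.abs(obs)
    p = (1 + exceed) / (1 + n_boot)
    np.fill_diagonal(p, np.nan)
    return pd.DataFrame(p, index=taxa, columns=taxa)


def sign_conservation(
    corr_healthy,
    corr_disease,
    pairs: list[tuple] | None = None,
):
    """Count pairs whose correlation keeps its sign across health states.

    Returns ``(n_same_sign, n_total, flags)`` where flags is a per-pair record
    ('same', 'discordant' or 'zero'); the three categories partition n_total.
    By default all off-diagonal upper-triangle entries of square inputs are
    compared; for cross-site per-taxon use, pass 1-D aligned vectors or an
    explicit pair list.
    """
    ch = corr_healthy.to_numpy() if isinstance(corr_healthy, pd.DataFrame) else np.asarray(corr_healthy, dtype=float)
    cd = corr_disease.to_numpy() if isinstance(corr_disease, pd.DataFrame) else np.asarray(corr_disease, dtype=float)
    if ch.shape != cd.shape:
        raise CohortError("correlation inputs must have matching shapes")
    if pairs is not None:
        try:
            h = np.array([ch[i] if np.ndim(i) == 0 and ch.ndim == 1 else ch[tuple(i)] for i in pairs], dtype=float)
            d = np.array([cd[i] if np.ndim(i) == 0 and cd.ndim == 1 else cd[tuple(i)] for i in pairs], dtype=float)
        except (IndexError, KeyError) as exc:
            raise CohortError(f"pair missing from correlation input: {exc}") from exc
    elif ch.ndim == 1:
        h, d = ch, cd
    else:
        iu = np.triu_indices(ch.shape[0], k=1)
        h, d = ch[iu], cd[iu]
    sh, sd = np.sign(h), np.sign(d)
    same = (sh == sd) & (sh != 0)
    zero = (sh == 0) | (sd == 0)
    flags = np.where(same, "same", np.where(zero, "zero", "discordant"))
    return int(same.sum()), int(h.size), flags


def strong_pairs(corr: pd.DataFrame, threshold: float = 0.4):
    """Pairs with |rho| strictly above ``threshold``, sorted by |rho|
    descending, ties broken lexicographically by (row id, column id)."""
    if not (0 <= threshold < 1):
        raise CohortError("threshold must lie in [0, 1)")
    rows = list(map(str, corr.index))
    cols = list(map(str, corr.columns))
    square = rows == cols
    out = []
    vals = corr.to_numpy()
    for i, rid in enumerate(rows):
        for j, cid in enumerate(cols):
            if square and j <= i:
                continue
            rho = float(vals[i, j])
            if np.isfinite(rho) and abs(rho) > threshold:
                out.append((rid, cid, rho))
    out.sort(key=lambda rec: (-abs(rec[2]), rec[0], rec[1]))
    return out


# ---------------------------------------------------------------------------
# cross-site plumbing


def paired_joint_table(
    table: AbundanceTable,
    records: list[SampleRecord],
    group: str | None = None,
) -> pd.DataFrame:
    """Site-namespaced joint composition per subject.

    Rows are ``uterus:<taxon>`` then ``vagina:<taxon>``; columns are subjects
    that have both a uterine and a vaginal sample (optionally restricted to
    one health group).  Values are counts concatenated from the two samples.
    """
    if table.mode != "counts":
        raise CohortError("paired_joint_table requires counts mode")
    by_subject: dict[str, dict[str, str]] = {}
    groups: dict[str, str] = {}
    cols = set(table.sample_ids)
    for r in records:
        if r.sample_id not in cols:
            continue
        by_subject.setdefault(r.subject_id, {})[r.site] = r.sample_id
        groups[r.subject_id] = r.group
    subjects = [
        s for s, sites in sorted(by_subject.items())
        if "uterus" in sites and "vagina" in sites
        and (group is None or groups[s] == group)
    ]
    if not subjects:
        raise CohortError("no subjects with both sites" +
                          (f" in group {group!r}" if group else ""))
    u_cols = [table.sample_index(by_subject[s]["uterus"]) for s in subjects]
    v_cols = [table.sample_index(by_subject[s]["vagina"]) for s in subjects]
    joint = np.vstack([table.values[:, u_cols], table.values[:, v_cols]])
    index = [f"uterus:{t}" for t in table.taxon_ids] + \
            [f"vagina:{t}" for t in table.taxon_ids]
    return pd.DataFrame(joint, index=index, columns=subjects)


def cross_site_block(corr: pd.DataFrame) -> pd.DataFrame:
    """Extract the uterus x vagina block of a namespaced joint correlation
    matrix, with the site prefixes stripped."""
    u = [i for i in corr.index if str(i).startswith("uterus:")]
    v = [i for i in corr.columns if str(i).startswith("vagina:")]
    block = corr.loc[u, v].copy()
    block.index = [str(i).split(":", 1)[1] for i in u]
    block.columns = [str(i).split(":", 1)[1] for i in v]
    return block
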