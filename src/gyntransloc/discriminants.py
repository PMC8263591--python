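"""Discriminatory-taxon scoring and cross-site direction-of-change concordance.

``lefse_lite`` is a deliberately simplified two-stage LDA-effect-size screen:
a per-taxon Kruskal-Wallis gate, then a signed log10 effect size from a
one-dimensional linear discriminant fit on bootstrap subsamples of
abundances scaled to 1e6 (the conventional pre-scaling).  There is no
subclass/Wilcoxon stage and no cladogram roll-up: the design here has exactly
two flat groups.

``direction_of_change`` asks, for a set of taxa, whether the disease-minus-
healthy shift in mean relative abundance has the same sign in the uterus and
the vagina, and summarizes the concordant fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cohort_io import AbundanceTable, CohortError

__all__ = [
    "EffectSizeRecord",
    "ConcordanceResult",
    "lefse_lite",
    "direction_of_change",
]

#: LEfSe-convention abundance pre-scaling (per-million)
LEFSE_SCALE = 1e6
#: bootstrap subsample fraction per class
BOOT_FRACTION = 2.0 / 3.0
#: ridge added to the pooled covariance diagonal, as a fraction of its trace
COV_RIDGE = 1e-6


@dataclass
class EffectSizeRecord:
    taxon: str
    kw_p: float
    lda_log10: float  # signed; NaN if the taxon failed stage 1
    enriched_group: str
    passes: bool


@dataclass
class ConcordanceResult:
    taxa: list[str]
    delta_site1: np.ndarray  # disease - healthy mean, first site (uterus)
    delta_site2: np.ndarray  # second site (vagina)
    concordant: np.ndarray  # bool per taxon
    both_zero: np.ndarray  # bool per taxon; excluded from the summary
    n_concordant: int
    n_total: int

    @property
    def fraction(self) -> float:
        return self.n_concordant / self.n_total if self.n_total else float("nan")


def _labels_for(table: AbundanceTable, labels) -> np.ndarray:
    if isinstance(labels, dict):
        missing = [s for s in table.sample_ids if s not in labels]
        if missing:
            raise CohortError(f"labels missing for samples: {missing[:5]}")
        return np.asarray([labels[s] for s in table.sample_ids])
    lab = np.asarray(labels)
    if lab.shape[0] != table.n_samples:
        raise CohortError("labels length must match number of samples")
    return lab


def lefse_lite(
    table: AbundanceTable,
    labels,
    alpha: float = 0.05,
    lda_threshold: float = 3.0,
    n_boot: int = 30,
    seed: int | None = None,
    scale: float = LEFSE_SCALE,
) -> list[EffectSizeRecord]:
    """Two-stage discriminatory-taxon screen on a relative-abundance table.

    Stage 1: Kruskal-Wallis per taxon at ``alpha``.  Stage 2: survivors get an
    effect size, the bootstrap mean of the discriminant-projected class-mean
    difference on the per-million scale, reported as signed log10(1 + effect).
    A taxon passes when kw_p < alpha and |lda_log10| > lda_threshold.

    The sign is positive when the taxon is enriched in the alphabetically
    first group.  Samples are re-ordered internally by (group, sample id), so
    the result is invariant to input sample order for a fixed seed.
    """
    if table.mode != "relative":
        raise CohortError("lefse_lite requires a relative-mode table")
    lab = _labels_for(table, labels)
    groups = sorted(set(map(str, lab)))
    if len(groups) != 2:
        raise CohortError(f"lefse_lite requires exactly 2 groups, got {groups}")
    # canonical sample order: group then sample id (order invariance)
    order = sorted(range(table.n_samples),
                   key=lambda j: (str(lab[j]), table.sample_ids[j]))
    x = table.values[:, order].T * scale  # samples x taxa, per-million
    lab = lab[order]
    idx1 = np.flatnonzero(lab == groups[0])
    idx2 = np.flatnonzero(lab == groups[1])
    if len(idx1) < 3 or len(idx2) < 3:
        raise CohortError("each group needs at least 3 samples")

    n_taxa = table.n_taxa
    kw_p = np.ones(n_taxa)
    for t in range(n_taxa):
        a, b = x[idx1, t], x[idx2, t]
        if np.ptp(np.concatenate([a, b])) == 0:
            kw_p[t] = 1.0  # all values tied: no evidence
        else:
            kw_p[t] = stats.kruskal(a, b).pvalue
    survivors = np.flatnonzero(kw_p < alpha)

    mean1 = x[idx1].mean(axis=0)
    mean2 = x[idx2].mean(axis=0)
    enriched = np.where(mean1 >= mean2, groups[0], groups[1])

    lda = np.full(n_taxa, np.nan)
    if survivors.size:
        rng = np.random.default_rng(seed)
        xs = x[:, survivors]
        n1 = max(2, int(round(len(idx1) * BOOT_FRACTION)))
        n2 = max(2, int(round(len(idx2) * BOOT_FRACTION)))
        effects = np.zeros((n_boot, survivors.size))
        for b in range(n_boot):
            s1 = rng.choice(idx1, size=n1, replace=False)
            s2 = rng.choice(idx2, size=n2, replace=False)
            a1, a2 = xs[s1], xs[s2]
            mu1, mu2 = a1.mean(axis=0), a2.mean(axis=0)
            dmu = mu1 - mu2
            sw = ((n1 - 1) * np.cov(a1, rowvar=False, ddof=1)
                  + (n2 - 1) * np.cov(a2, rowvar=False, ddof=1)) / (n1 + n2 - 2)
            sw = np.atleast_2d(sw)
            ridge = COV_RIDGE * max(np.trace(sw), 1.0)
            sw = sw + ridge * np.eye(sw.shape[0])
            w = np.linalg.solve(sw, dmu)
            norm = np.linalg.norm(w)
            u = w / norm if norm > 0 else w
            proj = abs(float(u @ dmu))
            effects[b] = 0.5 * (np.abs(dmu) + np.abs(u) * proj)
        mean_effect = effects.mean(axis=0)
        mag = np.log10(1.0 + mean_effect)
        sign = np.where(enriched[survivors] == groups[0], 1.0, -1.0)
        lda[survivors] = sign * mag

    records = []
    for t, taxon in enumerate(table.taxon_ids):
        passes = bool(kw_p[t] < alpha and np.isfinite(lda[t])
                      and abs(lda[t]) > lda_threshold)
        records.append(
            EffectSizeRecord(taxon, float(kw_p[t]), float(lda[t]),
                             str(enriched[t]), passes)
        )
    return records


def direction_of_change(
    table_u: AbundanceTable,
    table_v: AbundanceTable,
    labels,
    taxa: list[str] | None = None,
    healthy_group: str = "healthy",
    disease_group: str = "endometritis",
) -> ConcordanceResult:
    """Cross-site concordance of disease-associated abundance shifts.

    For each taxon, Delta_site = mean(disease) - mean(healthy) relative
    abundance; a taxon is concordant when the two sites' deltas share a
    nonzero sign.  Taxa with Delta = 0 at both sites are excluded from both
    the numerator and the denominator; a one-sided zero counts as discordant.

    ``labels`` maps sample id -> group for the samples of both tables.
    """
    if table_u.mode != "relative" or table_v.mode != "relative":
        raise CohortError("direction_of_change requires relative-mode tables")
    if taxa is None:
        taxa = [t for t in table_u.taxon_ids if t in set(table_v.taxon_ids)]
    for name, tab in (("uterus", table_u), ("vagina", table_v)):
        missing = [t for t in taxa if t not in set(tab.taxon_ids)]
        if missing:
            raise CohortError(f"taxon {missing[0]!r} missing from the {name} table")

    def site_delta(tab: AbundanceTable) -> np.ndarray:
        lab = np.asarray([labels[s] for s in tab.sample_ids])
        hi = np.flatnonzero(lab == disease_group)
        lo = np.flatnonzero(lab == healthy_group)
        if hi.size == 0 or lo.size == 0:
            raise CohortError(
                f"need both {healthy_group!r} and {disease_group!r} samples"
            )
        pos = {t: i for i, t in enumerate(tab.taxon_ids)}
        rows = [pos[t] for t in taxa]
        vals = tab.values[rows, :]
        return vals[:, hi].mean(axis=1) - vals[:, lo].mean(axis=1)

    du = site_delta(table_u)
    dv = site_delta(table_v)
    su, sv = np.sign(du), np.sign(dv)
    both_zero = (su == 0) & (sv == 0)
    concordant = (su == sv) & (su != 0)
    n_total = int((~both_zero).sum())
    return ConcordanceResult(
        list(taxa), du, dv, concordant, both_zero,
        int(concordant.sum()), n_total,
    )
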