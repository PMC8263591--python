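"""Gibbs-sampling attribution of a sink community to source environments.

Each read of the sink (uterine) sample is assigned a latent source: one of
the known source environments (e.g. the subject's own vaginal sample, a pool
of other women's vaginal samples) or an "Unknown" source whose taxon profile
is learned from the reads currently assigned to it.  The collapsed Gibbs
conditional for read r of taxon t is

    P(z_r = v | .) prop. (m_vt + a_v) / (M_v + T a_v) * (n_v + b) / (n - 1 + V b)

with m_vt the taxon-t count of source v (fixed for known sources, dynamic
for Unknown), M_v its total, n_v the sink reads currently assigned to v,
T the number of taxa and V the number of sources including Unknown.
a_v is ``alpha1`` for known sources and ``alpha2`` for Unknown; ``beta`` is
the prior mass on the mixing proportions.  The mixing proportion of source v
is the posterior mean of n_v / n over retained draws and restarts.

Defaults (alpha1=0.001, alpha2=0.1, beta=10, 100 burn-in sweeps, 25 draws at
thinning 10, 10 restarts) are the historical defaults of the Gibbs source
tracker this model follows.  The inner loop is JIT-compiled with numba.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy import stats

from .cohort_io import AbundanceTable, CohortError, SampleRecord

__all__ = [
    "SourceAttribution",
    "TranslocationContrast",
    "gibbs_source_proportions",
    "track_cohort",
    "translocation_contrast",
]

ALPHA1 = 0.001
ALPHA2 = 0.1
BETA = 10.0


@dataclass
class SourceAttribution:
    sink_id: str
    proportions: dict[str, float]  # named sources + "Unknown", sums to 1
    stdevs: dict[str, float]
    n_draws: int

    def __post_init__(self) -> None:
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise CohortError("source proportions must sum to 1")
        if any(v < 0 for v in self.proportions.values()):
            raise CohortError("source proportions must be non-negative")


@dataclass
class TranslocationContrast:
    source: str
    group_proportions: dict[str, list[float]]
    group_medians: dict[str, float]
    p_value: float
    difference: float  # median(group2) - median(group1), groups sorted


@njit(cache=False)
def _gibbs_chain(read_taxa, kp, alpha2, beta, n_taxa, burnin, draws, thin, seed):
    """One restart of the collapsed sampler; returns draws x V proportions."""
    np.random.seed(seed)
    n = read_taxa.size
    vk = kp.shape[0]  # known sources
    v_all = vk + 1  # + Unknown
    z = np.empty(n, np.int64)
    n_v = np.zeros(v_all, np.int64)
    u_t = np.zeros(n_taxa, np.int64)  # Unknown's taxon counts
    for r in range(n):
        s = np.random.randint(0, v_all)
        z[r] = s
        n_v[s] += 1
        if s == vk:
            u_t[read_taxa[r]] += 1
    out = np.zeros((draws, v_all))
    w = np.empty(v_all)
    d = 0
    total_sweeps = burnin + draws * thin
    for sweep in range(total_sweeps):
        for r in range(n):
            t = read_taxa[r]
            s = z[r]
            n_v[s] -= 1
            if s == vk:
                u_t[t] -= 1
            acc = 0.0
            for v in range(vk):
                acc += kp[v, t] * (n_v[v] + beta)
                w[v] = acc
            acc += (u_t[t] + alpha2) / (n_v[vk] + n_taxa * alpha2) * (n_v[vk] + beta)
            w[vk] = acc
            u = np.random.random() * acc
            v = 0
            while w[v] < u:
                v += 1
            z[r] = v
            n_v[v] += 1
            if v == vk:
                u_t[t] += 1
        if sweep >= burnin and (sweep - burnin) % thin == thin - 1:
            for v in range(v_all):
                out[d, v] = n_v[v] / n
            d += 1
    return out


def gibbs_source_proportions(
    sink_counts,
    source_table,
    source_names: list[str],
    sink_id: str = "sink",
    alpha1: float = ALPHA1,
    alpha2: float = ALPHA2,
    beta: float = BETA,
    n_burnin: int = 100,
    n_draws: int = 25,
    thin: int = 10,
    n_restarts: int = 10,
    rarefy_to: int | None = None,
    seed: int | None = None,
) -> SourceAttribution:
    """Attribute a sink sample to named sources plus Unknown.

    ``sink_counts`` is a taxon count vector; ``source_table`` a
    (sources x taxa) count matrix over the SAME taxon namespace (alignment is
    the caller's responsibility, enforced by shape).  ``rarefy_to`` optionally
    subsamples the sink to a fixed depth before sampling (off by default).
    """
    sink = np.asarray(sink_counts, dtype=np.int64)
    sources = np.asarray(source_table, dtype=float)
    if sources.ndim != 2 or sources.shape[1] != sink.shape[0]:
        raise CohortError(
            f"taxon namespace mismatch: sink has {sink.shape[0]} taxa, "
            f"sources have {sources.shape[-1]}"
        )
    if len(source_names) != sources.shape[0]:
        raise CohortError("source_names length must match source rows")
    if "Unknown" in source_names:
        raise CohortError('"Unknown" is reserved for the learned source')
    if n_draws < 10:
        raise CohortError("n_draws must be >= 10")
    if sink.sum() < 1:
        raise CohortError("sink must contain at least 1 read")
    if np.any(sink < 0) or np.any(sources < 0):
        raise CohortError("counts must be non-negative")

    n_taxa = sink.shape[0]
    # canonicalize source order so a permutation of the inputs permutes the
    # outputs identically (the chain itself is order-sensitive)
    order = np.argsort(np.asarray(source_names, dtype=object))
    sources = sources[order]
    source_names = [source_names[i] for i in order]
    rng = np.random.default_rng(seed)
    if rarefy_to is not None and sink.sum() > rarefy_to:
        reads = np.repeat(np.arange(n_taxa), sink)
        keep = rng.choice(reads, size=rarefy_to, replace=False)
        sink = np.bincount(keep, minlength=n_taxa)
    read_taxa = np.repeat(np.arange(n_taxa), sink).astype(np.int64)

    kp = (sources + alpha1) / (
        sources.sum(axis=1, keepdims=True) + n_taxa * alpha1
    )
    all_draws = []
    for _ in range(n_restarts):
        chain_seed = int(rng.integers(2**31))
        all_draws.append(
            _gibbs_chain(
                read_taxa, kp, float(alpha2), float(beta), n_taxa,
                int(n_burnin), int(n_draws), int(thin), chain_seed,
            )
        )
    draws = np.vstack(all_draws)  # (restarts*draws) x V
    names = list(source_names) + ["Unknown"]
    mean = draws.mean(axis=0)
    mean = mean / mean.sum()  # exact simplex closure against fp noise
    sd = draws.std(axis=0, ddof=0)
    return SourceAttribution(
        sink_id,
        {nm: float(p) for nm, p in zip(names, mean)},
        {nm: float(s) for nm, s in zip(names, sd)},
        draws.shape[0],
    )


def track_cohort(
    table: AbundanceTable,
    records: list[SampleRecord],
    pooled: bool = False,
    seed: int | None = None,
    **gibbs_kwargs,
) -> list[SourceAttribution]:
    """Per-subject source tracking of each uterine sink.

    In the default per-subject mode, a sink's sources are its own paired
    vaginal sample (``paired_vagina``) plus a pool of every other subject's
    vaginal sample (``other_vaginas``).  With ``pooled=True`` a single pooled
    vaginal source (``vagina_pool``) is used instead.
    """
    if table.mode != "counts":
        raise CohortError("track_cohort requires a counts-mode table")
    cols = set(table.sample_ids)
    by_subject: dict[str, dict[str, str]] = {}
    for r in records:
        if r.sample_id in cols:
            by_subject.setdefault(r.subject_id, {})[r.site] = r.sample_id
    subjects = sorted(
        s for s, sites in by_subject.items()
        if "uterus" in sites and "vagina" in sites
    )
    if not subjects:
        raise CohortError("no subjects with both a uterine and a vaginal sample")
    v_idx = {s: table.sample_index(by_subject[s]["vagina"]) for s in subjects}
    v_total = table.values[:, [v_idx[s] for s in subjects]].sum(axis=1)
    rng = np.random.default_rng(seed)
    out = []
    for s in subjects:
        sink = np.round(table.column(by_subject[s]["uterus"])).astype(np.int64)
        own = table.values[:, v_idx[s]]
        if pooled:
            sources = np.vstack([v_total])
            names = ["vagina_pool"]
        else:
            sources = np.vstack([own, v_total - own])
            names = ["paired_vagina", "other_vaginas"]
        out.append(
            gibbs_source_proportions(
                sink, sources, names,
                sink_id=by_subject[s]["uterus"],
                seed=int(rng.integers(2**31)),
                **gibbs_kwargs,
            )
        )
    return out


def translocation_contrast(
    attributions: list[SourceAttribution],
    records: list[SampleRecord],
    source: str | list[str] = "paired_vagina",
) -> TranslocationContrast:
    """Rank-based two-group comparison of a source's attributed proportions.

    Each sink is labelled with its sample's health group; the two groups'
    ``source`` proportions (a single source name, or a list whose
    proportions are summed, e.g. all vaginal sources) are compared with a
    two-sided Wilcoxon rank-sum (Mann-Whitney) test.
    """
    sources = [source] if isinstance(source, str) else list(source)
    group_of = {r.sample_id: r.group for r in records}
    per_group: dict[str, list[float]] = {}
    for att in attributions:
        if att.sink_id not in group_of:
            raise CohortError(f"sink {att.sink_id!r} missing from metadata")
        missing = [s for s in sources if s not in att.proportions]
        if missing:
            raise CohortError(f"source {missing[0]!r} absent from attribution")
        per_group.setdefault(group_of[att.sink_id], []).append(
            sum(att.proportions[s] for s in sources)
        )
    if len(per_group) != 2:
        raise CohortError(f"need exactly 2 groups, got {sorted(per_group)}")
    small = [g for g, v in per_group.items() if len(v) < 3]
    if small:
        raise CohortError(f"group {small[0]!r} has fewer than 3 sinks")
    g1, g2 = sorted(per_group)
    stat = stats.mannwhitneyu(
        per_group[g1], per_group[g2], alternative="two-sided"
    )
    medians = {g: float(np.median(v)) for g, v in per_group.items()}
    return TranslocationContrast(
        "+".join(sources),
        per_group,
        medians,
        float(stat.pvalue),
        medians[g2] - medians[g1],
    )
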