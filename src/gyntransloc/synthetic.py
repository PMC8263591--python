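"""Synthetic paired vagina/uterus cohorts with recorded ground truth.

The generator emulates the structure of a paired-body-site 16S cohort:

* each subject's vaginal community is a Dirichlet draw; in the default
  ``lactobacillus_dominant`` mode one taxon carries most of the concentration
  mass, mirroring the Lactobacillus-dominated healthy vagina, while
  ``diverse`` uses a flat concentration vector;
* the uterine community is a mixture ``pi * vaginal + (1 - pi) *
  uterus-endogenous`` of the subject's own vaginal composition and an
  independent uterus-specific Dirichlet draw — ``pi`` is the ground-truth
  vagina->uterus translocation proportion that source attribution should
  recover;
* group effects (e.g. endometritis enrichment of a taxon) act
  multiplicatively on Dirichlet concentrations, so compositions stay valid by
  construction and the planted sign of each effect is known;
* sequencing is multinomial at a fixed read depth.

A second generator plants species-level marker-SNP structure: "transferred"
species share a strain across sites (uterine SNPs are a subset of vaginal
ones, with vagina-unique extras), "unrelated" species carry independent SNP
sets, and a pileup emitter writes samtools-mpileup text so the entire
strain-tracking stage can be exercised end to end against known truth.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cohort_io import AbundanceTable, CohortError, PhyloTree, SampleRecord, read_tree
from .strain_tracking import ALLELES, MarkerIndex, MarkerInfo, MarkerSNPProfile

__all__ = [
    "CohortParams",
    "SyntheticTruth",
    "simulate_paired_cohort",
    "expected_site_compositions",
    "expected_tables",
    "simulate_tree",
    "simulate_marker_snps",
    "simulate_pileup",
]

#: default share of the dominant taxon in lactobacillus_dominant mode
DOMINANT_SHARE = 0.7


@dataclass
class CohortParams:
    """Study conditions for the paired-cohort generator.

    ``effect_taxa`` entries are ``(taxon_id, site, group, log_effect)``: the
    named taxon's Dirichlet concentration at that site is multiplied by
    ``exp(log_effect)`` for subjects of that group.
    """

    n_subjects: int = 100
    n_taxa: int = 300
    base_concentration: np.ndarray | None = None
    pi_transloc: float = 0.5
    pi_by_group: dict[str, float] | None = None
    uterus_specific_concentration: np.ndarray | None = None
    effect_taxa: list[tuple[str, str, str, float]] = field(default_factory=list)
    depth_per_sample: int = 10000
    dominance_mode: str = "lactobacillus_dominant"
    fraction_disease: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 2:
            raise CohortError("n_taxa must be >= 2")
        if self.n_subjects < 1:
            raise CohortError("n_subjects must be >= 1")
        if not 0 <= self.pi_transloc <= 1:
            raise CohortError("pi_transloc must lie in [0, 1]")
        if self.pi_by_group is not None:
            for g, p in self.pi_by_group.items():
                if not 0 <= p <= 1:
                    raise CohortError(f"pi for group {g!r} must lie in [0, 1]")
        if self.depth_per_sample < 1:
            raise CohortError("depth_per_sample must be >= 1")
        if self.dominance_mode not in ("lactobacillus_dominant", "diverse"):
            raise CohortError(f"unknown dominance_mode {self.dominance_mode!r}")
        for c, name in (
            (self.base_concentration, "base_concentration"),
            (self.uterus_specific_concentration, "uterus_specific_concentration"),
        ):
            if c is not None and len(np.asarray(c)) != self.n_taxa:
                raise CohortError(f"{name} length mismatch with n_taxa")
        for taxon, site, group, eff in self.effect_taxa:
            if not np.isfinite(eff):
                raise CohortError(f"effect for {taxon!r} must be finite")
            if site not in ("uterus", "vagina"):
                raise CohortError(f"effect site {site!r} invalid")

    @property
    def taxon_ids(self) -> list[str]:
        return [f"OTU{i + 1:04d}" for i in range(self.n_taxa)]

    def pi_for(self, group: str) -> float:
        if self.pi_by_group and group in self.pi_by_group:
            return self.pi_by_group[group]
        return self.pi_transloc


@dataclass
class SyntheticTruth:
    """Ground truth recorded by the generators."""

    pi_by_subject: dict[str, float] = field(default_factory=dict)
    effect_direction: dict[str, dict[str, int]] = field(default_factory=dict)
    strain_map: dict[str, dict[str, set]] = field(default_factory=dict)
    transferred_species: set[str] = field(default_factory=set)
    seed: int | None = None


def _concentrations(params: CohortParams) -> tuple[np.ndarray, np.ndarray]:
    n = params.n_taxa
    if params.base_concentration is not None:
        base_v = np.asarray(params.base_concentration, dtype=float).copy()
    elif params.dominance_mode == "lactobacillus_dominant":
        base_v = np.full(n, 0.5)
        rest = base_v[1:].sum()
        # dominant taxon holds DOMINANT_SHARE of expected vaginal abundance
        base_v[0] = DOMINANT_SHARE / (1 - DOMINANT_SHARE) * rest
    else:
        base_v = np.ones(n)
    if params.uterus_specific_concentration is not None:
        base_u = np.asarray(params.uterus_specific_concentration, dtype=float).copy()
    else:
        base_u = np.ones(n)
    if np.any(base_v <= 0) or np.any(base_u <= 0):
        raise CohortError("Dirichlet concentrations must be positive")
    return base_v, base_u


def _group_concentrations(
    params: CohortParams, group: str
) -> tuple[np.ndarray, np.ndarray]:
    base_v, base_u = _concentrations(params)
    pos = {t: i for i, t in enumerate(params.taxon_ids)}
    for taxon, site, g, eff in params.effect_taxa:
        if g != group:
            continue
        if taxon not in pos:
            raise CohortError(f"effect taxon {taxon!r} not in the cohort")
        if site == "vagina":
            base_v[pos[taxon]] *= np.exp(eff)
        else:
            base_u[pos[taxon]] *= np.exp(eff)
    return base_v, base_u


def expected_site_compositions(params: CohortParams) -> dict[tuple[str, str], np.ndarray]:
    """Expected (mean) relative composition per (site, group).

    The Dirichlet mean is the normalized concentration vector; the expected
    uterine composition is the pi-mixture of the vaginal and
    uterus-endogenous means."""
    out = {}
    for group in ("healthy", "endometritis"):
        conc_v, conc_u = _group_concentrations(params, group)
        mean_v = conc_v / conc_v.sum()
        mean_u_end = conc_u / conc_u.sum()
        pi = params.pi_for(group)
        out[("vagina", group)] = mean_v
        out[("uterus", group)] = pi * mean_v + (1 - pi) * mean_u_end
    return out


def _truth_directions(params: CohortParams) -> dict[str, dict[str, int]]:
    comps = expected_site_compositions(params)
    taxa = params.taxon_ids
    effect_names = {t for t, *_ in params.effect_taxa}
    out: dict[str, dict[str, int]] = {"uterus": {}, "vagina": {}}
    for site in ("uterus", "vagina"):
        delta = comps[(site, "endometritis")] - comps[(site, "healthy")]
        for i, t in enumerate(taxa):
            if t in effect_names:
                d = delta[i]
                out[site][t] = int(np.sign(d)) if abs(d) > 1e-15 else 0
            else:
                out[site][t] = 0
    return out


def simulate_paired_cohort(
    params: CohortParams,
) -> tuple[AbundanceTable, list[SampleRecord], SyntheticTruth]:
    """Generate a paired cohort: one uterine and one vaginal counts sample per
    subject, metadata, and the recorded ground truth."""
    rng = np.random.default_rng(params.seed)
    taxa = params.taxon_ids
    n = params.n_subjects
    n_disease = int(round(n * params.fraction_disease))
    groups = np.array(["healthy"] * (n - n_disease) + ["endometritis"] * n_disease)
    rng.shuffle(groups)

    conc = {g: _group_concentrations(params, g)
            for g in ("healthy", "endometritis")}

    sample_ids: list[str] = []
    columns: list[np.ndarray] = []
    records: list[SampleRecord] = []
    truth = SyntheticTruth(seed=params.seed)
    truth.effect_direction = _truth_directions(params)

    for k in range(n):
        subject = f"S{k + 1:04d}"
        group = str(groups[k])
        conc_v, conc_u = conc[group]
        v = rng.dirichlet(conc_v)
        u_end = rng.dirichlet(conc_u)
        pi = params.pi_for(group)
        u = pi * v + (1 - pi) * u_end
        counts_u = rng.multinomial(params.depth_per_sample, u)
        counts_v = rng.multinomial(params.depth_per_sample, v)
        age = float(rng.integers(19, 72))
        delivery = str(rng.choice(["vaginal", "cesarean", "none"]))
        n_ab = int(rng.poisson(1.0))
        for site, cnt in (("uterus", counts_u), ("vagina", counts_v)):
            sid = f"{subject}{'U' if site == 'uterus' else 'V'}"
            sample_ids.append(sid)
            columns.append(cnt)
            records.append(
                SampleRecord(sid, subject, site, group, age, delivery, n_ab)
            )
        truth.pi_by_subject[subject] = pi

    table = AbundanceTable(
        taxa, sample_ids, np.column_stack(columns).astype(float), "counts"
    )
    return table, records, truth


def expected_tables(
    params: CohortParams,
) -> tuple[AbundanceTable, AbundanceTable, dict[str, str]]:
    """Noise-free relative tables built from the expected compositions: one
    column per group and site, for exact direction-of-change bookkeeping."""
    comps = expected_site_compositions(params)
    taxa = params.taxon_ids
    labels: dict[str, str] = {}
    tabs = {}
    for site, tag in (("uterus", "U"), ("vagina", "V")):
        ids, cols = [], []
        for group in ("healthy", "endometritis"):
            sid = f"{group}_{tag}"
            ids.append(sid)
            cols.append(comps[(site, group)])
            labels[sid] = group
        tabs[site] = AbundanceTable(taxa, ids, np.column_stack(cols), "relative")
    return tabs["uterus"], tabs["vagina"], labels


# ---------------------------------------------------------------------------
# random tree


def simulate_tree(taxon_ids: Sequence[str], seed: int | None = None) -> PhyloTree:
    """Random rooted binary tree by sequential random join, exponential
    branch lengths; deterministic newick for a fixed seed."""
    ids = list(map(str, taxon_ids))
    if len(ids) < 2:
        raise CohortError("need at least 2 taxa for a tree")
    if len(set(ids)) != len(ids):
        raise CohortError("duplicate taxon ids")
    rng = np.random.default_rng(seed)
    clusters = list(ids)
    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        a, b = clusters[i], clusters[j]
        la, lb = rng.exponential(1.0, size=2)
        merged = f"({a}:{la:.6f},{b}:{lb:.6f})"
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return read_tree(clusters[0] + ";")


# ---------------------------------------------------------------------------
# marker SNPs and pileups


def simulate_marker_snps(
    species: Sequence[str],
    markers_per_species: int = 5,
    marker_length: int = 300,
    shared_snp_rate: float = 0.02,
    unique_snp_rate: float = 0.01,
    transferred: Sequence[str] | None = None,
    breadth_uterus: float = 0.6,
    breadth_vagina: float = 0.9,
    min_discordant_snps: int = 5,
    seed: int | None = None,
) -> tuple[MarkerSNPProfile, MarkerSNPProfile, SyntheticTruth, MarkerIndex]:
    """Plant per-species marker SNP sets for one uterus/vagina pair.

    Transferred species (default: the first half of ``species``) share a
    strain: every uterine SNP also appears in the vagina, and the vagina
    carries at least one extra unique SNP (the SNP-richer site defines the
    direction).  Unrelated species get independent SNP sets with at least
    ``min_discordant_snps`` discordant SNPs per side, so they can never be
    mistaken for a shared strain under full containment.

    Returns the uterine profile, the vaginal profile, the truth record, and
    the generated marker index (with reference sequences for the pileup
    emitter).
    """
    species = list(map(str, species))
    if markers_per_species < 1:
        raise CohortError("need at least one marker per species")
    if marker_length < 50:
        raise CohortError("marker_length must be >= 50")
    for r, nm in ((shared_snp_rate, "shared_snp_rate"),
                  (unique_snp_rate, "unique_snp_rate")):
        if not 0 <= r <= 0.2:
            raise CohortError(f"{nm} must lie in [0, 0.2]")
    if transferred is None:
        transferred = species[: len(species) // 2 or 1]
    transferred = set(transferred)
    rng = np.random.default_rng(seed)

    markers: dict[str, MarkerInfo] = {}
    cov_u: dict[str, set[int]] = {}
    cov_v: dict[str, set[int]] = {}
    snps_u: set[tuple[str, int, str]] = set()
    snps_v: set[tuple[str, int, str]] = set()
    truth = SyntheticTruth(seed=seed)
    truth.transferred_species = set(transferred) & set(species)

    def pick_positions(breadth: float) -> set[int]:
        k = int(round(breadth * marker_length))
        return set(
            (rng.choice(marker_length, size=k, replace=False) + 1).tolist()
        )

    def alt_base(ref: str) -> str:
        choices = [b for b in ALLELES if b != ref]
        return str(rng.choice(choices))

    for sp in species:
        shared_set: set = set()
        vu_set: set = set()
        uu_set: set = set()
        for k in range(markers_per_species):
            mid = f"{sp}|m{k + 1}"
            ref = "".join(rng.choice(list(ALLELES), size=marker_length))
            markers[mid] = MarkerInfo(sp, marker_length, ref)
            pos_u = pick_positions(breadth_uterus)
            pos_v = pick_positions(breadth_vagina)
            cov_u[mid] = pos_u
            cov_v[mid] = pos_v
            both = sorted(pos_u & pos_v)
            v_only_ok = sorted(pos_v - pos_u)
            if sp in transferred:
                for p in both:
                    if rng.random() < shared_snp_rate:
                        s = (mid, p, alt_base(ref[p - 1]))
                        shared_set.add(s)
                extras_pool = [p for p in sorted(pos_v)
                               if (mid, p) not in {(m, q) for m, q, _ in shared_set}]
                for p in extras_pool:
                    if rng.random() < unique_snp_rate:
                        vu_set.add((mid, p, alt_base(ref[p - 1])))
            else:
                for p in sorted(pos_u):
                    if rng.random() < unique_snp_rate:
                        uu_set.add((mid, p, alt_base(ref[p - 1])))
                for p in sorted(pos_v):
                    if rng.random() < unique_snp_rate:
                        vu_set.add((mid, p, alt_base(ref[p - 1])))

        first = f"{sp}|m1"
        ref1 = markers[first].reference
        if sp in transferred:
            # guarantee the planted structure: >=1 shared and >=1 vagina-unique
            if not shared_set:
                p = sorted(cov_u[first] & cov_v[first])[0]
                shared_set.add((first, p, alt_base(ref1[p - 1])))
            if not vu_set:
                taken = {(m, p) for m, p, _ in shared_set}
                p = next(q for q in sorted(cov_v[first])
                         if (first, q) not in taken)
                vu_set.add((first, p, alt_base(ref1[p - 1])))
            snps_u |= shared_set
            snps_v |= shared_set | vu_set
        else:
            # guarantee >= min_discordant_snps discordant SNPs per side
            taken = {(m, p) for m, p, _ in (uu_set | vu_set)}
            def top_up(target: set, cov: dict) -> None:
                for k in range(markers_per_species):
                    mid = f"{sp}|m{k + 1}"
                    for p in sorted(cov[mid]):
                        if len(target) >= min_discordant_snps:
                            return
                        if (mid, p) not in taken:
                            target.add((mid, p,
                                        alt_base(markers[mid].reference[p - 1])))
                            taken.add((mid, p))
            shared_pos = {(m, p) for m, p, _ in uu_set} & {(m, p) for m, p, _ in vu_set}
            uu_set = {s for s in uu_set if (s[0], s[1]) not in shared_pos}
            vu_set = {s for s in vu_set if (s[0], s[1]) not in shared_pos}
            top_up(uu_set, cov_u)
            top_up(vu_set, cov_v)
            snps_u |= uu_set
            snps_v |= vu_set
        truth.strain_map[sp] = {
            "shared": set(shared_set),
            "vagina_unique": set(vu_set),
            "uterus_unique": set(uu_set),
        }

    index = MarkerIndex(markers)
    profile_u = MarkerSNPProfile("uterus", cov_u, snps_u)
    profile_v = MarkerSNPProfile("vagina", cov_v, snps_v)
    return profile_u, profile_v, truth, index


def simulate_pileup(
    profile: MarkerSNPProfile,
    index: MarkerIndex,
    mean_depth: float = 30.0,
    error_rate: float = 0.0,
    seed: int | None = None,
) -> str:
    """Emit samtools-mpileup text realizing a profile.

    Per covered position the depth is Poisson(``mean_depth``) clipped to >= 1
    (so the covered set, hence breadth, is realized exactly); planted SNP
    positions emit the alternate allele per read with probability
    ``1 - error_rate``, other positions emit reference ('.'/',') with a
    random non-reference base at the error rate.  Uncovered positions are
    omitted.
    """
    if mean_depth < 1:
        raise CohortError("mean_depth must be >= 1")
    if not 0 <= error_rate <= 0.05:
        raise CohortError("error_rate must lie in [0, 0.05]")
    rng = np.random.default_rng(seed)
    snp_at = {(m, p): alt for m, p, alt in profile.snps}
    lines = []
    for marker in sorted(profile.covered):
        info = index[marker]
        ref_seq = info.reference
        if ref_seq is None:
            raise CohortError(f"marker {marker!r} has no reference sequence")
        for pos in sorted(profile.covered[marker]):
            depth = max(1, int(rng.poisson(mean_depth)))
            ref_base = ref_seq[pos - 1]
            alt = snp_at.get((marker, pos))
            chars = []
            for _ in range(depth):
                err = rng.random() < error_rate
                if alt is not None:
                    if err:
                        chars.append("." if rng.random() < 0.5 else ",")
                    else:
                        chars.append(alt)
                else:
                    if err:
                        chars.append(str(rng.choice(
                            [b for b in ALLELES if b != ref_base])))
                    else:
                        chars.append("." if rng.random() < 0.5 else ",")
            lines.append(
                f"{marker}\t{pos}\t{ref_base}\t{depth}\t{''.join(chars)}\t"
                + "I" * depth
            )
    return "\n".join(lines) + "\n"
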