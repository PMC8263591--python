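"""Orchestration of the three headline analyses on a paired cohort.

``run_endometritis_contrast`` chains filtering, normalization, alpha
diversity, Bray-Curtis/UniFrac ordination with PERMANOVA, the LDA-effect-size
screen per site, cross-site direction-of-change concordance, and the
SparCC-style cross-site correlation with its sign-conservation and
strong-pair summaries.  ``run_translocation`` performs per-subject Gibbs
source attribution plus the strain-level SNP-containment stage on simulated
marker pileups.  ``run_aging`` bins subjects by decade and summarizes
diversity and between-sample distances against age.

Every run writes one TSV per stage plus ``manifest.json`` recording all
parameters and the seed; outputs carry the manifest hash in a leading
comment line, so a manifest plus inputs fully determines (and re-creates)
the outputs bit for bit.  Configuration is a flat TOML file; unknown keys
are rejected in one validation pass before any computation starts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort_io, cooccurrence, discriminants, diversity, ordination
from . import source_attribution, strain_tracking, synthetic
from .cohort_io import AbundanceTable, CohortError, SampleRecord

logger = logging.getLogger("gyntransloc")
logging.basicConfig(
    level=logging.INFO,
    format="%(asctime)s %(name)s %(levelname)s %(message)s",
)

__all__ = [
    "RunConfig",
    "AGE_BINS",
    "run_endometritis_contrast",
    "run_translocation",
    "run_aging",
]

#: age bins: <20, 20-29, 30-39, 40-49, 50-59, >=60 (right-open except last)
AGE_BINS = ((0, 20), (20, 30), (30, 40), (40, 50), (50, 60), (60, 200))
AGE_BIN_LABELS = ("10+", "20+", "30+", "40+", "50+", "60+")


def age_bin(age: float) -> str:
    for (lo, hi), lab in zip(AGE_BINS, AGE_BIN_LABELS):
        if lo <= age < hi:
            return lab
    raise CohortError(f"age {age} outside binning range")


@dataclass
class RunConfig:
    """Flat run configuration; every field is echoed into the manifest."""

    seed: int
    out_dir: str = "gyntransloc_out"
    # inputs (omit to simulate a cohort with the parameters below)
    table_path: str | None = None
    metadata_path: str | None = None
    tree_path: str | None = None
    # synthetic cohort
    n_subjects: int = 100
    n_taxa: int = 300
    pi_healthy: float = 0.4
    pi_disease: float = 0.8
    depth_per_sample: int = 10000
    dominance_mode: str = "lactobacillus_dominant"
    n_effect_taxa: int = 20
    effect_size: float = 1.5
    # filtering
    min_observed: int = 50
    min_goods: float = 0.8
    # ordination / tests
    n_permutations: int = 999
    pcoa_axes: int = 2
    # discriminants
    lefse_alpha: float = 0.05
    lda_threshold: float = 3.0
    lefse_boot: int = 30
    # co-occurrence
    corr_top_taxa: int = 50
    sparcc_inner: int = 20
    sparcc_exclusion_rounds: int = 10
    corr_boot: int = 100
    strong_threshold: float = 0.4
    # source attribution
    st_burnin: int = 100
    st_draws: int = 25
    st_thin: int = 10
    st_restarts: int = 10
    # strain tracking
    strain_subjects: int = 10
    strain_species: int = 6
    strain_markers: int = 5
    strain_marker_length: int = 300
    strain_depth: float = 30.0
    strain_error: float = 0.01
    breadth_min: float = 0.4
    containment_min: float = 1.0

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(raw) - known)
        problems = []
        if unknown:
            problems.append(f"unknown config keys: {unknown}")
        if "seed" not in raw:
            problems.append("missing required key 'seed'")
        if problems:
            raise CohortError("; ".join(problems))
        return cls(**raw)

    def validate(self) -> None:
        """Fail-fast: collect every problem, report them in one pass."""
        problems = []
        for name in ("table_path", "metadata_path", "tree_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                problems.append(f"{name} does not exist: {p}")
        if not 0 <= self.pi_healthy <= 1 or not 0 <= self.pi_disease <= 1:
            problems.append("pi values must lie in [0, 1]")
        if self.n_permutations < 99:
            problems.append("n_permutations must be >= 99")
        if not 0 <= self.strong_threshold < 1:
            problems.append("strong_threshold must lie in [0, 1)")
        if self.seed is None:
            problems.append("seed is mandatory for stochastic stages")
        if problems:
            raise CohortError("invalid configuration: " + "; ".join(problems))

    def manifest(self) -> dict:
        params = dataclasses.asdict(self)
        # the hash covers everything that determines the numbers; the output
        # location does not
        hashed = {k: v for k, v in params.items() if k != "out_dir"}
        blob = json.dumps(hashed, sort_keys=True).encode()
        return {
            "parameters": params,
            "seed": self.seed,
            "hash": hashlib.sha256(blob).hexdigest()[:16],
        }


def _write_tsv(df: pd.DataFrame, path: Path, manifest_hash: str, **to_csv_kwargs) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# manifest={manifest_hash}\n")
        df.to_csv(fh, sep="\t", **to_csv_kwargs)


def _stage(name: str, start: float, **info) -> None:
    details = " ".join(f"{k}={v}" for k, v in info.items())
    logger.info("stage=%s %s wall=%.2fs", name, details, time.time() - start)


def _load_or_simulate(
    config: RunConfig,
) -> tuple[AbundanceTable, list[SampleRecord], synthetic.SyntheticTruth | None]:
    if config.table_path is not None:
        if config.metadata_path is None:
            raise CohortError("metadata_path required with table_path")
        table = cohort_io.read_abundance_table(config.table_path)
        records = cohort_io.read_metadata(config.metadata_path)
        cohort_io.validate_metadata_against_table(records, table)
        return table, records, None
    params = synthetic.CohortParams(
        n_subjects=config.n_subjects,
        n_taxa=config.n_taxa,
        pi_by_group={"healthy": config.pi_healthy,
                     "endometritis": config.pi_disease},
        depth_per_sample=config.depth_per_sample,
        dominance_mode=config.dominance_mode,
        effect_taxa=_default_effects(config),
        seed=config.seed,
    )
    table, records, truth = synthetic.simulate_paired_cohort(params)
    return table, records, truth


def _default_effects(config: RunConfig) -> list[tuple[str, str, str, float]]:
    """Planted disease effects: alternating enrichment/depletion on the
    mid-abundance taxa, applied to the vaginal source so the uterus inherits
    the same direction through the mixture."""
    effects = []
    for k in range(config.n_effect_taxa):
        taxon = f"OTU{k + 2:04d}"  # skip the dominant taxon
        sign = 1.0 if k % 2 == 0 else -1.0
        effects.append((taxon, "vagina", "endometritis",
                        sign * config.effect_size))
    return effects


def run_endometritis_contrast(config: RunConfig) -> dict:
    """Health-group contrast: filter -> normalize -> diversity ->
    PCoA/PERMANOVA -> effect-size screen -> concordance -> co-occurrence."""
    config.validate()
    man = config.manifest()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {"manifest": man}
    rng = np.random.default_rng(config.seed)

    t0 = time.time()
    table, records, _truth = _load_or_simulate(config)
    meta = cohort_io.metadata_frame(records)
    _stage("load", t0, taxa=table.n_taxa, samples=table.n_samples)

    t0 = time.time()
    table, dropped = cohort_io.filter_samples(
        table, config.min_observed, config.min_goods
    )
    records = [r for r in records if r.sample_id in set(table.sample_ids)]
    meta = cohort_io.metadata_frame(records)
    rel = cohort_io.to_relative(table)
    _stage("filter", t0, kept=table.n_samples, dropped=len(dropped))
    results["dropped_samples"] = dropped

    t0 = time.time()
    alpha = diversity.alpha_diversity_table(table)
    alpha = alpha.join(meta[["subject_id", "site", "group", "age"]])
    _write_tsv(alpha, out / "diversity.tsv", man["hash"])
    _stage("diversity", t0, samples=len(alpha))
    results["alpha"] = alpha

    t0 = time.time()
    bc = diversity.pairwise_bray_curtis(table)
    _write_tsv(pd.DataFrame(bc.data, index=bc.ids, columns=bc.ids),
               out / "distance_bc.tsv", man["hash"])
    ord_res = ordination.pcoa(bc, n_axes=config.pcoa_axes)
    coords = pd.DataFrame(
        ord_res.coordinates, index=ord_res.sample_ids,
        columns=[f"PC{i + 1}" for i in range(ord_res.coordinates.shape[1])],
    )
    _write_tsv(coords, out / "pcoa.tsv", man["hash"])
    perm_rows = []
    for site in ("uterus", "vagina"):
        sids = [r.sample_id for r in records if r.site == site]
        labels = {r.sample_id: r.group for r in records if r.site == site}
        sub = bc.filter(sids)
        pr = ordination.permanova(
            sub, labels, config.n_permutations,
            seed=int(rng.integers(2**31)),
        )
        perm_rows.append({"site": site, "pseudo_F": pr.pseudo_f,
                          "p_value": pr.p_value,
                          "n_permutations": pr.n_permutations})
    permanova_df = pd.DataFrame(perm_rows)
    _write_tsv(permanova_df, out / "permanova.tsv", man["hash"], index=False)
    _stage("ordination", t0)
    results["permanova"] = permanova_df
    results["pcoa"] = ord_res

    t0 = time.time()
    lefse_out = {}
    for site in ("uterus", "vagina"):
        sids = [r.sample_id for r in records if r.site == site]
        labels = {r.sample_id: r.group for r in records}
        recs = discriminants.lefse_lite(
            rel.select_samples(sids), labels,
            alpha=config.lefse_alpha, lda_threshold=config.lda_threshold,
            n_boot=config.lefse_boot, seed=int(rng.integers(2**31)),
        )
        df = pd.DataFrame([vars(r) for r in recs])
        _write_tsv(df, out / f"lefse_{site}.tsv", man["hash"], index=False)
        lefse_out[site] = recs
    _stage("discriminants", t0,
           flagged_u=sum(r.passes for r in lefse_out["uterus"]),
           flagged_v=sum(r.passes for r in lefse_out["vagina"]))
    results["lefse"] = lefse_out

    t0 = time.time()
    flagged = sorted(
        {r.taxon for site in lefse_out for r in lefse_out[site] if r.passes}
    )
    u_ids = [r.sample_id for r in records if r.site == "uterus"]
    v_ids = [r.sample_id for r in records if r.site == "vagina"]
    labels = {r.sample_id: r.group for r in records}
    conc_taxa = flagged or list(table.taxon_ids)
    conc = discriminants.direction_of_change(
        rel.select_samples(u_ids), rel.select_samples(v_ids), labels, conc_taxa
    )
    conc_df = pd.DataFrame({
        "taxon": conc.taxa,
        "delta_uterus": conc.delta_site1,
        "delta_vagina": conc.delta_site2,
        "concordant": conc.concordant,
    })
    _write_tsv(conc_df, out / "concordance.tsv", man["hash"], index=False)
    _stage("concordance", t0, n_concordant=conc.n_concordant,
           n_total=conc.n_total)
    results["concordance"] = conc

    t0 = time.time()
    # restrict the compositional correlation to the most abundant taxa per
    # site so the joint system stays well-conditioned at cohort scale
    mean_ab = rel.values.mean(axis=1)
    top = np.argsort(mean_ab)[::-1][: config.corr_top_taxa]
    top_taxa = [table.taxon_ids[i] for i in sorted(top)]
    sub_table = table.select_taxa(top_taxa)
    corr_by_group = {}
    for group in ("healthy", "endometritis"):
        joint = cooccurrence.paired_joint_table(sub_table, records, group=group)
        corr = cooccurrence.sparcc_correlation(
            joint, n_inner_iterations=config.sparcc_inner,
            n_exclusion_rounds=config.sparcc_exclusion_rounds,
            seed=int(rng.integers(2**31)),
        )
        block = cooccurrence.cross_site_block(corr)
        _write_tsv(block, out / f"crosscorr_{group}.tsv", man["hash"])
        corr_by_group[group] = block
    # per-taxon cross-site correlation = diagonal of the uterus x vagina block
    diag_h = pd.Series(np.diag(corr_by_group["healthy"]),
                       index=corr_by_group["healthy"].index)
    diag_d = pd.Series(np.diag(corr_by_group["endometritis"]),
                       index=corr_by_group["endometritis"].index)
    n_same, n_tot, flags = cooccurrence.sign_conservation(
        diag_h.to_numpy(), diag_d.to_numpy()
    )
    strong = cooccurrence.strong_pairs(
        corr_by_group["healthy"], config.strong_threshold
    )
    sign_df = pd.DataFrame({
        "taxon": diag_h.index, "rho_healthy": diag_h.to_numpy(),
        "rho_disease": diag_d.to_numpy(), "flag": flags,
    })
    _write_tsv(sign_df, out / "sign_conservation.tsv", man["hash"], index=False)
    _stage("cooccurrence", t0, sign_conserved=n_same, n_taxa=n_tot,
           strong_pairs=len(strong))
    results["sign_conservation"] = (n_same, n_tot)
    results["strong_pairs"] = strong

    (out / "manifest.json").write_text(json.dumps(man, indent=2, sort_keys=True))
    return results


def run_translocation(config: RunConfig) -> dict:
    """Source attribution of each uterine sink plus the strain-level stage."""
    config.validate()
    man = config.manifest()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {"manifest": man}
    rng = np.random.default_rng(config.seed)

    t0 = time.time()
    table, records, truth = _load_or_simulate(config)
    table, _dropped = cohort_io.filter_samples(
        table, config.min_observed, config.min_goods
    )
    records = [r for r in records if r.sample_id in set(table.sample_ids)]
    _stage("load", t0, taxa=table.n_taxa, samples=table.n_samples)

    t0 = time.time()
    attributions = source_attribution.track_cohort(
        table, records,
        n_burnin=config.st_burnin, n_draws=config.st_draws,
        thin=config.st_thin, n_restarts=config.st_restarts,
        seed=int(rng.integers(2**31)),
    )
    rows = []
    for att in attributions:
        for src, p in att.proportions.items():
            rows.append({"sink_id": att.sink_id, "source": src,
                         "proportion": p, "sd": att.stdevs[src]})
    st_df = pd.DataFrame(rows)
    _write_tsv(st_df, out / "source_attribution.tsv", man["hash"], index=False)
    contrast = source_attribution.translocation_contrast(
        attributions, records, source=["paired_vagina", "other_vaginas"]
    )
    _stage("sourcetrack", t0, sinks=len(attributions),
           p=f"{contrast.p_value:.4g}")
    results["attributions"] = attributions
    results["contrast"] = contrast
    if truth is not None:
        # vaginal-origin fraction sums the paired and pooled vaginal sources
        est = {a.sink_id[:-1]: a.proportions["paired_vagina"]
               + a.proportions.get("other_vaginas", 0.0)
               for a in attributions}
        errors = [abs(est[s] - truth.pi_by_subject[s])
                  for s in est if s in truth.pi_by_subject]
        results["pi_mae"] = float(np.mean(errors)) if errors else float("nan")

    t0 = time.time()
    species = [f"sp{i + 1:02d}" for i in range(config.strain_species)]
    calls = []
    for k in range(config.strain_subjects):
        pu, pv, s_truth, index = synthetic.simulate_marker_snps(
            species, config.strain_markers, config.strain_marker_length,
            seed=int(rng.integers(2**31)),
        )
        text_u = synthetic.simulate_pileup(
            pu, index, config.strain_depth, config.strain_error,
            seed=int(rng.integers(2**31)))
        text_v = synthetic.simulate_pileup(
            pv, index, config.strain_depth, config.strain_error,
            seed=int(rng.integers(2**31)))
        prof_u = strain_tracking.call_snps(
            strain_tracking.parse_pileup(text_u, index), sample_id=f"S{k}U")
        prof_v = strain_tracking.call_snps(
            strain_tracking.parse_pileup(text_v, index), sample_id=f"S{k}V")
        calls.extend(strain_tracking.strain_sharing(
            prof_u, prof_v, index,
            breadth_min=config.breadth_min,
            containment_min=config.containment_min,
            subject_id=f"S{k + 1:04d}",
        ))
    calls_df = pd.DataFrame([vars(c) for c in calls])
    _write_tsv(calls_df, out / "strain_calls.tsv", man["hash"], index=False)
    summary = strain_tracking.cohort_strain_summary(calls)
    (out / "strain_summary.json").write_text(
        json.dumps({"manifest_hash": man["hash"],
                    **{k: v for k, v in summary.items()
                       if k != "containment_u_in_v_values"}},
                   indent=2, default=str))
    _stage("straintrack", t0, calls=len(calls),
           shared=summary["n_same_strain"])
    results["strain_summary"] = summary

    (out / "manifest.json").write_text(json.dumps(man, indent=2, sort_keys=True))
    return results


def run_aging(config: RunConfig) -> dict:
    """Age-trend analysis: per-bin alpha diversity and Bray-Curtis
    dissimilarity summaries plus diversity-age Pearson correlations."""
    config.validate()
    man = config.manifest()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {"manifest": man}

    t0 = time.time()
    table, records, _ = _load_or_simulate(config)
    table, _dropped = cohort_io.filter_samples(
        table, config.min_observed, config.min_goods
    )
    records = [r for r in records if r.sample_id in set(table.sample_ids)]
    _stage("load", t0, taxa=table.n_taxa, samples=table.n_samples)

    t0 = time.time()
    alpha = diversity.alpha_diversity_table(table)
    meta = cohort_io.metadata_frame(records)
    alpha = alpha.join(meta[["site", "age"]])
    alpha["age_bin"] = [age_bin(a) for a in alpha["age"]]
    corr_rows = []
    for site in ("uterus", "vagina"):
        sub = alpha[alpha["site"] == site]
        r, p = ordination.pearson_with_age(sub["shannon"], sub["age"])
        corr_rows.append({"site": site, "pearson_r": r, "p_value": p})
    corr_df = pd.DataFrame(corr_rows)
    _write_tsv(corr_df, out / "age_correlation.tsv", man["hash"], index=False)

    per_bin = (alpha.groupby(["site", "age_bin"])["shannon"]
               .agg(["mean", "std", "count"]).reset_index())
    _write_tsv(per_bin, out / "age_bin_diversity.tsv", man["hash"], index=False)

    bc = diversity.pairwise_bray_curtis(table)
    bin_of = dict(zip(alpha.index, alpha["age_bin"]))
    site_of = dict(zip(alpha.index, alpha["site"]))
    rows = []
    for site in ("uterus", "vagina"):
        for lab in AGE_BIN_LABELS:
            sids = [s for s in bc.ids
                    if site_of[s] == site and bin_of[s] == lab]
            if len(sids) < 2:
                continue
            sub = bc.filter(sids).data
            iu = np.triu_indices(len(sids), k=1)
            rows.append({"site": site, "age_bin": lab,
                         "mean_bc": float(sub[iu].mean()),
                         "n_samples": len(sids)})
    bins_df = pd.DataFrame(rows)
    _write_tsv(bins_df, out / "age_bin_bc.tsv", man["hash"], index=False)
    _stage("aging", t0, bins=len(bins_df))
    results["age_correlation"] = corr_df
    results["per_bin_diversity"] = per_bin
    results["per_bin_bc"] = bins_df

    (out / "manifest.json").write_text(json.dumps(man, indent=2, sort_keys=True))
    return results
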