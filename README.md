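# gyntransloc

Analysis toolkit for paired vagina/uterus microbiome cohorts: do the two
communities of the same woman vary in synchrony, and do bacteria translocate
from the vagina to the uterine cavity?

The package implements, as one tested pipeline:

- **Cohort I/O and retention** — taxa x sample count tables (TSV), sample
  metadata, newick trees; samples with < 50 observed taxa or Good's
  coverage C = 1 − F1/N < 0.8 are discarded; relative and per-10⁵
  normalization.
- **Diversity** — Shannon H = −Σ pᵢ ln pᵢ (nats), Chao1
  S_obs + F1²/(2F2), Good's coverage, Bray-Curtis Σ|x−y|/Σ(x+y), and
  unweighted UniFrac (unique / union branch length, presence = count ≥ 1).
- **Ordination & tests** — classical-scaling PCoA (negative eigenvalues
  surfaced, never clipped into coordinates), permutation PERMANOVA with the
  add-one p-value, Pearson age correlations, Benjamini-Hochberg FDR.
- **Discriminatory taxa** — a two-stage LDA-effect-size screen
  (Kruskal-Wallis gate, then a signed log₁₀ effect from a bootstrapped
  linear discriminant on abundances scaled to 10⁶; |score| > 3 flags a
  taxon) and the cross-site direction-of-change concordance statistic.
- **Compositional co-occurrence** — SparCC-style correlation from log-ratio
  variances on site-namespaced joint compositions, bootstrap p-values,
  sign-conservation counts across health groups, and strong pairs at
  |ρ| > 0.4.
- **Source attribution** — a collapsed Gibbs sampler assigning each uterine
  read to the subject's own vaginal sample, a pool of other vaginas, or a
  learned Unknown source; the posterior mean of the vaginal assignment
  fraction estimates the translocation proportion π, compared between
  health groups by Wilcoxon rank-sum.
- **Strain-level containment** — samtools-mpileup parsing, consensus SNP
  calls (depth ≥ 4, alt fraction ≥ 0.8), per-marker coverage-breadth gating
  (> 40% in both samples), and the sharing rule: a species is the same
  strain across sites when all identical SNPs of one site are contained in
  the other, with direction vagina→uterus when the uterine set is contained
  and the vagina holds unique extras.
- **Synthetic cohorts** — a ground-truth generator producing paired
  communities with a known mixing proportion (uterus = π·vagina + (1−π)·
  endogenous), planted group effects with known sign, random trees, and
  marker-SNP pileups with planted shared strains, so every stage is
  testable without downloads.

See `docs/methods.md` for the models, assumptions and numerical choices.

## Worked example

Simulate a 30-subject cohort with a translocation contrast (π = 0.4 in
healthy women, 0.8 under endometritis), attribute every uterine community
to its sources, and run the strain stage:

```python
from gyntransloc import RunConfig, run_translocation

cfg = RunConfig(seed=11, out_dir="demo_out", n_subjects=30)
res = run_translocation(cfg)
print(res["contrast"].group_medians, res["contrast"].p_value)
print(res["pi_mae"])
```

which prints (seed 11):

```
{'healthy': 0.4267208000000001, 'endometritis': 0.8393740000000002} 3.3918213908250945e-06
0.0315
```

The group medians are the per-sink vaginal-origin fractions (paired plus
pooled vaginal sources): the sampler recovers the planted 0.4 vs 0.8
contrast with a mean absolute error of ~0.03, and the rank-sum test
separates the groups at p ≈ 3e-06.  `demo_out/` additionally holds the
per-sink attribution table, the per-species strain-sharing calls (all
planted transfers called vagina→uterus, no unrelated pair ever called
shared), and a `manifest.json` whose hash stamps every output, so the run
is bit-reproducible from its manifest.

The same configuration object drives the health-group contrast
(`run_endometritis_contrast`: filtering → diversity → PCoA/PERMANOVA →
effect-size screen → concordance → co-occurrence) and the age-trend
analysis (`run_aging`).  Every stage is also a console subcommand:

```sh
gyntransloc simulate --subjects 100 --taxa 300 --pi 0.7 --seed 42 --out dir/
gyntransloc filter --table dir/table.tsv --min-observed 50 --min-goods 0.8 --out kept.tsv
gyntransloc straintrack --uterus u.pileup --vagina v.pileup --markers idx.tsv --out calls.tsv
```

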