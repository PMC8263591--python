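# Methods

This package implements the statistical machinery used to ask whether the
uterine and vaginal microbiome of the same woman vary in synchrony, and
whether bacteria move from the vagina to the uterus: community-level
statistics on taxon count tables, mixture attribution of each uterine
community to vaginal sources, and a strain-level SNP-containment test on
marker-gene pileups.  Every stage is exercised against a synthetic
paired-site cohort generator whose ground truth is recorded, so all claims
made by the test suite are claims about recoverable, planted structure.

## Cohort model and normalization

Input is a taxa x samples count table plus metadata linking each sample to a
subject, a body site (uterus or vagina) and a health group (healthy,
endometritis, other).  Shallow samples are discarded when they have fewer
than 50 observed taxa or Good's coverage C = 1 - F1/N below 0.8 (F1 =
singleton taxa, N = reads).  Both cut-offs are strict "<", so a sample
sitting exactly on a boundary is kept; observed taxa are those with at least
one count, with no additional minimum-count threshold.  Downstream analyses
use per-sample relative abundances (columns summing to 1) or counts scaled
to 1e5 per sample; both normalizations are zero-preserving and
rank-preserving, with column sums checked to 1e-9 relative tolerance
(double-precision headroom).

## Diversity

Shannon entropy is reported in nats (natural logarithm) — the convention of
the QIIME-era toolchains this pipeline mirrors; base-2 users should divide
by ln 2.  Chao1 is S_obs + F1^2/(2 F2), falling back to the bias-corrected
S_obs + F1(F1-1)/2 when there are no doubletons.  Bray-Curtis is
sum|x-y|/sum(x+y), computed on relative abundances by default.  Unweighted
UniFrac treats a branch as observed for a sample when any descendant tip is
present (count >= 1, no rarefaction), and excludes the edge above the root,
which belongs to no split of the tip set; the distance is unique branch
length over union branch length.  The implementation is validated against
an independent per-edge enumeration oracle (dendropy) to 1e-10 on random
trees.

## Ordination and tests

PCoA is classical scaling: square the distances, double-center, take the
eigendecomposition, and scale eigenvectors by the square roots of the
positive eigenvalues.  Negative eigenvalues — the signature of a
non-Euclidean dissimilarity — are reported in the result and their axes
dropped; no Lingoes/Cailliez correction is applied by default.  PERMANOVA
uses the Gower-form pseudo-F with full-dataset label shuffles (no strata)
and the add-one p-value (1 + exceedances)/(1 + permutations), so p is never
zero and has resolution 1/(permutations + 1); the default is 999
permutations.  Note that the add-one minimum is attainable only when the
groups are large enough that a permutation recreating the observed split is
improbable.  Type-I error is verified by Monte-Carlo calibration (1000 null
data sets).  Pearson correlations use the two-sided t-based p; the
Benjamini-Hochberg step-up adjustment controls FDR across taxa.

## Discriminatory taxa (LDA effect size)

The screen is a deliberately simplified two-stage variant of the
LDA-effect-size approach, with exactly two flat groups and no
subclass/Wilcoxon stage or cladogram logic.  Stage 1 is a per-taxon
Kruskal-Wallis test at alpha = 0.05.  Stage 2 scales abundances to 1e6 (the
conventional pre-scaling, exposed as a flag), draws 30 bootstrap subsamples
of 2/3 of each class, fits a linear discriminant on the surviving taxa with
the pooled within-class covariance ridged by 1e-6 of its trace on the
diagonal (stabilizing near-singular taxa blocks), and scores each taxon by
the bootstrap mean of 0.5(|Δμ_f| + |u_f| · |uᵀΔμ|), where Δμ is the
class-mean difference and u the unit discriminant axis.  The reported score
is sign(enrichment) · log10(1 + effect); a taxon passes at |score| > 3.0.

One property of the per-million convention worth knowing: the 10^3 effect
gate blocks label-shuffled nulls only when per-taxon mean abundances are
modest (roughly below 1%).  A highly dominant taxon fluctuates enough in
absolute per-million units that a chance Kruskal-Wallis survivor can clear
the gate; the gate is a scale on effect size, not a calibrated test.

Cross-site concordance takes the taxa flagged at either site, computes
Δ_site = mean(disease) - mean(healthy) relative abundance per taxon and per
site, and counts taxa whose two Δ's share a nonzero sign.  Taxa with Δ = 0
at both sites are excluded from numerator and denominator; a one-sided zero
counts as discordant (the conservative reading of "changed in the same
direction").

## Compositional co-occurrence (SparCC)

Cross-site correlation concatenates each subject's uterine and vaginal
taxon vectors into one site-namespaced composition, so the constant-sum
treatment stays coherent; only the uterus x vagina block is reported by
default.  The estimator computes log-ratio variances t_ij = var(log
x_i/x_j) across subjects, solves the sparsity-assumption linear system for
basis variances w (the system matrix is diag(degree) plus the inclusion
adjacency), forms r_ij = (w_i + w_j - t_ij)/(2 sqrt(w_i w_j)) clipped to
[-1, 1], and iteratively excludes the strongest pair above |r| = 0.1 for up
to 10 rounds, stopping early if the system would degenerate.

Fractions are formed in one of two ways.  The deterministic estimator
(`n_inner_iterations=1`) normalizes each subject to fractions and adds a
fixed zero-replacement fraction (1e-6, renormalized), which makes the
estimate *exactly* invariant to per-subject scalar rescaling — the defining
log-ratio property, verified to 1e-9.  The resampling mode (default 20
inner iterations) draws fractions from Dirichlet(counts + 1) per subject
and takes the median estimate; it is depth-aware (deeper samples pin their
fractions more tightly) and therefore only asymptotically scale-invariant.
This is a deliberate departure from the convention of adding the
pseudocount to raw counts in the deterministic path, made so the estimator
satisfies its own invariance.  Bootstrap p-values shuffle every taxon's
values across subjects independently, destroying association while keeping
marginals, with the add-one two-sided rank p over 100 replicates.  A plain
Spearman estimator is provided as a cross-check.  Sign conservation counts
pairs whose correlation keeps a nonzero sign across health groups (zeros
reported separately; the three categories partition the total), and strong
pairs are those with |rho| strictly above 0.4.

## Source attribution (Gibbs mixture)

Each uterine sample (the sink) is modelled as a mixture of known source
environments — the subject's own vaginal sample and a pool of the other
women's vaginal samples in the default per-subject mode, or one pooled
vaginal source — plus an Unknown source whose taxon profile is learned from
the reads assigned to it.  The collapsed Gibbs conditional for a sink read
of taxon t is

    P(z = v | ·) ∝ (m_vt + α_v)/(M_v + T α_v) · (n_v + β)/(n − 1 + V β)

with α_v = 0.001 for known sources, 0.1 for Unknown, and β = 10; chains run
100 burn-in sweeps and retain 25 draws at thinning 10, over 10 random
restarts (the historical defaults of this sampler family, all exposed as
flags since no single setting is canonical).  Source order is canonicalized
internally so permuting the inputs permutes the outputs identically, and a
fixed seed reproduces draws bit for bit.  The inner loop is JIT-compiled
(numba).  Sink rarefaction is available but off by default.  The
vaginal-origin fraction of a sink sums the paired and pooled vaginal
sources: the two overlap compositionally, so the paired source alone
underestimates a planted mixing proportion.  With well-separated sources
and 5000-read sinks the posterior-mean estimate recovers a planted
proportion of 0.7 with mean absolute error below 0.05.  The group contrast
compares per-sink vaginal-origin fractions between health groups with a
two-sided Wilcoxon rank-sum test.

## Strain-level containment

Reads piled against species-specific marker genes give, per sample and
marker, a covered-position set (depth >= 1) and consensus SNPs: a call at
(marker, position, alt) requires depth >= 4 and majority-alternate
frequency >= 0.8.  These thresholds are this package's choice of
consensus-style calling for near-clonal marker data, fully flag-exposed.
The mpileup base-string grammar is handled in full ('.'/',' reference,
explicit letters, '^'+mapq and '$' tokens, '+n/-n' indel runs skipped, '*'
counted toward depth but not alleles); coordinates are 1-based.

A marker is eligible for a subject when its coverage breadth (covered
positions over length — breadth, not mean depth) strictly exceeds 0.4 in
*both* samples of the pair; gating is per marker, not per species.  An
identical SNP is an exact (marker, position, allele) match on eligible
markers — exact allele match is enforced, with position-only matching
available as a flag.  A species is the same strain across sites when the
identical set contains all of one side's SNPs (containment >= 1.0 by
default; a relaxed threshold such as 0.9 is available since real coverage
is imperfect).  Direction is vagina-to-uterus when the uterine set is fully
contained and the vagina holds extra SNPs, and symmetrically; equal
nonempty sets leave direction undetermined.  A species with no SNPs on
either side is reported as "undetermined by absence", not shared; a species
with SNPs on exactly one side has an undefined containment on the empty
side and is not called shared (the vacuous reading would assert direction
with zero evidence).

## Synthetic cohort generator

The generator is the package's study condition, not a tuning dial.  Each
subject's vaginal composition is a Dirichlet draw; the default
`lactobacillus_dominant` mode gives one taxon 70% of the expected mass
(mirroring the Lactobacillus-dominated healthy vagina) while `diverse` is
flat.  The uterine community is pi * vaginal + (1 - pi) * an independent
uterus-endogenous Dirichlet draw; pi is the planted translocation
proportion (the mixture means obey E[u_t] = pi v_t + (1 - pi) u0_t, checked
to three Monte-Carlo standard errors).  Group effects multiply Dirichlet
concentrations by exp(effect), keeping compositions valid by construction;
planted directions are recorded from the exact expected compositions, so
renormalization side-effects are bookkept rather than assumed.  Sequencing
is multinomial at 10,000 reads per sample by default (a desk-scale depth;
real amplicon libraries are an order of magnitude deeper, which only
tightens multinomial noise).  Defaults of 100 subjects, 300 taxa, and a
pi contrast of 0.4 (healthy) vs 0.8 (endometritis) define the standard
synthetic contrast; no published value of pi exists, so these are free
parameters of the benchmark, chosen once.

The marker-SNP generator plants, per species, either a shared strain
(uterine SNPs a subset of vaginal SNPs, with at least one shared and one
vagina-unique SNP guaranteed) or unrelated strains (independent SNP sets
with at least five discordant SNPs per side guaranteed, so full containment
is impossible by construction).  Coverage breadths default to 0.6 (uterus)
and 0.9 (vagina), reflecting the sparser uterine biomass.  The pileup
emitter realizes breadth exactly (covered positions draw Poisson depth
clipped to >= 1), writes alternate alleles at SNP positions at per-read
probability 1 - error, and uses the simple base-string dialect; the parser
nonetheless handles the full grammar.

What the generator does not emulate: chimeras, primer/copy-number bias,
contamination, overdispersion beyond the Dirichlet, within-sample strain
mixtures, indels, and real marker databases.  Passing tests therefore
demonstrate correctness of the statistical machinery on known structure,
not performance on real sequencing artifacts.

## Numerical choices and degenerate inputs

Column-sum tolerances are 1e-9 relative (1e-6 absolute for the 1e5 scale).
Eigenvalues below 1e-12 of the spectral radius count as zero in PCoA.
SparCC basis variances are floored at 1e-12; a degenerate exclusion system
reverts to the previous solution.  All-zero sample columns, empty tables,
vocabulary violations, mismatched namespaces and constant vectors raise
errors naming the offending sample/taxon rather than propagating NaNs.
Ties in the strong-pair ordering break lexicographically by taxon id;
majority-allele ties in SNP calling cannot pass the > 0.5 threshold by
construction.

## Pipeline problem sizes

The orchestrated runs default to 100 subjects x 300 taxa for the
health-group contrast; the cross-site correlation stage restricts to the 50
most abundant taxa per site, keeping the joint log-ratio system
well-conditioned at cohort scale (the operation itself has no such limit).
The translocation run uses 30 subjects for attribution and 10 simulated
subjects x 6 species for the strain stage.  These sizes are the package's
benchmark conditions; all are configuration fields.

## Known limitations

The LDA gate is an effect-size scale, not a calibrated test (see above).
SparCC assumes sparsity of true correlations; dense correlation structure
biases basis variances.  The Gibbs attribution treats known sources as
fixed multinomials (no source uncertainty) and its Unknown source absorbs
any sink taxon missing from the sources, so incomplete source tables
inflate Unknown rather than failing.  The strain rule is single-consensus
per site: within-sample strain mixtures violate its assumptions and are out
of scope.
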