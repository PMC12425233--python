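# Methods

`mscikit` detects transcriptome signatures of meiotic sex chromosome
inactivation (MSCI) in stage-enriched spermatogenesis RNA-seq: count
matrices from testis regions enriched for mitotic (spermatogonia), meiotic
(spermatocyte) and post-meiotic (spermatid) cells, one matrix per species.
This note documents the models, the defaults and why, what the synthetic
generator does and does not emulate, and the numerical choices.

## Differential expression: a transparent NB Wald pipeline

Counts for gene *g* in sample *j* are modelled as negative binomial with
mean `mu_gj = s_j * q_gj` and variance `mu + alpha_g * mu^2`
(`alpha_g >= 0`; `alpha = 0` is Poisson — the dominant RNA-seq convention).

* **Size factors** are median-of-ratios: `s_j = median_g(c_gj / gm_g)`
  with `gm_g` the geometric mean across samples, restricted to genes with
  strictly positive counts everywhere. Note that the reference `gm_g` is
  data-derived, so only *ratios* of size factors are scale-equivariant;
  all downstream quantities depend on the factors only through ratios.
* **Dispersions** are gene-wise method-of-moments on normalized counts,
  `(s^2 - m) / m^2` pooled across stage groups weighted by degrees of
  freedom and floored at `alpha_floor = 1e-8`. There is deliberately no
  shrinkage toward a trend: the pipeline's calibration is then demonstrated
  empirically rather than inherited from a moderation scheme.
* **The Wald contrast** fits, per gene, `log mu = b0 + b1 * 1[group B] +
  log s_j` by iteratively reweighted least squares at fixed dispersion
  (tolerance 1e-8, max 100 iterations, linear predictors clamped at ±30 to
  keep degenerate all-zero groups finite). `log2FC = b1 / ln 2`; the
  standard error comes from the Fisher information at the fit (expected
  information weights `mu / (1 + alpha * mu)`, which coincide with the
  observed information in expectation at convergence); the p-value is the
  two-sided normal tail of `b1 / SE`. Genes with mean normalized count
  below 1 are *untested* (independent filter).
* **FDR** is Benjamini–Hochberg (via statsmodels, with NaN passthrough for
  untested genes). Genes are `down`/`up` when `q < 0.05` with the matching
  sign, else `unchanged`. The 0.05 default is a convention; no specific
  threshold is implied by the underlying study design.

With three replicates per stage the method-of-moments dispersions are
noisy and the Wald test is mildly liberal: across 500 simulated global-null
datasets the pooled p-value distribution deviates from uniform by a KS
distance of about 0.05 (we treat D ≤ 0.10, the scale of known Wald
liberality at this replication level, as acceptable calibration and state
that tolerance up front).

## Enrichment: Yates chi-square against autosomes

For each contrast, genes are tallied per chromosome class (X, NeoX,
Autosome, Dot, Y, Unplaced). Proportions use **all annotated genes of the
biotype** on the class as denominator — not only tested genes — because not
every annotated gene is expressed in the germline and the class-level
proportion is the quantity compared across karyotypes; tested-universe
counts are reported alongside. Each non-autosomal class is compared with
the autosomes in a 2×2 table (regulated vs not) using the Yates-corrected
chi-square `sum (|O - E| - 0.5)^2 / E` (continuity excess clipped at zero),
with the 1-df tail and the conventional star thresholds 0.05/0.01/0.001.
Dot-sized classes (< 100 genes) are flagged low-power.

The Yates correction has a well-known cost: when the expected regulated
count per cell is small (a handful of genes), the test is conservative,
with true type-I error of 1–2% at a nominal 5%. Our null-calibration runs
measure exactly this — the X-down rejection rate across 500 null datasets
is ~1–2%, below nominal, erring in the safe direction. Users comparing
against a nominal 5% band should expect that conservatism whenever the
regulated sets are small.

## X:AA ratios: matched-fraction estimation

Overall-median X:AA ratios are inflated when the X and autosomes differ in
the share of genes expressed at all. The matched-fraction
("filter-by-fraction") estimator avoids this: at TPM threshold `t`
(strictly `> 0`, `> 2`, `> 10`), compute each class's fraction of genes
above `t`, take the minimum `f` across participating classes (three-way
with a neo-X), select each class's top `f` expressed genes with
`k = floor(f*n + 1e-9)` (at least 1; boundary ties broken by gene id so the
minimizing class recovers exactly its above-threshold set), and divide the
median of the X (or neo-X) top set by the autosomal one. The
simple-threshold estimator (median of values above `t`, no matching) is
computed for comparison. Ratios are produced per replicate (that sample's
TPM) and pooled (mean TPM across a stage's replicates); stage comparisons
use the per-replicate values in a Wilcoxon rank-sum test (exact for small
untied samples). The boxplot sampling unit of the original figures is not
stated, which is why both scopes are always emitted.

## Age dynamics

Gene ages are branch labels supplied as input: branch 0 (predating the
subgenus split) = old, branches 1–6 (< 62 My) = new, missing = unknown
(excluded). Per-gene stage values are means across replicates of
`log2(normalized + 1)`; the pseudocount (default 1) is required for zeros
and the normalization defaults to size-factor-normalized counts (TPM is
available as an option; which unit the original figures used is not
stated). Trajectories report mean ± SEM per (age group × class × stage)
with genes as the sampling unit; contrasts (new-X vs old-X per stage,
new-X vs new-autosome per stage, old-X mitosis vs meiosis) use Wilcoxon
rank-sum across genes, matching the very large degrees of freedom implied
by gene-level testing.

## Profiles and QC

Per-gene stage profiles are Z-scored with the population (n-denominator)
standard deviation — a documented convention; with three points the sample
sd is equally defensible. Flat profiles are excluded and reported. K-means
uses k-means++ with 50 restarts and a mandatory seed; `k = 12` by
precedent with earlier spermatogenesis microarray work. Reproducibility QC
is log2 Pearson correlation between samples and sample-level PCA on
centered log2 expression.

## The synthetic generator

`simulate_experiment` emulates the study's *structure*, not its data:

* genes in classes sized like a D. melanogaster genome (X ≈ 15%, dot ≈
  0.6% of genes; neo-X only when configured), log2-normal baselines
  (default mean 5, sd 2 — median ~32 normalized counts with a realistic
  dynamic range), log-normal gene lengths (only used for TPM; counts are
  length-independent for simplicity);
* NB counts (`Var = mu + alpha mu^2`, default `alpha = 0.1`, typical of
  bulk tissue replicates) with log-normal library size factors (sd 0.2);
* an MSCI effect: a configurable fraction of X/NeoX genes shifted by
  `msci_log2fc` during meiosis (scenario default: fraction 0.5 at −1,
  i.e. half the sex-linked genes halved);
* stage trajectories per (class × age group) as log2 offsets;
* **stage impurity**: each dissected region is a mixture of neighbouring
  cell populations, modelled by blending pre-mixture stage means with a
  row-stochastic purity matrix (default rows 0.85/0.15/0, 0.15/0.70/0.15,
  0/0.15/0.85). No impurity estimates exist for the real dissections, so
  these defaults are illustrative of "enriched but not pure", not
  calibrated. Mixing expected means rather than drawing cell labels keeps
  every expectation closed-form.

Because subgroups within a class differ from the baseline only by
multiplicative constants, the class population at any observed stage is a
finite mixture of log-normals, and `analytic_expectations` returns exact
class means and exact population median ratios (the recovery target of the
threshold-0 matched-fraction estimator) by root-finding on the mixture CDF.
The age scenario solves the new-autosome post-meiotic offset from the
purity matrix so that observed post-meiotic means of new-X and
new-autosome genes coincide exactly — post-meiotic convergence is null by
construction, making it a calibration fixture.

What the generator does **not** emulate: length-dependent counts, isoform
structure, GC/mappability bias, correlated genes, cell-level
heterogeneity, and any real annotation. Passing recovery tests therefore
demonstrates that the estimators recover the effects they define under
NB sampling with impurity — not that real libraries satisfy those
assumptions.

## Problem sizes used by the validation runs

The calibration and recovery runs use 5,000-gene genomes (760 X / 4,160
autosomal / 50 dot / 30 Y) with 3 replicates per stage — the study's shape
at a desk-friendly scale — with 500 null datasets, 200 MSCI datasets, 100
age seeds, and a 20,000-gene dataset for the large-n halving check, chosen
so the Monte-Carlo error of each reported rate is a percentage point or
two.

## Known limitations

* No dispersion or fold-change shrinkage; with 2–3 replicates per group the
  Wald p-values are mildly liberal (measured, see above).
* The Yates-corrected enrichment is conservative for small regulated sets.
* Exact joint invariance to rescaling one sample's counts together with
  its size factor does not hold under NB likelihood (the mean-variance
  link sees the raw scale); global factor rescaling is exactly invariant.
* Which side of the willistoni E–F junction carries the dot genes is
  ambiguous in public mappings; it is a `FusionRule` configuration choice
  (default: positions below the junction are dot).
* The ortholog filter takes ortholog relationships as input; it never
  infers them.
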