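# Methods

`famnorm` implements a reference-free pre-processing and evaluation
workflow for Infinium-450k-style methylation arrays in familial designs:
probe/sample QC, seven within- and between-array normalisation strategies
plus empirical-Bayes batch correction, an eight-metric evaluation battery,
and a synthetic-data generator that reproduces the study conditions the
metrics assume. This note records the models, the parameters that matter,
and the design decisions taken where the design was genuinely open.

## Measurement scales

The methylated (M) and unmethylated (U) fluorescence intensities are
summarised as the beta value β = M/(M + U + offset) with offset 100 by
default; the offset regularises the ratio when both signals are near
background. Beta is the biologically interpretable proportion-methylated
scale but is heteroskedastic near 0 and 1, so statistics are computed on
the M value, the base-2 logit m = log2(β/(1−β)), clipped at
β ∈ [ε, 1−ε] (ε = 1e-6) to keep it finite. With the default ε the
representable M-value range is ±19.93; tests that exercise the |m| = 20
boundary pass a smaller ε.

## Quality control

Probes are removed, in this fixed order, when (1) detection p > 0.05 in
more than one sample (a single failing sample is tolerated — the strict
reading of "more than one"), (2) bead count < 3 in ≥ 5 % of samples
(boundary inclusive, the conservative option), (3) they sit on a sex
chromosome (name set {chrX, chrY, X, Y}, any case), removed once and never
re-introduced so that X-inactivation dosage cannot masquerade as signal.
Sample QC flags arrays whose mean detection p exceeds 0.05 but never drops
them silently; the criterion is a deliberate, documented stand-in since no
published rule exists for this step.

## Normalisation methods

All methods are exposed as estimator classes with `fit`/`transform` and a
fitted-parameter record, plus thin `norm_*` functions.

* **Quantile normalisation (QN)** — meth and unmeth intensities are mapped
  per column onto the cross-sample mean of sorted values. Ties receive the
  mean of the reference values spanned by their rank range, so tied
  entries stay tied; untied entries take the reference value exactly,
  which makes the sorted-equality post-condition hold to 1e-9.
* **Stratified QN** — QN of type II probes within each genomic stratum
  (island / shore_shelf / open_sea), then each sample's type I intensities
  are mapped through the stratum's type II reference quantile function via
  mid-rank positions. No background correction. A stratum with fewer than
  two type II probes falls back to the global reference with a warning.
* **SWAN** — per sample and channel, equal-sized random subsets of type I
  and II probes are drawn within CpG-body-count classes {1, 2, 3+} (subset
  size = the smaller type's class size); the mean of the two sorted subset
  vectors is the target; subset probes are assigned the target by rank
  within their type and remaining probes follow by interpolation, with
  additive extension beyond the subset range. The subset draw uses the
  operation's explicit seed.
* **BMIQ** — per sample, a 3-state beta mixture (unmethylated / hemi /
  methylated) is fitted to the type I betas by EM (initialised by splitting
  at 1/3 and 2/3 with method-of-moments parameters; tolerance 1e-4 on the
  log-likelihood, max 100 iterations, fitted on a subsample of up to 5000
  probes for speed). The type II mixture is then fitted with its weights
  tied to the type I fit and initialised at it: the state composition is
  biological and shared between chemistries, only the component shapes
  differ technically. Type II probes are assigned to states at the
  weighted-density crossing points (so the states are intervals and the
  overall map is monotone), the U state is remapped through the left-tail
  CDF pair, the M state through the right tail, and the hemi state is
  stretched affinely between the transformed state boundaries so its range
  abuts the transformed U and M ranges. Type I values are untouched.
* **noob** — out-of-band intensities (type I probes read in the opposite
  channel) are pure non-specific background; a truncated-normal MLE
  (truncation at the 95th percentile guards against signal contamination)
  gives per-sample, per-channel background (μ, σ), the exponential signal
  mean follows by moments, and every intensity is replaced by the posterior
  expected signal under the normal-exponential convolution plus offset 15,
  guaranteeing positive corrected intensities. Dye-bias equalisation is out
  of scope (no red/green decoding in this data model).
* **dasen** — per sample and channel, each probe type's background level is
  the mode of a Gaussian-KDE fit to the low-intensity half; type I is
  shifted so its background matches type II; meth and unmeth are then
  quantile-normalised across samples within probe type, with flooring at
  1 a.u. applied after QN so the shared reference (and sorted equality) is
  preserved.
* **Functional normalisation** — control-probe summaries (per-type mean and
  sd, plus out-of-band means) are standardised and reduced to their first
  two principal components; within each stratum (channel × probe type) the
  per-sample quantile functions at 500 anchors are regressed on the PCs and
  the fitted technical deviations subtracted (PC scores are centred, so the
  across-sample mean quantile is preserved); monotonicity is enforced by a
  running maximum and probes are mapped through the adjusted quantile
  functions.
* **ComBat** — parametric empirical-Bayes location/scale batch adjustment
  on M values, following the standard algorithm: batch-size-weighted grand
  mean and pooled variance, per-probe per-batch location γ̂ and scale δ̂²,
  normal/inverse-gamma priors with method-of-moments hyperparameters,
  iterated to relative tolerance 1e-4. Output agrees with Bioconductor
  `sva::ComBat` to ~1e-5 on a shared fixture (a test runs the R oracle).
  Batches come from the sample sheet; a single batch is an identity with a
  warning, a singleton batch is rejected. `parametric=False` returns the
  unshrunk estimates (not sva's nonparametric KDE variant). Note that the
  EB-shrunk adjustment preserves the weighted grand mean only
  approximately; exact preservation holds for the unshrunk fit.

## Evaluation metrics

1. Per-sample beta densities on a 0.005 grid (Gaussian kernel, Silverman
   bandwidth, renormalised to unit mass on [0,1]) and the two-sample KS
   distance between pooled type I and type II betas.
2. Classical MDS of samples on the 1000 most-variable M-value rows
   (double-centred squared Euclidean distances, top-2 eigenvectors scaled
   by √eigenvalue, sign fixed by the first nonzero loading).
3. One-way ANOVA of batch (or family) on PC1 of the 1000 most-variable
   beta rows.
4. Replicate MAD: median over probes of |m₁ − m₂| per technical replicate
   pair; groups larger than two are evaluated pairwise.
5. DMRSE: imprinted (iDMR) probes are hemi-methylated with expected
   β = 0.5; each probe row is centred at its cross-sample mean, the per-
   sample mean deviations are taken, and their n−1 standard deviation is
   divided by √(#iDMR probes). Centring at the probe mean (not at 0.5)
   makes this a between-sample dispersion measure; deviation-from-0.5 is
   a different, level-sensitive diagnostic.
6. Hierarchical clustering on all probes (Euclidean, complete linkage; the
   paper names only the distance), cut at the number of batches, scored by
   adjusted Rand index against batch labels (≈0 desired post-correction).
7. meQTL association: stage 1 fits methylation at the target probe against
   a random effect with covariance 2K (K = IBS kinship from genome-wide
   genotypes) by profiled ML over the variance ratio on the eigenbasis of
   2K (bounded 1-D search, tolerance 1e-8, ridge 1e-8 on the
   decomposition; a flat profile ties toward the no-heritability model so
   the identity-kinship case reduces exactly to plain regression); the
   environmental residuals are then regressed on each SNP's additive
   dosage with two-sided t-tests and Bonferroni adjustment over the 2-Mb
   window. The kinship matrix must come from genome-wide markers: building
   it from the test window itself absorbs the association under test.
8. Age EWAS: per-probe linear regression of M values on age (beta values
   switchable); λ = median(observed −log10 p) / median(expected −log10 p)
   with expected quantiles at (i−0.5)/n. Because λ is median-based, a small
   fraction f of even overwhelming signals can only raise it to
   log10((0.5−f)/(1−f))/log10(0.5) — about 1.08 at f = 5 % — so genuine
   inflation above 1.2 requires broad drift, which is what aging produces.

## Synthetic data generator

The generator reproduces the familial study design: 45 unique individuals
in 4 three-generation pedigrees plus 6 technical replicate pairs split
across 3 batches (51 arrays), ages uniform on 23–89, 10 000 probes (72 %
type II; strata 31/33/36 % islands/shores/open sea; 227 iDMR probes forced
hemi-methylated at β = 0.5; 2 % sex-chromosome probes).

Biology: per-probe methylation states are drawn with stratum-dependent
composition (islands 65/15/20 % unmeth/hemi/meth, shores 40/20/40, open sea
20/12/68) and state centres from Beta(2,10)/Beta(10,10)/Beta(10,2); a
family random effect on the M scale has covariance 2Kσ²_fam (σ_fam = 0.5 M,
K from the pedigree by the standard kinship recursion); 35 % of probes
drift weakly with age (slope sd 0.012 M/yr); one bright hemi-state probe
carries a cis-meQTL of 0.8 M per allele, with 50 window SNPs in AR(1) LD
(ρ = 0.7, causal MAF 0.4, HWE) and 500 genome-wide background SNPs
gene-dropped through the pedigree for IBS kinship.

Technical layers: per-probe batch location shifts γ ~ N(0, 1 M), per-batch
noise scale δ ~ Gamma(40, 1/40), a common per-batch shift (sd 0.3 M, the
processing-date effect), a per-array offset (sd 0.15 M, e.g. conversion
efficiency), and technical noise (sd 0.2 M). Intensities follow
signal-plus-normal-background: probe affinity = 800 + Exp(2200) a.u.
(mean 3000; the floor represents vendor-QC'd probe brightness, with
explicit planted failures at 1.4 % of probes representing the dim tail),
background N(500 + batch + array shift, 100) per measurement, type II betas
compressed toward 0.5 by c = 0.8 before intensity synthesis, out-of-band
and negative-control intensities drawn from background alone. Detection p
is the upper tail of M+U under the per-sample negative-control fit; bead
counts are 3 + Poisson(12) with 0.4 % forced low. Replicate columns share
the biological layer, redraw every technical layer, and land in different
batches. All randomness flows from named sub-streams of one seed, so
outputs are bit-reproducible and enlarging one stage does not perturb
others.

Calibration: the QC-failure fractions match the published removal
fractions of this array generation (~1.4 % detection, ~0.1 % bead count);
the batch and drift magnitudes were set so the raw data reproduce the
qualitative study conditions (raw PC1-batch ANOVA p ≪ 0.01, raw DMRSE of
order 10⁻³, raw λ just below 1 rising to ~1.4 after correction).

What the generator does not emulate: realistic manifest coordinates,
cross-hybridising probes, SNPs in probe bodies, red/green dye chemistry
(and hence dye bias), and stratum-dependent probe-type composition.
Passing tests therefore demonstrate internal consistency and correct
recovery of planted structure under this model, not performance on real
arrays.

## Problem sizes used in the validation battery

The default simulation (10 000 probes × 51 arrays) is used for the
multi-seed sweeps (20 seeds for batch-removal and metric-ordering
properties, 50 for meQTL power, 20 for the null calibrations), 4000 probes
for the 15-branch pipeline ranking runs, and 18 000 probes for the
background-recovery check (~5000 out-of-band draws per channel); unit
tests run an 800-probe, 21-array configuration. These sizes were chosen so
the full battery completes in a few minutes while keeping every estimate's
sampling error well inside the asserted margins.

## Known limitations

* SWAN and the quantile-family methods align intensity marginals but
  cannot restore the probe-level (M,U) dependence structure, which caps
  how far they can align the type I/II beta distributions in this
  generator (~50 % KS reduction); BMIQ, operating on beta directly, is not
  so capped.
* After ComBat, batch means and scales are equalised per probe for every
  upstream normalisation, so batch-signal metrics barely discriminate
  among corrected branches; the discriminating metrics in practice are
  replicate MAD and DMRSE.
* The two-stage meQTL procedure (LMM residuals, then OLS) is the study's
  procedure, not a joint mixed-model scan; with strong per-probe batch
  noise its raw-data power is materially below its post-correction power.
* BMIQ's EM can hit the iteration cap on small probe sets; the last
  iterate is used and a warning raised.
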