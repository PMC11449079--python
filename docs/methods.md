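# Methods

## The ordering problem and its assumptions

A population of near-isogenic plants harvested at one chronological age is
spread over a window of developmental ages. The goal is to recover the
ordering of individuals along that latent axis from expression alone, with a
sample size (tens of plants) far below what unsupervised single-cell
trajectory methods require. The method leans on one structural assumption:
across the developmental transition of interest, most differentially
expressed genes change *monotonically* with biological age. Under that
assumption, any sufficiently large random set of DE genes — normalised to
[0, 1] and oriented to rise with age — votes for the same sample ordering
through its summed expression, and agreement between orderings built from
disjoint gene sets is a direct internal check of the assumption.

The consensus construction is deliberately simple and fully deterministic:

1. Per DE gene: z-score expression across samples (population SD), truncate
   at ±3, min–max rescale to [0, 1]; downregulated genes become 1 − x.
2. Partition genes at random into `n_groups` (default 100) balanced groups.
3. Each group orders the n samples ascending by Σᵢ xᵢ,ⱼ,ₖ (ties broken by
   sample identifier).
4. Each sample's *modal position* across groups is computed (mode ties take
   the smaller position). Positions 1..n are then filled in order: a claimed
   position goes to the claimant with the smallest mean rank across groups;
   unclaimed positions are filled at the end by remaining samples in mean-
   rank order. The result is always a permutation, and when modes are
   uninformative it degrades to mean-rank ordering.
5. The ordering is oriented so bolted plants sit late; positions are mapped
   to [0, 1] as (rank − 1)/(n − 1). No calendar units attach to this axis.

The modal-assignment rule in step 4 resolves collisions the bare
"most common predicted position" idea leaves open; it is a design choice of
this package, made for determinism, not a claim about any other
implementation.

## Smoothing and the AUC timing statistic

Expression over pseudotime is smoothed per gene with cubic B-splines
(clamped, equally spaced interior knots on [0, 1]) minimising
‖y − Bc‖² + λ·c′Pc, where P is the exact Gram matrix of basis second
derivatives (2-point Gauss–Legendre per knot span; exact because the
integrands are piecewise quadratic). This is a linear smoother, so
GCV = n·RSS/(n − tr H)² is available in closed form; one (basis size, λ)
pair is chosen to minimise GCV summed over all genes, and the spline
machinery is validated against an explicit leave-one-out oracle in the
tests. Degenerate fits (n − tr H ≤ 0) are flagged and rejected. Defaults:
basis sizes {8, 12, 16, 20, 24}, λ ∈ 10⁻⁶…10² (9 log-spaced values) —
declared grids, configurable, since no canonical grid exists.

Genes are then screened three ways:

- **Fit quality**: the k genes with smallest GCV are retained
  (default k = 4000; ties at the boundary break by gene identifier).
- **Spikiness**: genes with range/IQR > 4 (IQR = 0 counts as infinite) are
  dropped; a handful of extreme samples otherwise dominates the fit. The
  threshold 4 is a package default: a uniform ramp scores 2, a
  one-sample spike scores ∞.
- **Monotonicity**: the derivative of the [0, 1]-rescaled curve is
  evaluated on a 201-point grid; values within ±10⁻³ are zeroed, and the
  gene is monotone if the surviving signs are all one sign (or none, in
  which case the endpoint rule sign(f(1) − f(0)) fixes the direction).
  The tolerance absorbs numerical ripple without admitting genuine
  non-monotonicity; monotonicity is assessed on the rescaled curve so the
  tolerance has a common meaning across genes.

Each monotone gene is summarised by the **AUC**: the exact integral (via
the spline antiderivative) of its rescaled curve for decreasing genes, of
1 − curve for increasing genes. Both conventions make small AUC mean "the
change happens early in pseudotime". Term-level timing contrasts use
Kruskal–Wallis on AUC values grouped by annotation term (terms restricted
to comparable annotated-gene counts), followed by an all-pairs Nemenyi post
hoc with the χ² approximation and a compact letter display at corrected
p < 0.01. The Nemenyi test and the shape-based distance/k-shape-style
clustering used for curve families are implemented in-package and validated
by null-calibration, power, and brute-force-lag tests.

## Differential expression

With ~68 biological replicates per group, a per-gene two-sided Mann–Whitney
U on CPM is used; no between-sample scaling beyond CPM is applied because a
majority of the transcriptome is expected to shift, which breaks the
assumptions of TMM-style normalisation. The exact null is enumerated when
both groups have ≤ 8 samples and no ties (the cutoff is a tractability
choice, configurable); otherwise the normal approximation with tie and
continuity corrections applies. BH controls FDR; genes are classified
up/down at adjusted p < 0.05 and |log₂FC| > 0.1, with
log₂FC = log₂((m₁ + c)/(m₀ + c)) and pseudocount c = 0.5 CPM — the
pseudocount keeps zero-mean genes finite while perturbing large means
negligibly, and is configurable because no canonical choice exists.

## Trait prediction

Elastic-net linear models (biomass, leaf area) and elastic-net-penalised
logistic models (bolting) are trained on z-scored expression under a tiered
scheme: outer leave-one-out CV; inner 5-fold CV per training set selecting
penalty strength (default solver path for linear models; 10 C values for
logistic) and l1_ratio from {0.1, 0.5, 0.7, 0.9, 0.95, 0.99, 1.0}. Because
l1_ratio controls variable selection, a single value — the mode across
outer folds, ties to the smaller (more ridge-like) value — is then fixed
and all folds are refit, making coefficient vectors comparable; consensus
predictors are genes with nonzero median coefficient across folds.

Standardisation statistics are recomputed inside each outer training fold
by default, so a held-out sample's measurements never reach its own model;
a `standardize="global"` compatibility mode scales once on the full matrix.
Note one structural coupling: the shared modal l1_ratio is chosen from all
folds, so the *refit* predictions are not fold-independent — the per-fold
first-pass predictions are, and the leakage test targets those.

## Variant association and network filtering

Genotypes are encoded as alternate-allele dosages (0|0→0, 0|1 and 1|0→1,
1|1→2) after call-level QC: calls with GQ < 40 become missing, variants
called in < 80 % of samples are dropped, and — since no imputation is
performed — variants still incomplete after QC are dropped with a count.
All-heterozygous variants are removed and a MAF ≥ 0.05 floor applies
(boundary inclusive). Dosages are correlated with pseudotime rank (any
affine transform of position gives identical |r|) or continuous traits;
|Pearson r| > 0.5 flags candidates, and constant-dosage variants are
reported as undefined, never selected. Binary sample subgroups, where
needed, come from the sign of the first principal component of the centered
dosage matrix — one admissible definition among several; subgroup–
expression tests are per-gene linear models of log₂(TPM + 1) on the label
(algebraically the pooled-variance two-sample t-test), BH-adjusted.

Edge lists from any network-inference method are filtered sequentially:
weight ≥ 10⁻¹⁰, then the top 5 % by weight with the percentage base taken
*after* the weight floor (the sequential reading; a `top_base="pre"` flag
exposes the alternative), then intersection with a TF-binding prior.
Cutoff ties break by (weight desc, regulator, target).

## The synthetic population

The simulator emulates the study design, not the raw data: 68 plants with
latent ages uniform on (0, 1) (a bimodal option exists but is off by
default — the true age distribution of such populations is not
characterised, so uniform is the neutral choice); 2000 genes of which 65 %
decrease, 25 % increase and 10 % are flat, mirroring the observed excess of
downregulated genes; trajectories are logistic sigmoids
amplitude·σ((a − t₀)/w) with switch times t₀ ∈ (0.15, 0.85) and widths
w ∈ (0.05, 0.2) (sharp to gradual), lognormal amplitudes
(log-mean 3, log-SD 1, i.e. typical expression ≈ 20 in TPM-like units);
multiplicative lognormal noise (SD 0.3 on the log scale) and 5 % dropout
emulate biological and technical scatter. Bolting is age > 0.66, so about a
third of plants have bolted at harvest. Biomass (mg-like) and leaf area
(mm²-like) are linear in age (slopes 120 and 220, noise SDs 15 and 30 —
chosen so age explains most but not all trait variance). Twenty of 200
variants are causal: dosage 2·1(age > 0.66) flipped with probability 0.05
(making |r| > 0.5 selection nontrivial but recoverable); the rest are
Binomial(2, f) with f ~ U(0.1, 0.9).

What the simulator does **not** model: library-size or composition effects,
isoform structure, count noise (values are continuous intensities),
batch/spatial effects, linkage between variants, or non-monotone
(transient) expression programs beyond flat genes. Passing tests therefore
demonstrate that the algorithms recover truth *under the stated generative
assumptions* — monotone trajectories, independent noise — not that real
populations satisfy those assumptions; the gene-half agreement check is the
in-data diagnostic for the monotonicity assumption.

## Numerical and engineering choices

- All randomness flows through `numpy.random.default_rng`; the pipeline
  derives per-stage seeds from one global seed via `SeedSequence` spawn
  keys, so stages can be rerun independently and reruns are bit-identical.
- z-scores use the population (ddof = 0) standard deviation throughout.
- Genes that are constant, or constant after clipping, are excluded from
  normalisation with a warning rather than mapped arbitrarily.
- Degenerate inputs error loudly and early: empty groups, single-class
  traits, constant measures, zero-norm series, non-permutation rank rows.
- Test problem sizes (populations of 68 plants with 300–2000 genes, ten
  seeds for stochastic claims) are chosen to exercise the study-scale
  geometry while keeping the default suite fast.

## Known limitations

- The consensus ordering is transductive: it orders the fitted samples and
  does not place new samples on an existing axis.
- Pseudotime positions are ranks rescaled to [0, 1]; distances along the
  axis are not calibrated to time, so AUC values order events but do not
  date them.
- The k-shape-style clustering uses uncentered normalised cross-correlation
  consistent with the package's shape distance; other implementations
  z-normalise series first and can differ at the margin.
- With very few DE genes (tens), group sums are noisy and the consensus
  degrades; the gene-half agreement diagnostic exposes this.
- The logistic LOOCV is the slowest stage (saga solver over the C ×
  l1_ratio grid per fold); runtime grows quickly past a few hundred
  features.
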