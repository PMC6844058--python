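# Methods

`methdissect` estimates the cell-type composition of bulk DNA methylomes
without a full reference panel. The approach is *semi*-reference-free:
candidate marker regions are learned from the data (read-level bipolar
methylation), condensed into representative loci by co-methylation
analysis, and the bulk methylation matrix over those loci is factorized
into latent methylation components (LMCs) and mixing proportions. This
note records the models, the numerical choices, and what the synthetic
experiments do and do not demonstrate.

## 1. Read-level segments and pCSM candidates

The unit of observation is a 4-CpG *segment*: four consecutive called
CpGs within a single sequencing read, summarized as a 4-bit pattern.
Four sites are used because strand-asymmetric ("hemi") methylation,
which confounds single-CpG signals, is vanishingly rare across four
neighboring CpGs; a fully methylated or fully unmethylated 4-bit pattern
therefore reflects the state of the cell of origin rather than
measurement noise.

Conventions:

- Coordinates are 0-based half-open; CpGs from both strands collapse to
  the forward-strand C (symmetric CpG methylation assumed). A segment's
  genomic span runs from the first C to one past the last G
  (`last position + 2`).
- "Consecutive" means consecutive *called* CpGs in the read: an uncalled
  intervening CpG breaks adjacency, because patterns are read-derived.
- In single-cell mode the unit is a cell; multiple reads of one cell over
  a segment are reduced by per-site majority vote, and a pattern is kept
  only if all four sites resolve (ties drop the site). In bulk mode the
  unit is the read itself.
- Filters: coverage ≥ 10 units, autosomes only, and no overlap with a
  user-supplied blacklist (imprinted regions, which mimic cell-type
  signal through allele-specific methylation). The blacklist argument is
  mandatory — an explicitly empty set is accepted, a forgotten one is an
  error.

A segment is a **pCSM candidate** if at least one unit shows `1111` and
another `0000` — the bipolar signature of a mixture of epigenetically
distinct cell populations.

## 2. Bipolarity test

Per-unit levels (methylated sites / 4) of a candidate are modelled as a
beta mixture: one component under homogeneity, two (hypo- and
hypermethylated subsets) under bipolarity. The test statistic is the
likelihood ratio Λ = 2(ll₂ − ll₁).

**Observation model.** Levels out of m sites are fitted with a
beta-binomial likelihood (latent beta level, binomial m-site sampling);
continuous levels use the beta density on levels shrunk into the open
interval by ε = 1/(2·4) = 0.125 at the boundaries. The count model
matters: on grid data a continuous density lets a mixture component
collapse onto a single grid atom with unbounded likelihood, which makes
the bootstrap null heavy-tailed and destroys power. The bounded
beta-binomial pmf removes the degeneracy.

**Shape constraint.** All beta shapes satisfy a, b ≥ 1 (no U-shaped
densities). A single U-shaped beta is observationally equivalent to a
two-point bipolar mixture, so without the constraint the null can absorb
exactly the signal the test looks for. Under the constraint, a
homogeneous population is unimodal or J-shaped and boundary-concentrated
bimodality must be carried by the mixture. Total concentration a+b is
additionally capped at 10⁴, preserving the component mean.

**Fitting.** EM with weighted method-of-moments updates for the shapes
(fast and stable at per-segment sample sizes); log-likelihoods are
exact. Initialization: a mean-threshold split plus random splits (2
restarts by default); the degenerate equal-components solution is always
a candidate, so ll₂ ≥ ll₁ holds by construction. The per-segment RNG
seed derives from the genomic key (CRC32), making results independent of
processing order.

**Calibration.** Mixture-order LRTs are non-regular, so the default
p-value is a parametric bootstrap under the fitted one-component null
(200 replicates; beta draw, then binomial site resampling for count
data). Observed and replicate statistics use the *identical* fitting
procedure — asymmetric optimization effort between the two arms is a
subtle and serious miscalibration. The bootstrap is sequential
(Besag–Clifford): sampling stops once 10 exceedances accumulate, which
prices clearly-null segments at a quarter of the full cost without
biasing the p-value. A chi-square(df = 2) approximation is available for
ranking but is not used for calls. The replicate count sets the p-value
floor (1/(B+1)); an analysis whose multiple-testing cutoff approaches
that floor should raise `n_boot` (the planted 100-of-1000 benchmark uses
500).

A coverage cap (`max_test_units = 60`, deterministic subsample) bounds
the cost of very deep segments; the test's power is saturated well below
the cap at the effect sizes of interest, and subset assignment still
uses all units.

**Calling.** Candidates are tested; Benjamini–Hochberg adjustment runs
over tested candidates only. A segment is pCSM when the hard-assignment
subset means differ by more than 0.30 and the adjusted p-value is below
0.05. Non-candidates are never tested but still receive a subset split
so that their methylation difference is reported; homogeneous segments
(a single subset) get a difference of zero.

**Bulk mode.** Read patterns are clustered by a Dirichlet-process
mixture of product-Bernoulli components (collapsed Gibbs, concentration
1.0, Beta(1,1) site base, 500 sweeps / 100 burn-in, highest-posterior
sweep kept). Clusters are reduced to hypo/hyper groups at mean level
0.5, and the same LRT machinery on read levels supplies the p-value.

Overlapping (by default also bookended) pCSM segment spans are merged
into non-overlapping pCSM loci.

## 3. Co-methylation modules and eigen loci

Whole-genome bisulfite coverage is too shallow to use every pCSM locus
as a deconvolution feature, so loci are grouped by co-methylation across
a collection of methylomes and each group is represented by its most
informative members.

- Loci are first split into hypo/mid/hyper groups by k-means (k = 3) on
  their profiles.
- Within each group, a signed weighted network is built:
  a_ij = ((1 + cor_ij)/2)^β with Pearson correlation across samples
  (pairwise-complete on the pre-imputation mask; pairs with fewer than
  two shared samples fall back to zero). The soft power β is the
  smallest one whose connectivity distribution reaches scale-free-fit
  R² ≥ 0.8 (signed: anti-scale-free fits score zero), else the argmax.
- Topological overlap (TOM) similarity, average-linkage clustering of
  the TOM dissimilarity, fixed-height cut at 0.995 of the dendrogram
  height. Branches under `min_module_size = 30` are absorbed into the
  best-correlated large module when that correlation exceeds 0.75,
  otherwise pooled as the unassigned module 0. The fixed-height cut with
  absorption stands in for dynamic hybrid tree cutting; its parameters
  are exposed.
- **Eigen loci:** per module, PCA on the centered samples × loci
  submatrix; PC1's sign is fixed to correlate positively with the module
  mean profile; the top ⌈fraction·|module|⌉ loci by |PC1 loading| (10%
  by default) represent the module. Modules under 10 loci keep all
  members (warned). PC1's variance explained is logged as a diagnostic.

Missing entries are handled at matrix construction: loci covered in
fewer than `min_samples_covered` samples are dropped, the rest are
imputed with the locus mean and flagged; correlation uses only observed
entries.

## 4. Constrained, regularized NMF

The loci × samples matrix N over the eigen loci is factorized as
N ≈ W·H with W ∈ [0,1]^(loci×k) (LMC methylation profiles) and H with
columns on the probability simplex (mixing proportions), minimizing

    ‖N − W·H‖²_F + λ·Σ_ij W_ij (1 − W_ij).

The penalty is concave, vanishes exactly at {0,1}, and pushes LMC
profiles toward biologically plausible binary methylation states. It is
the quadratic realization of "regularize toward binary"; no
bit-compatibility with other implementations is claimed.

Alternating minimization:

- **H-step:** exact simplex-constrained least squares per sample column
  via a primal active-set QP (k is small). Normalizing an NNLS solution
  is *not* the least-squares optimum on the simplex, hence the exact QP.
  Columns are feasible at every iterate, not only at convergence.
- **W-step:** exact cyclic coordinate descent on each row's
  box-constrained quadratic. The penalty enters the curvature
  (G_jj − λ); when a coordinate turns concave the better of the {0,1}
  endpoints is taken. Updates are vectorized across rows.

Both steps are exact blockwise minimizations, so the objective trace is
non-increasing (asserted in tests at every iterate via a callback).
Default 10 restarts (W initialized from randomly chosen observed sample
columns plus jitter, H flat at 1/k; one seed stream per restart), best
final objective kept. For k = 1, λ = 0 the factorization reduces to the
closed form H = 1, W = row means, which the solver reproduces to 1e-10.

**Model selection.** Cross-validation holds out *loci*: the model is
fitted on training rows, held-out rows are regressed onto the fitted H
under the box constraint, and the mean squared reconstruction error is
recorded per (k, λ). Reported selections: the argmin, the
one-standard-error choice (smallest k, then λ, within one SE of the
minimum), and the curve's elbow (largest k preceded by an error drop
exceeding 5% of the total range) — the elbow is the right summary when
the tail is flat but essentially noiseless, where both the argmin and
the 1-SE rule drift to the largest k. Holding out samples instead of
loci is the main alternative; with ~100 synthetic samples and few loci
per fold it discards more signal and is not implemented.

**Matching.** LMCs are assigned to reference profiles by mutual-best
Pearson correlation; ties (within 1e-12) are ambiguous and stay
unmatched, as do constant columns (warned).

## 5. Synthetic data

The generator builds the full study design and is first-class, tested
code.

- **References** pool labelled single-cell call counts per type:
  level = Σ methylated / Σ total, with per-type coverage retained.
- **Mixtures:** proportions drawn Dirichlet(1,…,1) — uniform on the
  simplex, so every type has the same marginal — or supplied as a
  matrix. Mixing is coverage-weighted in level space,
  level = Σ_t p_t c_t m_t / Σ_t p_t c_t, reflecting that deeper
  references contribute more reads at a locus; with equal coverage this
  is the plain convex combination, and mixtures always lie inside the
  reference envelope. Optional binomial resampling at a stated depth
  adds read-sampling noise.
- **Planted single-cell data:** each locus carries 4 CpGs. A fraction
  `frac_csm` (default 0.2) of loci receives a planted type split — a
  random proper subset of types at Beta(9,1) levels, the rest at
  Beta(1,9), redrawn until the group means differ by > 0.3; the
  remaining loci share one Beta(0.3,0.3) level across all types (the
  U-shape mimics the hypo/hyper concentration of real methylomes).
  Every cell contributes `depth` (default 1, matching shallow
  single-cell coverage) reads per locus with Bernoulli site calls at its
  level. Full truth tables (CSM flags, hyper types, per-type levels) are
  returned. Fixed seeds give byte-identical output.
- **hVar-CpG baseline:** top-n sites by sample variance (ties by
  coordinate order), the standard highly-variable-site feature set the
  eigen-locus approach is compared against.
- **Scoring:** RMSE between matched LMC and reference profiles,
  √(Σ(mᵢ−m̂ᵢ)²/N); MAE of proportions, Σ|pᵢ−p̂ᵢ|/n_types with unmatched
  types estimated as zero — the denominator is the full type count
  (16 reproduces the canonical sixteen-type form), so failing to
  recover a type is penalized, not ignored.

**What the synthetic experiments show.** The default end-to-end
benchmark (5 types, 200 cells, 5,000 loci, ~6 minutes) recovers all five
types with proportion MAE below 0.01. It exercises every pipeline stage
against known truth, but its cells cover every locus, its types are
well-separated and equally abundant, and its noise is pure binomial
sampling. Real single-cell methylomes have sparse, biased coverage,
correlated cell types, rare populations below the detection limit, and
bisulfite-conversion artifacts — none of which the generator emulates
(deliberately: conversion failure and chimeric reads are out of scope).
Passing these tests validates the machinery, not performance on any
particular tissue.

## 6. Feature enrichment

Loci are compared against genomic feature sets (promoters, CpG islands,
shores/shelves derived by 2 kb flanking with parent and island bodies
subtracted, repeats, histone peaks) by hit-based fold enrichment: the
fraction of loci intersecting a feature (≥ 1 bp, each locus counted
once) divided by the mean fraction over 100 random length-matched
placements on the autosomes outside the blacklist. Empirical confidence
bounds come from the per-draw control fractions; a feature never hit by
controls yields an infinite, flagged fold.

## 7. Numerical and degenerate-input policy

- Beta EM: variance floored at 1e-6; means clipped to [1e-4, 1−1e-4];
  LRT below 1e-8 is treated as zero (p = 1). Constant-level segments are
  never significant.
- Simplex QP: 1e-12 ridge on the Gram matrix; singular KKT systems fall
  back to least squares; feasibility tolerances 1e-12.
- k-means empty clusters trigger reseeded restarts (max 10).
- Zero-variance loci are rejected before network construction with an
  explicit error.
- `rmse` requires equal-length non-empty vectors; `select_hvar_cpgs`
  warns and truncates when more sites are requested than exist.
- All stochastic stages accept one named seed; per-segment and
  per-restart streams are derived deterministically from it.

## 8. Problem sizes in the shipped experiments

The shipped tests and the reproduction script run entirely on generated
data at desk scale: 1,000-read extraction oracles; 1,000-segment planted
calling benchmarks; 1,000-replicate type-I simulations; 20–60-locus
factorization oracles; a 300-locus/16-reference/100-mixture study; and
the 5-type/200-cell/5,000-locus end-to-end benchmark. These sizes were
chosen so the full suite completes in minutes while every stage still
operates in its intended regime; the library itself has no scale-specific
constants beyond the documented defaults.
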