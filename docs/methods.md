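# Methods

## Box-counting fractal dimension

The estimator covers a 3D binary object with grid-aligned cubes of integer
side r, counts non-empty cubes N(r) for r = `r_max`..`r_min` (default
10..2 voxels, nine sizes), and fits ordinary least squares of log₂N on
log₂(1/r). The reported FD is the slope over the contiguous window of at
least `min_window` = 4 points with the highest R²; ties on R² (compared at
1e-12 resolution) prefer the longer window, then the window containing the
larger box sizes. The base of the logarithm cancels in the slope; the
intercept is base-2 specific.

Numerical/procedural choices:

- **Anchoring.** Boxes tile from the array origin with no offset search;
  partial boxes at the far faces count when non-empty. Consequence: N(r)
  is *not* guaranteed monotone in r (a box size aligned with the object's
  structure can need fewer cubes — the Menger sponge needs 400 boxes at
  r = 9 but 637 at r = 10). The minimal-covering definition is monotone;
  the anchored estimator trades that for simplicity and speed.
- **Region extraction.** A labeled region is binarized and cropped to its
  tight bounding box before counting (`crop=False` keeps the full grid), so
  the estimate is object-relative, not field-of-view-relative.
- **Degenerate inputs.** Empty volumes are rejected; a series whose counts
  are all equal (single-voxel objects) has no defined slope and is
  rejected; a window with zero variance in log N gets R² = 0 so it can
  never beat an informative window.
- **Accuracy envelope.** The r = 10..2 schedule carries staircase noise
  from the ceil-tiling of finite objects: a 64³ solid cube estimates 2.95
  (true 3), a 64×64×1 slab 1.97 (true 2), a level-4 Menger sponge 2.81
  (true 2.727). Small objects (≲12 voxels across) are biased low by several
  tenths; cortical regions at ~1 mm voxels are comfortably larger. On small
  irregular blobs a best-R² sub-window can also overshoot 3 by a few
  tenths; the sanity band used in tests is [−0.1, 3.6].

## Structural covariance network

Edges are across-subject Pearson correlations of regional FD (Spearman is
available). Proportional thresholding ranks the 2278 unique pairs and keeps
the top `floor(0.2 × 2278)` = 455 strictly positive values; negatives and
the diagonal are always dropped, ties at the cutoff break by value then
(row, col) order. Both the weighted matrix (used by modularity) and the
binary adjacency (used by degree-based metrics, which count links) are
carried. No covariate adjustment is applied before correlation.

## Modules and node roles

Modularity Q is evaluated on the weighted retained matrix with weighted
degrees and total weight 2m. Module detection uses seeded Louvain
(networkx); partitions are relabeled size-descending, and an exhaustive
set-partition enumerator (≤10 nodes) serves as an exact oracle in tests. If
the optimizer ever returned a partition below the single-module baseline
(Q = 0) the baseline partition is returned instead.

Z uses the population SD of within-module degrees (no n−1 correction);
σ = 0 modules give Z = 0, isolated nodes give P = 0.

**Lobe-level connectivity.** The four lobes (frontal 28, temporal 18,
parietal 14, occipital 8 regions) act as the module partition.
Inter-lobular connectivity is the mean participation coefficient over a
lobe's nodes. For intra-lobular connectivity the literal reading — mean Z
over the lobe — is identically 0 whenever the lobe's degree SD is positive
(z-scores average to zero over their defining module), so it cannot produce
the nonzero per-lobe values such analyses report. Both readings are always
computed; the headline `intra` column defaults to the mean retained
within-lobe edge weight (`intra_mode="weight"`), which is the quantity that
behaves like a per-lobe connectivity strength.

## Statistical comparison

- Regional tests: Student t (equal variances) by default, Welch optional;
  Benjamini–Hochberg step-up FDR across the 68 regions; Cohen's d with
  pooled SD. A cohort compared against itself is treated as the exact null
  (t = d = 0) rather than a 0/0 error.
- Permutation network test: each iteration subsamples 10 subjects per
  group, pools the 20, re-splits them at random into two pseudo-groups, and
  records the pseudo-group difference of Q, mean P and mean Z. The
  observed full-group difference is tested one-tailed in its own direction
  against the null; the critical value is the empirical 95th percentile;
  p-values are BH-adjusted across the three metrics. Everything derives
  from one seed (subject draws, splits, and the Louvain sweep order).

**Calibration caveat.** With full groups of 30 and a subsample of 10, the
null differences come from much noisier networks than the observed
difference, so the test is conservative: its measured type-I error at
nominal 0.05 is ≈0 in simulation. In the exchangeable regime (cohort size
equal to the subsample) the machinery is well behaved; there the
data-adaptive one-tailed rule rejects at about twice the nominal rate, as
expected for a sign-selected tail test on a symmetric null. Users wanting a
calibrated test should set `subsample` equal to the group size. The default
reproduces the subsampled design this pipeline emulates.

Mean Z as a *global* network metric is ~0 by construction for any network
and partition; it is carried for completeness but its permutation test
compares floating-point noise.

## Synthetic data

The simulator is the package's stand-in for a private two-group MRI cohort
and states its world once:

- 30 subjects per group, 68 regions.
- Region means set per lobe and hemisphere to healthy-control lobe means
  (2.1985–2.2990); region SD 0.03, the middle of the per-region range
  (0.01–0.08) seen in regional FD tables. Values land in ≈2.0–2.45.
- Five planted covariance modules of sizes 19/17/17/8/7 (the healthy-group
  modular decomposition) on contiguous region ids; block-constant
  correlation with rho_within = 0.6, rho_between = 0.1. This block-normal
  model is a simple stand-in — no generative model of inter-subject FD
  covariance is established for real cortex.
- The patient group lowers the means of 27 designated regions (the
  reported significantly-atrophied set) by effect_d = 0.3 region-SDs, the
  typical reported effect size (range 0.16–0.47).
- Draws are multivariate normal via Cholesky; the master seed spawns
  independent per-group substreams.

The block-constant correlation C = (1−ρ_w)I + (ρ_w−ρ_b)B + ρ_b J is
positive definite for 0 ≤ ρ_b ≤ ρ_w < 1 (each term PSD, first positive
definite); construction still checks the minimum eigenvalue.

What a green simulation test does **not** establish: recovery of real
cortical FD values (no surface geometry, segmentation noise, or spatial
autocorrelation is simulated), realistic inter-regional correlation
structure (real covariance is not block-constant), or the specific modular
memberships of real cohorts. Phantom tests establish the estimator's
accuracy only at the phantom's scale and regularity.

## Known limitations

- Single-offset box counting; no offset search, rotation averaging, or
  surface-based FD.
- Proportional thresholding at a single density (0.2 default); no density
  sweeps or subject-level networks.
- Louvain is a greedy heuristic: on 68-node networks it matches the exact
  optimum in our ≤8-node enumerations and clique constructions, but global
  optimality is not guaranteed; module counts on noisy networks can vary
  with seed.
- The permutation design's conservatism at subsample < group size (above).
- Statistical power for a single planted effect of d = 1.0 at n = 30/30
  after BH correction across 68 regions is capped near 0.62 (noncentral-t
  analysis confirmed by simulation); multiplicity is expensive at this
  sample size.
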