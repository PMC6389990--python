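# Methods

This note documents the models, the synthetic data generator, the numerical
choices, and the limits of what the test suite demonstrates.

## Decoding model

The decoder is a multivariate ridge regression from voxel space to semantic
space: for standardized predictors `X̃` (per-voxel z-scoring with
*training-fold* statistics; zero-variance voxels pass through unscaled) and
semantic coordinates `Y` centered on the training mean,

    W = X̃ᵀ (X̃X̃ᵀ + λI)⁻¹ Yc        (dual form, used when V > n)
    W = (X̃ᵀX̃ + λI)⁻¹ X̃ᵀ Yc        (primal form otherwise)

with a single penalty λ shared across the D output dimensions and the
intercept equal to the training mean of `Y`. `λ = 0` with more samples than
voxels reduces to ordinary least squares. The default penalty policy is
generalized cross-validation (GCV) on a 17-point logarithmic grid spanning
10⁻⁶–10² times the mean kernel eigenvalue, evaluated in the kernel form via
one eigendecomposition per training fold. GCV is deterministic, standard for
this class of encoding/decoding models, and uses the training fold only, so
it introduces no leakage. A fixed float λ can be supplied instead wherever
speed matters more than adaptivity.

The inverse mapping (activation prediction for novel concepts) is the
minimum-norm least-squares inverse image of a coordinate under the fitted
map: `x̂ = μ_x + σ_x ⊙ ((y − ŷ₀) W⁺)` with `W⁺` the Moore–Penrose
pseudo-inverse and `ŷ₀` the intercept. Rank deficiency is handled by the
pseudo-inverse without failure; the coordinate equal to the intercept maps
to the training-mean pattern, and `f(a+b) = f(a) + f(b) − f(0)` holds
exactly (affine linearity).

## Evaluation scheme

**Pair rule.** Correct iff the matched cosine-distance sum is strictly
smaller than the swapped sum; exact equality is a tie and contributes 0.5 to
accuracy. Zero-norm vectors are rejected rather than silently scored.

**Averaged analysis.** Six repetitions per target are averaged; within each
of the C(n,2) folds, voxel stability is recomputed on the remaining n−2
targets (mean of the 15 pairwise Pearson correlations between the six
repetition profiles, per voxel; flat profiles contribute r = 0) and the
top-k voxels (k = 500 by default, ties broken by voxel index) are used.
Held-out targets therefore never touch selection, standardization, fitting,
or penalty choice.

**Single-trial analysis.** No averaging and no stability selection. For a
pair of trials from two distinct targets, all 6 + 6 trials of both targets
are removed (348 of 360 remain); one fitted mapping serves all 36 trial
pairs of that target pair. Same-target trial pairs are evaluated with that
target's 6 trials held out and reported as a separate stratum, excluded from
the headline accuracy: their truths coincide under target-level models
(forcing ties), and mixing them into the headline number would conflate two
different questions. Full enumeration yields 1770 × 36 + 60 × 15 = 64,620
pairs. For multi-subject model comparisons, a seeded random subsample of
unordered target pairs can be drawn; this only widens the Monte-Carlo error
of each subject's mean accuracy, which the across-subject comparison
absorbs.

**Permutation null.** Each iteration permutes the target-to-coordinate
assignment (at target level, whole repetition blocks move together), refits
and re-evaluates the entire scheme with *test-pair truths intact*, and
records the overall accuracy; the significance cutoff is the empirical 95th
percentile. Stability selection depends only on the betas, never on the
coordinates, so "recomputing" stability under permutation is identical to
keeping it fixed — no switch is needed. In the multi-subject pipeline the
iterations are distributed across subjects and the accuracies pooled.

**Model comparison.** Paired two-sided t-tests on per-subject mean
accuracies for all 15 model pairs, Bonferroni-corrected by 15. Degenerate
cases use the limiting convention: identical accuracy vectors give t = 0,
p = 1; a constant nonzero difference gives t = ±∞, p = 0.

## Searchlight RSA

Model RDM: pairwise cosine distances between trial coordinates (zero-norm
rows are an error). Activation RDM: 1 − Pearson r between trial patterns;
zero-variance patterns receive distance 1 with a warning (r treated as 0).
Searchlights contain every mask voxel within 7 mm center-to-center Euclidean
distance (center included; 57 voxels in the interior of the 3.1 mm
reference grid). Per center, Spearman's ρ (average ranks on ties) between
the strictly-lower-triangle vectors of the two RDMs is Fisher-transformed;
ρ = ±1 is capped at atanh(1 − 10⁻¹⁵) to stay finite, and undefined
correlations (constant vectors, sub-2-voxel spheres) are set to 0 with a
warning. The diagonal and upper triangle are excluded to avoid double
counting; same-target trial pairs are included in the triangle vectors.

Group inference: subject z-maps are Gaussian-smoothed within the mask with
renormalized kernels (no bleed from outside; FWHM → σ as FWHM/(2√(2 ln 2))),
then tested with a one-sample sign-flip permutation scheme. The statistic is
pseudo-t = mean / √(smoothed variance / n) with the sample variance smoothed
at the same FWHM (6 mm default). With 2ⁿ ≤ n_perm the flip set is enumerated
exhaustively, otherwise n_perm random flips are drawn with the identity
always included. The FWE height threshold is the 95th percentile of the
per-permutation maximum statistic; supra-threshold voxels are reported as
6-connected clusters with peak pseudo-t, extent, and voxel-level FWE p.

## Synthetic data generator

The generator emulates the guessing-game design: 60 targets in 4 categories
× 15 items, 9 clue features per target in 6 ordered triplets (two
presentation sets of three blocks; each clue appears once per set at a fixed
within-triplet position, triplets strictly ordered by distinctiveness rank),
plus 10 non-clue features per target, all on a 3.1 mm isotropic voxel grid
(24³ default) with a centered spherical "gray-matter" mask.

Semantic structure is hierarchical Gaussian: category centroid
~ N(0, σ_cat²I); target = centroid + N(0, σ_item²I); feature = α·target +
N(0, σ_feat²I). Betas follow `β_t = W_fwd s_t + N(0, σ_ε²I)` where `s_t` is
the summed-feature coordinate of the trial's target and `W_fwd` is
N(0, 1/D) on a subset of informative voxels (zero elsewhere). Encoding the
*full* feature sum — rather than the presented clues — as the generative
signal makes recovery of the model ordering a genuine test of the analysis,
not a tautology. Each subject draws independent forward weights and noise
but shares the semantic space and stimulus design. When a contiguous
informative blob is requested (for localization tests), its location is
drawn from the design seed and shared across subjects, modeling common
functional anatomy; random informative placement remains per-subject.

Default dispersions (σ_cat = 1.0, σ_item = 0.6, σ_feat = 2.0, α = 0.35,
σ_ε = 60 beta units) were calibrated once so that default-noise decoding
lands between chance and ceiling: repetition-averaged accuracy ≈ 88–90% and
single-trial accuracies ≈ 50–67% across the six models, with the ordering
all_features > all_nonclues > target > clue123 > clue3. These are properties
of the generator, not claims about any empirical dataset. The large σ_feat
matters: feature vectors need substantial idiosyncratic components for the
clue-based and full-feature models to be distinguishable at realistic noise.

What the generator does **not** emulate: hemodynamics and HRF convolution
(betas are drawn directly, as the analysis consumes GLM betas),
spatiotemporal noise correlations, physiological and motion artifacts,
inter-subject anatomical variability, and any systematic relation between
semantic content and spatial layout beyond the informative set. Passing
tests therefore demonstrate correctness and calibration of the *analysis*
under a linear-forward-model world, not performance guarantees on real
fMRI data.

## Problem sizes used in tests and the acceptance script

The full stimulus design (60 targets, 360 trials, all 1770 folds) is always
kept; spatial grid and embedding dimension are reduced where full scale adds
nothing to the property under test: 12³ grid (≈ 550 masked voxels), D = 60,
150 informative voxels for recovery/ordering/RSA runs; 8³ grids and D = 16
for structural unit tests; the 17-subject model comparison subsamples 60
target pairs per subject (≈ 36,700 scored trial pairs per model). Null
calibration uses 200 permutations on a 12-target dataset and 100 null group
simulations with exhaustive 2⁶ sign flips. The RSA localization bound
dilates the generative blob by the searchlight radius (7 mm) plus the
smoothing kernel support (4σ ≈ 10.2 mm at 6 mm FWHM): a searchlight
centered up to one radius outside the blob genuinely overlaps it, and the
discrete Gaussian kernel is truncated at 4σ.

## Known limitations

- Key-word resolution is table-driven; no lemmatization or multi-word
  fallback (an unresolvable feature is an error, not a guess).
- The word2vec reader supports the text dialect only.
- The shared-λ ridge ignores per-dimension noise differences; per-dimension
  penalties were not needed at the tested scales.
- Cluster peak coordinates are reported in grid-mm units (voxel index ×
  voxel size); there is no template-space registration or atlas labeling.
- `run_experiment` at the full default configuration (24³ grid, D = 300,
  17 subjects, full pair enumeration) is a long single-CPU computation;
  the reduced configurations above are the intended desk-scale entry point.
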