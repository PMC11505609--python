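# Methods

This note documents the models, conventions and numerical choices behind
each module, what the synthetic-data generators do and do not emulate, and
the known limitations.

## Fluorescence IHC quantification

The positive-pixel pipeline is background subtraction → contrast
enhancement → binarization → masked counting. The original analyses of this
kind use unpublished in-house scripts, so every step here is an explicit,
deterministic convention exposed as configuration:

* **Background subtraction** — grayscale morphological opening with a disk
  (default radius 25 px); output = image − opening, clipped at 0. Any
  structure wider than the disk is treated as background, so the disk must
  exceed the largest object of interest. On a flat image the output is
  identically zero; on an already background-free sparse image the operation
  is idempotent (up to rounding of the discrete disk).
* **Contrast enhancement** — linear stretch of the [P_low, P_high]
  percentile window onto [0, 1] with clipping (defaults 1/99; the nuclei
  counter uses 0/100 so that thresholding is scale-free). A degenerate
  window (P_low = P_high) is an error rather than a silent no-op.
* **Binarization** — Otsu's between-class-variance criterion on a 256-bin
  histogram by default; deterministic and parameter-free, hence
  reproducible where the original threshold is unknown. A fixed-threshold
  mode covers re-analysis against a known cutoff. A constant image has no
  separable classes and errors. Masks use strict `> threshold`.
* **Nuclei counting** — 8-connected components of the binarized DAPI
  channel; components are kept if their area lies in [min_area, max_area]
  (defaults 20 px and 10× the median component area — rejects specks and
  merged clumps) and their centroid lies inside the ROI (an explicit,
  testable edge rule). Density = count / ROI area, with ROI area =
  |ROI| · (pixel size in µm)² · 10⁻⁶ mm². No splitting of touching nuclei
  by default, since plain binarization is the documented behavior of such
  scripts; a distance-transform watershed is available but off.
* **Mean intensity** (myelin readout) is computed on raw, pre-enhancement
  intensities: enhancement is monotone but not affine over the clipped
  range, and the raw mean is the only convention that is exactly linear in
  acquisition gain.

Mask-based readouts (positive %, counts) are invariant to global intensity
scaling through the Otsu path; the mean intensity is exactly linear in it.

## Natural-abundance correction, MCL, M+X

A metabolite with *n* carbons carrying *j* tracer-derived ¹³C atoms is
observed at mass M+i with binomial probability that i−j of its n−j remaining
carbons are naturally ¹³C:

    M(i, j) = C(n−j, i−j) · p^(i−j) · (1−p)^(n−i),   i ≥ j,

with p = 0.0107 (terrestrial ¹³C fraction) by default. Columns of M are
probability distributions (sum 1), so the forward model conserves mass.
Correction solves min‖Mx − f_measured‖₂ subject to x ≥ 0 (NNLS) and
renormalizes; NNLS rather than M⁻¹ because inversion of noisy data produces
negative fractions. Noiseless round trips recover the true MID to < 1e-10
for n ≤ 6.

Only the carbon skeleton is corrected. Derivatization-agent atoms (Si, H, O
isotopes) would require the specific derivative formula per metabolite and
are out of scope; with electron-impact GC-MS fragments this term is not
negligible in absolute terms, so corrected MIDs are comparable within a
protocol, not across chemistries.

Enrichment summaries: MCL = Σᵢ i·fᵢ / n ∈ [0, 1] is the weighted average
labeled-carbon fraction (linear in the MID); M+X% = 100·f_X. Both are
computed from corrected MIDs. Two-group comparisons use the pooled-variance
(Student) unpaired t-test.

## Diffusion kurtosis imaging

Signal model per voxel, b in ms/µm², D in µm²/ms:

    ln S(b, n̂) = ln S₀ − b·D_app(n̂) + (b²/6)·MD²·W_app(n̂)
    D_app = n̂ᵀ D n̂,  W_app = Σ n̂ᵢn̂ⱼn̂ₖn̂ₗ Wᵢⱼₖₗ,  MD = tr(D)/3.

* **Design/parameterization.** The linear stage estimates 22 parameters
  (ln S₀, 6 unique D elements, 15 unique elements of V = MD²·W, with
  symmetry multiplicities folded into the regressors); W is recovered as
  V/MD². The nonlinear stage parameterizes (ln S₀, D, W) directly and
  evaluates MD(θ) inside the model, so its optimum is a genuine fit of the
  signal equation. Schemes must provide 22 independent rows (≥ 2 shells,
  enough distinct directions).
* **Fitting.** Ordinary LS on ln S initializes; two passes of weighted LS
  with weights = squared predicted signal follow (the first-order
  delta-method correction for the heteroscedasticity induced by the log
  transform); then trust-region nonlinear least squares on S₀·exp(model)
  refines to tolerance 1e-14. The linear initializer's D is projected to the
  nearest SPD matrix (eigenvalue floor 1e-6) if needed. Apparent kurtosis on
  the acquisition directions is kept inside [0, 10] by a soft penalty
  (weight 10); non-positive signals are masked, all-zero or under-determined
  voxels return flagged null fits instead of raising. Noiseless in-model
  signals are recovered to ~1e-14 relative.
* **Scalar metrics.** FA from the eigenvalues of D. MK averages
  K_app(n̂) = (MD²/D_app²)·W_app over a fixed 256-point spherical Fibonacci
  set, making MK independent of the acquisition directions (averaging over
  the 30 acquisition directions is available as an option). The discrete
  average deviates from the exact spherical mean by < ~0.1% for smooth
  kurtosis profiles; it is rotation-invariant only up to that quadrature
  error, so exact equivariance checks rotate the evaluation set jointly
  with the tensors.
* **Rician floor.** Magnitude MRI at low SNR has E[S²] = A² + 2σ², biasing
  weak signals upward. The adjustment √max(S² − kσ², 0) is applied with
  k configurable: k = 1 (default, subtract one noise variance — the common
  preprocessing convention) or k = 2 (the full second-moment identity).
  Choose to match the upstream pipeline; the difference matters only within
  a few σ of the floor. Denoising and Gibbs-ringing correction are assumed
  to have happened upstream.
* **Cumulant truncation.** The DKI equation is the 2nd-order cumulant
  expansion of ln S in b. For signals outside the model class (e.g. a
  mixture of Gaussian compartments, whose exact small-b kurtosis along n̂ is
  K = 3·Var_c[d_c]/E[d_c]²), a fit over an extended b-range systematically
  shrinks the apparent kurtosis toward the curvature that best matches the
  sampled range: for two equal compartments at 0.5 and 2.0 µm²/ms (K = 1.08)
  fitted MK on the 0.4–2.0 ms/µm² scheme is ≈ 0.80, i.e. a ~26% truncation
  bias; for a milder 70/30 mixture (spread 0.35–1.6) the bias is a few
  percent. This is a property of the model/b-range combination, not of the
  optimizer — the bias is invariant to fit weighting within a few percent —
  and is why the two-compartment validation quantity is reported as both
  the fitted and the closed-form value.
* **ROI summaries.** Per-ROI means of each metric map over mask voxels
  (hemispheres pooled by passing pooled masks) and relative volume =
  ROI voxels / whole-brain voxels (the voxel volume cancels; absolute mm³
  is also reported). No registration: maps and masks share one grid.

## Cohort statistics

* **ROUT outliers.** For a single sample the robust fit is the median and
  the scale is the RSDR analog: the 68.27th percentile of |residuals|
  inflated by n/(n−1). Residual t-scores get two-sided p-values at n−1 df
  and are tested most-extreme-first against the step-down FDR schedule
  p_(i) < Q·i/n, stopping at the first failure. This is an approximation of
  the published robust-regression-and-outlier-removal procedure (the
  reference implementation is closed-source); measured behavior at Q = 1%,
  n = 12: ~1–2% of clean Gaussian samples get any flag, a 50σ contaminant
  is always flagged. An all-identical sample has zero scale and, by
  definition, no outliers.
* **Two-way ANOVA** is type II via OLS (statsmodels); empty design cells
  error naming the cell; a constant factor collapses to the one-way model.
  **Tukey HSD** uses the cell-means pooled MSE with N−k df and the
  studentized-range distribution (Tukey–Kramer for unequal n); with two
  groups it reduces exactly to the pooled t-test through q = |t|·√2.
  **t-tests** are Student (pooled variance) in the unpaired case;
  zero-variance degeneracies are flagged in the result rather than raised.
* **Permutational mixed ANOVA.** The split-plot decomposition: between-
  subject effects (genotype, age, genotype×age) are tested on subject means
  against the subject-within-group stratum; within-subject effects (ROI and
  its interactions) against the ROI×subject residual stratum, with subject
  dummies absorbing between-subject variation. Sums of squares are type II
  (differences of residual sums of squares between nested models), which
  matches classical sequential ANOVA exactly on balanced designs and is
  well-defined on unbalanced ones; F-ratios agree with R's `aov`
  split-plot tables. Null distributions permute within the exchangeability
  stratum of each effect: subjects across group labels for between effects,
  ROI labels within each subject for within effects (subject means are
  invariant to the latter, so the strata do not interfere). p is the plain
  proportion of permuted F strictly exceeding the observed F — resolution
  1/n_perm, and p = 0 is possible by construction; the (+1)/(n_perm+1)
  estimator is available as an option, as is Freedman–Lane residual
  permutation. Because designs are fixed and only responses permute, every
  model's projection matrix is precomputed once and all permutations reduce
  to vectorized quadratic forms: 10,000 repetitions on a 28-subject ×
  8-ROI table take well under a second.
* **Simple main effects** re-run the permutation test for one factor within
  each level of a stratifying factor (replicate rows per subject collapse
  to means first); single-level strata are skipped with a note.

Measured calibration (null cohorts at the default design, 500 permutations):
per-effect type-I error at α = 0.05 within [0.02, 0.09] over 200
simulations, and Spearman rank correlation > 0.99 between permutation and
parametric p-values on Gaussian data.

## Synthetic data: what it emulates, what it does not

* **Image phantoms** place plaque-like disks, filament polylines
  (anti-aliased random walks, width 1–2 px) and nucleus disks at a constant
  foreground level on a constant background, plus i.i.d. Gaussian noise,
  clipped to [0, 1]. Defaults: 1024×1024 (camera geometry is otherwise
  unconstrained), 20× pixel scale 0.5128 µm/px. Nuclei and plaques are
  non-overlapping by rejection sampling (1000 retries, then an error naming
  the limiting parameter) so that object counts are unambiguous ground
  truth; `allow_touching` exercises the counter's failure mode. Rasterized
  truth counts pixels whose centers fall inside each disk. Not emulated:
  realistic plaque morphology, intensity gradients, optical blur, shading —
  so passing tests demonstrate correctness of the quantification logic, not
  robustness to real microscope artifacts.
* **MID tables** convolve built-in tracer-only MIDs (a toy TCA labeling
  table per substrate: glycolytic M+3 from [U-¹³C]glucose, M+2 entry from
  [1,2-¹³C]acetate, M+5 backbone from [U-¹³C]glutamine; synthetic values,
  no measured data) with the natural-abundance matrix, then apply
  multiplicative lognormal noise of given CV (MS abundances are positive
  with roughly proportional error) and renormalize. Defaults: 4 replicates
  per group, CV 2%. No flux model is fit and none is implied.
* **DKI phantoms** tile the volume into slab regions, each a mixture of
  Gaussian compartments; noiseless signal S₀·Σf_c·exp(−b·n̂ᵀD_c n̂) on the
  study scheme (5 b₀ + 4 shells × 30 directions; directions from a
  spherical Fibonacci set). Ground-truth MD/FA come from the mean tensor,
  MK from the analytic directional kurtosis of the mixture averaged over
  256 directions. Rician noise is |S + ε₁ + iε₂| with channel SD = S₀/SNR.
  Not emulated: brain geometry, partial volume, motion, eddy currents,
  Gibbs ringing.
* **Cohorts** follow an additive linear model with genotype/age contrast
  codes ±½ (so each main effect equals a group mean difference), a fixed
  ROI profile, interactions carried by an alternating centered ±1 ROI
  pattern, subject random intercepts, and Gaussian residuals. Defaults
  mirror the study design: 2×2 between-subject groups (7 subjects each, 28
  total) × 8 ROIs. The degenerate subject_sd = 0 case yields ICC ≈ 0.

## Problem sizes and determinism

Validation uses 100–200 random tensors for DKI recovery, 100 image phantoms
for counting, 200 null cohorts × 500 permutations for ANOVA calibration and
1000 simulations for ROUT rates — sizes at which every binomial acceptance
band is decisive while the full suite runs in tens of seconds. Every
generator and every permutation test is a pure function of its spec/seed;
the pipeline derives per-stage seeds from the manifest seed by hashing, so
end-to-end runs are byte-identical under identical configs.

## Known limitations

* The IHC thresholds/filters of any given historical dataset are unknown;
  this package fixes reproducible conventions rather than replicating a
  specific script.
* Natural-abundance correction omits derivatization chemistry (above).
* Exact analytic MK (elliptic-integral form) is not implemented; the dense
  spherical average differs negligibly for realistic kurtosis profiles but
  is quadrature, not closed form.
* MK of non-model signals carries the b-range truncation bias quantified
  above; comparisons are valid within a fixed scheme.
* ROUT is an open re-implementation of a described-but-closed procedure;
  only its calibration properties, not value-for-value output, are
  guaranteed.
* The permutation scheme (stratified label permutation) is one of several
  defensible choices; Freedman–Lane is provided, and the two agree closely
  on the designs tested.
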