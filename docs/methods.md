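# Methods

## The question the pipeline answers

Group comparisons of resting-state functional networks are run on data
that were spatially smoothed during preprocessing, and the kernel width
is an essentially free choice. This package measures how that choice
propagates to the *result* of the comparison: which links are declared
different between two groups, how large the effect sizes look, how long
the implicated links are, and how similar the detected subnetworks are
across kernels.

The pipeline is, per smoothing level:

1. **Smoothing.** Every in-mask voxel series is replaced by the
   renormalized Gaussian kernel average of its in-mask neighbours,
   `x_i <- Σ_j G_i(j) x_j / Σ_j G_i(j)`. The sweep covers no smoothing
   plus FWHM 4–32 mm in 2 mm steps (16 kernels); smoothing is always
   applied to the original data, never cumulatively.
2. **Network extraction.** ROI node signals are unweighted means of
   member-voxel series; link weights are Pearson correlations, Fisher
   z-transformed, cleaned link-wise by OLS on nuisance covariates (scan
   site, mean framewise displacement; never group), and mapped back with
   tanh.
3. **Comparison.** The network-based statistic (NBS): a two-group ANOVA
   F per link (df = 1, so F = t²), suprathreshold links (default
   F > 12.25, strict), connected components by breadth-first search
   sized in links, and a permutation null (group labels resampled,
   sizes preserved) of the maximal component link count. Component
   p-values use the +1 estimator, so they are never 0 and never below
   1/(M+1). A parallel "traditional" analysis thresholds each subject at
   7% density and permutation-tests five graph measures (degree,
   clustering, local and global efficiency, betweenness) with
   Benjamini–Hochberg control across nodes.
4. **Sweep-level quantities.** Per-kernel subnetworks and link counts; a
   signed Cohen's d grid over every link significant at ≥ 1 kernel,
   evaluated at all kernels, via |d| = √(F·(1/n₁+1/n₂)) with the sign of
   the patient-minus-control mean difference; link persistence (which
   kernels detect each link, ordered by first detecting kernel then
   count); the Hamming distance matrix between subnetwork link masks
   (upper-triangle positions only — counting both symmetric cells would
   double every value); and the Spearman rank correlation between
   physical link length (mm between ROI centroids) and F, over all
   links, per kernel.

## Synthetic cohorts and what they do (not) emulate

Real clinical cohorts have no ground truth, so validation runs on
synthetic cohorts with a planted contrast:

* **Signals.** Band-limited (0.01–0.08 Hz at TR = 2 s) Gaussian ROI
  series with a prescribed correlation matrix, built by frequency-domain
  masking of white noise followed by mixing through a matrix square
  root. Spectral masking is simpler than a time-domain filter and gives
  exact out-of-band suppression; what matters downstream is only the
  correlation structure and the effective degrees of freedom.
* **Contrast.** The control correlation matrix carries `r0` (default
  0.1) on background links; the patient matrix raises a connected set of
  planted links (default a 5-link chain) by `delta` (default 0.4). Both
  matrices are repaired to the nearest positive-semidefinite correlation
  matrix (eigenvalue clipping, diagonal renormalization); the *achieved*
  post-repair contrast, not the requested one, is the ground truth.
* **Voxel stage.** Each ROI is an axis-aligned block of voxels (default
  8 voxels at 2 mm, blocks separated by 2-voxel gaps so smoothing mixes
  neighbours); every member voxel carries the ROI series plus noise of
  sd `voxel_noise_sd`, optionally pre-smoothed to `intrinsic_fwhm`
  (default 4 mm, a free parameter — site-specific intrinsic smoothness
  of real data is not known) and rescaled so the sd keeps its meaning.
* **Nuisance.** Scan-site offsets and motion-correlated shifts enter
  additively at the Fisher-z link level — exactly the level the
  confound regression operates on. Site offsets are per-site, per-link
  Gaussian draws (sd `site_effect_sd`); the motion term is
  `fd_effect_slope · meanFD` times a fixed per-link pattern. Mean FD is
  log-normal(ln 0.15, 0.5) truncated at the 0.5 mm inclusion cap.
* **Not emulated:** hemodynamics, scanner artifacts beyond smooth noise,
  registration error, global signal, heterogeneous TR. Passing tests
  demonstrate the statistical machinery is correct and calibrated under
  these conditions; they do not certify behaviour on real BOLD data.

## Numerical choices

* **Kernels.** σ = FWHM/(2√(2 ln 2)); truncation at 4σ (spherical
  radius) with renormalization — <0.2% tail mass, keeps 32 mm kernels
  tractable. Convolution by FFT; a box-truncation mode exists, in which
  3D smoothing factorizes exactly into sequential 1D passes (used by the
  separability test). Mask-aware renormalization conserves the
  kernel-weight-weighted mean exactly (the plain spatial mean is only
  approximately conserved near boundaries, which is inherent to
  renormalized smoothing).
* **Smoothness estimator.** Per axis,
  `FWHM_a = Δa √(−2 ln 2 / ln(1 − v_a/(2v)))` from the variance of
  first differences between in-mask neighbours (v_a) and the field
  variance (v), averaged over frames; axes rougher than white noise
  floor at the voxel size; axes combine by geometric mean. It is
  invariant to offset and scale, and recovers applied kernels of
  4–12 mm on 40³ grids within a few percent.
* **Adaptive blurring.** Iterative global steps of FWHM
  `√(max(target² − current², 0))/2`, floored at 0.5 mm, re-estimating
  after each step. Near the target the steps become sub-voxel and barely
  act on a discrete grid, so the approach from below is slow: defaults
  are max_iter = 50, tol = 10% of target. Inputs already smoother than
  the target are returned unchanged with a flag (smoothing cannot be
  undone). Locally adaptive freezing of already-smooth regions is not
  implemented.
* **Thresholding.** k = round(d·R(R−1)/2) links kept (half-up), ranked
  by signed weight by default (`mode="absolute"` available); ties at the
  cutoff break toward the lower (row, col) index, so outputs are
  deterministic.
* **Confound regression.** Cleaned value = residual + fitted intercept,
  so the mean level survives and tanh returns weights on the original
  scale. Categorical covariates are dummy-coded against the
  alphabetically first level; covariates that are constant in the sample
  are dropped (nothing to remove); any remaining rank deficiency is an
  error.
* **NBS details.** Strict inequality at the suprathreshold; +1
  permutation estimator; per-kernel sub-seeds derived as
  `SeedSequence([master, kernel_index])` so each kernel is independently
  reproducible; "primary" subnetwork = largest significant component,
  ties to the smallest incident node index. F is computed on the
  cleaned, inverse-Fisher weights.
* **Permutation tests (graph measures).** Two-sided |Δmean|; exhaustive
  enumeration replaces Monte Carlo whenever the number of distinct
  relabelings is ≤ 10 × the permutation budget. Disconnected pairs
  contribute efficiency 0; betweenness uses fractional counting of tied
  shortest paths.

## Calibration of the null experiment

The type-I-error study (500 cohorts, 10/group, 12 ROIs, T = 256, 200
permutations) needs a suprathreshold that produces sparse exceedances.
We fix it at the per-link F critical value for α = 0.05 at df (1, 18)
(F = 4.414, ~3.3 expected suprathreshold links of 66) — the canonical
primary-threshold convention for this family of tests, and the choice
that keeps the maximal-component null least discrete. The measured call
rate sits slightly below nominal (~0.03–0.04): with a discrete component
statistic and the +1 estimator, p < 0.05 at M = 200 requires at most 9
exceeding permutations, which is intrinsically conservative.

## Problem sizes

Simulation studies run at deliberately small scale: 12-ROI networks
(66 links), 10–20 subjects per group, T = 256–512, 150–300 permutations
per test, and toy sweeps of 4–8 kernels on ~14×10×10 voxel grids. These
sizes give the statistical assertions comfortable margins (power ≈ 1 at
the planted effect, binomial bands on rates) while each experiment stays
in the seconds-to-minutes range.

## Known limitations

* The toy block parcellation has rectangular geometry and uniform ROI
  size; fixed-size 7-voxel spheres (centroid voxel + 6 face neighbours)
  are provided, but no anatomical atlas is bundled.
* Under strong smoothing neighbouring ROI signals mix, and the detected
  subnetwork inflates with neighbour links — this is the phenomenon
  under study, not an artifact, but it means per-kernel link counts
  depend on the toy geometry's gap width.
* The adaptive-blur scheme is global; voxelwise adaptivity is out of
  scope.
* `estimate_smoothness` assumes an approximately Gaussian spatial
  autocorrelation; heavy-tailed correlation structure will bias it.
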