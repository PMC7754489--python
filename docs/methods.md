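# Methods

This note documents the models, estimators and design choices behind
perfcensor: what each pipeline stage computes, what the synthetic phantom
does and does not emulate, and where the genuinely open choices were made.

## Data model and conventions

A scan is a `CardiacPCSeries`: magnitude and velocity rasters indexed
`[row, col, cardiac_phase]`, 0-based, row index increasing downward. The
velocity raster is in cm/s, signed; negative means downward (caudal)
through-plane flow. If the input file is a phase image in radians, it is
converted linearly (`v = phase / π · venc`); aliased values (|v| > venc) are
preserved, never clipped. The phase-encoding axis — along which ghost
replicas propagate — is explicit metadata (`pe_axis`), never inferred from
image content, because "vertical stripes" presumes a display orientation the
files may not share. All pixel-unit parameters are defined on the
(interpolated) acquisition grid, nominally 0.2 × 0.2 mm².

## Central white-matter mask

Detection is restricted to WM pixels strictly more than `wm_margin`
(default 80 px = 16 mm) from the outside contour of the brain-slice mask,
measured by the Euclidean distance transform of the brain mask. Euclidean
(not chessboard/cityblock) distance is the natural reading of "pixels away";
the inequality is strict: a pixel at exactly the margin is dropped. An empty
result warns instead of raising, since downstream stages handle empty masks.

## Perforator detection

1. **Background phase correction.** Per cardiac phase, subtract a median
   filtered (`phase_bg_window`, default 31 px, reflect padding) copy of the
   velocity map. Static tissue then averages ≈ 0 cm/s while single-pixel
   perforator signals, far below the window scale, pass through essentially
   unchanged. The window default must only satisfy "≫ perforator footprint
   (1–2 px), ≪ anatomical scale"; it is exposed in `RunConfig` and exercised
   by the parameter sweep.
2. **Velocity noise.** The per-sample velocity noise follows the standard
   PC-MRI relation σ_v = √2·venc / (π·SNR). The magnitude SNR is estimated
   self-containedly inside the analyzed WM: signal = mean temporal-mean
   magnitude; noise SD from the per-pixel temporal variance of the
   magnitude, summarized by its **median** (robust to the rare pulsatile
   perforator pixels) and rescaled by the exact χ² median factor
   `chi2.median(n−1)/(n−1)` so the estimator is unbiased for Gaussian noise
   — an uncorrected median-of-SD summary is ~2% low at n = 14, enough to
   decalibrate the significance test. In the noiseless limit σ_v is floored
   at 1e−12·venc so any nonzero mean flow is significant.
3. **Significance.** A WM voxel is significant when the two-sided
   (1−α) confidence interval of its cardiac-cycle mean velocity excludes
   zero: |v̄| > z(1−α/2)·σ_v/√n_phases, α = 0.05 by default. The normal
   quantile (z = 1.959964 at α = 0.05) is used rather than t because σ_v is
   estimated from thousands of voxels, not per-voxel samples.
4. **Grouping.** Connected components of significant voxels (8-neighbor by
   default — the more inclusive reading of "neighboring"; 4-neighbor is
   configurable) form candidate perforators. Groups whose peak mean velocity
   is ≥ 0 (upward flow) are discarded; in each kept group the voxel with the
   largest |v̄| becomes the perforator record, carrying its full
   velocity-time curve. Ties break to the first voxel in row-major order.

Note the α = 0.05 per-voxel test flags ~5% of pure-noise WM voxels by
construction (verified to within 3 binomial SDs in the acceptance suite).
Detection output therefore always contains a chance-detection floor
proportional to the analyzed area; on the sparse phantom this floor
outnumbers the planted perforators and pulls the subject-level velocity
average well below the planted values. This is a property of the detection
rule, not of the implementation.

## Ghost censoring

- **Detrending.** The temporal-mean magnitude image minus its 70×70 px
  median filtered copy. Even windows are realized as the next odd size
  (70 → 71), a sub-pixel difference; padding is reflect everywhere (a zero
  pad would create edge ramps that leak into the vessel percentile).
- **Vessel identification.** Threshold at the `⌈0.003·N⌉`-th brightest voxel
  over the **brain mask** (not the full field of view — air background would
  dilute the percentile; scope is configurable). Ties at the threshold are
  all included, making the result order-independent. Components of ≥ 3
  voxels survive ("more than two voxels"), so isolated single/double-voxel
  perforators are not mistaken for vessels. Cluster size is counted on the
  raw (pre-dilation) component.
- **Stripes.** Each cluster is dilated along the readout axis only (per the
  procedure's wording, not isotropically) and extended along the
  phase-encoding axis: ≥ 80-voxel clusters by (2 px, 200 px), smaller ones
  by (1 px, 110 px). "Extended by X px" is read as **per side**, which
  produces the full-length stripes the procedure describes; a total-length
  mode is available via `extend_mode="total"`. Growth clips at the image
  border, no wrap-around.
- **Censoring.** A perforator located on a stripe pixel (edge pixels
  included) is excluded with reason `ghost_stripe`; censoring is always a
  partition of the detected set. The **ghost fraction** — the percentage of
  analyzed WM covered by stripes — bounds the analyzable-area cost of the
  artifacts and, together with N_included, permits density-style reasoning.

Enlarging the top fraction, dilation or extension can only grow the stripe
union, so N_included is non-increasing and the ghost fraction non-decreasing
in these parameters (asserted as an acceptance property).

## Hemodynamic metrics

Each included perforator's curve is normalized by its own mean, making the
normalized mean exactly 1 and flipping downward curves positive; "normalize"
is not given a formula in the source procedure, and dividing by the signed
mean is the convention under which the PI of the averaged curve is exactly
(max−min)/mean. An alternative (divide by |mean|, keeping sign) is retained
for sensitivity checks. V_max/V_min are taken over the discrete cardiac
samples, no interpolation (14-phase sampling is the acquisition's own
resolution). The subject V_mean averages magnitudes — all included flow is
downward by the detection rule, and this matches the positive reported
convention.

Two PI estimators are implemented: `avg_curve_then_pi` (default) averages
the normalized curves pointwise and applies (max−min)/mean once;
`pi_then_avg` applies the formula per curve and averages. Because max/min
rectify noise, E[range of mean] ≤ E[mean of ranges]; at realistic noise the
per-curve estimator inflates PI severely while the averaged-curve estimator
stays close to truth. `pi_noise_simulation` quantifies this by Monte Carlo
(shared true waveform + i.i.d. Gaussian per-timepoint noise); its exact
original simulation parameters are not documented anywhere, so only the
qualitative ordering is asserted, at 30 curves, noise SD 0.3, 1000
replicates.

## Reliability statistics

`icc_two_way` computes single-measure two-way ICCs in the Shrout–Fleiss /
McGraw–Wong convention from the two-way ANOVA decomposition:
consistency ICC(3,1) = (MSR − MSE)/(MSR + (k−1)MSE) and absolute agreement
ICC(2,1), which additionally charges rater-mean variance. CIs: the exact
F-interval for consistency; the McGraw–Wong Satterthwaite approximation for
agreement. The error sum of squares is computed directly from residuals
(not by subtraction) so duplicated columns give exactly 1.0. With equal
column means the two forms differ by an O(1/n) term; they coincide only
asymptotically. The implementation is verified against an explicit
sums-of-squares oracle and against pingouin's `intraclass_corr`.
Qualitative bands: < 0.5 poor, 0.5–0.75 moderate, 0.75–0.90 good, > 0.90
excellent.

Between-method comparison runs both ICC forms plus Bland–Altman
(bias ± 1.96·SD of differences, sample SD) per outcome. A multilevel
mixed-model ICC pooling repeated scans is **not** implemented — its model
structure is not specified anywhere usable — so per-pairing two-way ICCs
are the supported comparison; published multilevel values are not
reproduction targets of this package.

`parameter_sweep` reruns the full pipeline over a Cartesian grid of
censoring parameters on fixed input, the standard robustness check for the
empirically chosen stripe geometry.

## The synthetic phantom

`synthesize(PhantomSpec)` renders, in image space (no k-space or MR physics
simulation — the analysis treats ghosts purely as image-space bands):

- a smooth brain disk (tissue intensity 100, Gaussian-tapered edge) times a
  multiplicative low-frequency inhomogeneity field (±10% by default);
- large-vessel clusters (+400 intensity) grown by random accretion, placed
  so their ghost bands cross the deep-WM analysis region, with attenuated
  replicas at ±k·ghost_spacing along the phase-encoding axis
  (amplitude decay 0.35 per replica, 2 replicas per side by default);
- single-pixel perforators with raised-cosine pulsatile downward waveforms
  (exact mean and PI by construction), scaled by a partial-volume fraction
  (0.6 by default — subvoxel vessels contribute only part of a voxel);
  planted ≥ 5 px apart and, unless requested on-ghost, ≥ 12 px clear of any
  ghost band. On-ghost perforators are planted inside actual replica
  footprints — physically where ghost energy lies — which also keeps them
  within reach of the default stripe extents;
- Gaussian noise on magnitude (per phase; optional Rician switch) and
  velocity. By default the velocity noise SD is **derived from the realized
  magnitude SNR via σ_v = √2·venc/(π·SNR)**, so the phantom is
  self-consistent with the detector's noise model and the significance test
  is calibrated by construction; an explicit `noise_sd_velocity` decouples
  them. Inside ghost bands the velocity noise is inflated 3× — the
  false-positive generator the censoring exists to remove.

Two independently seeded streams drive geometry and noise, so repeated
"scans" of one subject share an identical scene (`geometry_seed`) with fresh
noise (`seed`). Identical seeds give bit-identical output.

Ghost amplitude, spacing and replica count are free parameters: no
quantitative characterization of the artifacts exists to pin them, and the
defaults (spacing 40 px, decay 0.35) were chosen once to look like typical
multishot pulsation ghosts. What the phantom deliberately omits: motion
blurring, velocity aliasing, spatially correlated noise, gating jitter,
partial-volume point-spread (perforators are exactly one pixel), and any
anatomical realism beyond a disk. Passing tests therefore demonstrate the
correctness and calibration of the algorithmic chain under the stated noise
model, not clinical performance on real scans.

## Numerical choices

- Median filtering (both detrending stages) uses an exact sliding
  sorted-window kernel (numba) with reflect padding, verified bit-identical
  to `scipy.ndimage.median_filter`; large-window 2-D medians dominate
  runtime otherwise.
- Stripe growth is implemented as two sequential 1-D binary dilations
  (readout, then phase-encode), i.e. a rectangular structuring element,
  verified against per-voxel offset enumeration.
- Detection/labeling ties and orderings are all deterministic (row-major);
  the full pipeline is byte-reproducible for fixed inputs and config.
- Degenerate inputs (empty masks, empty included set, zero-mean curves,
  zero-variance ICC tables) raise `DegenerateInputError` rather than
  returning NaNs; the pipeline maps an empty included set to `metrics=None`
  while still reporting counts and ghost fraction.

## Problem sizes

The test suite and the acceptance script use 256² phantoms with 14 cardiac
phases for full-pipeline checks (20 seeds for censoring recovery and
detector calibration) and 128² scenes for unit-level checks; the acceptance
cohort is 10 subjects × 2 scans plus 5 pure-noise scans and a 1000-replicate
PI Monte Carlo.
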