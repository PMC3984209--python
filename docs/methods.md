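# Methods

`fiberlight` models two linked measurements from an optogenetic circuit-mapping
experiment: how much thalamic tissue a side-firing optical fiber activates
(a photon-transport problem), and how the evoked cortical response is
quantified from intrinsic optical imaging (an image-statistics problem).
This note records the models, the parameter choices, and the places where the
design was genuinely open.

## 1. Photon transport

### Model

Light propagation in brain tissue is simulated as a voxel Monte-Carlo random
walk in an infinite homogeneous medium (hop–drop–spin with absorption
weighting):

* free paths are exponential with total attenuation `μt = μa + μs`;
* at each interaction a fraction `μa/μt` of the packet weight is deposited in
  the enclosing voxel and the packet continues with the remainder;
* the scattering deflection follows the Henyey-Greenstein phase function with
  anisotropy `g`, sampled with the standard inverse-CDF closed form, with a
  uniform azimuth;
* packets below a weight of 1e−4 play Russian roulette with survival
  probability 0.1 (survivors re-weighted ×10), keeping the estimator unbiased
  while bounding walk length;
* packets crossing the grid boundary are tallied as escaped.  No
  refractive-index step is modelled at the grid faces: the source sits
  millimetres deep in tissue and the grid edge is ≥0.6 mm beyond the last
  voxel that ever crosses an activation threshold.

Fluence is estimated from absorbed energy, `Φ = E_dep/(μa·V)` per launched
packet, and expressed in multiples of the source exit intensity
`I₀ = P/(π r²)`.  The estimator requires `μa > 0`; a non-absorbing medium is
rejected rather than silently mis-estimated.

Energy is conserved exactly by construction:
`deposited + escaped + roulette-killed − roulette-boosted = launched`, and the
test suite asserts this to 1e−9 per photon and per run.

### Source model

The fiber is a 200 µm-core, NA 0.37 multimode fiber whose mirror-coated
45° tip redirects all light perpendicular to the fiber axis.  The source is
an emission disc of the core radius, uniform across the disc and uniform in
solid angle within a cone of half-angle `asin(NA/n)` — NA is conserved across
the fiber–tissue interface, so divergence in tissue (n = 1.37) is 15.7°.
A top-hat angular profile is the usual far-field approximation for an
overfilled multimode fiber.

In side-firing mode the disc centre is placed **one core radius off the
fiber axis along the emission normal** — at the cylindrical surface where the
redirected light physically leaves the fiber.  This matters: with the disc
on the axis, the activated volume is centred on the fiber tip and rotating
the fiber barely moves it (45° rotation overlap ≈ 50%); with the surface
offset the activated lobe is displaced laterally and rotation sweeps it
around the axis (overlap ≈ 18%), reproducing the segregated rotated lobes of
the original simulations.  `FiberConfig.emission_offset = 0` restores the
on-axis variant; an axial (flat-cleave) mode is also provided.

The insertion axis defaults to 57° from vertical in the x–z stereotaxic
plane (the documented insertion trajectory), `phi = 0` maps the emission
normal to the lateral horizontal perpendicular, and positive `phi` rotates it
right-handedly about the (downward) axis.  Absolute registration of `phi` to
anatomy varied across the original experiments and is left as a free
configuration parameter.

### Optical properties — the scattering-coefficient convention

The study states scattering and absorption coefficients of 4.37 mm⁻¹ and
0.48 mm⁻¹ for brain tissue at 473 nm together with `g = 0.9`.  Tissue-optics
tables at this wavelength report *reduced* scattering coefficients
`μs′ = μs(1−g)` of a few mm⁻¹ (full `μs` is tens of mm⁻¹), so 4.37 mm⁻¹ is
interpreted as `μs′`, giving `μs = 43.7 mm⁻¹` with `g = 0.9` for the
Henyey-Greenstein walk.  This is also the only reading that reproduces the
published simulation outputs: with `μs = 4.37, g = 0.9` the medium is nearly
ballistic at these scales and the activated volumes come out up to 1.9× too
large while the translation overlap collapses to ~6% (published ≈27%).
Both conventions remain available
(`OpticalProperties(mu_a=…, mu_s=…)` vs `OpticalProperties.from_reduced`).

### Normalization of the fluence map for thresholding

"Intensity at the source normalized to one" is implemented as an option of
`threshold_volume`:

* `normalization="exit"` — the map's native units: fluence in multiples of
  the disc-mean exit intensity `I₀`.
* `normalization="peak"` — the map is first rescaled so the fluence *at the
  source* (its maximum voxel) is one, and the measured tip intensity in
  mW/mm² is attached to that value.

Because backscattered light re-crosses the emission disc, the fluence at the
source exceeds `I₀` by ≈35% in brain-like tissue; the two conventions
therefore differ by a constant factor.  The study-reproduction drivers use
`"peak"`, which matches the published volumes across all four intensities
(1.00–1.22×); the exit convention overshoots them all by a uniform ≈1.6×.

### Activation threshold and outputs

Voxels count as activated when their fluence exceeds 0.5 mW/mm² — the ChR2
half-maximum firing irradiance (0.49 mW/mm² is accepted via configuration;
the difference is below voxel noise).  No connected-component filtering is
applied: the criterion is pure fluence.  Overlap between two poses is
`|A∩B|` divided by, per the `mode` option, the mean of the volumes
(default — the two volumes are congruent under pure rotation or translation,
making mean ≈ min there), the union (Jaccard), or the smaller volume.  The
published overlap metric is not specified; all three are reported.

### Discretisation and run sizes

* Grid: 10 µm isotropic voxels on a 2×2×2 mm cube centred on the fiber tip.
  The smallest published volume (0.0049 mm³) spans ~4,900 voxels, so
  voxelization error is far below Monte-Carlo noise.
* Photons: drivers default to 10⁷ per simulation (a few minutes on one CPU
  core with the numba kernel).  At 10⁷ the per-voxel noise near the
  activation boundary is a few percent and overlap estimates move by well
  under one percentage point between seeds.  The acceptance script uses
  5×10⁶ per run for its three simulations; at that size the reported overlap
  percentages are stable to ~1 pp.
* RNG: a seeded `numpy` Generator drives the jitted kernel; identical
  (config, seed) gives bitwise-identical maps.  Sweeps derive one
  independent seed per pose from the base seed and the pose label (CRC-32
  mix, < 2³¹), so poses are statistically independent but the whole sweep is
  reproducible.

## 2. Synthetic intrinsic optical imaging

### What the generator emulates

The acquisition protocol of the cortical read-out: 20 s trials of 80 frames
at 4 Hz; 8 pre-stimulus frames (2 s); a 250 ms stimulus starting at frame 9;
20 stimulus and 20 blank trials in seed-randomized order.  The evoked signal
is a *decrease* in reflectance (deoxyhemoglobin dip) of order −0.01% to
−0.03% relative to baseline:

* temporal shape — a gamma-variate kernel `k(t) = (t/tp)^a e^{a(1−t/tp)}`
  normalized to 1 at its peak, with peak 2.5 s after stimulus onset and
  FWHM 3 s (the shape parameter is solved from the FWHM).  These values are
  typical of rodent IOI hemodynamics and fit comfortably inside the 18 s
  post-stimulus window; the real study does not publish an HRF form.
* spatial shape — a Gaussian bump of SD `spatial_sigma` pixels; its
  half-maximum footprint has the closed-form area `2π ln2 σ²` pixels², which
  recovery tests use as ground truth.
* noise — i.i.d. multiplicative Gaussian per pixel and frame
  (default SD 1e−3).  With 20-trial averaging and σ = 4 px spatial filtering
  this puts the default amplitude (−2.2e−4) at the edge of detectability,
  the regime the study describes (its weakest stimulus needed a relaxed
  threshold).

Deliberately *not* modelled: vascular structure, photon shot noise, slow
drifts (an optional linear drift flag exists for robustness tests), camera
nonlinearity, and hemoglobin spectroscopy.  Passing recovery tests therefore
demonstrate that the analysis chain is unbiased and calibrated for
spatially-smooth responses in white noise — not that it is robust to vessel
artifacts or motion.

Pixel size defaults to 0.01 mm/px so a 300×300 field spans 3 mm of cortex;
the default synthetic field is 128×128 (1.28 mm) to keep trial sets at
~200 MB.  The camera scale of the original experiments is unpublished, so
in-vivo activation areas are not treated as reproducible targets.

### Analysis chain

`average_and_normalize` → frame-wise mean over the 20 trials of one
condition, then each pixel's time course divided by its own pre-stimulus
mean (pre-stimulus mean exactly 1).  `spatial_filter` → isotropic Gaussian
per frame, σ = 4 px in the drivers, `nearest` boundary so constant frames
are preserved.  `t_map` → pixelwise two-sided Welch t-test of the 8
pre-stimulus frames against a response window.  The stimulus itself is one
frame long, so "stimulation period" cannot mean a literal 1-frame window;
the default window is frames 9–24 (0–4 s post-onset), covering the
hemodynamic trough.  Significance is uncorrected `p < α` (0.05 or 0.01),
matching conventional IOI thresholding; a Benjamini–Hochberg option is
available for modern use.  Areas are significant-pixel counts × pixel
area; the peak amplitude is the signed extremum of the mask-averaged
time course in percent.

Design points that were open and how they were fixed:

* **Filter-then-test vs test-then-filter** — the Gaussian filter is applied
  to the frames of the averaged stack *before* the t-test (filtering "the
  activation map" before delimiting areas only affects areas if it happens
  before thresholding).  The chain is composable, so the unfiltered order is
  simply `t_map(stack)` without the `spatial_filter` step.
* **Welch vs pooled t** — Welch, two-sided (the source does not specify).
* **Samples** = frames of the trial-averaged stack (averaging comes first in
  the described pipeline); a per-trial variant is behind a flag.
* **Blank trials** are analysed identically as a null control but are not
  subtracted from stimulus trials.

### Calibration facts the tests pin down

* On blank stacks with σ_filter = 0 the significant-pixel fraction at
  α = 0.05 sits inside the binomial 99% CI over ≥10⁴ independent pixels
  (filtering correlates pixels, so calibration is checked unfiltered).
* Detection SNR is defined as the expected window-mean response at the bump
  centre divided by its standard error,
  `SNR = |A|·k̄·√(n_trials·n_frames_window)/σ_noise`.  At SNR = 5 the
  half-maximum footprint recovered from the window-averaged response map
  (smoothed with σ = 4 px for a stable peak estimate; the exact
  ``2π ln2 σ_s²`` footprint inflation of the smoothing is subtracted again)
  matches the closed form within 20%, and the centroid of the significance mask lies within
  2·spatial_sigma of the true centre, in ≥95% of 100 seeds.
  The *significance-mask area itself* is not compared to the footprint: it
  depends on α, noise and trial count by design (which is why the in-vivo
  areas are not reproduction targets).
* Intensity-response fits: `y = a + b·x` (areas) and `y = a + b·ln x`
  (amplitudes) by least squares, with R² and the overall F-test p (equal to
  the slope t-test for one regressor).  Noiseless data recover R² = 1 to
  1e−10; simulated data with a designed population ρ² match an independent
  brute-force replication of the sample-R² distribution.

## 3. Numerical notes and limitations

* The absorbed-energy fluence estimator is noisier than a track-length
  estimator per photon but cheap per step; at the default photon counts the
  difference is immaterial for thresholded volumes.
* `peak` normalization uses the map maximum; at low photon counts the
  maximum carries upward noise bias (≈4% at 10⁶ photons, ≈1% at 10⁷),
  slightly shrinking volumes.  Acceptance-scale runs are large enough that
  this bias is well inside the quoted tolerances.
* Volumes are monotone in threshold and intensity by construction;
  `threshold_volume(F, I₀, t)` is invariant under joint rescaling of
  (I₀, t).
* Degenerate inputs are rejected loudly: photons starting outside the grid,
  μa = 0 with the fluence estimator, empty masks in overlap or amplitude
  computations, response windows overlapping the pre-stimulus frames.
* The tissue is homogeneous and unbounded: no LGN geometry, no fiber-shaft
  shadowing, no wavelength dependence, no time resolution.  Simulated
  volumes are "tissue above irradiance" — mapping them onto anatomy or
  firing-rate predictions is out of scope.
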