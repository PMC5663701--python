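# Methods

## Detector model

Every simulated frame follows the standard photon-transfer model of a
CMOS-class sensor. For pixel *i* with offset `o_i` (ADU), gain `g_i`
(ADU/e⁻), read noise `σ_r,i` (electrons) and expected photon flux `Φ_i`:

    electrons = Poisson(η·Φ_i) + Normal(0, σ_r,i)
    ADU       = clip(round(o_i + g_i·electrons), 0, 2^bits − 1)

Assumptions baked into this model:

* **Read noise is added in electrons, before gain.** This makes the flat-field
  variance exactly `g²(η·Φ + σ_r²)` so that the per-pixel variance-vs-mean
  regression has slope `g` and intercept `g²σ_r²`.
* **Dark current is folded into the offset.** Exposures in the intended
  regime are ≤25 ms; an explicit exposure-dependent dark term would be
  unidentifiable from the data the pipeline consumes. The only offset drift
  mechanism is the thermal warm-up coupling.
* **Quantization** contributes an extra 1/12 ADU² of temporal variance from
  integer rounding; the calibration tests account for it, the calibration
  itself does not need to (it is ≪ g²σ_r² for both presets).
* **No EM-CCD excess noise, no rolling-shutter artifacts,** and quantum
  efficiency enters only as a scalar per wavelength.

Calibration maps are generated with independent lognormal pixel-to-pixel
scatter (default coefficient of variation 0.02, giving a read-noise bulk
band of roughly ±5% around `g·σ_r ≈ 13.4` ADU for the CMOS preset), a
sinusoidal column modulation of gain and read noise (the vertical-stripe
fixed pattern of column-parallel readout; default amplitude 0.02, period
8 px), and a 0.11% fraction of hot pixels whose read noise is multiplied by
3. The hot-scale factor 3 cleanly separates the hot population from the
bulk, so a threshold at 1.5× the median noise recovers the generated
fraction.

### Presets

`cmos`: 5.86 µm pixels, 1936×1216, 12-bit, η(660 nm)=0.48, η(500 nm)=0.75,
g=2.1 ADU/e⁻, σ_r=6.4 e⁻. `scmos`: 6.5 µm, 2048×2048, 16-bit,
η(660 nm)=0.69, η(580 nm)=0.72, g=0.46 ADU/e⁻, σ_r=1.4 e⁻. Pixel pitch,
sensor format, quantum efficiencies and the CMOS read noise are public
characteristics of the two detector classes; the offsets (100 ADU), both
gains and the sCMOS read noise are package assumptions chosen to be
representative — only their orders of magnitude matter to the pipeline, and
the CMOS gain of 2.1 ADU/e⁻ is implied by the pairing of a 1.3 ADU dark
rise with 0.62 electrons.

### Thermal warm-up

Housing temperature follows `T(t) = T_∞ − ΔT·exp(−t/τ)` (defaults
T_∞ = 53.9 °C, ΔT = 30 °C, τ = 12 min, so the series is within 0.5 °C of the
asymptote after ~52 min). An optional coupling scales the dark level by up
to +1.3 ADU and the read noise by up to +6% in proportion to the normalized
temperature rise.

### Emitter scenes

Emitters are rendered as pixel-integrated symmetric 2-D Gaussians
(error-function integral per pixel, not point sampling) — at ~110 nm pixels
point sampling would bias sub-pixel fitting tests. Scene kinds: `grid` and
`random` (bead-like, always on, or Bernoulli blinking), and `filament` (two
parallel lines, default 40 nm apart, emulating the projected wall separation
of a hollow filament). `label_scatter_nm` adds isotropic position scatter
emulating antibody-linkage displacement. With `mean_on_frames > 1` the
on/off state is a two-state Markov chain whose stationary on-fraction equals
`on_probability`; multi-frame on-times are what make consecutive-frame
nearest-neighbor analysis informative. The beamsplitter view partitions each
emitter's photons binomially per frame (exact conservation) and renders each
arm with its own maps, QE and projected pixel width (defaults 109.7 and
107.5 nm).

Coordinate convention everywhere: x = (col + 0.5)·pixel, y = (row +
0.5)·pixel, origin at the ROI's top-left corner.

## Calibration inversion

Offset and noise are the per-pixel temporal mean and unbiased (n−1)
standard deviation of a dark stack. Gain is the per-pixel unweighted OLS
slope of temporal variance against mean-above-offset across flat-field
levels; the intercept gives the read noise, reported both in ADU and in
electrons (divided by the fitted gain). Pixels with non-positive fitted
slope are flagged NaN and counted rather than clamped. The characterization
scenario reports read noise from the dark stack divided by the fitted gain
(the direct, many-frame measurement); the PTC intercept is retained as a
cross-check only, since at realistic frame counts the intercept estimator is
far noisier. A weighted regression variant was considered and rejected as
the default: the unweighted fit is the plainest reading of "linear
regression on the variance as a function of the mean", and it recovers both
parameters to well within the acceptance tolerances.

The warm-up fit is nonlinear least squares of the exponential model,
initialized at T_∞ ← last sample, ΔT ← last − first, τ ← duration/3; a
constant series short-circuits to the sample mean (the amplitude is
unidentifiable there).

## Localization

Candidates come from a difference-of-Gaussians bandpass (default σ = 1.0
and 2.5 px) with 8-connected local maxima above `threshold_factor` (default
4) times the robust standard deviation (1.4826·MAD) of the filtered image;
ties break lexicographically by (row, col); candidates closer than half a
fit window keep only the brighter one.

Each candidate window (default 7×7 px) is converted to photoelectrons with
scalar mean offset/gain (full maps optional; the scalar path mirrors setting
reconstruction software to the map means) and fitted by maximum likelihood
under a Poisson model with five parameters (x, y, σ, N, bg), initial σ =
1.2 px. Pixel values may be slightly negative after offset subtraction
(read noise); they are kept as-is — the Poisson score `Σ(1 − n/μ)·∂μ/∂θ`
still has zero expectation when the mean model is right, so the background
estimate stays unbiased, whereas clipping at zero would inflate it.
Optimization is L-BFGS-B with an analytic gradient. The convergence
tolerance is set to 1e−12 relative reduction (200 iterations max): the
Poisson deviance rides on a large data-dependent constant, so a looser
relative criterion would stop long before the informative part of the
likelihood has converged — with the tight tolerance, noise-free spots are
recovered to machine-level accuracy and fits cost ~5 ms.

Per-localization uncertainty is the model-based MLE precision evaluated at
the fitted signal statistics, with the camera read noise folded into the
effective background (below).

## Precision estimators

* **Direct**: per-axis sample standard deviations of repeated localizations
  of one emitter, combined as `σ = sqrt((σ_x² + σ_y²)/2)`; groups with one
  localization are excluded.
* **Model-based**: with `σ_a² = σ_PSF² + a²/12` and
  `τ = 2π·b_eff²·σ_a²/(N·a²)`, the LS variance is `σ_a²/N·(16/9 + 4τ)` and
  the MLE variance `σ_a²/N / (1 + ∫₀¹ ln t/(1 + t/τ) dt)`. The integral is
  evaluated on a fixed 200-node Gauss–Legendre rule after the substitution
  `t = u²` (removing the logarithmic endpoint singularity); agreement with
  adaptive quadrature is ~1e−7 relative over τ ∈ [0.01, 100]. Read noise
  enters as added background variance, `b_eff² = b² + σ_r²` — the standard
  convention for folding a Gaussian noise floor into a Poisson background.
* **NeNA**: nearest-neighbor distances between consecutive frames (search
  radius 200 nm) fitted by
  `p(d) = A·d/(2σ²)·exp(−d²/(4σ²)) + C·d`; the linear term absorbs
  uncorrelated pairs. The simplified two-term form is used; the original
  three-term correction adds a second Gaussian that the synthetic scenes do
  not need.

## Rendering and FRC

Rendering is either a 2-D histogram or a normalized-Gaussian sum (each
record contributes a unit-integral Gaussian of standard deviation equal to
its uncertainty; default display pixel 5.5 nm). FRC splits the table into
two halves, renders both as **histograms** (Gaussian smoothing would bias
the resolution), computes the ring-normalized cross-spectrum on one-bin
rings and reads the resolution at the first downward crossing of the fixed
1/7 threshold with linear interpolation between rings; no curve smoothing.
The default split alternates 500-frame blocks, which decorrelates
multi-frame blinking; a record-level random split leaves localizations of
the same on-event in both halves and inflates high-frequency correlation
(the known spurious-correlation effect — no correction term is applied, by
scope).

At test-scale localization counts (~10³ per half) the first-crossing rule
is noisy, so the dSTORM scenario reports, per arm, the median resolution
over several temporal block sizes (default 60–220 frames) at a finer 5 nm
rendering and 3-bin rings; the per-split values are retained in the report.

## Post-processing semantics

Boundary semantics are pinned and tested: the precision filter keeps
records with uncertainty strictly **less than** the threshold; the density
filter keeps records with **at least** `min_neighbors` other records within
the radius (all frames pooled, one pass, self excluded). Merging links
records within 20 nm across frame gaps of at most `max_gap + 1` (gap 1 lets
frames n and n+2 join through one dark frame — the permissive reading of a
"temporal delay of 1 frame"); linking is greedy nearest-per-frame with the
lower-uncertainty chain end winning conflicts; a chain collapses to the
intensity-weighted mean position, summed intensity, first frame, and the
weighted-mean standard error as uncertainty. Drift correction renders
equal temporal bins as histograms, takes each bin's shift from the
cross-correlation peak with parabolic sub-pixel interpolation (bin 1 is the
reference), interpolates per-frame shifts linearly between bin centers with
constant extrapolation at the ends, and subtracts them.

## Scenario design and problem sizes

All scenarios run on one CPU in minutes; the sizes are the package's own
test-scale defaults and scale up by configuration.

* **characterization** — 64×64 ROI, 4000 dark frames, 15 flat levels ×
  2000 frames: recovers the median gain within 2% and read noise within 5%;
  the hot-pixel fraction is measured on a 512×512 map where 0.11% of 262k
  pixels gives adequate counting statistics.
* **bead_precision** — continuously emitting emitters on a grid, imaged
  through the beamsplitter at several illumination levels, with a
  50 photons/px/frame background (a mid-range dSTORM-like level). At this
  background the model predicts the two presets' precisions to differ by
  ~23% at 500 detected photoelectrons and to agree within ~10% at 5000 —
  the divergence/convergence pattern the comparison is about.
* **dstorm_compare** — blinking emitters on a filament with 15 nm label
  scatter, broad lognormal blink brightness (median 5000 photons, σ=1.0 in
  log units): the dim tail of the distribution produces the detection-count
  asymmetry between the arms while the bright tail carries the
  reconstruction; per-blink on-times average 2 frames. Per arm:
  localize → filter (<15 nm) → drift-correct → NeNA, FRC, uncertainty-mode.
  With ~600 distinct labels blinking ~3–4 times each, the two FRC halves
  sample different label subsets and the resolution is set by structure
  sampling rather than per-arm precision; the sCMOS arm still trends
  slightly better (more localizations, better precision), so arm agreement
  is asserted on the mean over three replicates at the 20% level, not per
  realization.

## Known limitations

* The simulator draws blink photon budgets independently per frame rather
  than splitting a fixed photon budget across an on-event.
* Markov blinking has geometric on-times only; no dark-state hierarchy or
  photobleaching.
* The localization fitter is single-emitter; overlapping spots are not
  deconvolved, and no per-pixel-noise-weighted sCMOS likelihood is
  implemented (out of scope).
* Fitted-σ freedom means the empirical precision can exceed the fixed-σ
  model bound by a few percent; the consistency checks use a 15% band.
* Hardware-bound quantities (maximum frame rates, the absolute resolution
  and count numbers of the real detectors) are outside what synthetic data
  can certify; the pipeline checks directions and scaled-down analogues.
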