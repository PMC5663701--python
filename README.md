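# camcheck

Camera characterization and performance evaluation for single-molecule
localization microscopy (SMLM), driven entirely by a synthetic detector and
emitter simulator.

Industry-grade CMOS sensors are an attractive low-cost alternative to the
scientific CMOS (sCMOS) cameras that dominate SMLM, but assessing whether
they are *good enough* requires a quantitative chain: per-pixel calibration
of the detector, localization of single emitters through that calibration,
and precision/resolution metrics on the resulting localization tables.
`camcheck` implements that chain as a reusable, tested pipeline and pairs it
with a simulator that emulates the two detector classes (a 5.86 µm-pixel,
12-bit industry CMOS with ≈48% quantum efficiency and 6.4 e⁻ read noise at
660 nm, versus a 6.5 µm, 16-bit sCMOS with ≈69% QE and 1.4 e⁻ read noise),
so every stage can be validated against known ground truth without any real
data.

## What is inside

| module | role |
|---|---|
| `camcheck.synthetic_camera` | per-pixel offset/gain/read-noise maps (with vertical-stripe fixed pattern and hot pixels), Poisson + Gaussian-read-noise frame simulation, thermal warm-up series, bead/blinking/filament emitter scenes, 50/50 beamsplitter two-camera views |
| `camcheck.characterize` | photon-transfer-curve inversion: offset = dark-stack mean, read noise = dark-stack std, gain = per-pixel OLS slope of variance vs mean; exponential warm-up fit |
| `camcheck.localize` | difference-of-Gaussians detection + Poisson maximum-likelihood fitting of pixel-integrated 2-D Gaussians; per-localization uncertainty from the precision model |
| `camcheck.postprocess` | precision filter, local-density filter, consecutive-frame merging, drift correction by cross-correlation of temporally binned reconstructions |
| `camcheck.metrics` | direct (bead-repeat) precision, the Mortensen LS/MLE precision model, nearest-neighbor analysis (NeNA), histogram / normalized-Gaussian rendering, Fourier Ring Correlation (FRC) resolution |
| `camcheck.pipeline` | three end-to-end scenarios (characterization, bead precision, two-camera dSTORM comparison) with seeded reproducibility and JSON run reports |
| `camcheck.cli` | `camcheck simulate \| characterize \| localize \| postprocess \| metrics \| run` |

## The model in brief

Each pixel *i* converts light to counts as

```
ADU_i = clip( round( o_i + g_i · [ Poisson(η·Φ_i) + N(0, σ_r,i) ] ), 0, 2^bits − 1 )
```

with offset `o` (ADU), gain `g` (ADU/e⁻), read noise `σ_r` (e⁻) and quantum
efficiency `η`. Under uniform illumination the temporal variance is linear
in the mean above offset with slope `g` and intercept `g²σ_r²` — the photon
transfer curve that `characterize` fits per pixel.

The model-based localization precision uses the effective PSF width
`σ_a² = σ_PSF² + a²/12` (pixel width *a*) and background parameter
`τ = 2π b_eff² σ_a² / (N a²)` with `b_eff² = b² + σ_r²`:

```
LS:  σ_loc² = σ_a²/N · (16/9 + 4τ)
MLE: σ_loc² = σ_a²/N / (1 + ∫₀¹ ln t / (1 + t/τ) dt)
```

The MLE integral is evaluated by fixed Gauss–Legendre quadrature; at τ = 0
both estimators reduce to their shot-noise limits.

## Worked example

```python
import camcheck as cc

spec = cc.get_preset("cmos")
maps = cc.make_camera_maps(spec, shape=(64, 64), seed=1)

# calibrate from a simulated campaign: one dark stack + 15 flat levels
dark = cc.simulate_stack(maps, spec, "dark", 4000, seed=2)
offset, noise_adu = cc.estimate_offset_noise(dark)
series = [(cc.simulate_stack(maps, spec, "flat", 2000, mean_photons=lv, seed=10 + k), lv)
          for k, lv in enumerate(range(60, 960, 60))]
ptc = cc.estimate_gain_map(series, offset)
print(f"median gain {float(__import__('numpy').nanmedian(ptc.maps.gain)):.3f} ADU/e-")
# -> median gain 2.097 ADU/e-   (generated at 2.1)

# localize a simulated bead stack and compare to the model prediction
truth = cc.make_ground_truth("grid", 4, photons=3000, n_frames=250,
                             field_nm=(5265, 5265), background=50, seed=3)
stack = cc.simulate_stack(maps, spec, "emitters", 250, truth=truth,
                          projected_pixel_nm=110, seed=4)
table = cc.localize_stack(stack, float(offset.mean()), 2.1,
                          settings=cc.FitSettings(read_noise_e=6.4),
                          projected_pixel_nm=110)
print(len(table), "localizations")
# -> 1001 localizations
```

On this bead scene the median repeat precision of the fits is 6.56 nm
against a model prediction of 6.31 nm (median detected signal 1439 e⁻): the
empirical and model-based estimators agree within a few percent, which is
the core consistency check of the evaluation.

A full scenario runs from a YAML config:

```bash
camcheck run --config examples/characterization.yaml --seed 1
```

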