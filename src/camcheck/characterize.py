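"""Camera characterization: invert the photon-transfer model from raw stacks.

Offset and read noise come from dark frames (per-pixel temporal mean and
standard deviation); the gain comes from the photon transfer curve — for each
pixel, ordinary least squares of the temporal variance (ADU^2) against the
temporal mean above offset (ADU) across a series of flat-field illumination
levels.  For a Poisson + Gaussian-read-noise detector the relation is linear
with slope g (ADU per photoelectron) and intercept g^2 * sigma_r^2.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .synthetic_camera import CameraMaps, FrameStack

logger = logging.getLogger(__name__)

__all__ = [
    "PTCResult",
    "WarmupFit",
    "estimate_offset_noise",
    "estimate_gain_map",
    "adu_to_electrons",
    "summarize_maps",
    "fit_warmup",
]


@dataclass
class PTCResult:
    """Photon-transfer-curve calibration product.

    ``maps.read_noise`` is in electrons (ADU intercept converted by the fitted
    gain); ``read_noise_adu`` keeps the as-measured ADU scale.  Pixels whose
    fitted slope is non-positive are flagged NaN rather than clamped and
    counted in ``n_invalid``.
    """

    maps: CameraMaps
    read_noise_adu: np.ndarray
    r2: np.ndarray
    levels_used: int
    mean_gain: float
    mean_offset: float
    n_invalid: int

    @property
    def noise_e(self) -> np.ndarray:
        return self.maps.read_noise


@dataclass
class WarmupFit:
    """Exponential warm-up fit T(t) = T_inf - delta_T * exp(-t/tau)."""

    T_inf: float
    T_inf_se: float
    delta_T: float
    tau_min: float
    residual_sd: float


def estimate_offset_noise(dark: FrameStack | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel offset (temporal mean) and noise (temporal std, n-1) of a dark stack."""
    frames = dark.frames if isinstance(dark, FrameStack) else np.asarray(dark)
    if frames.ndim != 3:
        raise ValueError("dark stack must be 3-D (frame, row, col)")
    n = frames.shape[0]
    if n < 2:
        raise ValueError("at least 2 dark frames are required to estimate noise")
    if n < 100:
        warnings.warn(
            f"only {n} dark frames; offset/noise estimates will be poor "
            "(several thousand frames are typical)", stacklevel=2,
        )
    data = frames.astype(np.float64)
    offset = data.mean(axis=0)
    noise = data.std(axis=0, ddof=1)
    return offset, noise


def estimate_gain_map(
    series: list[tuple[FrameStack | np.ndarray, float]],
    offset: np.ndarray,
) -> PTCResult:
    """Per-pixel gain and read noise from a flat-field illumination series.

    ``series`` is a list of ``(stack, nominal_level)`` pairs at different
    light levels.  For each pixel an unweighted OLS of temporal variance vs
    (temporal mean - offset) across levels yields slope = gain (ADU/e-) and
    intercept = (gain * read_noise)^2; the read noise is returned both in ADU
    and, divided by the fitted gain, in electrons.
    """
    if len(series) < 2:
        raise ValueError(
            f"gain estimation needs >= 2 illumination levels, got {len(series)}"
        )
    offset = np.asarray(offset, dtype=float)

    means, variances = [], []
    for stack, _level in series:
        frames = stack.frames if isinstance(stack, FrameStack) else np.asarray(stack)
        if frames.shape[1:] != offset.shape:
            raise ValueError("all stacks must share the offset map's shape")
        data = frames.astype(np.float64)
        means.append(data.mean(axis=0) - offset)
        variances.append(data.var(axis=0, ddof=1))
    x = np.stack(means)       # (levels, rows, cols)
    y = np.stack(variances)

    xbar = x.mean(axis=0)
    ybar = y.mean(axis=0)
    sxx = ((x - xbar) ** 2).sum(axis=0)
    sxy = ((x - xbar) * (y - ybar)).sum(axis=0)
    syy = ((y - ybar) ** 2).sum(axis=0)

    with np.errstate(divide="ignore", invalid="ignore"):
        slope = sxy / sxx
        intercept = ybar - slope * xbar
        r2 = np.where(syy > 0, sxy ** 2 / (sxx * syy), 1.0)

    invalid = ~np.isfinite(slope) | (slope <= 0)
    n_invalid = int(np.count_nonzero(invalid))
    if n_invalid:
        logger.info("%d pixels with non-positive PTC slope flagged NaN", n_invalid)
    gain = np.where(invalid, np.nan, slope)
    read_noise_adu = np.sqrt(np.clip(intercept, 0.0, None))
    read_noise_adu = np.where(invalid, np.nan, read_noise_adu)
    noise_e = read_noise_adu / gain

    # CameraMaps requires strictly positive gain; keep the NaN-flagged arrays
    # in a container built without revalidation.
    maps = CameraMaps.__new__(CameraMaps)
    maps.offset = offset.copy()
    maps.gain = gain
    maps.read_noise = noise_e
    return PTCResult(
        maps=maps,
        read_noise_adu=read_noise_adu,
        r2=r2,
        levels_used=len(series),
        mean_gain=float(np.nanmean(gain)),
        mean_offset=float(offset.mean()),
        n_invalid=n_invalid,
    )


def adu_to_electrons(
    adu: float | np.ndarray,
    gain: float | np.ndarray,
    offset: float | np.ndarray = 0.0,
) -> float | np.ndarray:
    """Convert ADU to photoelectrons: (adu - offset) / gain.

    For difference quantities (an ADU rise rather than an absolute level) pass
    ``offset=0``.
    """
    if np.any(np.asarray(gain) <= 0):
        raise ValueError("gain must be > 0")
    return (np.asarray(adu, dtype=float) - offset) / gain


def _histogram_modes(values: np.ndarray, bins: int = 100) -> list[float]:
    """Centres of local maxima of a lightly smoothed histogram."""
    counts, edges = np.histogram(values[np.isfinite(values)], bins=bins)
    kernel = np.array([1.0, 2.0, 3.0, 2.0, 1.0])
    smooth = np.convolve(counts, kernel / kernel.sum(), mode="same")
    centers = 0.5 * (edges[:-1] + edges[1:])
    floor = 0.05 * smooth.max()
    modes = [
        float(centers[i])
        for i in range(1, len(smooth) - 1)
        if smooth[i] > smooth[i - 1] and smooth[i] >= smooth[i + 1] and smooth[i] > floor
    ]
    return modes


def summarize_maps(result: PTCResult, noise_threshold_adu: float, *,
                   hist_bins: int = 100) -> dict:
    """Summary statistics of a calibration: quantiles, histograms, hot fraction.

    The exceedance fraction counts pixels whose read noise (ADU) is above
    ``noise_threshold_adu`` — the hot-pixel statistic.  Because the defining
    quantile of the bulk band is a judgment call, several quantiles are
    reported rather than a single bulk range.
    """
    noise = result.read_noise_adu
    finite = noise[np.isfinite(noise)]
    qs = [0.01, 0.05, 0.25, 0.50, 0.75, 0.95, 0.99]
    quantiles = {f"q{int(q * 100):02d}": float(np.quantile(finite, q)) for q in qs}

    frac_above = float(np.mean(finite > noise_threshold_adu))
    gain = result.maps.gain
    gain_finite = gain[np.isfinite(gain)]
    offset = result.maps.offset

    def _hist(vals: np.ndarray) -> dict:
        counts, edges = np.histogram(vals, bins=hist_bins)
        return {"counts": counts.tolist(), "edges": edges.tolist()}

    return {
        "noise_adu_quantiles": quantiles,
        "noise_bulk_range_adu": (quantiles["q05"], quantiles["q95"]),
        "fraction_noise_above_threshold": frac_above,
        "noise_threshold_adu": float(noise_threshold_adu),
        "offset_mean_adu": float(offset.mean()),
        "offset_sd_adu": float(offset.std(ddof=1)),
        "gain_mean": float(gain_finite.mean()),
        "gain_modes": _histogram_modes(gain_finite, bins=hist_bins),
        "n_invalid_pixels": result.n_invalid,
        "histograms": {
            "noise_adu": _hist(finite),
            "offset_adu": _hist(offset.ravel()),
            "gain": _hist(gain_finite),
        },
    }


def fit_warmup(times_min: np.ndarray, temps_c: np.ndarray) -> WarmupFit:
    """Nonlinear least-squares fit of T(t) = T_inf - delta_T * exp(-t/tau).

    Initialized at T_inf = last sample, delta_T = last - first,
    tau = duration / 3.  Returns the asymptote with its standard error from
    the fit covariance.
    """
    t = np.asarray(times_min, dtype=float)
    T = np.asarray(temps_c, dtype=float)
    if t.size < 4:
        raise ValueError("need at least 4 samples to fit the warm-up curve")

    T_inf0 = T[-1]
    dT0 = T[-1] - T[0]
    tau0 = max((t[-1] - t[0]) / 3.0, 1e-6)
    if t[-1] - t[0] < tau0:
        warnings.warn("warm-up series spans less than one time constant", stacklevel=2)

    def model(tt, T_inf, dT, tau):
        return T_inf - dT * np.exp(-tt / tau)

    if abs(dT0) < 1e-12:
        # constant series: the exponential amplitude is unidentifiable
        resid = T - T.mean()
        return WarmupFit(
            T_inf=float(T.mean()),
            T_inf_se=float(T.std(ddof=1) / np.sqrt(T.size)) if T.size > 1 else 0.0,
            delta_T=0.0,
            tau_min=tau0,
            residual_sd=float(np.sqrt(np.mean(resid ** 2))),
        )

    try:
        popt, pcov = optimize.curve_fit(
            model, t, T, p0=(T_inf0, dT0, tau0), maxfev=10000
        )
    except RuntimeError as exc:
        raise RuntimeError(
            f"warm-up fit did not converge (initializer T_inf={T_inf0:.3g}, "
            f"delta_T={dT0:.3g}, tau={tau0:.3g} min): {exc}"
        ) from exc
    resid = T - model(t, *popt)
    return WarmupFit(
        T_inf=float(popt[0]),
        T_inf_se=float(np.sqrt(pcov[0, 0])),
        delta_T=float(popt[1]),
        tau_min=float(popt[2]),
        residual_sd=float(np.sqrt(np.mean(resid ** 2))),
    )
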