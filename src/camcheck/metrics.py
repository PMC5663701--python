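"""Localization-precision estimators and resolution measures.

Three complementary precision estimates plus the standard resolution measure
for localization microscopy:

* **direct** — the standard deviation of repeated localizations of a
  continuously emitting emitter (bead experiments);
* **model-based** — the closed-form (least-squares) and integral-form
  (maximum-likelihood) variance of a fitted Gaussian spot with pixelation and
  background, after Mortensen et al.;
* **NeNA** — nearest-neighbor analysis: the average precision inferred from
  the distance distribution between localizations of the same molecule in
  consecutive frames;
* **FRC** — Fourier Ring Correlation between two half-data reconstructions,
  with the resolution read at the fixed 1/7 threshold crossing.

The model-based estimator uses the effective PSF width
``sigma_a^2 = sigma_psf^2 + a^2/12`` (``a`` = projected pixel width) and the
background parameter ``tau = 2*pi*b_eff^2*sigma_a^2 / (N*a^2)`` where
``b_eff^2 = b^2 + sigma_r^2`` folds the camera read noise into the per-pixel
background variance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from numpy.polynomial import legendre
from scipy import optimize
from scipy.special import erf

__all__ = [
    "PrecisionModelParams",
    "FRCCurve",
    "NeNAResult",
    "direct_precision",
    "mortensen_precision",
    "compare_cameras_precision",
    "nena",
    "render",
    "frc_curve_from_images",
    "frc_resolution",
]


# ---------------------------------------------------------------------------
# Model-based precision (Mortensen family)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PrecisionModelParams:
    """Inputs of the model-based localization-precision estimate.

    ``background`` is the per-pixel background *variance* b^2 in
    photoelectrons^2 (for Poisson background at level b photons/pixel this is
    b itself); ``read_noise`` (electrons) is folded in as additional
    background variance.
    """

    N: float  # detected photoelectrons
    psf_sigma_nm: float
    pixel_nm: float
    background: float = 0.0  # b^2, e-^2 per pixel
    read_noise_e: float = 0.0  # sigma_r, folded into b_eff^2
    estimator: Literal["LS", "MLE"] = "MLE"

    def __post_init__(self) -> None:
        if self.N <= 0:
            raise ValueError("N must be > 0")
        if self.pixel_nm <= 0:
            raise ValueError("pixel_nm must be > 0")
        if self.psf_sigma_nm <= 0:
            raise ValueError("psf_sigma_nm must be > 0")
        if self.background < 0:
            raise ValueError("background variance must be >= 0")

    @property
    def sigma_a_nm(self) -> float:
        return math.sqrt(self.psf_sigma_nm ** 2 + self.pixel_nm ** 2 / 12.0)

    @property
    def b_eff_sq(self) -> float:
        return self.background + self.read_noise_e ** 2

    @property
    def tau(self) -> float:
        return 2.0 * math.pi * self.b_eff_sq * self.sigma_a_nm ** 2 / (
            self.N * self.pixel_nm ** 2
        )


# 200-point Gauss-Legendre rule on [0, 1], cached at import; the substitution
# t = u^2 removes the logarithmic endpoint singularity of the MLE integrand.
_GL_NODES, _GL_WEIGHTS = legendre.leggauss(200)
_GL_U = 0.5 * (_GL_NODES + 1.0)
_GL_W = 0.5 * _GL_WEIGHTS


def _mle_excess_factor(tau: np.ndarray | float) -> np.ndarray | float:
    """F(tau) with sigma_MLE^2 = (sigma_a^2/N) * F(tau); F(0) = 1.

    F(tau) = 1 / (1 + I(tau)) with I(tau) = int_0^1 ln(t) / (1 + t/tau) dt,
    evaluated after the substitution t = u^2 by fixed Gauss-Legendre
    quadrature.  I -> 0 as tau -> 0 (shot-noise limit) and -> -1 as
    tau -> inf.
    """
    tau_arr = np.atleast_1d(np.asarray(tau, dtype=float))
    out = np.ones_like(tau_arr)
    pos = tau_arr > 0
    if np.any(pos):
        u = _GL_U[np.newaxis, :]
        tpos = tau_arr[pos][:, np.newaxis]
        integrand = 4.0 * u * np.log(u) / (1.0 + u * u / tpos)
        integral = (integrand * _GL_W[np.newaxis, :]).sum(axis=1)
        out[pos] = 1.0 / (1.0 + integral)
    return out if np.ndim(tau) else float(out[0])


def mortensen_precision(params: PrecisionModelParams) -> float:
    """Model-based localization precision sigma_loc in nm.

    LS:  sigma^2 = (sigma_a^2 / N) * (16/9 + 4*tau)
    MLE: sigma^2 = (sigma_a^2 / N) * F(tau), F by numerical quadrature of the
    integral form; F(0) = 1 recovers the shot-noise limit sigma_a / sqrt(N).
    """
    sa2_over_N = params.sigma_a_nm ** 2 / params.N
    tau = params.tau
    if params.estimator == "LS":
        var = sa2_over_N * (16.0 / 9.0 + 4.0 * tau)
    elif params.estimator == "MLE":
        var = sa2_over_N * _mle_excess_factor(tau)
    else:
        raise ValueError(f"unknown estimator '{params.estimator}'")
    return math.sqrt(var)


def compare_cameras_precision(
    spec_a,
    spec_b,
    photons_incident: np.ndarray,
    *,
    wavelength_nm: float = 660.0,
    psf_sigma_nm: float = 130.0,
    pixel_nm: float = 110.0,
    background: float = 0.0,
    estimator: Literal["LS", "MLE"] = "MLE",
    use_read_noise: bool = True,
) -> dict:
    """Predicted precision vs incident photons for two camera specs.

    Each camera detects ``N = eta * photons_incident`` photoelectrons at its
    quantum efficiency and folds its own read noise into the effective
    background.  Returns per-camera sigma_loc curves, their ratio (B relative
    to A) and the percent difference.
    """
    photons = np.asarray(photons_incident, dtype=float)
    sigmas = []
    for spec in (spec_a, spec_b):
        eta = spec.qe_at(wavelength_nm)
        sigmas.append(np.array([
            mortensen_precision(PrecisionModelParams(
                N=eta * p,
                psf_sigma_nm=psf_sigma_nm,
                pixel_nm=pixel_nm,
                background=background,
                read_noise_e=spec.base_read_noise_e if use_read_noise else 0.0,
                estimator=estimator,
            ))
            for p in photons
        ]))
    ratio = sigmas[1] / sigmas[0]
    return {
        "photons_incident": photons,
        "sigma_loc_nm": {"a": sigmas[0], "b": sigmas[1],
                         spec_a.name: sigmas[0], spec_b.name: sigmas[1]},
        "ratio_b_over_a": ratio,
        "percent_difference": 100.0 * (ratio - 1.0),
    }


# ---------------------------------------------------------------------------
# Direct (bead-repeat) precision
# ---------------------------------------------------------------------------

def direct_precision(table: pd.DataFrame, groups: np.ndarray | str = "emitter") -> pd.DataFrame:
    """Per-emitter localization precision from repeated localizations.

    ``groups`` is either a column name of ``table`` or an array of group
    labels.  For each group with >= 2 localizations the per-axis sample
    standard deviations are combined as
    ``sigma = sqrt((sigma_x^2 + sigma_y^2) / 2)``; groups of one localization
    are excluded (their count is available as the difference between the
    number of labels and of returned rows).  The mean detected photoelectron
    count per group is included for precision-vs-N curves.
    """
    if isinstance(groups, str):
        labels = table[groups].to_numpy()
    else:
        labels = np.asarray(groups)
        if len(labels) != len(table):
            raise ValueError("group labels must match the table length")

    rows = []
    for label in pd.unique(labels):
        sub = table[labels == label]
        if len(sub) < 2:
            continue
        sx = float(sub["x_nm"].std(ddof=1))
        sy = float(sub["y_nm"].std(ddof=1))
        rows.append({
            "emitter": label,
            "n_localizations": len(sub),
            "sigma_x_nm": sx,
            "sigma_y_nm": sy,
            "sigma_nm": math.sqrt((sx ** 2 + sy ** 2) / 2.0),
            "mean_photons": float(sub["intensity_photon"].mean())
            if "intensity_photon" in sub else np.nan,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Nearest-neighbor analysis (NeNA)
# ---------------------------------------------------------------------------

@dataclass
class NeNAResult:
    sigma_nn_nm: float
    n_pairs: int
    fit: dict = field(default_factory=dict)


def _consecutive_nn_distances(table: pd.DataFrame, search_radius_nm: float) -> np.ndarray:
    from scipy.spatial import cKDTree

    frames = np.sort(table["frame"].unique())
    by_frame = {f: table[table["frame"] == f][["x_nm", "y_nm"]].to_numpy() for f in frames}
    dists = []
    for f in frames:
        nxt = by_frame.get(f + 1)
        if nxt is None or len(nxt) == 0:
            continue
        tree = cKDTree(nxt)
        d, _ = tree.query(by_frame[f], k=1, distance_upper_bound=search_radius_nm)
        dists.append(d[np.isfinite(d)])
    return np.concatenate(dists) if dists else np.array([])


def nena(
    table: pd.DataFrame,
    *,
    search_radius_nm: float = 200.0,
    bin_width_nm: float = 1.0,
) -> NeNAResult:
    """Average localization precision from consecutive-frame nearest neighbors.

    A molecule localized in frames f and f+1 contributes a displacement that
    is the difference of two position errors, so the distances follow a
    Rayleigh-like density ``p(d) = A * d/(2 sigma^2) * exp(-d^2/(4 sigma^2))``
    whose fitted sigma is the average single-localization precision; a linear
    term ``C*d`` absorbs uncorrelated (different-molecule) pairs.
    """
    d = _consecutive_nn_distances(table, search_radius_nm)
    if d.size == 0:
        raise ValueError("no consecutive-frame nearest-neighbor pairs found")
    if d.size < 100:
        import warnings

        warnings.warn(f"only {d.size} NN pairs; NeNA fit will be unstable", stacklevel=2)

    edges = np.arange(0.0, search_radius_nm + bin_width_nm, bin_width_nm)
    counts, edges = np.histogram(d, bins=edges, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])

    def model(dd, A, sigma, C):
        return A * dd / (2.0 * sigma ** 2) * np.exp(-dd ** 2 / (4.0 * sigma ** 2)) + C * dd

    sigma0 = max(centers[np.argmax(counts)] / math.sqrt(2.0), bin_width_nm)
    p0 = (1.0, sigma0, 1e-6)
    popt, pcov = optimize.curve_fit(
        model, centers, counts, p0=p0,
        bounds=([0.0, 1e-3, 0.0], [np.inf, search_radius_nm, np.inf]),
        maxfev=20000,
    )
    resid = counts - model(centers, *popt)
    return NeNAResult(
        sigma_nn_nm=float(popt[1]),
        n_pairs=int(d.size),
        fit={
            "amplitude": float(popt[0]),
            "background_slope": float(popt[2]),
            "sigma_se": float(np.sqrt(pcov[1, 1])),
            "rms_residual": float(np.sqrt(np.mean(resid ** 2))),
        },
    )


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def render(
    table: pd.DataFrame,
    pixel_nm: float,
    *,
    mode: Literal["histogram", "normalized_gaussian"] = "histogram",
    extent_nm: tuple[float, float] | None = None,
) -> np.ndarray:
    """Super-resolved reconstruction of a localization table.

    ``histogram`` bins localizations into pixels; ``normalized_gaussian``
    adds, per localization, a unit-integral 2-D Gaussian whose standard
    deviation is that localization's uncertainty, so the image total equals
    the record count up to boundary truncation.  ``extent_nm`` is (width,
    height); by default it covers the data.
    """
    if pixel_nm <= 0:
        raise ValueError("pixel_nm must be > 0")
    if extent_nm is None:
        if len(table) == 0:
            extent_nm = (pixel_nm, pixel_nm)
        else:
            extent_nm = (
                float(table["x_nm"].max()) + 3 * pixel_nm,
                float(table["y_nm"].max()) + 3 * pixel_nm,
            )
    n_cols = max(1, int(math.ceil(extent_nm[0] / pixel_nm)))
    n_rows = max(1, int(math.ceil(extent_nm[1] / pixel_nm)))
    image = np.zeros((n_rows, n_cols))
    if len(table) == 0:
        return image

    x = table["x_nm"].to_numpy() / pixel_nm  # column coordinate, pixel units
    y = table["y_nm"].to_numpy() / pixel_nm

    if mode == "histogram":
        cols = np.floor(x).astype(int)
        rows = np.floor(y).astype(int)
        ok = (cols >= 0) & (cols < n_cols) & (rows >= 0) & (rows < n_rows)
        np.add.at(image, (rows[ok], cols[ok]), 1.0)
        return image

    if mode != "normalized_gaussian":
        raise ValueError(f"unknown render mode '{mode}'")

    unc = table["uncertainty_nm"].to_numpy() / pixel_nm
    for xi, yi, si in zip(x, y, unc):
        si = max(si, 1e-3)
        half = int(math.ceil(4.0 * si)) + 1
        c0, c1 = int(xi) - half, int(xi) + half + 1
        r0, r1 = int(yi) - half, int(yi) + half + 1
        c0c, c1c = max(c0, 0), min(c1, n_cols)
        r0c, r1c = max(r0, 0), min(r1, n_rows)
        if c0c >= c1c or r0c >= r1c:
            continue
        s = si * math.sqrt(2.0)
        cc = np.arange(c0c, c1c, dtype=float)
        rr = np.arange(r0c, r1c, dtype=float)
        ex = 0.5 * (erf((cc + 1.0 - xi) / s) - erf((cc - xi) / s))
        ey = 0.5 * (erf((rr + 1.0 - yi) / s) - erf((rr - yi) / s))
        image[r0c:r1c, c0c:c1c] += np.outer(ey, ex)
    return image


# ---------------------------------------------------------------------------
# Fourier Ring Correlation
# ---------------------------------------------------------------------------

@dataclass
class FRCCurve:
    q: np.ndarray  # spatial frequency (1/nm) at ring centres
    frc: np.ndarray
    threshold: float
    resolution_nm: float  # inf if the threshold is never crossed
    reached: bool
    bound_nm: float = 0.0  # Nyquist bound 2*render_pixel when not reached

    @property
    def not_reached(self) -> bool:
        return not self.reached


def frc_curve_from_images(
    img1: np.ndarray,
    img2: np.ndarray,
    pixel_nm: float,
    *,
    threshold: float = 1.0 / 7.0,
    ring_width_bins: int = 1,
) -> FRCCurve:
    """FRC between two equally shaped square reconstructions.

    FRC(q) = Re sum_ring F1 * conj(F2) / sqrt(sum_ring |F1|^2 * sum_ring |F2|^2),
    rings one frequency bin wide; the resolution is 1/q at the first downward
    crossing of the threshold (1/7 by default), linearly interpolated between
    rings and not smoothed.
    """
    if img1.shape != img2.shape:
        raise ValueError("both images must share one shape")
    n = img1.shape[0]
    if img1.shape[1] != n:
        raise ValueError("FRC requires square images")
    if not np.any(img1) or not np.any(img2):
        raise ValueError("empty half-image: cannot compute FRC")

    f1 = np.fft.fftshift(np.fft.fft2(img1))
    f2 = np.fft.fftshift(np.fft.fft2(img2))
    cross = np.real(f1 * np.conj(f2))
    p1 = np.abs(f1) ** 2
    p2 = np.abs(f2) ** 2

    center = n // 2
    yy, xx = np.indices((n, n))
    radius = np.sqrt((xx - center) ** 2 + (yy - center) ** 2)
    ring = np.floor(radius / ring_width_bins).astype(int)

    n_rings = center // ring_width_bins
    idx = ring.ravel()
    keep = idx < n_rings
    num = np.bincount(idx[keep], weights=cross.ravel()[keep], minlength=n_rings)
    d1 = np.bincount(idx[keep], weights=p1.ravel()[keep], minlength=n_rings)
    d2 = np.bincount(idx[keep], weights=p2.ravel()[keep], minlength=n_rings)
    with np.errstate(divide="ignore", invalid="ignore"):
        frc = num / np.sqrt(d1 * d2)
    frc = np.nan_to_num(frc, nan=0.0)

    # ring k centre frequency: k * ring_width / (n * pixel)
    q = np.arange(n_rings) * ring_width_bins / (n * pixel_nm)

    resolution = math.inf
    reached = False
    for k in range(1, n_rings):
        if frc[k] < threshold <= frc[k - 1]:
            fr0, fr1 = frc[k - 1], frc[k]
            qc = q[k - 1] + (threshold - fr0) / (fr1 - fr0) * (q[k] - q[k - 1])
            if qc > 0:
                resolution = 1.0 / qc
                reached = True
            break
    return FRCCurve(q=q, frc=frc, threshold=threshold,
                    resolution_nm=resolution, reached=reached,
                    bound_nm=2.0 * pixel_nm)


def frc_resolution(
    table: pd.DataFrame,
    *,
    split: Literal["odd_even_frames", "random_halves", "frame_blocks"] = "frame_blocks",
    render_pixel_nm: float = 10.0,
    block_frames: int = 500,
    threshold: float = 1.0 / 7.0,
    ring_width_bins: int = 1,
    seed: int = 0,
) -> FRCCurve:
    """FRC resolution of a localization table.

    The table is split into two statistically independent halves (alternating
    frame blocks by default, to decorrelate multi-frame blinking), each half
    rendered as a histogram image at ``render_pixel_nm`` on a common square
    grid, and the ring correlation of the two reconstructions evaluated.
    """
    if len(table) == 0:
        raise ValueError("cannot compute FRC of an empty table")
    frames = table["frame"].to_numpy()
    if split == "odd_even_frames":
        mask = (frames % 2) == 0
    elif split == "frame_blocks":
        mask = (frames // block_frames) % 2 == 0
    elif split == "random_halves":
        rng = np.random.default_rng(seed)
        mask = rng.random(len(table)) < 0.5
    else:
        raise ValueError(f"unknown split '{split}'")
    half1, half2 = table[mask], table[~mask]
    if len(half1) == 0 or len(half2) == 0:
        raise ValueError(f"split '{split}' produced an empty half")

    extent = max(float(table["x_nm"].max()), float(table["y_nm"].max())) + 3 * render_pixel_nm
    n = int(math.ceil(extent / render_pixel_nm))
    n += n % 2  # even side keeps the DC bin at n//2
    ext = (n * render_pixel_nm, n * render_pixel_nm)
    img1 = render(half1, render_pixel_nm, mode="histogram", extent_nm=ext)
    img2 = render(half2, render_pixel_nm, mode="histogram", extent_nm=ext)
    return frc_curve_from_images(
        img1, img2, render_pixel_nm, threshold=threshold, ring_width_bins=ring_width_bins
    )
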