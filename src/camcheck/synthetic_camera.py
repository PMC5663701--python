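"""Synthetic detector and emitter simulator.

Generates per-pixel camera calibration maps, thermal warm-up series, and raw
ADU image stacks (dark frames, flat-field illumination, blinking or continuous
point emitters) with the statistical structure that the downstream analysis
assumes: Poisson photon shot noise filtered by the quantum efficiency,
Gaussian read noise added in electrons, per-pixel offset and gain applied
afterwards, and integer quantization with saturation clipping.

The generative model per pixel ``i`` and frame is

    electrons_i = Poisson(eta * Phi_i) + Normal(0, sigma_r_i)
    ADU_i       = clip(round(o_i + g_i * electrons_i), 0, 2**bit_depth - 1)

where ``Phi_i`` is the expected photon flux at the pixel, ``eta`` the quantum
efficiency at the simulated wavelength, ``o_i`` the offset (ADU), ``g_i`` the
gain (ADU per photoelectron) and ``sigma_r_i`` the read noise (electrons).
This is exactly the photon-transfer model that :mod:`camcheck.characterize`
inverts: for uniform illumination the temporal variance of a pixel is
``g**2 * (eta*Phi + sigma_r**2)`` while its mean above offset is
``g * eta * Phi``, a line with slope ``g`` and intercept ``g**2 * sigma_r**2``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.special import erf

logger = logging.getLogger(__name__)

__all__ = [
    "CameraSpec",
    "CameraMaps",
    "FrameStack",
    "GroundTruth",
    "WarmupModel",
    "TwoCameraView",
    "PRESETS",
    "get_preset",
    "make_camera_maps",
    "sensor_geometry",
    "simulate_stack",
    "simulate_two_camera_view",
    "simulate_warmup_series",
    "warmup_coupling",
    "make_ground_truth",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CameraSpec:
    """Static description of a detector model.

    Parameters
    ----------
    name : str
        Text label of the preset.
    sensor_shape : tuple
        Full sensor size as (rows, cols) in pixels.
    pixel_pitch_um : float
        Physical pixel width in micrometres.
    bit_depth : int
        ADC bit depth; saturation is ``2**bit_depth - 1`` ADU.
    qe : dict
        Mapping wavelength (nm) -> quantum efficiency in (0, 1].
    base_offset_adu : float
        Mean dark baseline in ADU.
    base_gain : float
        Mean conversion gain in ADU per photoelectron.
    base_read_noise_e : float
        Mean read noise in electrons.
    """

    name: str
    sensor_shape: tuple[int, int]
    pixel_pitch_um: float
    bit_depth: int
    qe: dict[float, float]
    base_offset_adu: float
    base_gain: float
    base_read_noise_e: float

    def __post_init__(self) -> None:
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel_pitch_um must be > 0")
        if self.base_gain <= 0:
            raise ValueError("base_gain must be > 0")
        if any(s <= 0 for s in self.sensor_shape):
            raise ValueError("sensor_shape must be positive")
        for wl, eta in self.qe.items():
            if not 0 < eta <= 1:
                raise ValueError(f"quantum efficiency at {wl} nm must be in (0, 1]")

    @property
    def saturation(self) -> int:
        return 2 ** self.bit_depth - 1

    def qe_at(self, wavelength_nm: float) -> float:
        """Quantum efficiency at a tabulated wavelength (no interpolation)."""
        try:
            return self.qe[wavelength_nm]
        except KeyError:
            raise KeyError(
                f"preset '{self.name}' has no quantum efficiency tabulated "
                f"at {wavelength_nm} nm (available: {sorted(self.qe)})"
            ) from None


@dataclass
class CameraMaps:
    """Per-pixel calibration maps: offset (ADU), gain (ADU/e-), read noise (e-)."""

    offset: np.ndarray
    gain: np.ndarray
    read_noise: np.ndarray

    def __post_init__(self) -> None:
        if not (self.offset.shape == self.gain.shape == self.read_noise.shape):
            raise ValueError("offset, gain and read_noise maps must share one shape")
        if np.any(self.gain <= 0):
            raise ValueError("gain map must be positive everywhere")
        if np.any(self.read_noise < 0):
            raise ValueError("read_noise map must be non-negative")
        if np.any(self.offset < 0):
            raise ValueError("offset map must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.offset.shape


@dataclass
class FrameStack:
    """Ordered stack of 2-D unsigned-integer ADU frames with acquisition metadata."""

    frames: np.ndarray  # (frame, row, col), uint16
    exposure_ms: float = 25.0
    frame_rate_fps: float = 40.0
    roi_origin: tuple[int, int] = (0, 0)
    n_saturated: int = 0

    def __post_init__(self) -> None:
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a 3-D (frame, row, col) array")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class GroundTruth:
    """Simulator record of the emitter scene, kept for parameter-recovery tests.

    ``photons_per_frame[f, e]`` is the number of photons emitter ``e`` emits in
    frame ``f`` *before* quantum efficiency; ``background`` is the expected
    background photon count per pixel per frame (its Poisson variance is the
    ``b**2`` of the precision model).
    """

    emitters: np.ndarray  # (n_emitters, 2) -> (x, y) nm
    photons_per_frame: np.ndarray  # (n_frames, n_emitters)
    background: float
    psf_sigma_nm: float
    wavelength_nm: float
    field_nm: tuple[float, float]

    def __post_init__(self) -> None:
        self.emitters = np.atleast_2d(np.asarray(self.emitters, dtype=float))
        if self.emitters.size == 0:
            self.emitters = self.emitters.reshape(0, 2)
        self.photons_per_frame = np.atleast_2d(
            np.asarray(self.photons_per_frame, dtype=float)
        )
        if np.any(self.photons_per_frame < 0):
            raise ValueError("photon counts must be >= 0")
        if self.psf_sigma_nm <= 0:
            raise ValueError("psf_sigma_nm must be > 0")

    @property
    def n_emitters(self) -> int:
        return self.emitters.shape[0]

    @property
    def n_frames(self) -> int:
        return self.photons_per_frame.shape[0]


@dataclass(frozen=True)
class WarmupModel:
    """Exponential housing warm-up: T(t) = T_inf - delta_T * exp(-t / tau)."""

    T_inf: float = 53.9  # degC asymptote
    delta_T: float = 30.0  # degC total rise
    tau_min: float = 12.0  # minutes
    noise_sd: float = 0.0  # degC measurement noise

    def __post_init__(self) -> None:
        if self.tau_min <= 0:
            raise ValueError("tau_min must be > 0")
        if self.delta_T < 0:
            raise ValueError("delta_T must be >= 0")

    def temperature(self, t_min: np.ndarray | float) -> np.ndarray:
        return self.T_inf - self.delta_T * np.exp(-np.asarray(t_min, float) / self.tau_min)


@dataclass
class TwoCameraView:
    """Beamsplitter simulation result: one stack per arm plus the photon split."""

    stack_a: FrameStack
    stack_b: FrameStack
    photons_a: np.ndarray  # (n_frames, n_emitters), before QE
    photons_b: np.ndarray

    def __iter__(self):
        return iter((self.stack_a, self.stack_b))


# ---------------------------------------------------------------------------
# Presets
#
# Values printed by the characterization (CMOS pixel pitch 5.86 um, sensor
# 1936 x 1216, QE 0.48/0.69 at 660 nm, read noise 6.4 e-) are used directly.
# The remaining constants (offsets, gains, sCMOS pitch and read noise) are
# package assumptions chosen to be representative of the detector classes.
# ---------------------------------------------------------------------------

PRESETS: dict[str, CameraSpec] = {
    "cmos": CameraSpec(
        name="cmos",
        sensor_shape=(1216, 1936),
        pixel_pitch_um=5.86,
        bit_depth=12,
        qe={660.0: 0.48, 500.0: 0.75},
        base_offset_adu=100.0,
        base_gain=2.1,
        base_read_noise_e=6.4,
    ),
    "scmos": CameraSpec(
        name="scmos",
        sensor_shape=(2048, 2048),
        pixel_pitch_um=6.5,
        bit_depth=16,
        qe={660.0: 0.69, 580.0: 0.72},
        base_offset_adu=100.0,
        base_gain=0.46,
        base_read_noise_e=1.4,
    ),
}


def get_preset(name: str) -> CameraSpec:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown camera preset '{name}' (available: {sorted(PRESETS)})") from None


# ---------------------------------------------------------------------------
# Calibration-map generation
# ---------------------------------------------------------------------------

def _lognormal_around(rng: np.random.Generator, base: float, cv: float,
                      shape: tuple[int, int]) -> np.ndarray:
    """Lognormal field with mean ``base`` and coefficient of variation ``cv``."""
    if cv == 0:
        return np.full(shape, float(base))
    sigma2 = math.log(1.0 + cv * cv)
    mu = math.log(base) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=shape)


def make_camera_maps(
    spec: CameraSpec,
    *,
    shape: tuple[int, int] | None = None,
    stripe_amplitude: float = 0.02,
    stripe_period: float = 8.0,
    hot_fraction: float = 0.0011,
    hot_scale: float = 3.0,
    pixel_cv: float = 0.02,
    seed: int = 0,
) -> CameraMaps:
    """Draw per-pixel offset/gain/read-noise maps around the preset base values.

    Each map gets independent lognormal pixel-to-pixel scatter with coefficient
    of variation ``pixel_cv``.  Read noise and gain additionally receive a
    column-wise sinusoidal modulation of relative amplitude ``stripe_amplitude``
    and period ``stripe_period`` pixels — the vertical-stripe fixed pattern
    typical of column-parallel CMOS readout.  A random ``hot_fraction`` of
    pixels has its read noise multiplied by ``hot_scale`` (hot pixels).

    Deterministic for a fixed ``seed``.
    """
    if stripe_amplitude < 0:
        raise ValueError("stripe_amplitude must be >= 0")
    if pixel_cv < 0:
        raise ValueError("pixel_cv must be >= 0")
    if not 0 <= hot_fraction < 1:
        raise ValueError("hot_fraction must be in [0, 1)")
    if stripe_period < 1:
        raise ValueError("stripe_period must be >= 1 pixel")
    if hot_scale < 1:
        raise ValueError("hot_scale must be >= 1")

    shape = tuple(shape) if shape is not None else tuple(spec.sensor_shape)
    rng = np.random.default_rng(seed)

    offset = _lognormal_around(rng, spec.base_offset_adu, pixel_cv, shape)
    gain = _lognormal_around(rng, spec.base_gain, pixel_cv, shape)
    read_noise = _lognormal_around(rng, spec.base_read_noise_e, pixel_cv, shape)

    cols = np.arange(shape[1], dtype=float)
    stripes = 1.0 + stripe_amplitude * np.sin(2.0 * np.pi * cols / stripe_period)
    gain *= stripes[np.newaxis, :]
    read_noise *= stripes[np.newaxis, :]

    n_hot = int(round(hot_fraction * offset.size))
    if n_hot > 0:
        flat_idx = rng.choice(offset.size, size=n_hot, replace=False)
        read_noise.flat[flat_idx] *= hot_scale

    return CameraMaps(offset=offset, gain=gain, read_noise=read_noise)


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def sensor_geometry(
    spec: CameraSpec,
    magnification: float,
    roi: tuple[int, int] | None = None,
    binning: int = 1,
) -> dict:
    """Projected pixel width, field of view and binning penalty.

    projected width (nm) = pitch * binning / magnification;
    the FOV is quoted for the unbinned ROI;
    fov_loss_from_binning = 1 - 1/binning**2 is the fraction of the maximal
    field of view given up by reaching the same projected pixel width through
    n x n binning instead of a natively larger pixel.
    """
    if magnification <= 0:
        raise ValueError("magnification must be > 0")
    if binning < 1:
        raise ValueError("binning must be >= 1")
    roi = tuple(roi) if roi is not None else tuple(spec.sensor_shape)

    pitch_nm = spec.pixel_pitch_um * 1000.0
    projected_nm = pitch_nm * binning / magnification
    base_width_nm = pitch_nm / magnification
    fov_um = (roi[0] * base_width_nm / 1000.0, roi[1] * base_width_nm / 1000.0)
    return {
        "projected_pixel_width_nm": projected_nm,
        "fov_um": fov_um,
        "fov_loss_from_binning": 1.0 - 1.0 / binning ** 2,
    }


# ---------------------------------------------------------------------------
# Stack simulation
# ---------------------------------------------------------------------------

def _pixel_edges_erf(centers_px: np.ndarray, pos_px: float, sigma_px: float) -> np.ndarray:
    """Integral of a unit 1-D Gaussian at pos_px over pixels [c, c+1)."""
    s = sigma_px * math.sqrt(2.0)
    return 0.5 * (erf((centers_px + 1.0 - pos_px) / s) - erf((centers_px - pos_px) / s))


def _render_emitter_photons(
    shape: tuple[int, int],
    truth: GroundTruth,
    projected_pixel_nm: float,
) -> np.ndarray:
    """Expected photon image per frame: erf-integrated PSFs plus flat background.

    Returns an array of shape (n_frames, rows, cols) of expected photon counts
    (before quantum efficiency).  Emitters whose centre falls outside the ROI
    are skipped with a logged warning.
    """
    n_frames = truth.n_frames
    rows, cols = shape
    sigma_px = truth.psf_sigma_nm / projected_pixel_nm
    phi = np.full((n_frames, rows, cols), float(truth.background))

    half = max(3, int(math.ceil(5.0 * sigma_px)))
    for e in range(truth.n_emitters):
        x_nm, y_nm = truth.emitters[e]
        # x maps to columns, y to rows; pixel j covers x/pp in [j, j+1)
        cx = x_nm / projected_pixel_nm
        cy = y_nm / projected_pixel_nm
        if not (0 <= cx < cols and 0 <= cy < rows):
            logger.warning("emitter %d at (%.1f, %.1f) nm outside ROI; skipped", e, x_nm, y_nm)
            continue
        c0 = max(0, int(cx) - half)
        c1 = min(cols, int(cx) + half + 1)
        r0 = max(0, int(cy) - half)
        r1 = min(rows, int(cy) + half + 1)
        ex = _pixel_edges_erf(np.arange(c0, c1, dtype=float), cx, sigma_px)
        ey = _pixel_edges_erf(np.arange(r0, r1, dtype=float), cy, sigma_px)
        footprint = np.outer(ey, ex)  # (rows, cols) patch, integrates to ~1
        photons = truth.photons_per_frame[:, e]
        active = np.nonzero(photons > 0)[0]
        if active.size:
            phi[active, r0:r1, c0:c1] += photons[active, None, None] * footprint[None, :, :]
    return phi


def simulate_stack(
    maps: CameraMaps,
    spec: CameraSpec,
    mode: Literal["dark", "flat", "emitters"],
    n_frames: int,
    *,
    mean_photons: float | None = None,
    truth: GroundTruth | None = None,
    projected_pixel_nm: float | None = None,
    wavelength_nm: float | None = None,
    exposure_ms: float = 25.0,
    frame_rate_fps: float = 40.0,
    seed: int = 0,
) -> FrameStack:
    """Simulate a raw ADU stack under the Poisson + Gaussian-read-noise model.

    ``mode='dark'`` uses zero photon flux, ``mode='flat'`` a uniform flux of
    ``mean_photons`` per pixel per frame, ``mode='emitters'`` renders the
    ``truth`` scene (erf-integrated Gaussian PSFs plus flat background) at
    ``projected_pixel_nm``.  The quantum efficiency is looked up at
    ``wavelength_nm`` (``truth.wavelength_nm`` in emitters mode); when no
    wavelength is given the flux is interpreted as already-detected
    photoelectrons (eta = 1).
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    shape = maps.shape
    rows, cols = shape

    if mode == "dark":
        phi = None
        eta = 1.0
    elif mode == "flat":
        if mean_photons is None:
            raise ValueError("flat mode requires mean_photons")
        phi = float(mean_photons)
        eta = 1.0 if wavelength_nm is None else spec.qe_at(wavelength_nm)
    elif mode == "emitters":
        if truth is None or projected_pixel_nm is None:
            raise ValueError("emitters mode requires truth and projected_pixel_nm")
        if projected_pixel_nm <= 0:
            raise ValueError("projected_pixel_nm must be > 0")
        phi = _render_emitter_photons(shape, truth, projected_pixel_nm)
        if phi.shape[0] < n_frames:
            raise ValueError("truth covers fewer frames than requested")
        phi = phi[:n_frames]
        eta = spec.qe_at(truth.wavelength_nm)
    else:
        raise ValueError(f"unknown mode '{mode}'")

    frames = np.empty((n_frames, rows, cols), dtype=np.uint16)
    n_saturated = 0
    sat = spec.saturation
    for f in range(n_frames):
        if phi is None:
            electrons = np.zeros(shape)
        elif np.isscalar(phi):
            electrons = rng.poisson(eta * phi, size=shape).astype(float)
        else:
            electrons = rng.poisson(eta * phi[f]).astype(float)
        electrons += rng.normal(0.0, 1.0, size=shape) * maps.read_noise
        adu = np.rint(maps.offset + maps.gain * electrons)
        n_saturated += int(np.count_nonzero(adu > sat))
        frames[f] = np.clip(adu, 0, sat).astype(np.uint16)
    if n_saturated:
        logger.warning("%d saturated pixel events in simulated stack", n_saturated)
    return FrameStack(
        frames=frames,
        exposure_ms=exposure_ms,
        frame_rate_fps=frame_rate_fps,
        n_saturated=n_saturated,
    )


def simulate_two_camera_view(
    truth: GroundTruth,
    cam_a: tuple[CameraMaps, CameraSpec, float],
    cam_b: tuple[CameraMaps, CameraSpec, float],
    *,
    split: float = 0.5,
    seed: int = 0,
) -> TwoCameraView:
    """Simultaneous two-camera imaging through a beamsplitter.

    Each emitter's photons in each frame are partitioned binomially (fraction
    ``split`` to camera A, the remainder to B — the partition conserves the
    per-frame photon total exactly); each arm is then rendered with its own
    calibration maps, quantum efficiency and projected pixel width.
    """
    if not 0 < split <= 1:
        raise ValueError("split must be in (0, 1]")
    rng = np.random.default_rng(seed)
    photons = np.rint(truth.photons_per_frame).astype(np.int64)
    photons_a = rng.binomial(photons, split).astype(float)
    photons_b = (photons - photons_a).astype(float)

    stacks = []
    for arm_photons, (maps, spec, pp), sub in (
        (photons_a, cam_a, 1),
        (photons_b, cam_b, 2),
    ):
        arm_truth = GroundTruth(
            emitters=truth.emitters.copy(),
            photons_per_frame=arm_photons,
            background=truth.background * (split if sub == 1 else 1 - split),
            psf_sigma_nm=truth.psf_sigma_nm,
            wavelength_nm=truth.wavelength_nm,
            field_nm=truth.field_nm,
        )
        stacks.append(
            simulate_stack(
                maps, spec, "emitters", truth.n_frames,
                truth=arm_truth, projected_pixel_nm=pp,
                seed=int(rng.integers(2 ** 31 - 1)),
            )
        )
    return TwoCameraView(stacks[0], stacks[1], photons_a, photons_b)


# ---------------------------------------------------------------------------
# Thermal warm-up
# ---------------------------------------------------------------------------

def simulate_warmup_series(
    model: WarmupModel,
    duration_min: float,
    interval_s: float = 40.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sampled housing-temperature series T(t) = T_inf - dT*exp(-t/tau) + noise."""
    if duration_min <= 0:
        raise ValueError("duration_min must be > 0")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, duration_min + 1e-9, interval_s / 60.0)
    temps = model.temperature(times)
    if model.noise_sd > 0:
        temps = temps + rng.normal(0.0, model.noise_sd, size=times.shape)
    return times, temps


def warmup_coupling(
    model: WarmupModel,
    times_min: np.ndarray,
    *,
    max_offset_rise_adu: float = 1.3,
    max_noise_rise: float = 0.06,
) -> tuple[np.ndarray, np.ndarray]:
    """Thermal coupling of the dark level and read noise to the warm-up curve.

    Returns ``(offset_delta_adu, noise_scale)`` per sample: the dark baseline
    rises by up to ``max_offset_rise_adu`` ADU and the read noise by a relative
    ``max_noise_rise`` (6% by default, i.e. a 6.05 -> 6.40 e- rise at the
    camera's 6.4 e- equilibrium noise) in proportion to the normalized
    temperature rise above the cold start.
    """
    t = np.asarray(times_min, dtype=float)
    if model.delta_T == 0:
        frac = np.ones_like(t)
    else:
        frac = (model.temperature(t) - (model.T_inf - model.delta_T)) / model.delta_T
    return max_offset_rise_adu * frac, 1.0 + max_noise_rise * frac


# ---------------------------------------------------------------------------
# Ground-truth scene generation
# ---------------------------------------------------------------------------

def _draw_photons(rng: np.random.Generator, dist: dict, size: int) -> np.ndarray:
    kind = dist.get("dist", "constant")
    if kind == "constant":
        return np.full(size, float(dist["value"]))
    if kind == "lognormal":
        median = float(dist.get("median", 1000.0))
        sigma = float(dist.get("sigma", 0.5))
        return rng.lognormal(mean=math.log(median), sigma=sigma, size=size)
    if kind == "poisson":
        return rng.poisson(float(dist["mean"]), size=size).astype(float)
    raise ValueError(f"unknown photon distribution '{kind}'")


def make_ground_truth(
    kind: Literal["grid", "random", "filament"],
    n_emitters: int,
    *,
    photons: dict | float = 1000.0,
    on_probability: float = 1.0,
    n_frames: int = 100,
    field_nm: tuple[float, float] = (7000.0, 7000.0),
    psf_sigma_nm: float = 130.0,
    background: float = 5.0,
    wavelength_nm: float = 660.0,
    filament_gap_nm: float = 40.0,
    filament_angle_rad: float = 0.5,
    label_scatter_nm: float = 0.0,
    mean_on_frames: float = 1.0,
    margin_nm: float | None = None,
    seed: int = 0,
) -> GroundTruth:
    """Generate an emitter scene.

    ``kind='grid'`` and ``'random'`` place always-on or blinking point
    emitters (beads / sparse single molecules); ``'filament'`` places emitters
    on two parallel lines ``filament_gap_nm`` apart through the field centre,
    emulating the projected wall separation of a hollow filament.  Emitters are
    on in a frame with independent probability ``on_probability`` and emit a
    photon count drawn from ``photons`` (a number for a fixed count, or a
    distribution spec dict such as ``{"dist": "lognormal", "median": 1000,
    "sigma": 0.5}``).  ``label_scatter_nm`` adds isotropic Gaussian scatter
    to every emitter position, emulating the displacement of the fluorophore
    from the target structure by the antibody linkage.

    With ``mean_on_frames > 1`` the on/off state follows a two-state Markov
    chain whose mean on-time is ``mean_on_frames`` frames and whose
    stationary on-fraction equals ``on_probability`` — photoswitchable dyes
    typically stay on across a few consecutive frames, which is what makes
    consecutive-frame nearest-neighbor analysis informative.
    """
    if not 0 <= on_probability <= 1:
        raise ValueError("on_probability must be in [0, 1]")
    rng = np.random.default_rng(seed)
    fx, fy = field_nm
    if margin_nm is None:
        margin_nm = 6.0 * psf_sigma_nm
    if n_emitters > 0 and (fx <= 2 * margin_nm or fy <= 2 * margin_nm):
        raise ValueError("field too small for the requested structure")

    if n_emitters == 0:
        positions = np.zeros((0, 2))
    elif kind == "grid":
        n_side = int(math.ceil(math.sqrt(n_emitters)))
        xs = np.linspace(margin_nm, fx - margin_nm, n_side)
        ys = np.linspace(margin_nm, fy - margin_nm, n_side)
        gx, gy = np.meshgrid(xs, ys)
        positions = np.column_stack([gx.ravel(), gy.ravel()])[:n_emitters]
        # sub-pixel dither so fits are not all pixel-centred
        positions = positions + rng.uniform(-50.0, 50.0, size=positions.shape)
    elif kind == "random":
        positions = np.column_stack([
            rng.uniform(margin_nm, fx - margin_nm, n_emitters),
            rng.uniform(margin_nm, fy - margin_nm, n_emitters),
        ])
    elif kind == "filament":
        cx, cy = fx / 2.0, fy / 2.0
        direction = np.array([math.cos(filament_angle_rad), math.sin(filament_angle_rad)])
        normal = np.array([-direction[1], direction[0]])
        half_len = 0.5 * min(fx, fy) - margin_nm
        t = rng.uniform(-half_len, half_len, n_emitters)
        side = np.where(rng.random(n_emitters) < 0.5, -1.0, 1.0)
        positions = (
            np.array([cx, cy])
            + t[:, None] * direction[None, :]
            + (side * filament_gap_nm / 2.0)[:, None] * normal[None, :]
        )
    else:
        raise ValueError(f"unknown ground-truth kind '{kind}'")

    if label_scatter_nm > 0 and len(positions):
        positions = positions + rng.normal(0.0, label_scatter_nm, positions.shape)

    if isinstance(photons, (int, float)):
        photons = {"dist": "constant", "value": float(photons)}

    if mean_on_frames <= 1.0 or on_probability in (0.0, 1.0):
        on = rng.random((n_frames, n_emitters)) < on_probability
    else:
        # two-state Markov chain: mean on-time = mean_on_frames,
        # stationary P(on) = on_probability
        k_off = 1.0 / mean_on_frames
        k_on = on_probability * k_off / (1.0 - on_probability)
        k_on = min(k_on, 1.0)
        on = np.zeros((n_frames, n_emitters), dtype=bool)
        state = rng.random(n_emitters) < on_probability
        on[0] = state
        for f in range(1, n_frames):
            u = rng.random(n_emitters)
            state = np.where(state, u > k_off, u < k_on)
            on[f] = state
    counts = np.zeros((n_frames, n_emitters))
    n_on = int(on.sum())
    if n_on:
        counts[on] = np.rint(_draw_photons(rng, photons, n_on))
    return GroundTruth(
        emitters=positions,
        photons_per_frame=counts,
        background=background,
        psf_sigma_nm=psf_sigma_nm,
        wavelength_nm=wavelength_nm,
        field_nm=(fx, fy),
    )
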