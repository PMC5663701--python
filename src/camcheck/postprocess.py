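"""Localization-table post-processing.

Precision filtering (strict "less than"), local-density filtering (at least
``min_neighbors`` others within a radius, all frames pooled), merging of
re-activations across consecutive frames, and drift correction by
cross-correlating reconstructions of temporal sub-stacks.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .metrics import render

logger = logging.getLogger(__name__)

__all__ = [
    "DriftTrack",
    "filter_by_precision",
    "density_filter",
    "merge_consecutive",
    "estimate_drift",
    "apply_drift",
]


def filter_by_precision(table: pd.DataFrame, max_uncertainty_nm: float) -> pd.DataFrame:
    """Keep records with uncertainty strictly below the threshold; order preserved."""
    if len(table) == 0:
        return table.copy()
    return table[table["uncertainty_nm"] < max_uncertainty_nm].copy()


def density_filter(table: pd.DataFrame, radius_nm: float, min_neighbors: int) -> pd.DataFrame:
    """Keep records with at least ``min_neighbors`` *other* records within ``radius_nm``.

    All frames are pooled; neighbor counts are computed once on the input
    table (a single pass, not iterated to a fixed point).
    """
    if radius_nm <= 0:
        raise ValueError("radius_nm must be > 0")
    if len(table) == 0:
        return table.copy()
    xy = table[["x_nm", "y_nm"]].to_numpy()
    tree = cKDTree(xy)
    counts = np.array(tree.query_ball_point(xy, r=radius_nm, return_length=True))
    counts -= 1  # the record itself does not count
    return table[counts >= min_neighbors].copy()


def merge_consecutive(table: pd.DataFrame, radius_nm: float = 20.0,
                      max_gap: int = 1) -> pd.DataFrame:
    """Merge re-activations of one molecule across nearby frames.

    Records are linked into a chain when they lie within ``radius_nm`` and
    their frame gap is at most ``max_gap + 1`` (``max_gap`` dark frames are
    tolerated inside a chain, so with the default gap of 1 frames n and n+2
    are linkable).  Linking is greedy nearest-in-frame per chain; when two
    chains compete for one record the lower-uncertainty chain end wins.  Each
    chain collapses to a single record at the intensity-weighted mean
    position with summed intensity, the first frame index, and the
    uncertainty of the weighted mean (sqrt(sum (w_i sigma_i)^2) / sum w_i).
    """
    if radius_nm <= 0:
        raise ValueError("radius_nm must be > 0")
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    if len(table) == 0:
        return table.copy()

    df = table.sort_values("frame", kind="stable").reset_index(drop=True)
    frames = df["frame"].to_numpy()
    xy = df[["x_nm", "y_nm"]].to_numpy()
    unc = df["uncertainty_nm"].to_numpy()

    chain_of = -np.ones(len(df), dtype=int)
    # open chains: (chain_id, last_index); closed when too old to extend
    chains: list[list[int]] = []
    open_chains: list[int] = []

    for f in np.unique(frames):
        # drop chains whose last frame can no longer link to frame f
        open_chains = [
            cid for cid in open_chains
            if f - frames[chains[cid][-1]] <= max_gap + 1
        ]
        idx_f = np.nonzero(frames == f)[0]
        if open_chains:
            last_idx = np.array([chains[cid][-1] for cid in open_chains])
            tree = cKDTree(xy[last_idx])
            # candidate links, resolved greedily: among competing links the
            # lower-uncertainty chain end wins its nearest record
            pairs = []
            for i in idx_f:
                dists, js = tree.query(xy[i], k=min(3, len(open_chains)),
                                       distance_upper_bound=radius_nm)
                dists = np.atleast_1d(dists)
                js = np.atleast_1d(js)
                for d, j in zip(dists, js):
                    if np.isfinite(d):
                        pairs.append((unc[last_idx[j]], d, int(j), int(i)))
            taken_chain: set[int] = set()
            taken_rec: set[int] = set()
            for u, d, j, i in sorted(pairs):
                if j in taken_chain or i in taken_rec:
                    continue
                cid = open_chains[j]
                chains[cid].append(i)
                chain_of[i] = cid
                taken_chain.add(j)
                taken_rec.add(i)
        for i in idx_f:
            if chain_of[i] < 0:
                chain_of[i] = len(chains)
                chains.append([i])
        open_chains = [cid for cid in range(len(chains))
                       if f - frames[chains[cid][-1]] <= max_gap + 1
                       and frames[chains[cid][-1]] <= f]

    out = []
    for members in chains:
        sub = df.iloc[members]
        w = sub["intensity_photon"].to_numpy()
        if not np.all(w > 0):
            w = np.ones(len(sub))
        wsum = w.sum()
        merged = {
            "frame": int(sub["frame"].min()),
            "x_nm": float((w * sub["x_nm"]).sum() / wsum),
            "y_nm": float((w * sub["y_nm"]).sum() / wsum),
            "sigma_nm": float((w * sub["sigma_nm"]).sum() / wsum),
            "intensity_photon": float(sub["intensity_photon"].sum()),
            "offset_photon": float(sub["offset_photon"].mean()),
            "bkgstd_photon": float(sub["bkgstd_photon"].mean()),
            "uncertainty_nm": float(
                math.sqrt(((w * sub["uncertainty_nm"].to_numpy()) ** 2).sum()) / wsum
            ),
        }
        out.append(merged)
    result = pd.DataFrame(out, columns=df.columns)
    return result.sort_values(["frame", "x_nm"], kind="stable").reset_index(drop=True)


@dataclass
class DriftTrack:
    """Estimated drift: per-bin shifts plus per-frame interpolation.

    The first bin defines the reference, so its shift is (0, 0).
    """

    bin_centers_frame: np.ndarray
    bin_shifts_nm: np.ndarray  # (n_bins, 2) -> (dx, dy)
    frame_range: tuple[int, int]

    def shifts_for_frames(self, frames: np.ndarray) -> np.ndarray:
        """Per-frame (dx, dy): linear between bin centers, constant at the ends."""
        frames = np.asarray(frames, dtype=float)
        lo, hi = self.frame_range
        if frames.size and (frames.min() < lo or frames.max() > hi):
            raise ValueError(
                f"frames outside the drift track range [{lo}, {hi}]"
            )
        dx = np.interp(frames, self.bin_centers_frame, self.bin_shifts_nm[:, 0])
        dy = np.interp(frames, self.bin_centers_frame, self.bin_shifts_nm[:, 1])
        return np.column_stack([dx, dy])


def _xcorr_shift_px(img_ref: np.ndarray, img: np.ndarray) -> tuple[float, float]:
    """Shift (dx, dy) of ``img`` relative to ``img_ref`` from the FFT
    cross-correlation peak with parabolic sub-pixel interpolation."""
    f_ref = np.fft.fft2(img_ref)
    f_img = np.fft.fft2(img)
    cc = np.real(np.fft.ifft2(f_img * np.conj(f_ref)))
    cc = np.fft.fftshift(cc)
    peak = np.unravel_index(np.argmax(cc), cc.shape)
    center = np.array(cc.shape) // 2

    def parabolic(vals_m, vals_0, vals_p) -> float:
        denom = vals_m - 2 * vals_0 + vals_p
        if denom == 0:
            return 0.0
        return 0.5 * (vals_m - vals_p) / denom

    pr, pc = peak
    dr = float(pr - center[0])
    dc = float(pc - center[1])
    if 0 < pr < cc.shape[0] - 1:
        dr += parabolic(cc[pr - 1, pc], cc[pr, pc], cc[pr + 1, pc])
    if 0 < pc < cc.shape[1] - 1:
        dc += parabolic(cc[pr, pc - 1], cc[pr, pc], cc[pr, pc + 1])
    return dc, dr  # (dx, dy) in pixels


def estimate_drift(table: pd.DataFrame, n_bins: int = 5,
                   render_pixel_nm: float = 20.0) -> DriftTrack:
    """Drift from cross-correlation of temporally binned reconstructions.

    Frames are split into ``n_bins`` equal temporal bins; each bin is
    rendered as a 2-D histogram at ``render_pixel_nm`` and its shift relative
    to the first bin read from the cross-correlation peak (parabolic
    sub-pixel interpolation).  Per-frame shifts interpolate linearly between
    bin centers with constant extrapolation at the ends.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if len(table) == 0:
        raise ValueError("cannot estimate drift from an empty table")
    frames = table["frame"].to_numpy()
    f_lo, f_hi = int(frames.min()), int(frames.max())
    edges = np.linspace(f_lo, f_hi + 1, n_bins + 1)

    extent = (
        float(table["x_nm"].max()) + 3 * render_pixel_nm,
        float(table["y_nm"].max()) + 3 * render_pixel_nm,
    )
    images = []
    centers = []
    for b in range(n_bins):
        sel = (frames >= edges[b]) & (frames < edges[b + 1])
        sub = table[sel]
        if len(sub) == 0:
            raise ValueError(f"temporal bin {b} contains no localizations")
        if len(sub) < 100:
            warnings.warn(
                f"temporal bin {b} has only {len(sub)} localizations; "
                "the drift estimate may be unreliable", stacklevel=2,
            )
        images.append(render(sub, render_pixel_nm, mode="histogram", extent_nm=extent))
        centers.append(0.5 * (edges[b] + edges[b + 1] - 1))

    shifts = np.zeros((n_bins, 2))
    for b in range(1, n_bins):
        dx_px, dy_px = _xcorr_shift_px(images[0], images[b])
        shifts[b] = (dx_px * render_pixel_nm, dy_px * render_pixel_nm)
    return DriftTrack(
        bin_centers_frame=np.asarray(centers),
        bin_shifts_nm=shifts,
        frame_range=(f_lo, f_hi),
    )


def apply_drift(table: pd.DataFrame, track: DriftTrack) -> pd.DataFrame:
    """Subtract the per-frame drift from each record's coordinates."""
    out = table.copy()
    if len(out) == 0:
        return out
    shifts = track.shifts_for_frames(out["frame"].to_numpy())
    out["x_nm"] = out["x_nm"].to_numpy() - shifts[:, 0]
    out["y_nm"] = out["y_nm"].to_numpy() - shifts[:, 1]
    return out
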