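"""Standard-format I/O: multipage TIFF stacks, calibration-map TIFFs,
localization CSV (ThunderSTORM-compatible and snake_case dialects), ground
truth CSV, YAML configs."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .localize import COLUMNS, LocalizationTable
from .synthetic_camera import CameraMaps, FrameStack, GroundTruth

__all__ = [
    "write_stack",
    "read_stack",
    "write_maps",
    "read_maps",
    "write_localizations",
    "read_localizations",
    "write_ground_truth",
    "load_config",
]

# ThunderSTORM CSV dialect <-> canonical snake_case columns
_TS_HEADERS = {
    "frame": "frame",
    "x [nm]": "x_nm",
    "y [nm]": "y_nm",
    "sigma [nm]": "sigma_nm",
    "intensity [photon]": "intensity_photon",
    "offset [photon]": "offset_photon",
    "bkgstd [photon]": "bkgstd_photon",
    "uncertainty [nm]": "uncertainty_nm",
    # common ThunderSTORM variants
    "uncertainty_xy [nm]": "uncertainty_nm",
    "id": "id",
}


def write_stack(path: str | Path, stack: FrameStack, *, metadata: dict | None = None) -> None:
    """Write a stack as little-endian 16-bit multipage TIFF + JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, stack.frames.astype("<u2"))
    meta = {
        "exposure_ms": stack.exposure_ms,
        "frame_rate_fps": stack.frame_rate_fps,
        "roi_origin": list(stack.roi_origin),
        "n_saturated": stack.n_saturated,
    }
    if metadata:
        meta.update(metadata)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def read_stack(path: str | Path) -> FrameStack:
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[np.newaxis]
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return FrameStack(
        frames=np.ascontiguousarray(frames, dtype=np.uint16),
        exposure_ms=meta.get("exposure_ms", 25.0),
        frame_rate_fps=meta.get("frame_rate_fps", 40.0),
        roi_origin=tuple(meta.get("roi_origin", (0, 0))),
        n_saturated=meta.get("n_saturated", 0),
    )


def write_maps(directory: str | Path, maps: CameraMaps, *, prefix: str = "") -> dict:
    """Write calibration maps as three 32-bit-float TIFFs with a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {}
    for name, arr in (("offset", maps.offset), ("gain", maps.gain),
                      ("read_noise", maps.read_noise)):
        fname = f"{prefix}{name}.tif"
        tifffile.imwrite(directory / fname, arr.astype(np.float32))
        manifest[name] = fname
    manifest["shape"] = list(maps.shape)
    (directory / f"{prefix}maps_manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def read_maps(directory: str | Path, *, prefix: str = "") -> CameraMaps:
    directory = Path(directory)
    manifest = json.loads((directory / f"{prefix}maps_manifest.json").read_text())
    arrays = {
        name: tifffile.imread(directory / manifest[name]).astype(float)
        for name in ("offset", "gain", "read_noise")
    }
    return CameraMaps(**arrays)


def write_localizations(
    path: str | Path,
    table: pd.DataFrame | LocalizationTable,
    *,
    dialect: str = "thunderstorm",
) -> None:
    """Write a localization table as CSV (6-decimal nm precision).

    ``dialect='thunderstorm'`` writes the quoted bracketed headers; ``'snake'``
    writes plain snake_case column names.  Provenance (when present) goes to a
    JSON sidecar.
    """
    path = Path(path)
    if isinstance(table, LocalizationTable):
        df, prov = table.df, table.provenance
    else:
        df, prov = table, None
    df = df[COLUMNS].copy()
    if dialect == "thunderstorm":
        header = ('frame,"x [nm]","y [nm]","sigma [nm]","intensity [photon]",'
                  '"offset [photon]","bkgstd [photon]","uncertainty [nm]"')
        body = df.to_csv(index=False, header=False, float_format="%.6f")
        path.write_text(header + "\n" + body)
    elif dialect == "snake":
        df.to_csv(path, index=False, float_format="%.6f")
    else:
        raise ValueError(f"unknown dialect '{dialect}'")
    if prov is not None:
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(prov, indent=1, default=str)
        )


def read_localizations(path: str | Path) -> LocalizationTable:
    """Read a localization CSV in either dialect (auto-detected by headers)."""
    path = Path(path)
    df = pd.read_csv(path)
    renames = {}
    for col in df.columns:
        key = col.strip().strip('"')
        if key in _TS_HEADERS:
            renames[col] = _TS_HEADERS[key]
        elif key in COLUMNS:
            renames[col] = key
        else:
            raise ValueError(f"unrecognized localization column: {col!r} in {path}")
    df = df.rename(columns=renames)
    missing = [c for c in ("frame", "x_nm", "y_nm") if c not in df.columns]
    if missing:
        raise ValueError(f"localization file {path} is missing columns: {missing}")
    for c in COLUMNS:
        if c not in df.columns:
            df[c] = np.nan
    df["frame"] = df["frame"].astype(int)
    sidecar = path.with_suffix(path.suffix + ".json")
    prov = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return LocalizationTable(df=df[COLUMNS], provenance=prov)


def write_ground_truth(path: str | Path, truth: GroundTruth) -> None:
    """Ground truth as CSV: emitter_id, frame, x_nm, y_nm, photons (on-events only)."""
    rows = []
    for e in range(truth.n_emitters):
        x, y = truth.emitters[e]
        on_frames = np.nonzero(truth.photons_per_frame[:, e] > 0)[0]
        for f in on_frames:
            rows.append((e, int(f), x, y, truth.photons_per_frame[f, e]))
    df = pd.DataFrame(rows, columns=["emitter_id", "frame", "x_nm", "y_nm", "photons"])
    df.to_csv(path, index=False, float_format="%.6f")


def load_config(path: str | Path) -> dict:
    """Load a YAML experiment configuration."""
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    return cfg
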