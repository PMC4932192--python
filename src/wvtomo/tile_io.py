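"""On-disk interchange: TIFF tiles + JSON manifest, TIFF plane export.

The manifest is the contract between simulation and reconstruction: one JSON
document carrying the plan, the optics and one row per raw frame (channel,
section, z-plane, phase, tile indices, stage position, filename).  Raw tiles
are written as 16-bit grayscale TIFF with a per-run intensity scale recorded
in the manifest; reconstructed planes are exported 8- or 16-bit with linear
min/max scaling per volume, LZW-compressed when the codec is available.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np
import tifffile

from .planner import AcquisitionPlan, OpticsConfig
from .scope_sim import RawTile

__all__ = ["write_run", "load_run", "export_volume"]

_RAW_DTYPE_MAX = 65535


def _imwrite(path: Path, arr: np.ndarray) -> None:
    try:
        tifffile.imwrite(path, arr, compression="lzw")
    except (ValueError, KeyError, ImportError):  # codec unavailable
        tifffile.imwrite(path, arr)


def _frame_name(t: RawTile) -> str:
    ix, iy = t.tile_index
    return (f"S{t.section_index:04d}_Y{iy:02d}_X{ix:02d}"
            f"_Z{t.z_plane_index}_P{t.phase_index}_{t.channel}.tif")


def write_run(out_dir: str | Path, tiles: List[RawTile], manifest: Dict) -> Path:
    """Write raw tiles as 16-bit TIFF plus ``manifest.json``; returns the manifest path.

    Intensities are quantized with a common scale chosen so the brightest
    pixel of the run maps to the top of the 16-bit range; the scale is stored
    in the manifest for lossless unscaling on load (up to quantization).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    peak = max((float(t.pixels.max()) for t in tiles), default=0.0)
    scale = (_RAW_DTYPE_MAX / peak) if peak > 0 else 1.0
    manifest = dict(manifest)
    manifest["intensity_scale"] = scale
    frames = []
    for t, row in zip(tiles, manifest["frames"]):
        name = _frame_name(t)
        q = np.clip(np.round(t.pixels * scale), 0, _RAW_DTYPE_MAX).astype(np.uint16)
        _imwrite(out / name, q)
        row = dict(row)
        row["file"] = name
        frames.append(row)
    manifest["frames"] = frames
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1))
    return mpath


def load_run(manifest_path: str | Path
             ) -> Tuple[List[RawTile], AcquisitionPlan, OpticsConfig, Dict]:
    """Load a written run back into RawTiles (intensities unscaled to linear units)."""
    mpath = Path(manifest_path)
    manifest = json.loads(mpath.read_text())
    plan = AcquisitionPlan.from_dict(manifest["plan"])
    optics = OpticsConfig.from_dict(manifest["optics"])
    scale = manifest.get("intensity_scale", 1.0)
    missing = [row["file"] for row in manifest["frames"]
               if not (mpath.parent / row["file"]).exists()]
    if missing:
        raise FileNotFoundError(f"manifest references missing frames: {missing[:5]}"
                                + ("..." if len(missing) > 5 else ""))
    tiles = []
    for row in manifest["frames"]:
        pixels = tifffile.imread(mpath.parent / row["file"]).astype(np.float64) / scale
        tiles.append(RawTile(
            pixels=pixels, channel=row["channel"], section_index=row["section"],
            z_plane_index=row["z_plane"], phase_index=row["phase"],
            tile_index=(row["ix"], row["iy"]),
            stage_position_um=(row["stage_x_um"], row["stage_y_um"]),
        ))
    return tiles, plan, optics, manifest


def export_volume(volume: np.ndarray, out_dir: str | Path, channel: str,
                  bit_depth: int = 8) -> List[Path]:
    """Write one plane per TIFF with linear min/max scaling over the whole volume."""
    if bit_depth not in (8, 16):
        raise ValueError("bit_depth must be 8 or 16")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lo, hi = float(volume.min()), float(volume.max())
    span = hi - lo if hi > lo else 1.0
    top = 255 if bit_depth == 8 else 65535
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    paths = []
    for k, plane in enumerate(volume):
        q = np.clip(np.round((plane - lo) / span * top), 0, top).astype(dtype)
        path = out / f"{channel}_plane{k:05d}.tif"
        _imwrite(path, q)
        paths.append(path)
    return paths
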