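"""Acquisition geometry and bookkeeping for block-face mosaic tomography.

A whole-specimen acquisition is organised as a *sectioning–imaging cycle*:
overlapping camera fields (tiles) cover one coronal plane, a short z-stack of
optical sections is taken at every tile position, then a thin slice is removed
from the block face and the cycle repeats.  This module holds the static
description of that geometry (:class:`OpticsConfig`, :class:`AcquisitionPlan`)
and the exact integer bookkeeping that relates sections, layers, z-stacks and
raw phase frames (:class:`AcquisitionAccount`).

Conventions
-----------
* Physical coordinates are in micrometres; pixel/voxel indices are 0-based and
  a pixel spans ``[i, i+1) * pixel_size``.
* ``z`` increases with depth below the original block surface; sections are
  indexed from 0 at the top.
* Tile origins sit at the minimum-x/minimum-y corner of the covered region and
  advance with a fixed stride; the last row/column may overhang the specimen.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence, Tuple

__all__ = [
    "OpticsConfig",
    "AcquisitionPlan",
    "AcquisitionAccount",
    "pattern_period_dmd",
    "pattern_period_sample",
    "sample_pixel_size",
    "tile_grid",
    "account",
]


@dataclass(frozen=True)
class OpticsConfig:
    """Optical train of the wide-field structured-illumination microscope.

    Defaults describe a 20x/1.0-NA water-immersion system with a 6.5 um sCMOS
    sensor and a DMD pattern generator whose micro-mirror pitch is 13.68 um,
    binary grating period 8 mirrors.  Channel-resolved PSF widths are Gaussian
    sigmas in micrometres.

    ``dmd_to_sample_magnification`` is the demagnification of the DMD plane
    onto the sample; it is not derivable from the other numbers (the relay
    chain is a property of the instrument) and therefore a plain config value.
    ``modulation_depth_scale_um`` is the defocus distance at which the grid
    modulation depth falls to 1/e; ``defocus_blur_slope`` is the (unitless)
    rate at which the lateral blur sigma grows with defocus.
    """

    camera_pixel_um: float = 6.5
    magnification: float = 20.0
    dmd_pitch_um: float = 13.68
    dmd_pixels_per_period: int = 8
    psf_sigma_lateral_um: Mapping[str, float] = field(
        default_factory=lambda: {"green": 0.23357, "red": 0.26330}
    )
    psf_sigma_axial_um: Mapping[str, float] = field(
        default_factory=lambda: {"green": 0.93426, "red": 1.09988}
    )
    modulation_depth_scale_um: float = 2.0
    defocus_blur_slope: float = 0.5
    dmd_to_sample_magnification: float = 40.0

    def __post_init__(self) -> None:
        for name in (
            "camera_pixel_um",
            "magnification",
            "dmd_pitch_um",
            "modulation_depth_scale_um",
            "defocus_blur_slope",
            "dmd_to_sample_magnification",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"OpticsConfig.{name} must be strictly positive")
        if self.dmd_pixels_per_period < 2:
            raise ValueError("dmd_pixels_per_period must be >= 2")
        for m in (self.psf_sigma_lateral_um, self.psf_sigma_axial_um):
            for ch, s in m.items():
                if not s > 0:
                    raise ValueError(f"PSF sigma for channel {ch!r} must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["psf_sigma_lateral_um"] = dict(self.psf_sigma_lateral_um)
        d["psf_sigma_axial_um"] = dict(self.psf_sigma_axial_um)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "OpticsConfig":
        return cls(**d)


@dataclass(frozen=True)
class AcquisitionPlan:
    """Complete tiling / z-stacking / sectioning geometry for one run.

    ``fov_pixels`` is the camera crop actually read out, (x, y).  The tile
    stride is ``fov - overlap`` with the overlap rounded to a whole pixel.
    One section yields ``z_planes_per_section`` optical planes spaced
    ``z_step_um`` apart, the first ``imaging_depth_um`` below the freshly cut
    surface; afterwards ``section_thickness_um`` of material is removed.
    """

    fov_pixels: Tuple[int, int] = (1700, 1800)
    pixel_size_um: float = 0.325
    overlap_um: float = 10.0
    z_planes_per_section: int = 2
    z_step_um: float = 2.0
    section_thickness_um: float = 4.0
    imaging_depth_um: float = 1.5
    n_sections: int = 1
    tile_grid: Tuple[int, int] | None = None
    phases_per_image: int = 3
    phase_step_rad: float = math.pi / 2
    channels: Tuple[str, ...] = ("green", "red")

    def __post_init__(self) -> None:
        if self.phases_per_image != 3:
            raise ValueError("phases_per_image must be 3 (three-phase demodulation)")
        if not 0 < self.phase_step_rad <= math.pi:
            raise ValueError("phase_step_rad must lie in (0, pi]")
        if self.pixel_size_um <= 0 or self.z_step_um <= 0 or self.section_thickness_um <= 0:
            raise ValueError("pixel_size_um, z_step_um, section_thickness_um must be positive")
        if self.imaging_depth_um < 0:
            raise ValueError("imaging_depth_um must be >= 0")
        if self.z_planes_per_section < 1 or self.n_sections < 1:
            raise ValueError("z_planes_per_section and n_sections must be >= 1")
        fx, fy = self.fov_um
        if not (self.overlap_um < fx and self.overlap_um < fy):
            raise ValueError("overlap_um must be smaller than the field of view")
        expected = self.z_planes_per_section * self.z_step_um
        if not math.isclose(self.section_thickness_um, expected, rel_tol=1e-9):
            warnings.warn(
                "section_thickness_um (%g) != z_planes_per_section * z_step_um (%g); "
                "optical planes will not tile depth seamlessly" % (self.section_thickness_um, expected),
                stacklevel=2,
            )

    @property
    def fov_um(self) -> Tuple[float, float]:
        return (
            self.fov_pixels[0] * self.pixel_size_um,
            self.fov_pixels[1] * self.pixel_size_um,
        )

    @property
    def overlap_px(self) -> int:
        """Tile overlap rounded to the nearest whole pixel."""
        return int(round(self.overlap_um / self.pixel_size_um))

    @property
    def stride_px(self) -> Tuple[int, int]:
        return (self.fov_pixels[0] - self.overlap_px, self.fov_pixels[1] - self.overlap_px)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fov_pixels"] = list(self.fov_pixels)
        d["channels"] = list(self.channels)
        d["tile_grid"] = list(self.tile_grid) if self.tile_grid is not None else None
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "AcquisitionPlan":
        d = dict(d)
        d["fov_pixels"] = tuple(d.get("fov_pixels", (1700, 1800)))
        d["channels"] = tuple(d.get("channels", ("green", "red")))
        if d.get("tile_grid") is not None:
            d["tile_grid"] = tuple(d["tile_grid"])
        return cls(**d)


@dataclass(frozen=True)
class AcquisitionAccount:
    """Exact per-channel frame bookkeeping for a completed (or planned) run.

    ``n_layers`` counts optical planes over the whole specimen,
    ``n_zstacks`` counts tile positions summed over sections,
    ``n_mosaic_images`` counts reconstructed optical-section tiles and
    ``n_raw_frames`` counts camera exposures (three phases per mosaic).
    """

    n_sections: int
    n_layers: int
    n_zstacks: int
    n_mosaic_images: int
    n_raw_frames: int

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    def log_line(self) -> str:
        return (
            f"acquisition account: {self.n_sections} sections, {self.n_layers} layers, "
            f"{self.n_zstacks} z-stacks, {self.n_mosaic_images} mosaic images, "
            f"{self.n_raw_frames} raw frames per channel"
        )


def pattern_period_dmd(optics: OpticsConfig) -> float:
    """Grating period on the DMD plane in micrometres (pitch x mirrors/period)."""
    return optics.dmd_pitch_um * optics.dmd_pixels_per_period


def pattern_period_sample(optics: OpticsConfig) -> float:
    """Grating period projected onto the sample plane, micrometres."""
    return pattern_period_dmd(optics) / optics.dmd_to_sample_magnification


def sample_pixel_size(optics: OpticsConfig) -> float:
    """Lateral sample-plane pixel pitch: sensor pixel / magnification."""
    return optics.camera_pixel_um / optics.magnification


def _n_tiles_1d(extent_um: float, fov_px: int, overlap_px: int, pixel_um: float) -> int:
    stride_px = fov_px - overlap_px
    if stride_px <= 0:
        raise ValueError(
            f"overlap ({overlap_px} px) >= field of view ({fov_px} px): degenerate stride"
        )
    extent_px = extent_um / pixel_um
    n = math.ceil((extent_px - overlap_px) / stride_px - 1e-9)
    return max(1, n)


def tile_grid(extent_x_um: float, extent_y_um: float, plan: AcquisitionPlan) -> Tuple[int, int]:
    """Smallest (nx, ny) tile grid covering the given extents.

    Tiles of width W advance with stride W - overlap; n tiles cover
    ``n*W - (n-1)*overlap`` so the minimal count is
    ``ceil((extent - overlap) / (W - overlap))`` with a floor of one tile.
    The overlap is quantized to whole pixels first.
    """
    if extent_x_um <= 0 or extent_y_um <= 0:
        raise ValueError("extents must be positive")
    ov = plan.overlap_px
    nx = _n_tiles_1d(extent_x_um, plan.fov_pixels[0], ov, plan.pixel_size_um)
    ny = _n_tiles_1d(extent_y_um, plan.fov_pixels[1], ov, plan.pixel_size_um)
    return nx, ny


def account(plan: AcquisitionPlan, tiles_per_section: Sequence[int]) -> AcquisitionAccount:
    """Conserved frame accounting for a run with per-section tile counts.

    The tile count may vary between sections (the scan range is commonly
    adapted to the specimen profile), so the caller supplies one count per
    section.  All derived quantities are per imaging channel.
    """
    if len(tiles_per_section) == 0:
        raise ValueError("tiles_per_section must not be empty")
    if len(tiles_per_section) != plan.n_sections:
        raise ValueError(
            f"tiles_per_section has {len(tiles_per_section)} entries, "
            f"plan declares {plan.n_sections} sections"
        )
    if any(t < 0 for t in tiles_per_section):
        raise ValueError("tile counts must be non-negative")
    n_zstacks = int(sum(tiles_per_section))
    n_layers = plan.n_sections * plan.z_planes_per_section
    n_mosaic = n_zstacks * plan.z_planes_per_section
    n_raw = n_mosaic * plan.phases_per_image
    return AcquisitionAccount(
        n_sections=plan.n_sections,
        n_layers=n_layers,
        n_zstacks=n_zstacks,
        n_mosaic_images=n_mosaic,
        n_raw_frames=n_raw,
    )
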