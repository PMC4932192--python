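"""Virtual structured-illumination block-face microscope.

Renders phase-shifted raw tiles from a :class:`~wvtomo.phantom.Phantom` under
an :class:`~wvtomo.planner.AcquisitionPlan`.  The forward model for one tile
pixel is

    I_p = vignette * 1/2 * [ U + M * cos(2*pi*x/T + p*phase_step) ] + noise

where ``U = sum_dz blur(emission(dz), sigma(dz))`` is the conventional
wide-field image, ``M = sum_dz m(dz) * blur(emission(dz), sigma(dz))`` is the
modulated (in-focus weighted) component, ``m(dz) = exp(-(dz/s)^2)`` is the
grid modulation depth at defocus ``dz`` with scale ``s``, the lateral blur
grows as ``sigma(dz) = sqrt(sigma0^2 + (slope*dz)^2)``, and ``T`` is the grid
period projected onto the sample.  The stripes run along y (modulation in x)
and are fixed in the camera frame — stage jitter moves the specimen, not the
pattern.  Demodulating the three phases (see :mod:`wvtomo.recon`) therefore
returns ``vignette * M / 2`` exactly: the optical-sectioning property.

The red channel is emissive only within the freshly stained surface shell
(:func:`~wvtomo.phantom.stain_surface`); the green channel is masked above the
current cut (that material has been sectioned away).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Tuple

import numpy as np
from scipy import ndimage

from . import planner
from .phantom import Phantom, stain_surface
from .planner import AcquisitionPlan, OpticsConfig

__all__ = [
    "RawTile",
    "VignetteField",
    "NoiseConfig",
    "SimOptions",
    "render_tile",
    "run_acquisition",
]


@dataclass
class RawTile:
    """One phase-shifted camera frame with full provenance."""

    pixels: np.ndarray  # [y, x], linear intensity, >= 0
    channel: str
    section_index: int
    z_plane_index: int
    phase_index: int
    tile_index: Tuple[int, int]  # (ix, iy)
    stage_position_um: Tuple[float, float]  # nominal (x, y)
    jitter_um: Tuple[float, float] = (0.0, 0.0)  # true offset, for testing only

    def __post_init__(self) -> None:
        if self.phase_index not in (0, 1, 2):
            raise ValueError("phase_index must be 0, 1 or 2")
        if not np.all(np.isfinite(self.pixels)) or np.any(self.pixels < 0):
            raise ValueError("tile pixels must be finite and non-negative")


@dataclass
class VignetteField:
    """Multiplicative illumination/detection gain over the tile, peak 1."""

    gain: np.ndarray  # [y, x], 0 < gain <= 1

    def __post_init__(self) -> None:
        if np.any(self.gain <= 0) or np.any(self.gain > 1.0 + 1e-12):
            raise ValueError("vignette gain must lie in (0, 1]")

    @classmethod
    def parabolic(cls, shape_yx: Tuple[int, int], strength: float = 0.3) -> "VignetteField":
        """Separable parabolic falloff ``(1 - a*((x-c)/c)^2)`` on both axes."""
        ny, nx = shape_yx
        cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
        gy = 1.0 - strength * ((np.arange(ny) - cy) / cy) ** 2
        gx = 1.0 - strength * ((np.arange(nx) - cx) / cx) ** 2
        return cls(gain=np.outer(gy, gx))

    @classmethod
    def flat(cls, shape_yx: Tuple[int, int]) -> "VignetteField":
        return cls(gain=np.ones(shape_yx))


@dataclass(frozen=True)
class NoiseConfig:
    """Shot/read noise and stage jitter; everything off by default, seeded.

    ``photons_per_unit`` converts the linear forward-model intensity to an
    expected photon count for Poisson shot noise (0 disables); read noise is
    additive Gaussian in intensity units; stage jitter is a per-z-stack 2D
    Gaussian offset of the true stage position.
    """

    photons_per_unit: float = 0.0
    read_noise_sd: float = 0.0
    jitter_sigma_um: float = 0.0
    seed: int = 0


@dataclass(frozen=True)
class SimOptions:
    """Renderer controls that are not instrument properties.

    ``depth_window_um`` truncates the defocus sum: layers farther than this
    from the imaged plane contribute a nearly uniform, fully demodulation-
    rejected background and are skipped for speed.  ``stain_dwell_s`` is the
    interval between sectioning and imaging seen by the staining model.
    """

    depth_window_um: float = 24.0
    stain_dwell_s: float = 15.0


def _crop_padded(layer: np.ndarray, y0: int, x0: int, ny: int, nx: int) -> np.ndarray:
    """Crop [y0:y0+ny, x0:x0+nx] with zero padding outside the layer."""
    out = np.zeros((ny, nx), dtype=layer.dtype)
    ys0, ys1 = max(0, y0), min(layer.shape[0], y0 + ny)
    xs0, xs1 = max(0, x0), min(layer.shape[1], x0 + nx)
    if ys0 < ys1 and xs0 < xs1:
        out[ys0 - y0:ys1 - y0, xs0 - x0:xs1 - x0] = layer[ys0:ys1, xs0:xs1]
    return out


def _plane_depth_um(plan: AcquisitionPlan, section_index: int, z_plane_index: int) -> float:
    cut = section_index * plan.section_thickness_um
    return cut + plan.imaging_depth_um + z_plane_index * plan.z_step_um


def tile_components(phantom: Phantom, plan: AcquisitionPlan, optics: OpticsConfig,
                    channel: str, section_index: int, z_plane_index: int,
                    tile_index: Tuple[int, int] = (0, 0),
                    sim: SimOptions | None = None) -> Tuple[np.ndarray, np.ndarray]:
    """Unmodulated (U) and modulated (M) intensity components of one tile.

    These depend on geometry and channel only, not on the illumination phase,
    so all three phase frames of a z-stack share them.
    """
    sim = sim or SimOptions()
    if channel not in plan.channels:
        raise ValueError(f"unknown channel {channel!r}")
    cut = section_index * plan.section_thickness_um
    plane = _plane_depth_um(plan, section_index, z_plane_index)
    if not 0.0 <= plane < phantom.depth_um:
        raise ValueError(
            f"imaged plane at {plane:.2f} um lies outside the phantom "
            f"(depth {phantom.depth_um:.2f} um)"
        )
    if channel == "red":
        emission = stain_surface(phantom, cut, sim.stain_dwell_s)
    else:
        emission = phantom.green_density

    p = plan.pixel_size_um
    dx, dy, dz_vox = phantom.voxel_xyz
    if not (np.isclose(dx, p) and np.isclose(dy, p)):
        raise ValueError(
            "renderer requires the phantom lateral voxel size to equal the "
            "sample-plane pixel size"
        )
    ix, iy = tile_index
    sx, sy = plan.stride_px
    x0, y0 = ix * sx, iy * sy
    nx, ny = plan.fov_pixels

    sigma0 = optics.psf_sigma_lateral_um[channel]
    slope = optics.defocus_blur_slope
    mscale = optics.modulation_depth_scale_um

    z_centers = phantom.z_centers_um
    dz = z_centers - plane
    in_window = (np.abs(dz) <= sim.depth_window_um) & (z_centers >= cut)

    U = np.zeros((ny, nx), dtype=np.float64)
    M = np.zeros((ny, nx), dtype=np.float64)
    for k in np.nonzero(in_window)[0]:
        sigma_px = np.hypot(sigma0, slope * dz[k]) / p
        # blur sees specimen beyond the tile: crop with a 3-sigma margin
        # (capped), nearest-pad whatever still lies outside
        mg = min(int(np.ceil(3.0 * sigma_px)), 64)
        patch = _crop_padded(emission[k], y0 - mg, x0 - mg,
                             ny + 2 * mg, nx + 2 * mg).astype(np.float64)
        if not patch.any():
            continue
        blurred = ndimage.gaussian_filter(patch, sigma_px, mode="nearest")
        if mg:
            blurred = blurred[mg:-mg, mg:-mg]
        m = np.exp(-((dz[k] / mscale) ** 2))
        U += blurred * dz_vox
        M += m * blurred * dz_vox
    return U, M


def render_tile(phantom: Phantom, plan: AcquisitionPlan, optics: OpticsConfig,
                channel: str, section_index: int, z_plane_index: int, phase_index: int,
                tile_index: Tuple[int, int] = (0, 0),
                vignette: VignetteField | None = None,
                jitter_um: Tuple[float, float] = (0.0, 0.0),
                noise: NoiseConfig | None = None,
                rng: np.random.Generator | None = None,
                sim: SimOptions | None = None,
                components: Tuple[np.ndarray, np.ndarray] | None = None) -> RawTile:
    """Render one phase-shifted raw frame.

    ``components`` may carry a precomputed ``(U, M)`` pair (see
    :func:`tile_components`) to amortise the defocus sum across the three
    phases; :func:`run_acquisition` uses this.
    """
    if phase_index not in (0, 1, 2):
        raise ValueError("phase_index must be 0, 1 or 2")
    if components is None:
        components = tile_components(phantom, plan, optics, channel,
                                     section_index, z_plane_index, tile_index, sim)
    U, M = components
    p = plan.pixel_size_um

    jx, jy = jitter_um
    if jx != 0.0 or jy != 0.0:
        shift = (-jy / p, -jx / p)
        U = ndimage.shift(U, shift, order=1, mode="constant")
        M = ndimage.shift(M, shift, order=1, mode="constant")

    T = planner.pattern_period_sample(optics)
    nx = U.shape[1]
    x_um = (np.arange(nx) + 0.5) * p
    pattern = np.cos(2.0 * np.pi * x_um / T + phase_index * plan.phase_step_rad)
    pixels = 0.5 * (U + M * pattern[None, :])

    if vignette is not None:
        if vignette.gain.shape != pixels.shape:
            raise ValueError("vignette shape does not match the tile")
        pixels = pixels * vignette.gain

    noise = noise or NoiseConfig()
    if noise.photons_per_unit > 0 or noise.read_noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(noise.seed)
        if noise.photons_per_unit > 0:
            pixels = rng.poisson(np.clip(pixels, 0, None) * noise.photons_per_unit
                                 ).astype(np.float64) / noise.photons_per_unit
        if noise.read_noise_sd > 0:
            pixels = pixels + rng.normal(0.0, noise.read_noise_sd, size=pixels.shape)
        pixels = np.clip(pixels, 0.0, None)

    ix, iy = tile_index
    sx, sy = plan.stride_px
    return RawTile(
        pixels=pixels,
        channel=channel,
        section_index=section_index,
        z_plane_index=z_plane_index,
        phase_index=phase_index,
        tile_index=(ix, iy),
        stage_position_um=(ix * sx * p, iy * sy * p),
        jitter_um=(float(jx), float(jy)),
    )


def _frame_rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


def run_acquisition(phantom: Phantom, plan: AcquisitionPlan, optics: OpticsConfig,
                    noise: NoiseConfig | None = None,
                    vignette: VignetteField | None = None,
                    sim: SimOptions | None = None,
                    seed: int | None = None) -> Tuple[List[RawTile], Dict]:
    """Execute the full sectioning-staining-imaging cycle over the phantom.

    Tiles are emitted section-major, then tile (row-major, x fastest), then
    z-plane, then phase, then channel.  After each section's tiles the cut
    surface advances by ``section_thickness_um`` and the staining model is
    re-evaluated at the new block face.  The manifest's totals equal
    :func:`wvtomo.planner.account` for the same plan.
    """
    noise = noise or NoiseConfig()
    sim = sim or SimOptions()
    if seed is None:
        seed = noise.seed
    if phantom.depth_um < plan.section_thickness_um:
        raise ValueError("phantom is shallower than one section")
    deepest = _plane_depth_um(plan, plan.n_sections - 1, plan.z_planes_per_section - 1)
    if deepest >= phantom.depth_um:
        raise ValueError(
            f"plan images to {deepest:.2f} um but the phantom is only "
            f"{phantom.depth_um:.2f} um deep"
        )

    ex, ey, _ = phantom.config.extent_um
    grid = plan.tile_grid or planner.tile_grid(ex, ey, plan)
    nx_t, ny_t = grid

    jitter_rng = _frame_rng(seed, 919)
    ch_index = {c: i for i, c in enumerate(plan.channels)}

    tiles: List[RawTile] = []
    frames: List[Dict] = []
    for s in range(plan.n_sections):
        for iy in range(ny_t):
            for ix in range(nx_t):
                if noise.jitter_sigma_um > 0:
                    jx, jy = jitter_rng.normal(0.0, noise.jitter_sigma_um, size=2)
                else:
                    jx, jy = 0.0, 0.0
                for z in range(plan.z_planes_per_section):
                    comp = {
                        ch: tile_components(phantom, plan, optics, ch, s, z, (ix, iy), sim)
                        for ch in plan.channels
                    }
                    for ph in range(plan.phases_per_image):
                        for ch in plan.channels:
                            rng = _frame_rng(seed, s, iy, ix, z, ph, ch_index[ch])
                            tile = render_tile(
                                phantom, plan, optics, ch, s, z, ph,
                                tile_index=(ix, iy), vignette=vignette,
                                jitter_um=(jx, jy), noise=noise, rng=rng,
                                sim=sim, components=comp[ch],
                            )
                            tiles.append(tile)
                            frames.append({
                                "channel": ch, "section": s, "z_plane": z,
                                "phase": ph, "ix": ix, "iy": iy,
                                "stage_x_um": tile.stage_position_um[0],
                                "stage_y_um": tile.stage_position_um[1],
                            })

    plan_counts = planner.account(plan, [nx_t * ny_t] * plan.n_sections)
    manifest = {
        "plan": plan.to_dict(),
        "optics": optics.to_dict(),
        "tile_grid": [nx_t, ny_t],
        "seed": seed,
        "frames": frames,
        "totals": {
            "n_sections": plan_counts.n_sections,
            "n_layers": plan_counts.n_layers,
            "n_zstacks": plan_counts.n_zstacks,
            "n_mosaic_images": plan_counts.n_mosaic_images,
            "n_raw_frames": plan_counts.n_raw_frames,
        },
    }
    return tiles, manifest
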