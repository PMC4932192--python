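"""Optical-section reconstruction: demodulation, stitching, illumination correction.

The processing chain mirrors how a block-face structured-illumination dataset
becomes a stack of corrected coronal planes:

1. :func:`demodulate` — recover the in-focus amplitude from three raw frames
   taken with a pi/2 illumination phase step.  For frames
   ``I_n = B + A*cos(phi + n*pi/2)`` one has ``I0 - I2 = 2A cos(phi)`` and
   ``I0 + I2 - 2*I1 = 2A sin(phi)``, so

       A = 1/2 * sqrt((I0 - I2)^2 + (I0 + I2 - 2*I1)^2)

   exactly, for any background B and pattern phase phi.  Unmodulated
   (out-of-focus) light lives entirely in B and is rejected.  The classic
   three-phase root-mean-square estimator for a 2*pi/3 step is available as
   ``method="rms_2pi3"``.
2. :func:`stitch_section` — place demodulated tiles at their nominal stage
   positions with linear feather blending across the overlap bands;
   optionally refine each tile's offset by phase correlation against its
   already-placed neighbours.
3. :func:`fit_lateral_correction` / :func:`apply_lateral_correction` —
   separable polynomial flat-field gain from the row/column mean-intensity
   profiles (vignetting removal).
4. :func:`equalize_axial` — per-section brightness gains so every section's
   foreground mean matches a common reference (default: the median section).

:func:`pipeline` chains the four stages over a simulator tile stream.  No
inter-section registration is performed: block-face acquisition is
self-registered because the specimen never leaves the stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
from numpy.polynomial import Polynomial
from numpy.polynomial import polynomial as P
from skimage.registration import phase_cross_correlation

from .planner import AcquisitionPlan
from .scope_sim import RawTile

__all__ = [
    "SectionImage",
    "CorrectionModel",
    "ReconResult",
    "demodulate",
    "widefield",
    "stitch_section",
    "fit_lateral_correction",
    "apply_lateral_correction",
    "equalize_axial",
    "pipeline",
]


@dataclass
class SectionImage:
    """A stitched optical-section plane for one channel."""

    pixels: np.ndarray  # [y, x]
    channel: str | None = None
    section_index: int = 0
    z_plane_index: int = 0
    origin_um: Tuple[float, float] = (0.0, 0.0)
    pixel_size_um: float = 1.0
    tile_offsets_px: Dict[Tuple[int, int], Tuple[float, float]] | None = None


@dataclass
class CorrectionModel:
    """Separable lateral gain model plus per-section axial gains.

    ``poly_x``/``poly_y`` are power-series coefficients of the fitted mean-
    intensity profiles along columns/rows; the applied gain at position p is
    ``poly(center)/poly(p)``, i.e. unity at the field centre and largest at
    the dimmest edge.
    """

    poly_x: np.ndarray
    poly_y: np.ndarray
    shape: Tuple[int, int]  # (ny, nx) domain
    support_x: Tuple[int, int] | None = None  # fitted column range, inclusive
    support_y: Tuple[int, int] | None = None
    reference_level: float = 0.0
    axial_gains: List[float] | None = None
    max_gain: float = 5.0  # safety clamp on the applied gain

    def gain_profiles(self) -> Tuple[np.ndarray, np.ndarray]:
        ny, nx = self.shape
        sx = self.support_x or (0, nx - 1)
        sy = self.support_y or (0, ny - 1)
        # constant extrapolation outside the fitted support
        xs = np.clip(np.arange(nx), sx[0], sx[1])
        ys = np.clip(np.arange(ny), sy[0], sy[1])
        px = P.polyval(xs, self.poly_x)
        py = P.polyval(ys, self.poly_y)
        gx = P.polyval((sx[0] + sx[1]) / 2.0, self.poly_x) / px
        gy = P.polyval((sy[0] + sy[1]) / 2.0, self.poly_y) / py
        gx = np.clip(gx, 1.0 / self.max_gain, self.max_gain)
        gy = np.clip(gy, 1.0 / self.max_gain, self.max_gain)
        return gx, gy

    def to_dict(self) -> dict:
        return {
            "poly_x": list(map(float, self.poly_x)),
            "poly_y": list(map(float, self.poly_y)),
            "shape": list(self.shape),
            "support_x": None if self.support_x is None else list(self.support_x),
            "support_y": None if self.support_y is None else list(self.support_y),
            "reference_level": float(self.reference_level),
            "axial_gains": None if self.axial_gains is None else list(map(float, self.axial_gains)),
        }


# ---------------------------------------------------------------------------
# demodulation


def _check_shapes(i0, i1, i2) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    a0, a1, a2 = (np.asarray(i, dtype=np.float64) for i in (i0, i1, i2))
    if not (a0.shape == a1.shape == a2.shape):
        raise ValueError(f"phase frames differ in shape: {a0.shape}, {a1.shape}, {a2.shape}")
    return a0, a1, a2


def demodulate(i0, i1, i2, method: str = "three_phase_pi2") -> np.ndarray:
    """Pixelwise in-focus amplitude from three phase-shifted frames.

    ``three_phase_pi2`` (default) is exact for a pi/2 phase step;
    ``rms_2pi3`` is the root-mean-square estimator
    ``sqrt(2)/3 * sqrt(sum of squared pairwise differences)``, exact for a
    2*pi/3 step.
    """
    a0, a1, a2 = _check_shapes(i0, i1, i2)
    if method == "three_phase_pi2":
        return 0.5 * np.hypot(a0 - a2, a0 + a2 - 2.0 * a1)
    if method == "rms_2pi3":
        return (np.sqrt(2.0) / 3.0) * np.sqrt(
            (a0 - a1) ** 2 + (a1 - a2) ** 2 + (a2 - a0) ** 2
        )
    raise ValueError(f"unknown demodulation method {method!r}")


def widefield(i0, i1, i2) -> np.ndarray:
    """Conventional wide-field image: (I0 + I2)/2, phase-independent."""
    a0, _, a2 = _check_shapes(i0, i1, i2)
    return 0.5 * (a0 + a2)


# ---------------------------------------------------------------------------
# stitching


def _feather_1d(n: int, band: int, ramp_before: bool, ramp_after: bool) -> np.ndarray:
    """Linear feather weights; two abutting ramps over a shared band sum to 1."""
    w = np.ones(n)
    if band > 0:
        up = np.arange(1, band + 1) / (band + 1.0)
        if ramp_before:
            w[:band] = up
        if ramp_after:
            w[n - band:] = up[::-1]
    return w


def stitch_section(tiles: Dict[Tuple[int, int], np.ndarray], plan: AcquisitionPlan,
                   refine: bool = False, search_radius_um: float = 3.0,
                   channel: str | None = None, section_index: int = 0,
                   z_plane_index: int = 0) -> SectionImage:
    """Blend a grid of demodulated tiles into one coronal plane.

    ``tiles`` maps ``(ix, iy)`` to the tile image.  Placement is nominal
    (stage stride, pixel-quantized); with ``refine`` each tile's offset is
    corrected by the phase-correlation peak against its already-placed left
    and top neighbours over the nominal overlap band, clipped to
    ``search_radius_um``.  Feather weights are renormalized to a partition of
    unity, so constant tiles stitch to a constant mosaic exactly.
    """
    if not tiles:
        raise ValueError("no tiles to stitch")
    nx_t = max(ix for ix, _ in tiles) + 1
    ny_t = max(iy for _, iy in tiles) + 1
    missing = [(ix, iy) for iy in range(ny_t) for ix in range(nx_t) if (ix, iy) not in tiles]
    if missing:
        raise ValueError(f"missing tiles in grid: {missing}")
    fov_x, fov_y = plan.fov_pixels
    for key, img in tiles.items():
        if img.shape != (fov_y, fov_x):
            raise ValueError(f"tile {key} has shape {img.shape}, expected {(fov_y, fov_x)}")
    band = plan.overlap_px
    if (nx_t > 1 or ny_t > 1) and band < 4:
        raise ValueError("pairwise overlap must be at least 4 pixels")
    sx, sy = plan.stride_px
    p = plan.pixel_size_um

    offsets: Dict[Tuple[int, int], Tuple[float, float]] = {}
    rad_px = search_radius_um / p
    for iy in range(ny_t):
        for ix in range(nx_t):
            if not refine or (ix, iy) == (0, 0):
                offsets[(ix, iy)] = (0.0, 0.0)
                continue
            cur = tiles[(ix, iy)]
            estimates = []
            if ix > 0:
                ref = tiles[(ix - 1, iy)][:, fov_x - band:]
                mov = cur[:, :band]
                shift, _, _ = phase_cross_correlation(ref, mov, upsample_factor=10, normalization=None)
                o = offsets[(ix - 1, iy)]
                estimates.append((o[0] + shift[0], o[1] + shift[1]))
            if iy > 0:
                ref = tiles[(ix, iy - 1)][fov_y - band:, :]
                mov = cur[:band, :]
                shift, _, _ = phase_cross_correlation(ref, mov, upsample_factor=10, normalization=None)
                o = offsets[(ix, iy - 1)]
                estimates.append((o[0] + shift[0], o[1] + shift[1]))
            dy = float(np.clip(np.mean([e[0] for e in estimates]), -rad_px, rad_px))
            dx = float(np.clip(np.mean([e[1] for e in estimates]), -rad_px, rad_px))
            offsets[(ix, iy)] = (dy, dx)

    margin = int(np.ceil(rad_px)) + 2 if refine else 0
    H = (ny_t - 1) * sy + fov_y
    W = (nx_t - 1) * sx + fov_x
    acc = np.zeros((H + 2 * margin, W + 2 * margin))
    wacc = np.zeros_like(acc)
    for (ix, iy), img in tiles.items():
        oy, ox = offsets[(ix, iy)]
        y0 = iy * sy + margin + int(round(oy))
        x0 = ix * sx + margin + int(round(ox))
        wy = _feather_1d(fov_y, band, iy > 0, iy < ny_t - 1)
        wx = _feather_1d(fov_x, band, ix > 0, ix < nx_t - 1)
        w = np.outer(wy, wx)
        acc[y0:y0 + fov_y, x0:x0 + fov_x] += w * img
        wacc[y0:y0 + fov_y, x0:x0 + fov_x] += w
    mosaic = np.where(wacc > 0, acc / np.where(wacc > 0, wacc, 1.0), 0.0)
    mosaic = mosaic[margin:margin + H, margin:margin + W]
    return SectionImage(
        pixels=mosaic, channel=channel, section_index=section_index,
        z_plane_index=z_plane_index, origin_um=(0.0, 0.0), pixel_size_um=p,
        tile_offsets_px=offsets,
    )


# ---------------------------------------------------------------------------
# illumination correction


def _fit_axis_profile(profile: np.ndarray, degree: int) -> Tuple[np.ndarray, Tuple[int, int]]:
    """Fit one axis profile over its covered support; return (coeffs, support).

    Shading is a smooth, order-of-unity field, so the fit must not chase
    structure: positions below 30% of the median covered intensity are treated
    as uncovered (mosaic overhang beyond the specimen, where coverage rolls
    off sharply) and excluded, and the profile is winsorized at 3x its median
    so a single bright object cannot bend the polynomial.  Smooth vignetting
    (a few tens of percent) passes both guards unchanged.
    """
    med = float(np.median(profile[profile > 0]))
    pos = np.nonzero(profile > 0.3 * med)[0]
    if pos.size < degree + 1:
        raise ValueError(
            f"need at least degree+1 = {degree + 1} positive positions along each axis"
        )
    data = np.minimum(profile[pos], 3.0 * med)
    for deg in range(degree, -1, -1):
        coef = Polynomial.fit(pos, data, deg).convert().coef
        if np.all(P.polyval(pos, coef) > 0):
            if deg < degree:
                warnings.warn(
                    f"degree-{degree} shading fit was not strictly positive; "
                    f"using degree {deg}",
                    stacklevel=3,
                )
            return coef, (int(pos.min()), int(pos.max()))
    raise ValueError("fitted intensity polynomial is not strictly positive over the field")


def fit_lateral_correction(images, degree: int = 4) -> CorrectionModel:
    """Fit separable flat-field gain polynomials from mean-intensity profiles.

    One polynomial of the given degree is fitted to the per-column mean
    intensity (x profile) and one to the per-row mean (y profile), averaged
    over all supplied images.  Rows/columns with zero mean carry no
    illumination information (outside the covered specimen) and are excluded
    from the fit; the gain is held constant beyond the fitted support.
    Degree 0 yields unit gain on any input.
    """
    if isinstance(images, np.ndarray) and images.ndim == 2:
        images = [images]
    imgs = [np.asarray(im, dtype=np.float64) for im in images]
    if not imgs:
        raise ValueError("no images supplied")
    shape = imgs[0].shape
    if any(im.shape != shape for im in imgs):
        raise ValueError("all images must share one shape")
    if all(not im.any() for im in imgs):
        raise ValueError("cannot fit an illumination model to all-zero input")
    profile_x = np.mean([im.mean(axis=0) for im in imgs], axis=0)
    profile_y = np.mean([im.mean(axis=1) for im in imgs], axis=0)
    cx, sup_x = _fit_axis_profile(profile_x, degree)
    cy, sup_y = _fit_axis_profile(profile_y, degree)
    return CorrectionModel(poly_x=cx, poly_y=cy, shape=shape,
                           support_x=sup_x, support_y=sup_y,
                           reference_level=float(np.mean([im.mean() for im in imgs])))


def apply_lateral_correction(image: np.ndarray, model: CorrectionModel) -> np.ndarray:
    """Multiply by the separable gain field gain(x) * gain(y)."""
    image = np.asarray(image, dtype=np.float64)
    if image.shape != tuple(model.shape):
        raise ValueError(f"image shape {image.shape} does not match model domain {model.shape}")
    gx, gy = model.gain_profiles()
    return image * gx[None, :] * gy[:, None]


def equalize_axial(sections: Sequence[np.ndarray | SectionImage],
                   reference_level: float | None = None
                   ) -> Tuple[List[np.ndarray], List[float]]:
    """Scale each section so its foreground mean matches the reference.

    Foreground is the strictly positive part of the image.  The default
    reference is the median of the section means — robust against a few
    anomalously dim or bright sections.  A section with zero mean gets gain 1
    and a warning.
    """
    arrays = [s.pixels if isinstance(s, SectionImage) else np.asarray(s, dtype=np.float64)
              for s in sections]
    if not arrays:
        raise ValueError("need at least one section")
    means = []
    for a in arrays:
        fg = a[a > 0]
        means.append(float(fg.mean()) if fg.size else 0.0)
    ref = float(np.median([m for m in means if m > 0])) if reference_level is None else reference_level
    gains: List[float] = []
    out: List[np.ndarray] = []
    for a, m in zip(arrays, means):
        if m <= 0:
            warnings.warn("section with zero foreground mean: gain forced to 1", stacklevel=2)
            gains.append(1.0)
            out.append(a.copy())
        else:
            g = ref / m
            gains.append(g)
            out.append(a * g)
    return out, gains


# ---------------------------------------------------------------------------
# full pipeline


@dataclass
class ReconResult:
    """Stacked corrected planes per channel plus the models that produced them.

    ``volumes[ch]`` has shape (n_planes, H, W) with plane order
    ``section_index * z_planes_per_section + z_plane_index``.
    """

    volumes: Dict[str, np.ndarray]
    correction_models: Dict[str, List[CorrectionModel]]
    axial_gains: Dict[str, List[float]]
    pixel_size_um: float
    plan: AcquisitionPlan
    log: List[str] = field(default_factory=list)


def pipeline(tiles: Iterable[RawTile], plan: AcquisitionPlan,
             refine: bool = False, search_radius_um: float = 3.0,
             lateral_degree: int = 4, lateral: bool = True, equalize: bool = True,
             demod_method: str = "three_phase_pi2") -> ReconResult:
    """Demodulate, stitch, flat-field and equalize a raw tile stream.

    Lateral correction is fitted per section and channel on the stitched
    planes of that section (correction after stitching, section by section);
    axial equalization then puts every section of a channel on a common mean.
    """
    tiles = list(tiles)
    if not tiles:
        raise ValueError("empty manifest: no tiles to reconstruct")

    grouped: Dict[Tuple[str, int, int, Tuple[int, int]], Dict[int, np.ndarray]] = {}
    for t in tiles:
        key = (t.channel, t.section_index, t.z_plane_index, tuple(t.tile_index))
        grouped.setdefault(key, {})[t.phase_index] = t.pixels
    log: List[str] = [f"pipeline: {len(tiles)} raw frames in"]

    demod: Dict[Tuple[str, int, int], Dict[Tuple[int, int], np.ndarray]] = {}
    for (ch, s, z, idx), phases in grouped.items():
        if sorted(phases) != [0, 1, 2]:
            raise ValueError(
                f"frame group channel={ch} section={s} z={z} tile={idx} has phases "
                f"{sorted(phases)}; need exactly (0, 1, 2)"
            )
        demod.setdefault((ch, s, z), {})[idx] = demodulate(
            phases[0], phases[1], phases[2], method=demod_method
        )
    log.append(f"demodulated {len(demod)} planes-of-tiles")

    channels = sorted({k[0] for k in demod}, key=lambda c: plan.channels.index(c))
    sections = sorted({k[1] for k in demod})
    z_planes = sorted({k[2] for k in demod})

    result_volumes: Dict[str, np.ndarray] = {}
    result_models: Dict[str, List[CorrectionModel]] = {}
    result_gains: Dict[str, List[float]] = {}
    for ch in channels:
        planes: Dict[Tuple[int, int], np.ndarray] = {}
        for s in sections:
            for z in z_planes:
                sec = stitch_section(demod[(ch, s, z)], plan, refine=refine,
                                     search_radius_um=search_radius_um,
                                     channel=ch, section_index=s, z_plane_index=z)
                planes[(s, z)] = sec.pixels
        log.append(f"channel {ch}: stitched {len(planes)} planes")

        models: List[CorrectionModel] = []
        if lateral:
            for s in sections:
                model = fit_lateral_correction([planes[(s, z)] for z in z_planes],
                                               degree=lateral_degree)
                models.append(model)
                for z in z_planes:
                    planes[(s, z)] = apply_lateral_correction(planes[(s, z)], model)
            log.append(f"channel {ch}: lateral correction degree {lateral_degree} "
                       f"fitted per section")
        result_models[ch] = models

        if equalize:
            section_means = []
            for s in sections:
                stackmean = np.concatenate([planes[(s, z)].ravel() for z in z_planes])
                fg = stackmean[stackmean > 0]
                section_means.append(float(fg.mean()) if fg.size else 0.0)
            ref = float(np.median([m for m in section_means if m > 0])) if any(
                m > 0 for m in section_means) else 1.0
            gains = []
            for s, m in zip(sections, section_means):
                g = ref / m if m > 0 else 1.0
                gains.append(g)
                for z in z_planes:
                    planes[(s, z)] = planes[(s, z)] * g
            log.append(f"channel {ch}: axial gains {np.round(gains, 3).tolist()}")
        else:
            gains = [1.0] * len(sections)
        result_gains[ch] = gains

        ordered = [planes[(s, z)] for s in sections for z in z_planes]
        result_volumes[ch] = np.stack(ordered, axis=0)

    return ReconResult(volumes=result_volumes, correction_models=result_models,
                       axial_gains=result_gains, pixel_size_um=plan.pixel_size_um,
                       plan=plan, log=log)
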