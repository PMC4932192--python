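"""Measurement layer: PSF metrology, soma detection, morphometry, statistics.

Coordinates follow the package convention: volumes are ``[z, y, x]`` arrays,
physical points are micrometre ``(x, y, z)`` tuples (matching SWC).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit
from scipy.spatial import cKDTree
from skimage.feature import blob_log

from .swc import APICAL, AXON, BASAL, SOMA, NeuronTree

__all__ = [
    "BeadMeasurement",
    "MorphometryReport",
    "GroupComparison",
    "measure_fwhm",
    "detect_somata",
    "colocalize",
    "morphometry",
    "compare_groups",
    "project",
]

FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))  # 2.3548...


@dataclass
class BeadMeasurement:
    """Gaussian-fit PSF widths from one sub-resolution bead."""

    bead_center_um: Tuple[float, float, float]  # (x, y, z)
    fwhm_lateral_um: float
    fwhm_axial_um: float
    channel: str | None = None
    fit_residual: float = 0.0

    def __post_init__(self) -> None:
        if self.fwhm_lateral_um <= 0 or self.fwhm_axial_um <= 0:
            raise ValueError("FWHM values must be positive")
        if self.fit_residual < 0:
            raise ValueError("fit residual must be >= 0")


@dataclass
class MorphometryReport:
    """Per-compartment path lengths and branch-point counts of one neuron."""

    axon_length_um: float = 0.0
    dendrite_length_um: float = 0.0
    apical_length_um: float = 0.0
    basal_length_um: float = 0.0
    other_length_um: float = 0.0
    axon_branch_count: int = 0
    dendrite_branch_count: int = 0
    apical_branch_count: int = 0
    basal_branch_count: int = 0
    axon_segment_count: int = 0
    dendrite_segment_count: int = 0
    bouton_count: int | None = None
    projection_class: str = "local"
    furthest_target_label: str = ""
    length_by_layer: Dict[int, float] | None = None


@dataclass
class GroupComparison:
    """Two-sided equal-variance Student's t comparison of two samples."""

    group_a_values: np.ndarray
    group_b_values: np.ndarray
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    t_statistic: float
    p_value: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")
        if self.sem_a < 0 or self.sem_b < 0:
            raise ValueError("SEMs must be >= 0")


# ---------------------------------------------------------------------------
# bead metrology


def _gauss1d(u, a, c, sigma, b):
    return a * np.exp(-((u - c) ** 2) / (2.0 * sigma**2)) + b


def _fit_profile(profile: np.ndarray, spacing_um: float) -> Tuple[float, float, float]:
    """Fit A*exp(-(u-c)^2/2s^2)+b to a 1D profile; return (sigma_um, center_um, rms)."""
    u = np.arange(profile.size, dtype=float)
    c0 = float(np.argmax(profile))
    b0 = float(np.min(profile))
    a0 = float(profile.max() - b0)
    # moment-based sigma seed
    w = np.clip(profile - b0, 0, None)
    s0 = math.sqrt(max(float(np.sum(w * (u - c0) ** 2) / max(np.sum(w), 1e-12)), 0.25))
    try:
        popt, _ = curve_fit(_gauss1d, u, profile, p0=(a0, c0, s0, b0), maxfev=10000)
    except RuntimeError as e:
        raise RuntimeError(f"Gaussian profile fit did not converge: {e}") from None
    a, c, sigma, b = popt
    if a <= 0 or not np.isfinite(sigma):
        raise RuntimeError("Gaussian profile fit produced a degenerate solution")
    resid = float(np.sqrt(np.mean((profile - _gauss1d(u, *popt)) ** 2)))
    return abs(sigma) * spacing_um, c * spacing_um, resid


def measure_fwhm(bead_stack: np.ndarray, voxel_size_um: Sequence[float],
                 channel: str | None = None) -> BeadMeasurement:
    """PSF FWHMs from a stack containing one dominant bead image.

    1D Gaussians are fitted to the x, y and z intensity profiles through the
    brightest voxel; the lateral FWHM is the mean of x and y,
    ``FWHM = 2*sqrt(2*ln 2) * sigma``.  ``voxel_size_um`` is (dz, dy, dx),
    matching the stack axes.
    """
    stack = np.asarray(bead_stack, dtype=np.float64)
    if stack.ndim != 3:
        raise ValueError("bead_stack must be a 3D array [z, y, x]")
    dz, dy, dx = voxel_size_um
    if stack.max() <= stack.min():
        raise ValueError("no local maximum above background in the bead stack")
    iz, iy, ix = np.unravel_index(int(np.argmax(stack)), stack.shape)
    sig_x, cx, rx = _fit_profile(stack[iz, iy, :], dx)
    sig_y, cy, ry = _fit_profile(stack[iz, :, ix], dy)
    sig_z, cz, rz = _fit_profile(stack[:, iy, ix], dz)
    return BeadMeasurement(
        bead_center_um=(cx, cy, cz),
        fwhm_lateral_um=FWHM_PER_SIGMA * 0.5 * (sig_x + sig_y),
        fwhm_axial_um=FWHM_PER_SIGMA * sig_z,
        channel=channel,
        fit_residual=float(rx + ry + rz),
    )


# ---------------------------------------------------------------------------
# soma detection and co-localization


def detect_somata(volume: np.ndarray, voxel_size_um: Sequence[float],
                  min_radius_um: float, max_radius_um: float,
                  threshold: float = 0.1, intensity_floor: float = 0.25,
                  suppress_dist_um: float | None = None,
                  ) -> List[Tuple[Tuple[float, float, float], float]]:
    """Scale-space Laplacian-of-Gaussian blob detection of cell bodies.

    ``voxel_size_um`` is (dz, dy, dx).  Returns ``(center_xyz_um, radius_um)``
    pairs.  ``threshold`` is the absolute scale-normalized LoG response floor
    (the volume is peak-normalized first); ``intensity_floor`` additionally
    requires the intensity at a detection to exceed that fraction of the
    volume peak, which rejects LoG ripples over dim background and thin
    neurites.  Non-maximum suppression keeps only the brighter of two
    detections closer than ``suppress_dist_um`` (default: the mean requested
    radius; pass the expected cell diameter when one cell may peak in two
    adjacent sections).
    """
    if not 0 < min_radius_um < max_radius_um:
        raise ValueError("need 0 < min_radius_um < max_radius_um")
    vol = np.asarray(volume, dtype=np.float64)
    if vol.ndim != 3:
        raise ValueError("volume must be 3D [z, y, x]")
    peak = float(vol.max())
    if peak <= 0:
        return []
    dz, dy, dx = voxel_size_um
    scale = np.array([dz, dy, dx])
    # blob sigma (in voxels, per axis) for a solid sphere of radius r: r/sqrt(3)
    sig_min = (min_radius_um / math.sqrt(3)) / scale
    sig_max = (max_radius_um / math.sqrt(3)) / scale
    blobs = blob_log(vol / peak, min_sigma=sig_min, max_sigma=sig_max,
                     num_sigma=7, threshold=threshold, overlap=1.0)
    if blobs.size == 0:
        return []
    centers_um = blobs[:, [2, 1, 0]] * np.array([dx, dy, dz])  # (x, y, z)
    radii_um = (np.mean(blobs[:, 3:] * scale, axis=1) * math.sqrt(3)
                if blobs.shape[1] > 4 else blobs[:, 3] * float(np.mean(scale)) * math.sqrt(3))
    values = vol[tuple(np.clip(blobs[:, :3].astype(int), 0,
                               np.array(vol.shape) - 1).T)]
    keep_mask = values >= intensity_floor * peak
    order = np.argsort(values)[::-1]
    suppress_dist = (suppress_dist_um if suppress_dist_um is not None
                     else 0.5 * (min_radius_um + max_radius_um))
    kept: List[int] = []
    for i in order:
        if not keep_mask[i]:
            continue
        if all(np.linalg.norm(centers_um[i] - centers_um[j]) >= suppress_dist for j in kept):
            kept.append(i)
    return [(tuple(map(float, centers_um[i])), float(radii_um[i])) for i in kept]


def colocalize(green_centers: Sequence[Sequence[float]],
               red_centers: Sequence[Sequence[float]],
               tolerance_um: float
               ) -> Tuple[List[Tuple[int, int, float]], List[int], List[int]]:
    """Greedy nearest-neighbour matching of two centre lists.

    Candidate pairs within ``tolerance_um`` are matched closest-first; each
    centre is used at most once.  Returns ``(pairs, unmatched_green,
    unmatched_red)`` with pairs as ``(i_green, i_red, distance_um)``.
    """
    if tolerance_um <= 0:
        raise ValueError("tolerance_um must be positive")
    g = np.atleast_2d(np.asarray(green_centers, dtype=float)) if len(green_centers) else np.empty((0, 3))
    r = np.atleast_2d(np.asarray(red_centers, dtype=float)) if len(red_centers) else np.empty((0, 3))
    if g.shape[0] == 0 or r.shape[0] == 0:
        return [], list(range(g.shape[0])), list(range(r.shape[0]))
    tree = cKDTree(r)
    candidates = []
    for i, point in enumerate(g):
        for j in tree.query_ball_point(point, tolerance_um):
            candidates.append((float(np.linalg.norm(point - r[j])), i, j))
    candidates.sort()
    used_g, used_r = set(), set()
    pairs: List[Tuple[int, int, float]] = []
    for d, i, j in candidates:
        if i in used_g or j in used_r:
            continue
        pairs.append((i, j, d))
        used_g.add(i)
        used_r.add(j)
    unmatched_g = [i for i in range(g.shape[0]) if i not in used_g]
    unmatched_r = [j for j in range(r.shape[0]) if j not in used_r]
    return pairs, unmatched_g, unmatched_r


# ---------------------------------------------------------------------------
# morphometry


def _edge_class(node_type: int) -> str:
    return {AXON: "axon", BASAL: "basal", APICAL: "apical", SOMA: "soma"}.get(
        node_type, "other")


def morphometry(tree: NeuronTree, layer_boundaries: Sequence[float] | None = None,
                long_range_threshold_um: float = 1000.0,
                furthest_target_label: str = "") -> MorphometryReport:
    """Per-compartment length and branch-point statistics of one neuron.

    An edge belongs to the compartment class of its child node; edges whose
    child is a soma node are excluded from dendrite/axon totals.  Branch
    points are nodes of a class with at least two children.  A neuron is
    ``long-range`` when the geodesic (along-tree) distance from the root to
    the furthest axonal node exceeds the threshold.  ``layer_boundaries``
    (depths in um) optionally bins axon length by the z of each edge midpoint.
    """
    nodes = tree.nodes
    children = tree.children()
    lengths: Dict[str, float] = {"axon": 0.0, "basal": 0.0, "apical": 0.0,
                                 "soma": 0.0, "other": 0.0}
    seg_counts: Dict[str, int] = {k: 0 for k in lengths}
    unknown_types = set()
    layer_len: Dict[int, float] | None = (
        {i: 0.0 for i in range(len(layer_boundaries) + 1)} if layer_boundaries is not None else None)

    # geodesic distance from root, accumulated in topological order
    geodesic: Dict[int, float] = {tree.root.id: 0.0}
    for i in tree.topological_order():
        n = nodes[i]
        if n.parent == -1:
            continue
        parent = nodes[n.parent]
        d = float(np.linalg.norm(np.subtract(n.position, parent.position)))
        geodesic[i] = geodesic[n.parent] + d
        cls = _edge_class(n.type)
        if cls == "other":
            unknown_types.add(n.type)
        lengths[cls] += d
        if layer_len is not None and cls == "axon":
            zm = 0.5 * (n.z + parent.z)
            layer_len[int(np.searchsorted(layer_boundaries, zm))] += d

    branch_counts: Dict[str, int] = {k: 0 for k in lengths}
    # segments: maximal unbranched runs = terminals + extra children at branch points
    for i, ch in children.items():
        cls = _edge_class(nodes[i].type)
        if len(ch) >= 2:
            branch_counts[cls] += 1
            seg_counts[cls] += len(ch) - 1
        elif not ch:
            seg_counts[cls] += 1

    if unknown_types:
        warnings.warn(
            f"unknown SWC type codes {sorted(unknown_types)} counted as 'other'",
            stacklevel=2,
        )

    axon_extent = max((geodesic[i] for i in nodes if nodes[i].type == AXON), default=0.0)
    return MorphometryReport(
        axon_length_um=lengths["axon"],
        dendrite_length_um=lengths["apical"] + lengths["basal"],
        apical_length_um=lengths["apical"],
        basal_length_um=lengths["basal"],
        other_length_um=lengths["other"],
        axon_branch_count=branch_counts["axon"],
        dendrite_branch_count=branch_counts["apical"] + branch_counts["basal"],
        apical_branch_count=branch_counts["apical"],
        basal_branch_count=branch_counts["basal"],
        axon_segment_count=seg_counts["axon"],
        dendrite_segment_count=seg_counts["apical"] + seg_counts["basal"],
        projection_class="long-range" if axon_extent > long_range_threshold_um else "local",
        furthest_target_label=furthest_target_label,
        length_by_layer=layer_len,
    )


# ---------------------------------------------------------------------------
# statistics and projections


def compare_groups(values_a: Sequence[float], values_b: Sequence[float],
                   alpha: float = 0.05) -> GroupComparison:
    """Two-sided, equal-variance (pooled) Student's t-test with mean +/- s.e.m."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    sem_a = float(a.std(ddof=1) / math.sqrt(a.size))
    sem_b = float(b.std(ddof=1) / math.sqrt(b.size))
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        if a.mean() == b.mean():
            t, p = 0.0, 1.0
        else:
            t = math.inf if a.mean() > b.mean() else -math.inf
            p = 0.0
    else:
        t, p = stats.ttest_ind(a, b, equal_var=True)
        t, p = float(t), float(p)
    return GroupComparison(
        group_a_values=a, group_b_values=b,
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        sem_a=sem_a, sem_b=sem_b,
        t_statistic=t, p_value=p, alpha=alpha,
    )


def project(volume: np.ndarray, axis: int = 0, mode: str = "max",
            slab_bounds: Tuple[int, int] | None = None) -> np.ndarray:
    """Maximum- or minimum-intensity projection over a slab along one axis."""
    vol = np.asarray(volume)
    if slab_bounds is not None:
        lo, hi = slab_bounds
        if not 0 <= lo < hi <= vol.shape[axis]:
            raise ValueError(f"empty or out-of-range slab {slab_bounds} along axis {axis}")
        vol = np.take(vol, np.arange(lo, hi), axis=axis)
    if vol.shape[axis] == 0:
        raise ValueError("empty slab")
    if mode == "max":
        return vol.max(axis=axis)
    if mode == "min":
        return vol.min(axis=axis)
    raise ValueError(f"mode must be 'max' or 'min', got {mode!r}")
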