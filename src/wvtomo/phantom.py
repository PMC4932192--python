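"""Synthetic two-channel specimen phantoms with ground truth.

A :class:`Phantom` holds two voxelized fluorophore-density grids over the same
volume: ``green_density`` (cytoplasmic label: neuron skeletons with bright
somata) and ``red_affinity`` (stainable nucleic-acid density: cell nuclei).
The red channel is *not* directly emissive — emission is produced by
:func:`stain_surface`, which models a low-permeability nuclear dye carried in
the immersion bath: after each cut the dye penetrates the fresh block face and
binds within an exponential depth shell, so only a superficial lamina of
nuclei lights up, with no background from deep tissue.

All randomness flows from ``PhantomConfig.seed``; identical configs produce
bit-identical phantoms.

Array axes are ``[z, y, x]`` (z increases with depth below the block surface);
ground-truth coordinates are micrometre ``(x, y, z)`` tuples, matching SWC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import List, Sequence, Tuple

import numpy as np

from .swc import APICAL, AXON, BASAL, SOMA, NeuronTree, SWCNode

__all__ = [
    "PhantomConfig",
    "Phantom",
    "generate_phantom",
    "stain_surface",
    "generate_bead_phantom",
]


@dataclass(frozen=True)
class PhantomConfig:
    """Content, staining-model and noise-floor parameters of a phantom.

    ``volume_shape_vox`` is (nx, ny, nz); ``voxel_size_um`` a scalar or
    (dx, dy, dz).  ``penetration_length_um`` (lambda) and ``staining_tau_s``
    (tau) parameterise the separable dye model
    ``affinity * exp(-(z - cut)/lambda) * (1 - exp(-t/tau))``; the dye is fast
    (tau of seconds) and shallow (lambda of a few micrometres), which is what
    makes real-time surface counterstaining work.  ``soma_overlap_fraction``
    fixes how many neuron somata coincide with a nucleus centre — the
    co-localization ground truth.
    """

    volume_shape_vox: Tuple[int, int, int] = (128, 128, 48)
    voxel_size_um: float | Tuple[float, float, float] = 0.325
    n_neurons: int = 3
    neuron_branching: float = 2.0
    neuron_radius_um: float = 0.6
    soma_radius_um: float = 3.0
    n_nuclei: int = 12
    nucleus_radius_mean_um: float = 2.5
    nucleus_radius_sd_um: float = 0.25
    nucleus_min_separation_um: float | None = None  # default: one mean diameter
    soma_overlap_fraction: float = 0.6
    pi_concentration_ug_ml: float = 2.0
    penetration_length_um: float = 3.0
    staining_tau_s: float = 5.0
    background_level: float = 1.0
    neuron_intensity: float = 100.0
    nucleus_affinity: float = 80.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(c < 0 for c in (self.n_neurons, self.n_nuclei)):
            raise ValueError("object counts must be >= 0")
        if min(self.neuron_radius_um, self.soma_radius_um, self.nucleus_radius_mean_um) <= 0:
            raise ValueError("radii must be positive")
        if self.penetration_length_um <= 0 or self.staining_tau_s <= 0:
            raise ValueError("penetration_length_um and staining_tau_s must be positive")
        if not 0.0 <= self.soma_overlap_fraction <= 1.0:
            raise ValueError("soma_overlap_fraction must lie in [0, 1]")
        if self.background_level < 0:
            raise ValueError("background_level must be >= 0")

    @property
    def voxel_xyz(self) -> Tuple[float, float, float]:
        v = self.voxel_size_um
        return (v, v, v) if np.isscalar(v) else tuple(v)  # type: ignore[return-value]

    @property
    def extent_um(self) -> Tuple[float, float, float]:
        dx, dy, dz = self.voxel_xyz
        nx, ny, nz = self.volume_shape_vox
        return (nx * dx, ny * dy, nz * dz)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["volume_shape_vox"] = list(self.volume_shape_vox)
        if not np.isscalar(self.voxel_size_um):
            d["voxel_size_um"] = list(self.voxel_size_um)  # type: ignore[arg-type]
        return d

    @classmethod
    def from_dict(cls, d) -> "PhantomConfig":
        d = dict(d)
        d["volume_shape_vox"] = tuple(d.get("volume_shape_vox", (128, 128, 48)))
        v = d.get("voxel_size_um", 0.325)
        if not np.isscalar(v):
            d["voxel_size_um"] = tuple(v)
        return cls(**d)


@dataclass
class Phantom:
    """Voxelized specimen with ground truth.

    ``truth_nuclei`` is a list of ``(center_xyz_um, radius_um)``;
    ``truth_beads`` a list of ``center_xyz_um``.
    """

    green_density: np.ndarray  # [z, y, x]
    red_affinity: np.ndarray  # [z, y, x]
    truth_trees: List[NeuronTree]
    truth_nuclei: List[Tuple[Tuple[float, float, float], float]]
    truth_beads: List[Tuple[float, float, float]]
    config: PhantomConfig

    @property
    def voxel_xyz(self) -> Tuple[float, float, float]:
        return self.config.voxel_xyz

    @property
    def depth_um(self) -> float:
        return self.green_density.shape[0] * self.voxel_xyz[2]

    @property
    def z_centers_um(self) -> np.ndarray:
        dz = self.voxel_xyz[2]
        return (np.arange(self.green_density.shape[0]) + 0.5) * dz


# ---------------------------------------------------------------------------
# rasterization helpers


def _splat_max(grid: np.ndarray, center_xyz_um, sigma_um: float, amplitude: float,
               voxel_xyz, cutoff: float = 3.0) -> None:
    """Deposit a Gaussian blob by voxelwise maximum (uniform-brightness tubes)."""
    dx, dy, dz = voxel_xyz
    cx, cy, cz = center_xyz_um
    nzv, nyv, nxv = grid.shape
    hx = int(np.ceil(cutoff * sigma_um / dx))
    hy = int(np.ceil(cutoff * sigma_um / dy))
    hz = int(np.ceil(cutoff * sigma_um / dz))
    ix, iy, iz = int(cx / dx), int(cy / dy), int(cz / dz)
    x0, x1 = max(0, ix - hx), min(nxv, ix + hx + 1)
    y0, y1 = max(0, iy - hy), min(nyv, iy + hy + 1)
    z0, z1 = max(0, iz - hz), min(nzv, iz + hz + 1)
    if x0 >= x1 or y0 >= y1 or z0 >= z1:
        return
    xs = (np.arange(x0, x1) + 0.5) * dx - cx
    ys = (np.arange(y0, y1) + 0.5) * dy - cy
    zs = (np.arange(z0, z1) + 0.5) * dz - cz
    d2 = (zs[:, None, None] ** 2 + ys[None, :, None] ** 2 + xs[None, None, :] ** 2)
    blob = amplitude * np.exp(-d2 / (2.0 * sigma_um**2))
    np.maximum(grid[z0:z1, y0:y1, x0:x1], blob, out=grid[z0:z1, y0:y1, x0:x1])


def _soft_sphere(grid: np.ndarray, center_xyz_um, radius_um: float, amplitude: float,
                 voxel_xyz, edge_um: float = 0.5) -> None:
    """Solid sphere with a linear soft edge, deposited by maximum."""
    dx, dy, dz = voxel_xyz
    cx, cy, cz = center_xyz_um
    nzv, nyv, nxv = grid.shape
    r_out = radius_um + edge_um
    x0, x1 = max(0, int((cx - r_out) / dx)), min(nxv, int((cx + r_out) / dx) + 2)
    y0, y1 = max(0, int((cy - r_out) / dy)), min(nyv, int((cy + r_out) / dy) + 2)
    z0, z1 = max(0, int((cz - r_out) / dz)), min(nzv, int((cz + r_out) / dz) + 2)
    if x0 >= x1 or y0 >= y1 or z0 >= z1:
        return
    xs = (np.arange(x0, x1) + 0.5) * dx - cx
    ys = (np.arange(y0, y1) + 0.5) * dy - cy
    zs = (np.arange(z0, z1) + 0.5) * dz - cz
    d = np.sqrt(zs[:, None, None] ** 2 + ys[None, :, None] ** 2 + xs[None, None, :] ** 2)
    blob = amplitude * np.clip((radius_um + edge_um - d) / edge_um, 0.0, 1.0)
    np.maximum(grid[z0:z1, y0:y1, x0:x1], blob, out=grid[z0:z1, y0:y1, x0:x1])


def rasterize_tree(grid: np.ndarray, tree: NeuronTree, voxel_xyz,
                   tube_sigma_um: float, intensity: float,
                   soma_sigma_um: float | None = None,
                   soma_intensity: float | None = None,
                   step_um: float | None = None) -> None:
    """Render a neuron tree into ``grid`` as Gaussian-profile tubes.

    Edges are sampled at ``step_um`` (default half the smallest voxel) and
    splatted by maximum, so tube brightness is independent of edge length.
    The root gets a larger soma blob when ``soma_sigma_um`` is given.
    """
    if step_um is None:
        step_um = 0.5 * min(voxel_xyz)
    nodes = tree.nodes
    for node in nodes.values():
        if node.parent == -1:
            continue
        p = np.asarray(nodes[node.parent].position)
        q = np.asarray(node.position)
        length = float(np.linalg.norm(q - p))
        n_steps = max(1, int(np.ceil(length / step_um)))
        for t in np.linspace(0.0, 1.0, n_steps + 1):
            _splat_max(grid, p + t * (q - p), tube_sigma_um, intensity, voxel_xyz)
    if soma_sigma_um is not None:
        root = tree.root
        _splat_max(grid, root.position, soma_sigma_um,
                   soma_intensity if soma_intensity is not None else intensity,
                   voxel_xyz)


# ---------------------------------------------------------------------------
# object placement


def _place_points(rng: np.random.Generator, n: int, lo: np.ndarray, hi: np.ndarray,
                  min_sep: float, avoid: Sequence[np.ndarray] = (),
                  avoid_dist: float = 0.0, max_tries: int = 20000) -> List[np.ndarray]:
    """Rejection-sample points in an axis-aligned box with a minimum spacing.

    Earlier draws win ties: a candidate is rejected if it comes closer than
    ``min_sep`` to an accepted point or ``avoid_dist`` to any avoided point.
    """
    if n == 0:
        return []
    if np.any(hi <= lo):
        raise ValueError("volume too small to contain the requested objects")
    pts: List[np.ndarray] = []
    tries = 0
    while len(pts) < n:
        tries += 1
        if tries > max_tries:
            raise ValueError(
                f"could not place {n} objects with separation {min_sep} um "
                f"in the available volume"
            )
        c = lo + rng.random(3) * (hi - lo)
        if any(np.linalg.norm(c - p) < min_sep for p in pts):
            continue
        if any(np.linalg.norm(c - p) < avoid_dist for p in avoid):
            continue
        pts.append(c)
    return pts


def _grow_tree(rng: np.random.Generator, root_xyz: np.ndarray, cfg: PhantomConfig,
               lo: np.ndarray, hi: np.ndarray) -> NeuronTree:
    """Random binary-branching 3D walk with smooth curvature, saved as SWC nodes.

    Produces an axon-like arborisation: segments of 12-30 um grown in ~1 um
    steps, direction diffusing on the sphere, reflected at the volume margins;
    a Poisson(``neuron_branching``) budget of branch points splits a tip in
    two.  The root is a soma node, everything else axon.
    """
    nodes = {1: SWCNode(1, SOMA, *root_xyz, cfg.soma_radius_um, -1)}
    next_id = 2
    budget = int(rng.poisson(cfg.neuron_branching))
    # initial direction: biased downwards so trees cross section boundaries
    d0 = rng.normal(size=3)
    d0[2] = abs(d0[2]) + 1.0
    tips = [(1, d0 / np.linalg.norm(d0))]
    step = 1.0
    max_nodes = 400
    while tips and next_id <= max_nodes:
        parent, direction = tips.pop(0)
        seg_len = rng.uniform(12.0, 30.0)
        pos = np.array(nodes[parent].position, dtype=float)
        n_steps = int(seg_len / step)
        for _ in range(n_steps):
            direction = direction + rng.normal(scale=0.12, size=3)
            direction /= np.linalg.norm(direction)
            pos = pos + direction * step
            # reflect at margins
            for ax in range(3):
                if pos[ax] < lo[ax]:
                    pos[ax] = 2 * lo[ax] - pos[ax]
                    direction[ax] = abs(direction[ax])
                elif pos[ax] > hi[ax]:
                    pos[ax] = 2 * hi[ax] - pos[ax]
                    direction[ax] = -abs(direction[ax])
            nodes[next_id] = SWCNode(next_id, AXON, *pos, cfg.neuron_radius_um, parent)
            parent = next_id
            next_id += 1
            if next_id > max_nodes:
                break
        if budget > 0 and next_id <= max_nodes:
            budget -= 1
            for sign in (1.0, -1.0):
                d = direction + sign * rng.normal(scale=0.6, size=3)
                tips.append((parent, d / np.linalg.norm(d)))
    return NeuronTree(nodes)


# ---------------------------------------------------------------------------
# public generators


def generate_phantom(config: PhantomConfig) -> Phantom:
    """Build a deterministic two-channel phantom from its config.

    Exactly ``round(soma_overlap_fraction * n_neurons)`` neuron roots coincide
    with a nucleus centre; the remaining roots are kept well clear of every
    nucleus (four mean radii) so detection-based co-localization has an
    unambiguous ground truth.
    """
    nx, ny, nz = config.volume_shape_vox
    if nx * ny * nz > 512**3:
        raise ValueError("phantom volume exceeds the supported desk scale (<= 512^3 voxels)")
    voxel = config.voxel_xyz
    rng = np.random.default_rng(config.seed)
    green = np.full((nz, ny, nx), config.background_level, dtype=np.float32)
    red = np.full((nz, ny, nx), config.background_level, dtype=np.float32)

    ex, ey, ez = config.extent_um
    r_nuc = config.nucleus_radius_mean_um
    margin = r_nuc + 1.0
    lo = np.array([margin, margin, margin])
    hi = np.array([ex - margin, ey - margin, ez - margin])

    min_sep = (config.nucleus_min_separation_um
               if config.nucleus_min_separation_um is not None else 2.0 * r_nuc)
    n_overlap = int(round(config.soma_overlap_fraction * config.n_neurons))
    if n_overlap > config.n_nuclei:
        raise ValueError(
            f"soma_overlap_fraction requires {n_overlap} nuclei but only "
            f"{config.n_nuclei} requested"
        )

    centers = _place_points(rng, config.n_nuclei, lo, hi, min_sep)
    radii = np.clip(
        rng.normal(r_nuc, config.nucleus_radius_sd_um, size=config.n_nuclei),
        0.5 * r_nuc, 1.5 * r_nuc,
    )
    truth_nuclei = [(tuple(map(float, c)), float(r)) for c, r in zip(centers, radii)]
    for c, r in zip(centers, radii):
        _soft_sphere(red, c, r, config.nucleus_affinity, voxel)

    # neuron roots: the first n_overlap sit on nucleus centres, the rest far away
    roots: List[np.ndarray] = [np.array(c) for c in centers[:n_overlap]]
    n_free = config.n_neurons - n_overlap
    if n_free > 0:
        roots += _place_points(rng, n_free, lo, hi, min_sep,
                               avoid=centers, avoid_dist=4.0 * r_nuc)

    trees: List[NeuronTree] = []
    for root in roots:
        tree = _grow_tree(rng, root, config, lo, hi)
        trees.append(tree)
        rasterize_tree(
            green, tree, voxel,
            tube_sigma_um=config.neuron_radius_um,
            intensity=config.neuron_intensity,
            soma_sigma_um=config.soma_radius_um / 1.5,
            soma_intensity=1.5 * config.neuron_intensity,
        )

    return Phantom(green, red, trees, truth_nuclei, [], config)


def stain_surface(phantom: Phantom, cut_depth_um: float, dwell_time_s: float,
                  config: PhantomConfig | None = None) -> np.ndarray:
    """Emitted red density after ``dwell_time_s`` of surface staining.

    ``emitted(z, t) = affinity(z) * exp(-(z - cut)/lambda) * (1 - exp(-t/tau))``
    for voxel-centre depths ``z >= cut_depth_um`` and exactly zero above the
    cut (that material has been removed); monotone increasing in dwell time.
    """
    cfg = config or phantom.config
    if dwell_time_s < 0:
        raise ValueError("dwell_time_s must be >= 0")
    if not 0.0 <= cut_depth_um <= phantom.depth_um:
        raise ValueError("cut_depth_um outside the phantom depth range")
    z = phantom.z_centers_um
    depth_factor = np.where(
        z >= cut_depth_um,
        np.exp(-(z - cut_depth_um) / cfg.penetration_length_um),
        0.0,
    )
    time_factor = 1.0 - np.exp(-dwell_time_s / cfg.staining_tau_s)
    return (phantom.red_affinity * depth_factor[:, None, None] * time_factor).astype(np.float32)


def generate_bead_phantom(centers_um: Sequence[Tuple[float, float, float]],
                          shape_vox: Tuple[int, int, int],
                          voxel_size_um: float | Tuple[float, float, float],
                          amplitude: float = 1.0) -> Phantom:
    """Sub-resolution fluorescent beads as single-voxel point emitters.

    Used for PSF metrology: the rendered grid is zero except at the voxel
    containing each bead centre, so convolving with a candidate PSF yields the
    exact sampled PSF.
    """
    nxv, nyv, nzv = shape_vox
    voxel = (voxel_size_um,) * 3 if np.isscalar(voxel_size_um) else tuple(voxel_size_um)
    dx, dy, dz = voxel
    grid = np.zeros((nzv, nyv, nxv), dtype=np.float32)
    for (cx, cy, cz) in centers_um:
        ix, iy, iz = int(cx / dx), int(cy / dy), int(cz / dz)
        if not (0 <= ix < nxv and 0 <= iy < nyv and 0 <= iz < nzv):
            raise ValueError(f"bead at ({cx}, {cy}, {cz}) um lies outside the volume")
        grid[iz, iy, ix] = amplitude
    cfg = PhantomConfig(volume_shape_vox=shape_vox, voxel_size_um=voxel_size_um,
                        n_neurons=0, n_nuclei=0)
    return Phantom(grid, np.zeros_like(grid), [], [],
                   [tuple(map(float, c)) for c in centers_um], cfg)
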