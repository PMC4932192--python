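# Methods

## Scope and model overview

`wvtomo` models the computational chain of a wide-field large-volume
tomograph: a block-face microscope that projects a binary grid pattern
through a DMD onto the cut surface of a resin-embedded specimen, acquires
three phase-shifted frames per tile and z-plane, covers each coronal plane
with overlapping tiles, removes a thin slice, and repeats. A nucleic-acid
dye in the immersion bath stains each fresh surface within seconds, giving a
cytoarchitecture (red) channel acquired co-registered with the cytoplasmic
label (green). The package contains both halves: a forward simulator
(phantom + virtual microscope) and the reconstruction/measurement pipeline,
so each processing stage can be validated against ground truth.

Conventions: volumes are `[z, y, x]` arrays; physical points are micrometre
`(x, y, z)` tuples matching SWC; z grows with depth below the original block
surface; a pixel/voxel spans `[i, i+1)·size`; sections are indexed from 0 at
the top; tile origins advance with fixed stride from the minimum corner and
the last row/column may overhang the specimen.

## Acquisition geometry (planner)

The plan fixes camera crop (default 1,700 × 1,800 px), sample pixel
(6.5 μm / 20× = 0.325 μm), tile overlap (10 μm, quantized to whole pixels
before the stride computation), z-stack (2 planes at 2 μm) and section
thickness (4 μm), with the first imaged plane 1.5 μm below the cut surface
(configurable; real instruments image "slightly below" the surface to avoid
knife marks). Tile counts follow `n = ceil((extent − overlap)/(W − overlap))`
with a floor of one. The frame account is exact integer arithmetic:
`layers = sections × z-planes`, `mosaics = z-stacks × z-planes`,
`raw frames = 3 × mosaics`, all per channel; per-section tile counts may vary
(scan ranges adapt to the specimen profile).

## Phantom

Two voxel grids over one volume:

* **green_density** — neuron trees grown as random binary-branching 3D walks
  (segments 12–30 μm in 1 μm steps, direction diffusing on the sphere,
  reflected at the margins, Poisson-distributed branch budget), rasterized as
  Gaussian-profile tubes by *maximum* splatting so brightness is independent
  of path sampling; roots get a brighter soma blob.
* **red_affinity** — stainable nucleic-acid density: soft-edged spheres at
  rejection-sampled centres with a minimum spacing (default one mean nucleus
  diameter, configurable via `nucleus_min_separation_um`), radii clipped
  Gaussian around 2.5 μm.

Exactly `round(soma_overlap_fraction × n_neurons)` roots coincide with
nucleus centres; the remaining roots are kept at least four mean radii from
every nucleus so detection-based co-localization has an unambiguous answer.
All randomness derives from one seed; phantoms are bit-reproducible.

**Surface staining.** The red channel emits
`affinity · e^{−(z−cut)/λ} · (1 − e^{−t/τ})` for voxel centres at or below
the cut, exactly zero above it. λ = 3 μm and τ = 5 s are stated model
defaults (the penetration behaviour of the dye is demonstrated empirically
in the literature but no quantitative law is published); with these values a
15 s section-to-image interval reaches > 95% of saturation, which is the
regime that makes real-time staining viable. DAPI-like slow penetration is
not modelled.

## Virtual microscope (scope_sim)

One tile's expected intensity is

```
I_p = vignette · ½ [ U + M · cos(2πx/T + p·π/2) ],
U = Σ_dz blur(E(dz), σ(dz)),   M = Σ_dz m(dz) · blur(E(dz), σ(dz)),
σ(dz) = √(σ₀² + (slope·dz)²),  m(dz) = exp(−(dz/s)²)
```

summed over phantom layers within ±24 μm of the imaged plane
(`depth_window_um`; farther layers carry `m < e^{−144}` and a nearly uniform
wide-field background, and are skipped for speed). Stripes are fixed in the
camera frame and run along y. Defaults: modulation scale *s* = 2 μm, blur
slope 0.5, pattern period at the sample = 109.44 μm / 40 = 2.736 μm
(≈ 8.4 px). The DMD-to-sample magnification is not derivable from the other
optics values and is a plain config parameter. Each layer's blur is computed
on a 3σ-margin crop (capped at 64 px), nearest-padded, so tile edges agree
with neighbouring tiles across the overlap bands.

Because the pattern phase is independent of depth, the demodulated image is
exactly `vignette · M/2`: the response of a point emitter falls as `m(dz)`
times a blur-spread factor, which is what the optical-sectioning tests
assert (monotone decrease; < e⁻⁴ at dz = 2s).

Noise (optional, seeded per frame from the run seed and the frame indices):
Poisson shot noise on `photons_per_unit × intensity`, additive Gaussian read
noise. Stage jitter: one 2D Gaussian offset (default σ 0.3 μm when enabled)
per z-stack, recorded in each `RawTile` for stitching-refinement tests. The
acquisition loop emits frames section-major, tile row-major, then z-plane,
phase, channel, and advances the cut by the section thickness after each
section — the sectioning–staining–imaging cycle.

## Reconstruction (recon)

* **Demodulation.** `A = ½·√((I0−I2)² + (I0+I2−2I1)²)` is algebraically
  exact for the π/2 phase step (see derivation in the module docstring) and
  invariant to any constant added to all three frames. The classic
  root-mean-square three-phase estimator (exact for a 2π/3 step) is
  available behind `method="rms_2pi3"`.
* **Stitching.** Tiles placed at nominal stage positions (pixel-quantized);
  linear feather ramps across each shared overlap band, renormalized to a
  partition of unity, so constants are preserved exactly and consistent
  tiles reproduce the source scene to machine precision. With refinement on,
  each tile is registered to its already-placed left/top neighbours by
  phase cross-correlation over the nominal overlap strips
  (`normalization=None`; the phase-normalized variant is unreliable on
  smooth microscopy content), estimates averaged, clipped to the search
  radius (default ±3 μm) and chained through the grid.
* **Lateral (flat-field) correction.** A degree-4 polynomial is fitted to
  the per-column and per-row mean-intensity profiles of each stitched
  section; the applied gain is `poly(centre)/poly(p)`, separable in x and y.
  Shading is a smooth order-of-unity field, so the fit is guarded against
  chasing structure: positions below 30% of the median covered intensity
  (mosaic overhang beyond the specimen) are excluded with constant gain
  extrapolation outside, the profile is winsorized at 3× its median so a
  single bright soma cannot bend the polynomial, the degree is reduced until
  the fitted profile is strictly positive (degree 0 always is; a warning is
  issued), and the applied gain is clamped to [1/5, 5]. Smooth vignetting of
  a few tens of percent passes all guards unchanged and is restored to
  within 1%.
* **Axial equalization.** Each section's foreground (positive-pixel) mean is
  scaled to a common reference, default the median of section means (robust
  to a few dim or bright sections); zero-mean sections get gain 1 with a
  warning. Gains are recorded.
* **Pipeline order.** demodulate → stitch → lateral-correct (fitted per
  section, after stitching — "section by section") → axial-equalize → stack
  planes in order `section × z_planes + z_plane`. No inter-section
  registration is performed: block-face acquisition is self-registered.
  Export quantizes to 8- or 16-bit TIFF (LZW when the codec is present) with
  linear min/max scaling per volume; all internal stages run in float.

## Measurement (quant)

* **Bead FWHM.** 1D Gaussians (amplitude, centre, σ, offset) are fitted to
  the x/y/z profiles through the brightest voxel of a bead stack;
  `FWHM = 2√(2 ln 2)·σ`; lateral = mean of x and y. A Gaussian fit is used
  rather than half-maximum interpolation because a 0.55 μm peak sampled at
  0.32 μm leaves only ~3 informative samples per side. Median absolute
  error stays below 5% for σ ∈ [0.2, 1.2] μm at peak SNR 20 (Poisson).
* **Soma detection.** Scale-space Laplacian-of-Gaussian (anisotropic sigmas
  `r/√3` per axis in voxel units) with three filters: the detector's
  scale-normalized response threshold, an intensity floor (fraction of the
  volume peak — LoG response scales are not bounded by the image range and
  admit background ripples otherwise), and non-maximum suppression by centre
  distance (default the mean requested radius; pass the cell diameter when a
  nucleus straddling a section boundary may peak in two consecutive
  sections). Two cells closer than the suppression distance merge into one
  detection — a documented limitation.
* **Co-localization.** Greedy closest-first matching under a distance
  tolerance, each centre used at most once.
* **Morphometry.** Edge lengths are Euclidean parent–child distances
  classified by the child's SWC type; apical + basal = dendrite total by
  construction; soma-ending edges are excluded from neurite totals. Branch
  count = nodes of the class with ≥ 2 children ("branch number" is ambiguous
  between branch points and segments, so segment counts are reported as
  well). A neuron is "long-range" when the along-tree distance from root to
  the furthest axonal node exceeds 1,000 μm (an artifact parameter; the
  original classification is by target brain region, which needs an atlas
  and is out of scope — `furthest_target_label` is caller-supplied).
  Totals are invariant under node reindexing and collinear edge subdivision.
* **Group statistics.** Two-sided equal-variance Student's t with
  mean ± s.e.m. per group; degenerate zero-variance cases are defined
  explicitly (equal means → p = 1). The implementation is checked against
  the hand-written pooled-variance formula to 1e-12 and its null rejection
  rate is Monte-Carlo calibrated at α = 0.05.
* **Projections.** Pixelwise max/min over a slab; minimum-intensity
  projections through a counterstain stack expose ring-shaped cell-dense
  walls (the barrel-column use case).

## What the phantom does and does not show

The phantom reproduces the features the pipeline stages care about:
grid-modulated in-focus signal over unmodulated background, depth-limited
surface staining, vignetting, stage jitter, tile/section boundaries crossed
by continuous structures, co-localized somata/nuclei, and sub-resolution
point sources. It does **not** reproduce real tissue optics (scattering,
depth-dependent aberrations, refractive-index mismatch), real
cytoarchitecture (layers, nuclei organs, barrels beyond constructed rings),
photobleaching, knife chatter, or camera fixed-pattern noise. Passing tests
therefore validate the algorithms' correctness and calibration on the
modelled physics, not end-to-end performance on real brains.

## Problem sizes and numerical choices

The round-trip validation runs a 256 × 256 × 64-voxel phantom
(0.32 × 0.32 × 1 μm voxels, ~82 × 82 × 64 μm) under a 2 × 2 tile grid,
15 sections × 2 z-planes, noiseless — about a minute of CPU; unit tests use
64–160 px tiles. Bead metrology stacks are 33 × 33 × 61 voxels. Demodulation
and stitching are exact in float64; detection thresholds in the round trip
(LoG 0.2, intensity floor 0.3, suppression 6 μm) correspond to the noiseless,
well-separated study conditions of the phantom configuration. The whole-brain
numbers (thousands of sections, 10⁵ z-stacks) appear only through the integer
accounting, which is scale-free.

## Known limitations

* The forward model applies the illumination pattern after the detection
  blur (modulation depth handled by `m(dz)`), an approximation that makes
  demodulation exactly `M/2`; it does not model diffraction OTFs.
* The defocus blur/modulation laws are phenomenological (Gaussian), chosen
  for monotonicity and cheapness, not fitted to a physical pupil model.
* Flat-field fitting on sparse, structure-dominated channels estimates
  shading from content; the guards above bound, but do not eliminate, the
  resulting gain error.
* Bouton counting and atlas-based target labelling are out of scope;
  `detect_somata` is a generic blob detector, not a reimplementation of a
  dedicated soma-localization package.
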