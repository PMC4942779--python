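"""Synthetic multimodal mosaic generator with ground-truth masks and labels.

The generator emulates the contrasts that distinguish healthy from inflamed
colonic mucosa in CARS/TPEF/SHG imaging so that the whole analysis pipeline
is testable without patient data:

* morphology — crypts placed on a jittered lattice inside the mucosa;
  healthy presets give regular, uniformly spaced, round crypts, diseased
  presets give distorted shapes, variable diameters and spacing, lower
  density (mucosal atrophy) and frequent branching;
* intensity — per-channel epithelium/background levels, dark mucin cores of
  goblet cells (dark in CARS and TPEF), bright lymphocyte-like spots in the
  TPEF channels (strongest at 525 nm), a global elevation of the TPEF
  background under inflammation, and SHG-bright fibrosis patches that are
  absent from healthy mucosa;
* acquisition — per-tile vignetting (the source of mosaic seam artifacts)
  followed by Poisson shot noise and additive Gaussian read noise.

Everything is deterministic given the cohort seed. The emitted RoiSet is
the exact ground truth of the rendered crypts, so geometry features can be
checked against the generator's realised parameters.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Tuple

import numpy as np
from scipy import ndimage as ndi

from .errors import PackingError, ShapeMismatchError
from .types import CHANNELS, TPEF_CHANNELS, IndexLabels, MultimodalSample, RoiSet

MUCOSA_MARGIN_PX = 8


@dataclass
class MorphologySpec:
    """Crypt-field morphology parameters.

    crypt_radius_um is (mean, coefficient of variation). shape_irregularity
    in [0, 1] scales both ellipse elongation and radial boundary
    perturbation; spacing_cv scales lattice jitter relative to the lattice
    spacing; branch_prob is the probability that a crypt is rendered as two
    fused lobes (branching).
    """

    crypt_density_per_mm2: float = 120.0
    crypt_radius_um: Tuple[float, float] = (30.0, 0.08)
    shape_irregularity: float = 0.05
    spacing_cv: float = 0.05
    branch_prob: float = 0.02

    def __post_init__(self) -> None:
        if self.crypt_density_per_mm2 < 0:
            raise ValueError("crypt density must be >= 0")
        if not 0 <= self.shape_irregularity <= 1:
            raise ValueError("shape_irregularity must be in [0, 1]")
        if not 0 <= self.branch_prob <= 1:
            raise ValueError("branch_prob must be in [0, 1]")
        if self.spacing_cv < 0:
            raise ValueError("spacing_cv must be >= 0")


@dataclass
class IntensitySpec:
    """Per-channel intensity model for one class.

    ``baseline`` is the lamina-propria (mucosa outside crypts) level and
    ``crypt_level`` the crypt-epithelium level, in arbitrary detector units.
    ``tpef_background_gain`` multiplies both TPEF channels over the whole
    mucosa (inflammation elevates autofluorescence globally);
    ``shg_fibrosis_patch_fraction`` is the mucosa area fraction covered by
    SHG-bright fibrosis/scarring patches. ``texture_cv`` adds smooth
    multiplicative heterogeneity so first-order statistics are non-trivial.
    """

    baseline: Dict[str, float] = field(default_factory=lambda: {
        "CARS2850": 0.25, "CARS2930": 0.25, "TPEF458": 0.15,
        "TPEF525": 0.12, "SHG": 0.002,
    })
    crypt_level: Dict[str, float] = field(default_factory=lambda: {
        "CARS2850": 0.55, "CARS2930": 0.60, "TPEF458": 0.30,
        "TPEF525": 0.25, "SHG": 0.002,
    })
    goblet_dark_fraction: float = 0.5
    lymphocyte_spot_density_per_mm2: float = 30.0
    lymphocyte_spot_brightness: float = 0.5
    tpef_background_gain: float = 1.0
    shg_fibrosis_patch_fraction: float = 0.0
    shg_fibrosis_level: float = 0.45
    shg_ring_level: float = 0.0
    texture_cv: float = 0.08
    outside_level: float = 0.01

    def __post_init__(self) -> None:
        for d in (self.baseline, self.crypt_level):
            missing = [c for c in CHANNELS if c not in d]
            if missing:
                raise ValueError(f"intensity level missing channel(s): {missing}")
            if any(v < 0 for v in d.values()):
                raise ValueError("intensity levels must be >= 0")
        if self.tpef_background_gain < 1 and not math.isclose(
                self.tpef_background_gain, 1.0):
            # a gain below 1 would model bleaching, not inflammation
            raise ValueError("tpef_background_gain must be >= 1")
        if not 0 <= self.shg_fibrosis_patch_fraction <= 1:
            raise ValueError("shg_fibrosis_patch_fraction must be in [0, 1]")


@dataclass
class NoiseSpec:
    """Poisson shot noise (photons per intensity unit) + Gaussian read noise.

    ``poisson_scale=None`` disables shot noise entirely.
    """

    poisson_scale: float | None = 60.0
    gaussian_sd: float = 0.01

    def __post_init__(self) -> None:
        if self.poisson_scale is not None and self.poisson_scale <= 0:
            raise ValueError("poisson_scale must be > 0 (or None to disable)")
        if self.gaussian_sd < 0:
            raise ValueError("gaussian_sd must be >= 0")


def healthy_morphology() -> MorphologySpec:
    return MorphologySpec()


def diseased_morphology() -> MorphologySpec:
    """Distorted, sparser, more variable crypts (atrophy + branching)."""
    return MorphologySpec(
        crypt_density_per_mm2=70.0,
        crypt_radius_um=(36.0, 0.30),
        shape_irregularity=0.45,
        spacing_cv=0.30,
        branch_prob=0.35,
    )


def healthy_intensity() -> IntensitySpec:
    return IntensitySpec()


def diseased_intensity() -> IntensitySpec:
    """Elevated TPEF background, dense bright lymphocyte-like spots,
    SHG fibrosis patches."""
    return IntensitySpec(
        lymphocyte_spot_density_per_mm2=250.0,
        tpef_background_gain=1.6,
        shg_fibrosis_patch_fraction=0.15,
    )


@dataclass
class CohortSpec:
    """Conditions for a synthetic cohort.

    Default tiles are 256x256 px at 1.76 um/px — a scaled stand-in for the
    450 um field of view of a full-resolution 2048x2048 tile; full scale is
    available by configuration. ``class_mix`` is the healthy fraction.
    """

    n_samples: int = 40
    class_mix: float = 0.5
    seed: int = 0
    tile_grid: Tuple[int, int] = (2, 2)
    tile_shape_px: Tuple[int, int] = (256, 256)
    pixel_size_um: float = 1.76
    healthy_morph: MorphologySpec = field(default_factory=healthy_morphology)
    diseased_morph: MorphologySpec = field(default_factory=diseased_morphology)
    healthy_intens: IntensitySpec = field(default_factory=healthy_intensity)
    diseased_intens: IntensitySpec = field(default_factory=diseased_intensity)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    vignette_strength: float = 0.25
    vignette_center: Tuple[float, float] = (0.05, 0.05)

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if not 0 <= self.class_mix <= 1:
            raise ValueError("class_mix must be in [0, 1]")
        if not 0 <= self.vignette_strength < 1:
            raise ValueError("vignette_strength must be in [0, 1)")

    @property
    def canvas_shape(self) -> Tuple[int, int]:
        return (self.tile_grid[0] * self.tile_shape_px[0],
                self.tile_grid[1] * self.tile_shape_px[1])

    def n_healthy(self) -> int:
        n = int(round(self.class_mix * self.n_samples))
        if 0 < self.class_mix < 1:
            n = min(max(n, 1), self.n_samples - 1)
        return n


def _rasterize_crypt(center: Tuple[float, float], r_px: float,
                     morph: MorphologySpec, rng: np.random.Generator,
                     shape: Tuple[int, int]) -> Tuple[np.ndarray, np.ndarray]:
    """Rasterize one crypt (possibly two fused lobes); returns (rows, cols)."""
    irr = morph.shape_irregularity
    elong = 1.0 + irr * rng.uniform(0.0, 1.0)
    a = r_px * math.sqrt(elong)
    b = r_px / math.sqrt(elong)
    theta = rng.uniform(0.0, math.pi)
    harmonics = np.arange(2, 5)
    amps = irr * 0.25 * rng.uniform(0.3, 1.0, size=harmonics.size)
    phases = rng.uniform(0.0, 2 * math.pi, size=harmonics.size)
    branch = rng.uniform() < morph.branch_prob
    if branch:
        branch_dir = rng.uniform(0.0, 2 * math.pi)
        branch_d = 1.4 * r_px
        branch_r = 0.8 * r_px
    extent = max(a, b) * (1.0 + amps.sum()) + (branch_d + branch_r if branch else 0.0)
    half = int(math.ceil(extent)) + 2
    cy, cx = center
    r0, r1 = int(math.floor(cy)) - half, int(math.floor(cy)) + half + 1
    c0, c1 = int(math.floor(cx)) - half, int(math.floor(cx)) + half + 1
    r0, c0 = max(r0, 0), max(c0, 0)
    r1, c1 = min(r1, shape[0]), min(c1, shape[1])
    if r0 >= r1 or c0 >= c1:
        return np.empty(0, int), np.empty(0, int)
    yy, xx = np.mgrid[r0:r1, c0:c1]

    def lobe(cy_, cx_, a_, b_):
        dy = yy - cy_
        dx = xx - cx_
        u = dx * math.cos(theta) + dy * math.sin(theta)
        v = -dx * math.sin(theta) + dy * math.cos(theta)
        rho = np.sqrt((u / a_) ** 2 + (v / b_) ** 2)
        ang = np.arctan2(v, u)
        boundary = 1.0
        for k, amp, ph in zip(harmonics, amps, phases):
            boundary = boundary + amp * np.sin(k * ang + ph)
        return rho <= boundary

    mask = lobe(cy, cx, a, b)
    if branch:
        mask |= lobe(cy + branch_d * math.sin(branch_dir),
                     cx + branch_d * math.cos(branch_dir),
                     branch_r, branch_r)
    rr, cc = np.nonzero(mask)
    return rr + r0, cc + c0


def render_crypt_field(morph: MorphologySpec, shape: Tuple[int, int],
                       pixel_size_um: float,
                       rng: np.random.Generator) -> RoiSet:
    """Place non-overlapping crypts on a jittered lattice inside the mucosa.

    The number of lattice sites is chosen so the realised object count
    matches ``crypt_density_per_mm2`` times the mucosa area; candidates
    that would overlap an existing crypt or leave the mucosa are skipped.
    Raises PackingError if fewer than half the requested crypts can be
    placed after bounded retries.
    """
    H, W = shape
    mucosa = np.zeros(shape, bool)
    m = MUCOSA_MARGIN_PX
    if H <= 2 * m or W <= 2 * m:
        raise ValueError("canvas too small for a mucosa region")
    mucosa[m:H - m, m:W - m] = True
    mm_per_px = pixel_size_um / 1000.0
    mucosa_area_mm2 = mucosa.sum() * mm_per_px ** 2
    n_target = int(round(morph.crypt_density_per_mm2 * mucosa_area_mm2))
    labels = np.zeros(shape, np.int32)
    if n_target == 0:
        return RoiSet(labels, mucosa)

    r_mean_px = morph.crypt_radius_um[0] / pixel_size_um
    pad = m + r_mean_px * (1.0 + morph.shape_irregularity)
    h_avail, w_avail = H - 2 * pad, W - 2 * pad
    if h_avail <= 0 or w_avail <= 0:
        raise PackingError("canvas cannot hold a single crypt at this radius")

    for _attempt in range(3):
        labels = np.zeros(shape, np.int32)
        ncols = max(1, int(math.ceil(math.sqrt(n_target * w_avail / h_avail))))
        nrows = max(1, int(math.ceil(n_target / ncols)))
        spacing = min(h_avail / nrows, w_avail / ncols)
        ys = pad + (np.arange(nrows) + 0.5) * (h_avail / nrows)
        xs = pad + (np.arange(ncols) + 0.5) * (w_avail / ncols)
        centers = np.array([(y, x) for y in ys for x in xs])
        order = rng.permutation(len(centers))[:n_target]
        jitter = rng.normal(0.0, morph.spacing_cv * spacing, size=(len(order), 2))
        k = 0
        for idx, (dy, dx) in zip(order, jitter):
            cy, cx = centers[idx, 0] + dy, centers[idx, 1] + dx
            r_px = max(2.0, rng.normal(r_mean_px,
                                       morph.crypt_radius_um[1] * r_mean_px))
            rr, cc = _rasterize_crypt((cy, cx), r_px, morph, rng, shape)
            if rr.size == 0:
                continue
            if (~mucosa[rr, cc]).any() or (labels[rr, cc] != 0).any():
                continue
            k += 1
            labels[rr, cc] = k
        if k >= max(1, int(math.ceil(0.5 * n_target))):
            return RoiSet(labels, mucosa)
    raise PackingError(
        f"placed {k} of {n_target} crypts; requested density too high "
        "for non-overlapping placement"
    )


def _smooth_noise_field(shape, sigma, rng) -> np.ndarray:
    """Zero-mean, unit-sd smooth Gaussian random field."""
    g = ndi.gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
    g -= g.mean()
    sd = g.std()
    return g / sd if sd > 0 else g


def _goblet_core_mask(roi: RoiSet, fraction: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Dark mucin cores: the deep interior of a random subset of crypts."""
    core = np.zeros(roi.shape, bool)
    if fraction <= 0 or roi.n_crypts == 0:
        return core
    objects = ndi.find_objects(roi.crypt_labels)
    for label, sl in enumerate(objects, start=1):
        if sl is None or rng.uniform() >= fraction:
            continue
        sub = roi.crypt_labels[sl] == label
        dist = ndi.distance_transform_edt(sub)
        dmax = dist.max()
        if dmax > 2:
            core[sl] |= dist > 0.55 * dmax
    return core


def render_channels(roi: RoiSet, intens: IntensitySpec,
                    rng: np.random.Generator,
                    pixel_size_um: float = 1.76) -> Dict[str, np.ndarray]:
    """Render a noiseless five-channel stack for one crypt field.

    Channel construction order: piecewise levels -> goblet cores -> SHG
    fibrosis patches and optional basement-membrane ring -> lymphocyte
    spots -> multiplicative texture -> TPEF background gain (applied last
    over the whole mucosa, so a gain of g scales the mucosal TPEF mean by
    exactly g).
    """
    shape = roi.shape
    mucosa = roi.mucosa_mask
    crypts = roi.crypt_mask
    muc_wo = roi.mucosa_without_crypts
    mm_per_px = pixel_size_um / 1000.0

    out: Dict[str, np.ndarray] = {}
    for ch in CHANNELS:
        img = np.full(shape, intens.outside_level, dtype=np.float64)
        img[mucosa] = intens.baseline[ch]
        img[crypts] = intens.crypt_level[ch]
        out[ch] = img

    core = _goblet_core_mask(roi, intens.goblet_dark_fraction, rng)
    for ch in ("CARS2850", "CARS2930", "TPEF458", "TPEF525"):
        out[ch][core] *= 0.15

    if intens.shg_fibrosis_patch_fraction > 0 and mucosa.any():
        fld = _smooth_noise_field(shape, sigma=12.0, rng=rng)
        thr = np.quantile(fld[mucosa], 1.0 - intens.shg_fibrosis_patch_fraction)
        patches = mucosa & (fld >= thr)
        out["SHG"][patches] += intens.shg_fibrosis_level
    if intens.shg_ring_level > 0 and crypts.any():
        ring = ndi.binary_dilation(crypts, iterations=1) & ~crypts & mucosa
        out["SHG"][ring] += intens.shg_ring_level

    if intens.lymphocyte_spot_density_per_mm2 > 0 and muc_wo.any():
        area_mm2 = muc_wo.sum() * mm_per_px ** 2
        n_spots = rng.poisson(intens.lymphocyte_spot_density_per_mm2 * area_mm2)
        if n_spots > 0:
            flat_idx = np.flatnonzero(muc_wo)
            picks = rng.choice(flat_idx, size=min(n_spots, flat_idx.size),
                               replace=False)
            impulses = np.zeros(shape)
            impulses.flat[picks] = 1.0
            sigma_spot = 1.5
            blobs = ndi.gaussian_filter(impulses, sigma_spot)
            blobs *= 2 * math.pi * sigma_spot ** 2  # unit peak height
            out["TPEF525"] += intens.lymphocyte_spot_brightness * blobs
            out["TPEF458"] += 0.5 * intens.lymphocyte_spot_brightness * blobs

    if intens.texture_cv > 0:
        for ch in CHANNELS:
            fld = _smooth_noise_field(shape, sigma=6.0, rng=rng)
            mult = np.clip(1.0 + intens.texture_cv * fld, 0.0, None)
            out[ch][mucosa] *= mult[mucosa]

    if intens.tpef_background_gain != 1.0:
        for ch in TPEF_CHANNELS:
            out[ch][mucosa] *= intens.tpef_background_gain

    for ch in CHANNELS:
        np.clip(out[ch], 0.0, None, out=out[ch])
    return out


def vignette_field(tile_shape: Tuple[int, int], strength: float,
                   center_offset: Tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
    """Per-tile illumination profile v(r) = 1 - strength * (r / r_max)^2.

    ``center_offset`` shifts the illumination peak off the tile centre by
    the given fraction of the tile size (misaligned illumination is what
    makes mosaic seams visible); r_max is the largest centre-to-corner
    distance, so the darkest corner sits at exactly 1 - strength.
    """
    th, tw = tile_shape
    cy = (th - 1) / 2.0 + center_offset[0] * th
    cx = (tw - 1) / 2.0 + center_offset[1] * tw
    yy, xx = np.mgrid[0:th, 0:tw]
    r2 = (yy - cy) ** 2 + (xx - cx) ** 2
    corners = [(0, 0), (0, tw - 1), (th - 1, 0), (th - 1, tw - 1)]
    r2max = max((y - cy) ** 2 + (x - cx) ** 2 for y, x in corners)
    return 1.0 - strength * r2 / r2max


def apply_acquisition(channels: Dict[str, np.ndarray],
                      tile_grid: Tuple[int, int],
                      vignette_strength: float,
                      noise: NoiseSpec,
                      rng: np.random.Generator,
                      *,
                      sample_id: str,
                      pixel_size_um: float,
                      vignette_center: Tuple[float, float] = (0.05, 0.05),
                      ) -> MultimodalSample:
    """Apply per-tile vignetting, Poisson shot noise and Gaussian read noise."""
    shape = next(iter(channels.values())).shape
    rows, cols = tile_grid
    if shape[0] % rows or shape[1] % cols:
        raise ShapeMismatchError(
            f"stack shape {shape} not divisible into a {rows}x{cols} tile grid"
        )
    tile_shape = (shape[0] // rows, shape[1] // cols)
    vignette = np.tile(vignette_field(tile_shape, vignette_strength,
                                      vignette_center), (rows, cols))
    out = {}
    for ch in CHANNELS:
        img = np.asarray(channels[ch], dtype=np.float64) * vignette
        if noise.poisson_scale is not None:
            img = rng.poisson(img * noise.poisson_scale) / noise.poisson_scale
        if noise.gaussian_sd > 0:
            img = img + rng.normal(0.0, noise.gaussian_sd, size=img.shape)
        out[ch] = np.clip(img, 0.0, None)
    return MultimodalSample(sample_id=sample_id, channels=out,
                            pixel_size_um=pixel_size_um,
                            tile_grid=tile_grid, tile_shape_px=tile_shape)


def generate_sample(spec: CohortSpec, cls: str, sample_id: str,
                    rng: np.random.Generator
                    ) -> Tuple[MultimodalSample, RoiSet, IndexLabels]:
    morph = spec.healthy_morph if cls == "healthy" else spec.diseased_morph
    intens = spec.healthy_intens if cls == "healthy" else spec.diseased_intens
    roi = render_crypt_field(morph, spec.canvas_shape, spec.pixel_size_um, rng)
    channels = render_channels(roi, intens, rng, spec.pixel_size_um)
    sample = apply_acquisition(
        channels, spec.tile_grid, spec.vignette_strength, spec.noise, rng,
        sample_id=sample_id, pixel_size_um=spec.pixel_size_um,
        vignette_center=spec.vignette_center)
    labels = IndexLabels.healthy() if cls == "healthy" else IndexLabels.diseased()
    return sample, roi, labels


def geometry_effect_spec(n_samples: int = 40, seed: int = 0) -> CohortSpec:
    """Cohort whose classes differ only in crypt morphology (both classes
    share the healthy intensity model)."""
    return CohortSpec(n_samples=n_samples, seed=seed,
                      healthy_intens=healthy_intensity(),
                      diseased_intens=healthy_intensity())


def intensity_effect_spec(n_samples: int = 40, seed: int = 0) -> CohortSpec:
    """Cohort whose classes differ only in intensity-related properties
    (both classes share the healthy crypt morphology)."""
    return CohortSpec(n_samples=n_samples, seed=seed,
                      healthy_morph=healthy_morphology(),
                      diseased_morph=healthy_morphology())


def generate_cohort(spec: CohortSpec
                    ) -> List[Tuple[MultimodalSample, RoiSet, IndexLabels]]:
    """Generate a deterministic cohort of (sample, ground-truth ROI, labels).

    Healthy samples come first; labels are (0,0,0) for healthy and (2,2,1)
    for diseased presets.
    """
    n_h = spec.n_healthy()
    classes = ["healthy"] * n_h + ["diseased"] * (spec.n_samples - n_h)
    seeds = np.random.SeedSequence(spec.seed).spawn(spec.n_samples)
    out = []
    for i, (cls, child) in enumerate(zip(classes, seeds)):
        rng = np.random.default_rng(child)
        out.append(generate_sample(spec, cls, f"sample{i:03d}", rng))
    return out
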