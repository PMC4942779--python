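"""Preprocessing chain: median filter -> downsample x4 -> mosaic
illumination correction -> contrast adjustment.

The stage order is fixed; each stage can be disabled but never reordered.
Masks follow the image through downsampling (crypt labels by per-block
majority with ties broken toward the lower label, mucosa by block-any) so
image and ROI stay on the same grid.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Tuple

import numpy as np
from scipy import ndimage as ndi

from .errors import ShapeMismatchError
from .types import CHANNELS, MultimodalSample, RoiSet, relabel_sequential


@dataclass
class PreprocessConfig:
    """Parameters of the preprocessing chain.

    flatfield_sigma_px=None uses tile_width/8 at the resolution the
    correction runs at (i.e. after downsampling).
    """

    median_kernel: int = 3
    downsample_factor: int = 4
    flatfield_method: str = "poly"
    flatfield_degree: int = 4
    flatfield_sigma_px: float | None = None
    contrast_percentiles: Tuple[float, float] = (1.0, 99.0)
    enable_median: bool = True
    enable_downsample: bool = True
    enable_flatfield: bool = True
    enable_contrast: bool = True

    def __post_init__(self) -> None:
        if self.median_kernel < 1 or self.median_kernel % 2 == 0:
            raise ValueError("median_kernel must be an odd integer >= 1")
        if self.downsample_factor < 1:
            raise ValueError("downsample_factor must be >= 1")
        lo, hi = self.contrast_percentiles
        if not (0 <= lo < hi <= 100):
            raise ValueError("contrast percentiles must satisfy 0 <= low < high <= 100")


def median_filter(channel: np.ndarray, kernel: int = 3) -> np.ndarray:
    """kernel x kernel median with reflected edges."""
    if kernel % 2 == 0 or kernel < 1:
        raise ValueError("median kernel must be odd and >= 1")
    channel = np.asarray(channel, dtype=float)
    if channel.ndim != 2:
        raise ValueError("expected a 2-D channel")
    if kernel == 1:
        return channel.copy()
    return ndi.median_filter(channel, size=kernel, mode="reflect")


def downsample(channel: np.ndarray, factor: int, allow_crop: bool = False) -> np.ndarray:
    """Block-mean downsampling by ``factor`` (preserves the global mean)."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    channel = np.asarray(channel, dtype=float)
    if factor == 1:
        return channel.copy()
    H, W = channel.shape
    if H % factor or W % factor:
        if not allow_crop:
            raise ShapeMismatchError(
                f"shape {channel.shape} not divisible by factor {factor}"
            )
        channel = channel[: H - H % factor, : W - W % factor]
        H, W = channel.shape
    return channel.reshape(H // factor, factor, W // factor, factor).mean(axis=(1, 3))


def downsample_labels(labels: np.ndarray, factor: int) -> np.ndarray:
    """Per-block majority vote; ties broken toward the lower label
    (background 0 wins a tie with any crypt)."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    labels = np.asarray(labels)
    if factor == 1:
        return labels.copy()
    H, W = labels.shape
    if H % factor or W % factor:
        raise ShapeMismatchError(f"shape {labels.shape} not divisible by {factor}")
    blocks = (labels.reshape(H // factor, factor, W // factor, factor)
              .swapaxes(1, 2).reshape(-1, factor * factor))
    out = np.empty(blocks.shape[0], dtype=labels.dtype)
    for i, block in enumerate(blocks):
        out[i] = np.bincount(block).argmax()
    return out.reshape(H // factor, W // factor)


def downsample_mask(mask: np.ndarray, factor: int) -> np.ndarray:
    """Block-any downsampling for boolean masks."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    mask = np.asarray(mask, dtype=bool)
    if factor == 1:
        return mask.copy()
    H, W = mask.shape
    if H % factor or W % factor:
        raise ShapeMismatchError(f"shape {mask.shape} not divisible by {factor}")
    return (mask.reshape(H // factor, factor, W // factor, factor)
            .any(axis=(1, 3)))


def seam_step_metric(image: np.ndarray, tile_grid: Tuple[int, int]) -> float:
    """Mean absolute intensity step across tile borders (mosaic artifact
    severity). Returns 0 for a 1x1 grid."""
    image = np.asarray(image, dtype=float)
    rows, cols = tile_grid
    H, W = image.shape
    if H % rows or W % cols:
        raise ShapeMismatchError("image not divisible into the tile grid")
    th, tw = H // rows, W // cols
    steps = []
    for j in range(1, cols):
        steps.append(np.abs(image[:, j * tw] - image[:, j * tw - 1]))
    for i in range(1, rows):
        steps.append(np.abs(image[i * th] - image[i * th - 1]))
    if not steps:
        return 0.0
    return float(np.concatenate([s.ravel() for s in steps]).mean())


def _poly_surface_fit(tile_mean: np.ndarray, degree: int) -> np.ndarray:
    """Least-squares 2-D polynomial surface through the average tile."""
    th, tw = tile_mean.shape
    y = (np.arange(th) - (th - 1) / 2.0) / th
    x = (np.arange(tw) - (tw - 1) / 2.0) / tw
    yy, xx = np.meshgrid(y, x, indexing="ij")
    terms = [yy.ravel() ** i * xx.ravel() ** j
             for i in range(degree + 1) for j in range(degree + 1 - i)]
    design = np.stack(terms, axis=1)
    coef, *_ = np.linalg.lstsq(design, tile_mean.ravel(), rcond=None)
    return (design @ coef).reshape(th, tw)


def estimate_flatfield(channel: np.ndarray, tile_grid: Tuple[int, int],
                       sigma: float | None = None, method: str = "poly",
                       degree: int = 4) -> np.ndarray:
    """Retrospective flat-field from the pixel-wise mean over all tiles.

    The average tile is smoothed either by a least-squares polynomial
    surface fit (default; unbiased for smooth low-order illumination
    profiles and free of boundary artifacts) or by a Gaussian filter of
    width ``sigma``, then normalised to mean 1 and floored at 1e-3 of its
    mean.
    """
    rows, cols = tile_grid
    H, W = channel.shape
    th, tw = H // rows, W // cols
    tiles = channel.reshape(rows, th, cols, tw)
    tile_mean = tiles.mean(axis=(0, 2))
    if method == "poly":
        flat = _poly_surface_fit(tile_mean, degree)
    elif method == "gaussian":
        flat = ndi.gaussian_filter(tile_mean, tw / 8.0 if sigma is None else sigma,
                                   mode="reflect")
    else:
        raise ValueError(f"unknown flat-field method {method!r}")
    mean = flat.mean()
    if mean <= 0:
        return np.ones_like(flat)
    flat = flat / mean
    return np.maximum(flat, 1e-3)


def correct_mosaic_illumination(sample: MultimodalSample,
                                sigma: float | None = None,
                                method: str = "poly",
                                degree: int = 4) -> MultimodalSample:
    """Divide every tile by the estimated flat-field.

    The per-channel mean is preserved exactly by a final rescale. Training-
    free: the flat-field is the smoothed average tile of the image being
    corrected (see :func:`estimate_flatfield`).
    """
    rows, cols = sample.tile_grid
    out = {}
    for ch in CHANNELS:
        img = sample.channels[ch]
        flat = estimate_flatfield(img, (rows, cols), sigma, method, degree)
        corrected = img / np.tile(flat, (rows, cols))
        cmean = corrected.mean()
        if cmean > 0:
            corrected = corrected * (img.mean() / cmean)
        out[ch] = corrected
    return sample.with_channels(out)


def adjust_contrast(channel: np.ndarray,
                    percentiles: Tuple[float, float] = (1.0, 99.0)) -> np.ndarray:
    """Linear rescale mapping [p_low, p_high] -> [0, 1] with clipping.

    A constant channel maps to all-zeros with a warning.
    """
    channel = np.asarray(channel, dtype=float)
    lo, hi = np.percentile(channel, percentiles)
    if hi <= lo:
        warnings.warn("constant channel: contrast adjustment returns zeros",
                      stacklevel=2)
        return np.zeros_like(channel)
    return np.clip((channel - lo) / (hi - lo), 0.0, 1.0)


def preprocess_sample(sample: MultimodalSample, roi: RoiSet,
                      config: PreprocessConfig | None = None
                      ) -> Tuple[MultimodalSample, RoiSet]:
    """Run the full chain in its fixed order and keep masks aligned."""
    config = config or PreprocessConfig()
    channels = {ch: sample.channels[ch] for ch in CHANNELS}
    pixel_size = sample.pixel_size_um
    tile_shape = sample.tile_shape_px
    crypt_labels = roi.crypt_labels
    mucosa = roi.mucosa_mask

    if config.enable_median:
        channels = {ch: median_filter(img, config.median_kernel)
                    for ch, img in channels.items()}

    if config.enable_downsample and config.downsample_factor > 1:
        f = config.downsample_factor
        th, tw = tile_shape
        if th % f or tw % f:
            raise ShapeMismatchError(
                f"tile shape {tile_shape} not divisible by factor {f}"
            )
        channels = {ch: downsample(img, f) for ch, img in channels.items()}
        crypt_labels = relabel_sequential(downsample_labels(crypt_labels, f))
        mucosa = downsample_mask(mucosa, f)
        pixel_size *= f
        tile_shape = (th // f, tw // f)

    sample = MultimodalSample(sample_id=sample.sample_id, channels=channels,
                              pixel_size_um=pixel_size,
                              tile_grid=sample.tile_grid,
                              tile_shape_px=tile_shape)

    if config.enable_flatfield:
        sample = correct_mosaic_illumination(sample, config.flatfield_sigma_px,
                                             config.flatfield_method,
                                             config.flatfield_degree)

    if config.enable_contrast:
        sample = sample.with_channels({
            ch: adjust_contrast(img, config.contrast_percentiles)
            for ch, img in sample.channels.items()
        })

    roi_out = RoiSet.from_arrays(crypt_labels, mucosa, policy="clip")
    return sample, roi_out
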