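"""Core domain containers.

A *sample* is a co-registered five-channel non-linear microscopy mosaic
(two CARS channels, two TPEF autofluorescence channels, and SHG), acquired
as an exact grid of tiles. Regions of interest are a labelled crypt mask
plus a mucosa mask on the same pixel grid; the second ROI used throughout
("mucosa without crypts") is derived, never stored. Histological index
labels follow the pathologist's two-level scheme: architecture and
chronicity in {0, 2}, activity in {0, 1}.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Mapping, Tuple

import numpy as np
import pandas as pd

from .errors import (
    ChannelMissingError,
    InvalidLevelError,
    RoiInconsistentError,
    ShapeMismatchError,
)

#: Fixed channel order used everywhere (storage page order, catalogue order).
CHANNELS: Tuple[str, ...] = ("CARS2850", "CARS2930", "TPEF458", "TPEF525", "SHG")
TPEF_CHANNELS: Tuple[str, ...] = ("TPEF458", "TPEF525")
#: Channels participating in inter-modality contrast pairs (SHG excluded).
CONTRAST_CHANNELS: Tuple[str, ...] = ("CARS2850", "CARS2930", "TPEF458", "TPEF525")

INDEX_NAMES: Tuple[str, ...] = ("architecture", "chronicity", "activity")
INDEX_LEVELS: Dict[str, Tuple[int, ...]] = {
    "architecture": (0, 2),
    "chronicity": (0, 2),
    "activity": (0, 1),
}


@dataclass
class MultimodalSample:
    """Five co-registered intensity channels plus mosaic-tile metadata.

    Parameters
    ----------
    sample_id : str
    channels : mapping of channel name -> 2-D non-negative float array,
        all shape-identical. Integer arrays are promoted to float64.
    pixel_size_um : float
        Physical edge length of one pixel in micrometres.
    tile_grid : (rows, cols)
        Mosaic layout; the image is an exact tiling.
    tile_shape_px : (h, w)
        Shape of a single tile in pixels.
    """

    sample_id: str
    channels: Dict[str, np.ndarray]
    pixel_size_um: float
    tile_grid: Tuple[int, int] = (1, 1)
    tile_shape_px: Tuple[int, int] | None = None

    def __post_init__(self) -> None:
        missing = [c for c in CHANNELS if c not in self.channels]
        if missing:
            raise ChannelMissingError(f"missing channel(s): {missing}")
        extra = [c for c in self.channels if c not in CHANNELS]
        if extra:
            raise ChannelMissingError(f"unknown channel(s): {extra}")
        arrays = {}
        shape = None
        for name in CHANNELS:
            a = np.asarray(self.channels[name])
            if a.ndim != 2:
                raise ShapeMismatchError(f"channel {name} is not 2-D")
            if np.issubdtype(a.dtype, np.integer) or a.dtype == bool:
                a = a.astype(np.float64)
            if shape is None:
                shape = a.shape
            elif a.shape != shape:
                raise ShapeMismatchError(
                    f"channel {name} shape {a.shape} != {shape}"
                )
            if not np.all(np.isfinite(a)):
                raise ValueError(f"channel {name} contains non-finite values")
            if a.min() < 0:
                raise ValueError(f"channel {name} contains negative intensities")
            arrays[name] = a
        self.channels = arrays
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        rows, cols = self.tile_grid
        if rows < 1 or cols < 1:
            raise ValueError("tile_grid entries must be >= 1")
        if self.tile_shape_px is None:
            self.tile_shape_px = (shape[0] // rows, shape[1] // cols)
        th, tw = self.tile_shape_px
        if shape != (rows * th, cols * tw):
            raise ShapeMismatchError(
                f"image shape {shape} is not an exact {rows}x{cols} tiling "
                f"of {th}x{tw} tiles"
            )

    @property
    def shape(self) -> Tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def stack(self) -> np.ndarray:
        """Channels stacked in the fixed order, shape (5, H, W)."""
        return np.stack([self.channels[c] for c in CHANNELS])

    def with_channels(self, channels: Mapping[str, np.ndarray], **meta) -> "MultimodalSample":
        return MultimodalSample(
            sample_id=meta.get("sample_id", self.sample_id),
            channels=dict(channels),
            pixel_size_um=meta.get("pixel_size_um", self.pixel_size_um),
            tile_grid=meta.get("tile_grid", self.tile_grid),
            tile_shape_px=meta.get("tile_shape_px", None),
        )


def relabel_sequential(labels: np.ndarray) -> np.ndarray:
    """Relabel positive labels to contiguous 1..K preserving numeric order."""
    labels = np.asarray(labels)
    present = np.unique(labels)
    present = present[present > 0]
    lut = np.zeros(int(labels.max()) + 1 if labels.size and labels.max() > 0 else 1,
                   dtype=np.int32)
    for new, old in enumerate(present, start=1):
        lut[int(old)] = new
    return lut[labels] if labels.size else labels.astype(np.int32)


@dataclass
class RoiSet:
    """Labelled crypt objects plus the mucosa mask on a shared grid.

    Invariants: labels are contiguous 1..K, every crypt pixel lies inside
    the mucosa. Use :meth:`from_arrays` to normalise arbitrary rasters.
    """

    crypt_labels: np.ndarray
    mucosa_mask: np.ndarray

    def __post_init__(self) -> None:
        self.crypt_labels = np.asarray(self.crypt_labels)
        self.mucosa_mask = np.asarray(self.mucosa_mask).astype(bool)
        if self.crypt_labels.shape != self.mucosa_mask.shape:
            raise ShapeMismatchError(
                f"crypt labels {self.crypt_labels.shape} vs mucosa "
                f"{self.mucosa_mask.shape}"
            )
        if not np.issubdtype(self.crypt_labels.dtype, np.integer):
            raise TypeError("crypt_labels must be an integer array")
        if self.crypt_labels.size and self.crypt_labels.min() < 0:
            raise ValueError("crypt labels must be non-negative")
        present = np.unique(self.crypt_labels)
        present = present[present > 0]
        k = len(present)
        if k and not np.array_equal(present, np.arange(1, k + 1)):
            raise ValueError("crypt labels must be contiguous 1..K")
        if np.any((self.crypt_labels > 0) & ~self.mucosa_mask):
            raise RoiInconsistentError("crypt pixels outside the mucosa mask")

    @classmethod
    def from_arrays(cls, crypt_labels: np.ndarray, mucosa_mask: np.ndarray,
                    policy: str = "error") -> "RoiSet":
        """Build a RoiSet from arbitrary rasters.

        policy='error' raises on crypt pixels outside the mucosa;
        policy='clip' removes them before relabelling.
        """
        crypt_labels = np.asarray(crypt_labels)
        mucosa = np.asarray(mucosa_mask).astype(bool)
        if crypt_labels.shape != mucosa.shape:
            raise ShapeMismatchError("mask shapes differ")
        if crypt_labels.size and crypt_labels.min() < 0:
            raise ValueError("crypt labels must be non-negative")
        crypt_labels = crypt_labels.astype(np.int32)
        outside = (crypt_labels > 0) & ~mucosa
        if outside.any():
            if policy == "clip":
                crypt_labels = crypt_labels.copy()
                crypt_labels[outside] = 0
            elif policy == "error":
                raise RoiInconsistentError(
                    f"{int(outside.sum())} crypt pixel(s) outside the mucosa"
                )
            else:
                raise ValueError(f"unknown policy {policy!r}")
        return cls(relabel_sequential(crypt_labels), mucosa)

    @property
    def shape(self) -> Tuple[int, int]:
        return self.crypt_labels.shape

    @property
    def n_crypts(self) -> int:
        return int(self.crypt_labels.max()) if self.crypt_labels.size else 0

    @property
    def crypt_mask(self) -> np.ndarray:
        return self.crypt_labels > 0

    @property
    def mucosa_without_crypts(self) -> np.ndarray:
        """The second ROI class: epithelial mucosa excluding all crypts."""
        return self.mucosa_mask & ~self.crypt_mask


@dataclass(frozen=True)
class IndexLabels:
    """Per-sample histological index levels (two-level pathologist scheme)."""

    architecture: int
    chronicity: int
    activity: int

    def __post_init__(self) -> None:
        for name in INDEX_NAMES:
            value = getattr(self, name)
            allowed = INDEX_LEVELS[name]
            if value not in allowed:
                raise InvalidLevelError(
                    f"{name}={value!r} not in allowed levels {allowed}"
                )

    def as_dict(self) -> Dict[str, int]:
        return {name: getattr(self, name) for name in INDEX_NAMES}

    @classmethod
    def healthy(cls) -> "IndexLabels":
        return cls(0, 0, 0)

    @classmethod
    def diseased(cls) -> "IndexLabels":
        return cls(2, 2, 1)


def labels_to_frame(labels: Mapping[str, IndexLabels]) -> pd.DataFrame:
    """Convert a sample_id -> IndexLabels mapping to a DataFrame."""
    rows = {sid: lab.as_dict() for sid, lab in labels.items()}
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=list(INDEX_NAMES))
    frame.index.name = "sample_id"
    return frame


@dataclass
class FeatureTable:
    """Samples x named features with per-feature metadata tags.

    ``data`` is a DataFrame indexed by sample_id; ``meta`` maps each feature
    name to ``{"family": "geometry"|"irp", "roi": ..., "modality": ...}``.
    """

    data: pd.DataFrame
    meta: Dict[str, Dict[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValueError(f"duplicate feature names: {dupes}")
        if self.meta:
            missing = [c for c in self.data.columns if c not in self.meta]
            if missing:
                raise ValueError(f"feature_meta missing entries for: {missing}")
        self.data.index.name = "sample_id"

    @property
    def sample_ids(self):
        return list(self.data.index)

    @property
    def feature_names(self):
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def features_in_family(self, family: str) -> list:
        return [f for f in self.feature_names if self.meta.get(f, {}).get("family") == family]
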