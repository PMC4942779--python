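"""Readers and writers for on-disk artifacts.

Conventions
-----------
* A sample is a single multi-page TIFF with the fixed page order
  (CARS2850, CARS2930, TPEF458, TPEF525, SHG) plus a JSON sidecar
  ``<stem>.json`` recording channel names, pixel size, tile geometry and a
  ``grid`` tag ("raw" or "downsampled") so masks can be matched to the grid
  they annotate.
* Masks are integer (crypt labels, uint16) / 8-bit (mucosa) TIFFs on the
  same grid as the image they annotate.
* Feature tables are CSV (first column sample_id, header = feature names)
  with a JSON sidecar ``<stem>.meta.json`` holding per-feature tags.
* Index labels are CSV with columns sample_id, architecture, chronicity,
  activity, validated against the allowed level sets.

Coordinates are 0-based (row, col). Pixel values are read as-is;
normalisation happens only in :mod:`ibdquant.preprocess`.
"""
from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Dict, Mapping, Tuple

import numpy as np
import pandas as pd
import tifffile

from .errors import ChannelMissingError, InvalidLevelError, ShapeMismatchError
from .types import CHANNELS, INDEX_NAMES, FeatureTable, IndexLabels, MultimodalSample, RoiSet


def _sidecar_path(image_path: Path) -> Path:
    return image_path.with_suffix(".json")


def write_sample(sample: MultimodalSample, path, grid: str = "raw") -> None:
    """Write a sample as a multi-page TIFF plus JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, sample.stack())
    meta = {
        "sample_id": sample.sample_id,
        "channels": list(CHANNELS),
        "pixel_size_um": float(sample.pixel_size_um),
        "tile_grid": [int(v) for v in sample.tile_grid],
        "tile_shape_px": [int(v) for v in sample.tile_shape_px],
        "grid": grid,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))


def read_sample(path, sidecar=None) -> MultimodalSample:
    """Read a sample from a stacked multi-page TIFF (or per-channel files).

    ``path`` may be a single stacked TIFF path or a mapping
    channel name -> single-plane image path. The JSON sidecar (default:
    ``<stem>.json`` next to the stacked TIFF) supplies the metadata.
    """
    if isinstance(path, Mapping):
        missing = [c for c in CHANNELS if c not in path]
        if missing:
            raise ChannelMissingError(f"missing channel file(s): {missing}")
        planes = {}
        shape = None
        for name in CHANNELS:
            a = tifffile.imread(Path(path[name]))
            if a.ndim != 2:
                raise ShapeMismatchError(f"channel {name} file is not a single plane")
            if shape is None:
                shape = a.shape
            elif a.shape != shape:
                raise ShapeMismatchError(f"channel {name} shape {a.shape} != {shape}")
            planes[name] = a
        if sidecar is None:
            raise ValueError("sidecar metadata path required for per-channel input")
        meta = json.loads(Path(sidecar).read_text())
    else:
        path = Path(path)
        stack = tifffile.imread(path)
        if stack.ndim == 2:
            stack = stack[None]
        if stack.shape[0] != len(CHANNELS):
            raise ChannelMissingError(
                f"expected {len(CHANNELS)} planes, found {stack.shape[0]}"
            )
        sidecar = Path(sidecar) if sidecar is not None else _sidecar_path(path)
        if not sidecar.exists():
            raise FileNotFoundError(f"metadata sidecar not found: {sidecar}")
        meta = json.loads(sidecar.read_text())
        order = meta.get("channels", list(CHANNELS))
        if sorted(order) != sorted(CHANNELS):
            raise ChannelMissingError(f"sidecar channel list invalid: {order}")
        planes = {name: stack[i] for i, name in enumerate(order)}
    return MultimodalSample(
        sample_id=meta["sample_id"],
        channels=planes,
        pixel_size_um=float(meta["pixel_size_um"]),
        tile_grid=tuple(meta["tile_grid"]),
        tile_shape_px=tuple(meta["tile_shape_px"]) if meta.get("tile_shape_px") else None,
    )


def write_roi_set(roi: RoiSet, crypt_path, mucosa_path) -> None:
    crypt_path, mucosa_path = Path(crypt_path), Path(mucosa_path)
    crypt_path.parent.mkdir(parents=True, exist_ok=True)
    if roi.n_crypts > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 crypt labels")
    tifffile.imwrite(crypt_path, roi.crypt_labels.astype(np.uint16))
    tifffile.imwrite(mucosa_path, roi.mucosa_mask.astype(np.uint8))


def read_roi_set(crypt_path, mucosa_path, policy: str = "error") -> RoiSet:
    """Read crypt-label and mucosa rasters; labels are relabelled to 1..K.

    ``policy`` controls crypt pixels outside the mucosa: 'error' raises
    RoiInconsistentError, 'clip' drops them.
    """
    crypts = tifffile.imread(Path(crypt_path))
    mucosa = tifffile.imread(Path(mucosa_path))
    if crypts.shape != mucosa.shape:
        raise ShapeMismatchError(
            f"crypt mask {crypts.shape} vs mucosa mask {mucosa.shape}"
        )
    if not np.issubdtype(np.asarray(crypts).dtype, np.integer):
        crypts = np.asarray(crypts)
        if not np.allclose(crypts, np.round(crypts)):
            raise TypeError("crypt mask must be integer-valued")
        crypts = np.round(crypts).astype(np.int32)
    return RoiSet.from_arrays(crypts, mucosa.astype(bool), policy=policy)


def _meta_path(csv_path: Path) -> Path:
    return csv_path.with_suffix(".meta.json")


def write_feature_table(table: FeatureTable, path) -> None:
    """CSV (sample_id + feature columns) plus JSON metadata sidecar.

    Values survive a round-trip to at least 12 significant digits.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.data.to_csv(path, index_label="sample_id", float_format="%.17g")
    _meta_path(path).write_text(json.dumps(table.meta, indent=2))


def read_feature_table(path) -> FeatureTable:
    path = Path(path)
    with open(path, newline="") as fh:
        header = next(csv.reader(fh))
    names = header[1:]
    if len(set(names)) != len(names):
        raise ValueError("duplicate feature names in header")
    data = pd.read_csv(path, index_col="sample_id")
    if data.empty:
        data = data.astype(float)
    non_numeric = [c for c in data.columns if not np.issubdtype(data[c].dtype, np.number)]
    if non_numeric:
        raise ValueError(f"non-numeric feature column(s): {non_numeric}")
    meta_path = _meta_path(path)
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return FeatureTable(data=data, meta=meta)


def write_labels(labels: Mapping[str, IndexLabels], path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_id", *INDEX_NAMES])
        for sid in labels:
            lab = labels[sid]
            writer.writerow([sid, lab.architecture, lab.chronicity, lab.activity])


def read_labels(path) -> Dict[str, IndexLabels]:
    """Read per-sample index labels, validated against allowed level sets."""
    frame = pd.read_csv(Path(path))
    required = {"sample_id", *INDEX_NAMES}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"labels CSV missing column(s): {sorted(missing)}")
    out: Dict[str, IndexLabels] = {}
    for _, row in frame.iterrows():
        try:
            levels = {name: int(row[name]) for name in INDEX_NAMES}
        except (TypeError, ValueError) as exc:
            raise InvalidLevelError(f"non-integer level for {row['sample_id']}") from exc
        out[str(row["sample_id"])] = IndexLabels(**levels)
    return out
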