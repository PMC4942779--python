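"""The 87-feature catalogue: crypt geometry plus intensity-related
properties (IRP) over two ROI classes.

Catalogue composition
---------------------
* 15 geometry features: mean and population std over crypts of area,
  perimeter, equivalent diameter, radius, eccentricity and solidity (12),
  crypt density per mm^2 of mucosa, and mean/std of the nearest-neighbour
  centroid distance (inter-cryptal spacing variability).
* 60 texture features: six first-order histogram statistics (mean, std,
  smoothness, 3rd moment, uniformity, entropy) per modality (5) per ROI
  (crypts; mucosa without crypts).
* 12 contrast features: Michelson-type contrast of ROI means between the
  six pairs of the four CARS/TPEF channels, per ROI. SHG carries texture
  features but enters no contrast pair.

First-order statistics follow the Gonzalez-Woods histogram convention with
L=256 equal bins on [0, 1] and z at bin centres; intensities must already
be normalised to [0, 1] (the contrast-adjustment stage guarantees this).
Degenerate inputs (no crypts, empty ROI) yield zero-valued features plus a
QC flag — never NaN.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from skimage import measure

from .errors import EmptyRoiError
from .types import (
    CHANNELS,
    CONTRAST_CHANNELS,
    FeatureTable,
    MultimodalSample,
    RoiSet,
)

N_BINS = 256
STAT_NAMES: Tuple[str, ...] = ("mean", "std", "smoothness", "third_moment",
                               "uniformity", "entropy")
ROI_NAMES: Tuple[str, ...] = ("crypts", "mucosa_wo_crypts")
GEOMETRY_PROPS: Tuple[str, ...] = ("area", "perimeter", "equivalent_diameter",
                                   "radius", "eccentricity", "solidity")


@dataclass(frozen=True)
class CryptMeasure:
    """Geometry of a single labelled crypt, in physical units."""

    label: int
    area_um2: float
    perimeter_um: float
    equivalent_diameter_um: float
    radius_um: float
    eccentricity: float
    solidity: float
    centroid_um: Tuple[float, float]


@dataclass(frozen=True)
class FirstOrderStats:
    """Six first-order histogram statistics of a masked region."""

    mean: float
    std: float
    smoothness: float
    third_moment: float
    uniformity: float
    entropy_bits: float

    def as_dict(self) -> Dict[str, float]:
        return {"mean": self.mean, "std": self.std, "smoothness": self.smoothness,
                "third_moment": self.third_moment, "uniformity": self.uniformity,
                "entropy": self.entropy_bits}


@dataclass(frozen=True)
class FeatureSpec:
    """One catalogue entry: how to compute it and its metadata tags."""

    name: str
    family: str           # "geometry" | "irp"
    roi: str              # "crypts" | "mucosa_wo_crypts" | "n/a"
    modality: str         # channel name, "A-B" pair, or "n/a"
    kind: str             # "geometry" | "stat" | "contrast"
    stat: str | None = None
    pair: Tuple[str, str] | None = None

    def meta(self) -> Dict[str, str]:
        return {"family": self.family, "roi": self.roi, "modality": self.modality}


def default_catalogue() -> List[FeatureSpec]:
    """The default 87-entry catalogue (15 geometry + 60 texture + 12 contrast)."""
    cat: List[FeatureSpec] = []
    for prop in GEOMETRY_PROPS:
        for agg in ("mean", "std"):
            cat.append(FeatureSpec(f"{prop}_{agg}", "geometry", "n/a", "n/a",
                                   "geometry"))
    cat.append(FeatureSpec("crypt_density", "geometry", "n/a", "n/a", "geometry"))
    for agg in ("mean", "std"):
        cat.append(FeatureSpec(f"nn_distance_{agg}", "geometry", "n/a", "n/a",
                               "geometry"))
    for ch in CHANNELS:
        for roi in ROI_NAMES:
            for stat in STAT_NAMES:
                cat.append(FeatureSpec(f"{ch}_{stat}_{roi}", "irp", roi, ch,
                                       "stat", stat=stat))
    for a, b in combinations(CONTRAST_CHANNELS, 2):
        for roi in ROI_NAMES:
            cat.append(FeatureSpec(f"{a}_vs_{b}_contrast_{roi}", "irp", roi,
                                   f"{a}-{b}", "contrast", pair=(a, b)))
    return cat


def catalogue_meta(catalogue: Sequence[FeatureSpec] | None = None
                   ) -> Dict[str, Dict[str, str]]:
    catalogue = catalogue if catalogue is not None else default_catalogue()
    return {spec.name: spec.meta() for spec in catalogue}


def measure_crypts(roi: RoiSet, pixel_size_um: float) -> List[CryptMeasure]:
    """Per-crypt geometry via region properties, converted to micrometres.

    Perimeter uses weighted boundary-step counting (diagonal steps weight
    sqrt(2)); equivalent diameter is sqrt(4*area/pi), radius is half of it.
    """
    if roi.n_crypts == 0:
        return []
    out = []
    for props in measure.regionprops(roi.crypt_labels):
        area_um2 = props.area * pixel_size_um ** 2
        eq_d = math.sqrt(4.0 * area_um2 / math.pi)
        out.append(CryptMeasure(
            label=int(props.label),
            area_um2=float(area_um2),
            perimeter_um=float(props.perimeter * pixel_size_um),
            equivalent_diameter_um=float(eq_d),
            radius_um=float(eq_d / 2.0),
            eccentricity=float(props.eccentricity),
            solidity=float(props.solidity),
            centroid_um=(float(props.centroid[0] * pixel_size_um),
                         float(props.centroid[1] * pixel_size_um)),
        ))
    return out


def crypt_density(roi: RoiSet, pixel_size_um: float) -> float:
    """Crypt count per mm^2 of mucosa."""
    mucosa_px = int(roi.mucosa_mask.sum())
    if mucosa_px == 0:
        raise EmptyRoiError("mucosa mask is empty")
    area_mm2 = mucosa_px * (pixel_size_um / 1000.0) ** 2
    return roi.n_crypts / area_mm2


def nearest_neighbor_distances(measures: Sequence[CryptMeasure]) -> np.ndarray:
    """Distance from each crypt centroid to its nearest neighbour (um)."""
    if len(measures) < 2:
        return np.zeros(0)
    pts = np.array([m.centroid_um for m in measures])
    dist, _ = cKDTree(pts).query(pts, k=2)
    return dist[:, 1]


def aggregate_geometry(measures: Sequence[CryptMeasure], density: float
                       ) -> Tuple[Dict[str, float], List[str]]:
    """Aggregate per-crypt measures into the 15 geometry features.

    Returns (features, qc_flags). An empty crypt list yields all-zero
    geometry features with a 'no-crypts' QC flag; a single crypt yields
    zero std and nearest-neighbour entries with a 'single-crypt' flag.
    """
    feats: Dict[str, float] = {}
    qc: List[str] = []
    attr = {"area": "area_um2", "perimeter": "perimeter_um",
            "equivalent_diameter": "equivalent_diameter_um",
            "radius": "radius_um", "eccentricity": "eccentricity",
            "solidity": "solidity"}
    if not measures:
        qc.append("no-crypts")
        for prop in GEOMETRY_PROPS:
            feats[f"{prop}_mean"] = 0.0
            feats[f"{prop}_std"] = 0.0
        feats["crypt_density"] = float(density)
        feats["nn_distance_mean"] = 0.0
        feats["nn_distance_std"] = 0.0
        return feats, qc
    for prop in GEOMETRY_PROPS:
        vals = np.array([getattr(m, attr[prop]) for m in measures])
        feats[f"{prop}_mean"] = float(vals.mean())
        feats[f"{prop}_std"] = float(vals.std())
    feats["crypt_density"] = float(density)
    nn = nearest_neighbor_distances(measures)
    if nn.size == 0:
        qc.append("single-crypt")
        feats["nn_distance_mean"] = 0.0
        feats["nn_distance_std"] = 0.0
    else:
        feats["nn_distance_mean"] = float(nn.mean())
        feats["nn_distance_std"] = float(nn.std())
    return feats, qc


def first_order_stats(channel: np.ndarray, mask: np.ndarray,
                      n_bins: int = N_BINS) -> FirstOrderStats:
    """First-order histogram statistics of ``channel`` within ``mask``.

    The histogram uses ``n_bins`` equal bins on [0, 1] with z at bin
    centres; with p the bin frequencies: m = sum(z*p),
    sigma = sqrt(sum((z-m)^2 p)), smoothness = 1 - 1/(1+sigma^2),
    third moment = sum((z-m)^3 p), uniformity = sum(p^2),
    entropy = -sum(p log2 p) in bits.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyRoiError("empty ROI for first-order statistics")
    vals = np.asarray(channel, dtype=float)[mask]
    if vals.min() < -1e-9 or vals.max() > 1 + 1e-9:
        raise ValueError("intensities must be normalised to [0, 1]")
    vals = np.clip(vals, 0.0, 1.0)
    counts, _ = np.histogram(vals, bins=n_bins, range=(0.0, 1.0))
    p = counts / counts.sum()
    z = (np.arange(n_bins) + 0.5) / n_bins
    m = float(np.sum(z * p))
    var = float(np.sum((z - m) ** 2 * p))
    sd = math.sqrt(max(var, 0.0))
    third = float(np.sum((z - m) ** 3 * p))
    uniformity = float(np.sum(p ** 2))
    nz = p[p > 0]
    entropy = float(-np.sum(nz * np.log2(nz)))
    return FirstOrderStats(mean=m, std=sd, smoothness=1.0 - 1.0 / (1.0 + var),
                           third_moment=third, uniformity=uniformity,
                           entropy_bits=entropy)


def intermodality_contrast(channel_a: np.ndarray, channel_b: np.ndarray,
                           mask: np.ndarray) -> float:
    """Michelson-type contrast (m_a - m_b)/(m_a + m_b) of ROI means.

    Returns 0 when both means are zero. Antisymmetric under channel swap.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyRoiError("empty ROI for inter-modality contrast")
    m_a = float(np.asarray(channel_a, dtype=float)[mask].mean())
    m_b = float(np.asarray(channel_b, dtype=float)[mask].mean())
    denom = m_a + m_b
    if denom == 0:
        return 0.0
    return (m_a - m_b) / denom


def extract_features(sample: MultimodalSample, roi: RoiSet,
                     catalogue: Sequence[FeatureSpec] | None = None
                     ) -> Tuple[Dict[str, float], List[str]]:
    """One feature row for a preprocessed sample.

    Returns (ordered name -> value dict, QC flags). Deterministic given
    inputs; degenerate ROIs produce zeros plus a QC flag, never NaN.
    """
    catalogue = list(catalogue) if catalogue is not None else default_catalogue()
    if sample.shape != roi.shape:
        raise ValueError("sample and ROI are on different grids")
    qc: List[str] = []
    measures = measure_crypts(roi, sample.pixel_size_um)
    density = crypt_density(roi, sample.pixel_size_um)
    geo, geo_qc = aggregate_geometry(measures, density)
    qc.extend(geo_qc)

    masks = {"crypts": roi.crypt_mask, "mucosa_wo_crypts": roi.mucosa_without_crypts}
    stats_cache: Dict[Tuple[str, str], FirstOrderStats | None] = {}

    def stats_for(ch: str, roi_name: str):
        key = (ch, roi_name)
        if key not in stats_cache:
            mask = masks[roi_name]
            if not mask.any():
                flag = f"empty-roi:{roi_name}"
                if flag not in qc:
                    qc.append(flag)
                stats_cache[key] = None
            else:
                stats_cache[key] = first_order_stats(sample.channels[ch], mask)
        return stats_cache[key]

    out: Dict[str, float] = {}
    for spec in catalogue:
        if spec.kind == "geometry":
            if spec.name not in geo:
                raise KeyError(f"unknown geometry feature {spec.name!r}")
            out[spec.name] = geo[spec.name]
        elif spec.kind == "stat":
            st = stats_for(spec.modality, spec.roi)
            out[spec.name] = 0.0 if st is None else st.as_dict()[spec.stat]
        elif spec.kind == "contrast":
            a, b = spec.pair
            mask = masks[spec.roi]
            if not mask.any():
                flag = f"empty-roi:{spec.roi}"
                if flag not in qc:
                    qc.append(flag)
                out[spec.name] = 0.0
            else:
                out[spec.name] = intermodality_contrast(
                    sample.channels[a], sample.channels[b], mask)
        else:
            raise ValueError(f"unknown feature kind {spec.kind!r}")
    return out, qc


def extract_feature_table(items: Iterable[Tuple[MultimodalSample, RoiSet]],
                          catalogue: Sequence[FeatureSpec] | None = None
                          ) -> Tuple[FeatureTable, Dict[str, List[str]]]:
    """Extract a FeatureTable for an iterable of (sample, roi) pairs."""
    catalogue = list(catalogue) if catalogue is not None else default_catalogue()
    rows = {}
    qc_all: Dict[str, List[str]] = {}
    for sample, roi in items:
        feats, qc = extract_features(sample, roi, catalogue)
        rows[sample.sample_id] = feats
        if qc:
            qc_all[sample.sample_id] = qc
    data = pd.DataFrame.from_dict(rows, orient="index",
                                  columns=[s.name for s in catalogue])
    if data.isna().any().any():
        bad = data.columns[data.isna().any()].tolist()
        raise ValueError(f"NaN feature values in: {bad}")
    return FeatureTable(data=data, meta=catalogue_meta(catalogue)), qc_all
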