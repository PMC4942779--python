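"""Fisher-discriminant-ratio (FDR) feature ranking for two-class labels.

FDR(x) = (mu1 - mu2)^2 / (s1^2 + s2^2) with sample variances (ddof=1).
It is affine-invariant, symmetric under class swap and non-negative; a
zero pooled variance with distinct means is reported as +inf and flagged
(zero-variance features at small n are artifacts, not evidence), and such
entries are excluded from family means.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Tuple

import numpy as np
import pandas as pd

from .errors import DegenerateClassesError
from .types import FeatureTable, IndexLabels, labels_to_frame


def fisher_discriminant_ratio(values, labels) -> float:
    """FDR of one feature for a two-class labelling.

    Requires exactly two label values with >= 2 samples each. Returns +inf
    when the pooled variance is zero but the means differ, 0 when both are
    zero.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise ValueError("values and labels must align")
    classes = np.unique(labels)
    if classes.size != 2:
        raise DegenerateClassesError(f"need exactly 2 classes, got {classes.size}")
    v1 = values[labels == classes[0]]
    v2 = values[labels == classes[1]]
    if len(v1) < 2 or len(v2) < 2:
        raise DegenerateClassesError("each class needs >= 2 samples")
    diff = v1.mean() - v2.mean()
    pooled = v1.var(ddof=1) + v2.var(ddof=1)
    if pooled == 0:
        return float("inf") if diff != 0 else 0.0
    return float(diff ** 2 / pooled)


@dataclass
class FdrRanking:
    """Features ordered by non-increasing FDR for one histological index."""

    entries: List[Tuple[str, float]]
    class_definition: Tuple[str, int, int]

    def to_frame(self, feature_meta: Mapping[str, Mapping[str, str]] | None = None
                 ) -> pd.DataFrame:
        rows = []
        for rank, (name, fdr) in enumerate(self.entries, start=1):
            row = {"rank": rank, "feature": name, "fdr": fdr}
            if feature_meta and name in feature_meta:
                row.update(feature_meta[name])
            rows.append(row)
        return pd.DataFrame(rows)

    def top(self, n: int) -> List[str]:
        return [name for name, _ in self.entries[:n]]


def _labels_series(labels, index_name: str, sample_ids) -> pd.Series:
    if isinstance(labels, Mapping):
        frame = labels_to_frame({k: v for k, v in labels.items()})
    else:
        frame = labels
    missing = [s for s in sample_ids if s not in frame.index]
    if missing:
        raise ValueError(f"samples without labels: {missing}")
    return frame.loc[list(sample_ids), index_name]


def rank_features(table: FeatureTable, labels, index_name: str) -> FdrRanking:
    """Rank every catalogue feature by FDR for the chosen index.

    ``labels`` is a sample_id -> IndexLabels mapping or a DataFrame indexed
    by sample_id. Ties break alphabetically; +inf entries sort first.
    """
    y = _labels_series(labels, index_name, table.sample_ids).to_numpy()
    classes = np.unique(y)
    if classes.size != 2:
        raise DegenerateClassesError(
            f"index {index_name!r} has {classes.size} level(s) in this cohort"
        )
    scored = []
    for name in table.feature_names:
        fdr = fisher_discriminant_ratio(table.data[name].to_numpy(), y)
        scored.append((name, fdr))
    scored.sort(key=lambda kv: (-kv[1], kv[0]))
    return FdrRanking(entries=scored,
                      class_definition=(index_name, int(classes[0]), int(classes[1])))


def family_significance_summary(ranking: FdrRanking,
                                feature_meta: Mapping[str, Mapping[str, str]]
                                ) -> pd.DataFrame:
    """Mean finite FDR grouped by each metadata dimension (family, roi,
    modality) — the coarse significance-trend view across feature groups."""
    rows = []
    finite = [(n, f) for n, f in ranking.entries if np.isfinite(f)]
    frame = pd.DataFrame(finite, columns=["feature", "fdr"])
    for dim in ("family", "roi", "modality"):
        frame[dim] = [feature_meta.get(n, {}).get(dim, "n/a")
                      for n in frame["feature"]]
    out = []
    for dim in ("family", "roi", "modality"):
        grouped = frame.groupby(dim)["fdr"].agg(["mean", "size"]).reset_index()
        for _, g in grouped.iterrows():
            out.append({"dimension": dim, "group": g[dim],
                        "mean_fdr": float(g["mean"]), "n_features": int(g["size"])})
    return pd.DataFrame(out, columns=["dimension", "group", "mean_fdr", "n_features"])
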