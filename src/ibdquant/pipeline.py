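"""Pipeline orchestration: simulate -> preprocess -> extract -> rank ->
train -> predict -> report, as independently re-runnable stages over
on-disk artifacts.

Every stage reads only the previous stage's artifacts, so any stage can be
re-run in isolation; a run is replayable bit-identically from its saved
config (the resolved spec, including the seed, is written as YAML).
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Tuple

import numpy as np
import pandas as pd
import yaml

from . import io as ioq
from .classify import (
    SelectionResult,
    TwoClassLDA,
    load_model,
    predict_indices,
    select_features,
)
from .features import default_catalogue, extract_feature_table
from .preprocess import PreprocessConfig, preprocess_sample
from .ranking import family_significance_summary, rank_features
from .synthetic import (
    CohortSpec,
    IntensitySpec,
    MorphologySpec,
    NoiseSpec,
    generate_cohort,
)
from .types import INDEX_NAMES, FeatureTable, IndexLabels

logger = logging.getLogger("ibdquant")


@dataclass
class ClassifyConfig:
    max_features: int | None = None     # per-index default (10/20/20)
    families: str = "geometry_plus_irp"
    reg_lambda: float = 1e-3


@dataclass
class RunConfig:
    """Fully serialisable description of one pipeline run."""

    outdir: str = "run"
    cohort: CohortSpec = field(default_factory=CohortSpec)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    classify: ClassifyConfig = field(default_factory=ClassifyConfig)
    indices: Tuple[str, ...] = INDEX_NAMES

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "RunConfig":
        cohort_raw = dict(raw.get("cohort", {}))
        for key, sub in (("healthy_morph", MorphologySpec),
                         ("diseased_morph", MorphologySpec),
                         ("healthy_intens", IntensitySpec),
                         ("diseased_intens", IntensitySpec),
                         ("noise", NoiseSpec)):
            if key in cohort_raw and isinstance(cohort_raw[key], Mapping):
                cohort_raw[key] = sub(**cohort_raw[key])
        for key in ("tile_grid", "tile_shape_px", "vignette_center"):
            if key in cohort_raw:
                cohort_raw[key] = tuple(cohort_raw[key])
        cfg = cls(
            outdir=raw.get("outdir", "run"),
            cohort=CohortSpec(**cohort_raw),
            preprocess=PreprocessConfig(**{
                **raw.get("preprocess", {}),
                **({"contrast_percentiles":
                    tuple(raw["preprocess"]["contrast_percentiles"])}
                   if "contrast_percentiles" in raw.get("preprocess", {}) else {}),
            }),
            classify=ClassifyConfig(**raw.get("classify", {})),
        )
        if "indices" in raw:
            cfg.indices = tuple(raw["indices"])
        return cfg


# ---------------------------------------------------------------------------
# stages

def simulate_stage(spec: CohortSpec, outdir) -> Path:
    """Write raw samples, ground-truth masks, labels.csv and the resolved
    spec."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    labels: Dict[str, IndexLabels] = {}
    for sample, roi, lab in generate_cohort(spec):
        sid = sample.sample_id
        sample32 = sample.with_channels(
            {c: a.astype(np.float32) for c, a in sample.channels.items()})
        ioq.write_sample(sample32, outdir / f"{sid}.tif", grid="raw")
        ioq.write_roi_set(roi, outdir / f"{sid}_crypts.tif",
                          outdir / f"{sid}_mucosa.tif")
        labels[sid] = lab
    ioq.write_labels(labels, outdir / "labels.csv")
    Path(outdir / "cohort_spec.yaml").write_text(
        yaml.safe_dump(dataclasses.asdict(spec), sort_keys=False))
    logger.info("simulate: %d samples -> %s", spec.n_samples, outdir)
    return outdir


def _iter_samples(indir: Path):
    for tif in sorted(indir.glob("*.tif")):
        if tif.stem.endswith(("_crypts", "_mucosa")):
            continue
        sample = ioq.read_sample(tif)
        roi = ioq.read_roi_set(indir / f"{tif.stem}_crypts.tif",
                               indir / f"{tif.stem}_mucosa.tif")
        yield sample, roi


def preprocess_stage(indir, outdir, config: PreprocessConfig | None = None) -> Path:
    indir, outdir = Path(indir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = config or PreprocessConfig()
    n = 0
    for sample, roi in _iter_samples(indir):
        pre, roi_pre = preprocess_sample(sample, roi, config)
        sid = pre.sample_id
        ioq.write_sample(pre, outdir / f"{sid}.tif", grid="downsampled")
        ioq.write_roi_set(roi_pre, outdir / f"{sid}_crypts.tif",
                          outdir / f"{sid}_mucosa.tif")
        n += 1
    if (indir / "labels.csv").exists():
        (outdir / "labels.csv").write_bytes((indir / "labels.csv").read_bytes())
    logger.info("preprocess: %d samples -> %s", n, outdir)
    return outdir


def extract_stage(indir, out_csv) -> Path:
    indir, out_csv = Path(indir), Path(out_csv)
    table, qc = extract_feature_table(_iter_samples(indir))
    ioq.write_feature_table(table, out_csv)
    out_csv.with_suffix(".qc.json").write_text(json.dumps(qc, indent=2))
    logger.info("extract: %d samples x %d features -> %s",
                len(table.sample_ids), len(table.feature_names), out_csv)
    return out_csv


def rank_stage(features_csv, labels_csv, index_name: str, out_csv) -> Path:
    table = ioq.read_feature_table(Path(features_csv))
    labels = ioq.read_labels(Path(labels_csv))
    ranking = rank_features(table, labels, index_name)
    frame = ranking.to_frame(table.meta)
    out_csv = Path(out_csv)
    out_csv.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(out_csv, index=False)
    trends = family_significance_summary(ranking, table.meta)
    trends.to_csv(out_csv.with_name(out_csv.stem + "_trends.csv"), index=False)
    return out_csv


def train_stage(features_csv, labels_csv, index_name: str,
                cfg: ClassifyConfig, out_json) -> SelectionResult:
    table = ioq.read_feature_table(Path(features_csv))
    labels = ioq.read_labels(Path(labels_csv))
    result = select_features(table, labels, index_name,
                             max_features=cfg.max_features,
                             families=cfg.families,
                             reg_lambda=cfg.reg_lambda)
    out_json = Path(out_json)
    out_json.parent.mkdir(parents=True, exist_ok=True)
    out_json.write_text(json.dumps(result.to_dict(), indent=2))
    logger.info("train[%s]: %d features, LOO accuracy %.3f",
                index_name, len(result.selected_features), result.loo_accuracy)
    return result


def predict_stage(model_paths: Mapping[str, Path], features_csv, out_csv) -> Path:
    table = ioq.read_feature_table(Path(features_csv))
    models = {}
    for index_name, path in model_paths.items():
        payload = json.loads(Path(path).read_text())
        model_payload = payload.get("model", payload)
        if model_payload is None:
            raise ValueError(f"model for {index_name} is empty")
        models[index_name] = TwoClassLDA.from_dict(model_payload)
    rows = []
    for sid in table.sample_ids:
        pred = predict_indices(table.data.loc[sid], models)
        rows.append({"sample_id": sid, **pred.as_dict()})
    out_csv = Path(out_csv)
    out_csv.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(out_csv, index=False)
    return out_csv


# ---------------------------------------------------------------------------
# report

def _confusion(y_true, y_pred) -> Dict[str, int]:
    levels = sorted(set(y_true) | set(y_pred))
    counts = {}
    for a in levels:
        for b in levels:
            counts[f"true{a}_pred{b}"] = int(
                sum(1 for t, p in zip(y_true, y_pred) if t == a and p == b))
    return counts


def make_report(outdir) -> Path:
    """Render report.md from saved artifacts (deterministic; every number
    traceable to a CSV/JSON artifact in the run directory)."""
    outdir = Path(outdir)
    lines = ["# ibdquant run report", ""]
    labels_path = outdir / "preprocessed" / "labels.csv"
    predictions = outdir / "predictions.csv"
    for index_name in INDEX_NAMES:
        lines.append(f"## {index_name}")
        rank_csv = outdir / f"ranking_{index_name}.csv"
        if rank_csv.exists():
            frame = pd.read_csv(rank_csv)
            if frame.empty:
                lines.append("no features ranked")
            else:
                lines.append("top-10 features by FDR:")
                lines.append("")
                lines.append("| rank | feature | fdr | family |")
                lines.append("|---|---|---|---|")
                for _, row in frame.head(10).iterrows():
                    lines.append(f"| {row['rank']} | {row['feature']} | "
                                 f"{row['fdr']:.4g} | {row.get('family', '')} |")
        else:
            lines.append("no features ranked")
        sel_json = outdir / f"model_{index_name}.json"
        if sel_json.exists():
            sel = json.loads(sel_json.read_text())
            lines.append("")
            lines.append(f"selected features ({len(sel['selected_features'])}): "
                         + ", ".join(sel["selected_features"]))
            lines.append(f"LOO accuracy: {sel['loo_accuracy']:.3f}")
            ld = [v for v in sel["ld_values"] if v is not None]
            if ld and labels_path.exists():
                lab = ioq.read_labels(labels_path)
                y = [getattr(lab[s], index_name) for s in sorted(lab)]
                ld_frame = pd.DataFrame({"sample_id": sorted(lab),
                                         "level": y, "ld_centered": sel["ld_values"]})
                ld_frame.to_csv(outdir / f"report_ld_{index_name}.csv", index=False)
                lines.append(f"held-out LD values written to report_ld_{index_name}.csv")
            if labels_path.exists() and predictions.exists():
                lab = ioq.read_labels(labels_path)
                preds = pd.read_csv(predictions).set_index("sample_id")
                y_true = [getattr(lab[s], index_name) for s in preds.index]
                y_pred = preds[index_name].tolist()
                conf = _confusion(y_true, y_pred)
                lines.append("confusion (training-set predictions): "
                             + json.dumps(conf, sort_keys=True))
        lines.append("")
    report = outdir / "report.md"
    report.write_text("\n".join(lines))
    return report


@dataclass
class RunReport:
    outdir: Path
    selections: Dict[str, SelectionResult]
    report_path: Path


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute every stage in order and write a summary report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "run_config.yaml")
    raw = simulate_stage(config.cohort, outdir / "raw")
    pre = preprocess_stage(raw, outdir / "preprocessed", config.preprocess)
    features_csv = extract_stage(pre, outdir / "features.csv")
    labels_csv = pre / "labels.csv"
    selections = {}
    model_paths = {}
    for index_name in config.indices:
        rank_stage(features_csv, labels_csv, index_name,
                   outdir / f"ranking_{index_name}.csv")
        result = train_stage(features_csv, labels_csv, index_name,
                             config.classify, outdir / f"model_{index_name}.json")
        selections[index_name] = result
        model_paths[index_name] = outdir / f"model_{index_name}.json"
    predict_stage(model_paths, features_csv, outdir / "predictions.csv")
    report = make_report(outdir)
    return RunReport(outdir=outdir, selections=selections, report_path=report)
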