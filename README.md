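# ibdquant

Quantification and prediction of histological IBD indices — **architecture**
(crypt distortion), **chronicity** (lymphocyte/plasma-cell infiltration) and
**activity** (neutrophil presence and epithelial damage) — from five-channel
non-linear multimodal microscopy mosaics of colonic mucosa: two CARS channels
(2850 cm⁻¹, CH₂/lipids; 2930 cm⁻¹, CH₂+CH₃/proteins), two TPEF
autofluorescence channels (458 nm, NAD(P)H-weighted; 525 nm,
flavin-weighted) and SHG (fibrillar collagen).

The package is aimed at biomedical image analysts who want to reproduce,
probe or extend this kind of label-free histology pipeline. Because
clinical image sets of this type are rarely shareable, a first-class
synthetic-data module generates tiled multimodal mosaics with ground-truth
crypt masks and index labels emulating the healthy-vs-inflamed contrasts
(crypt distortion and atrophy, elevated TPEF background, bright
lymphocyte-like spots, SHG fibrosis patches, per-tile vignetting, shot and
read noise), so every stage is testable end to end without any download.

## The method

1. **Preprocessing** — 3×3 median filter, ×4 block-mean downsampling,
   retrospective mosaic flat-field correction (each tile divided by a
   smoothed average-tile illumination profile), and percentile-based
   contrast adjustment to [0, 1].
2. **Feature extraction** — an 87-feature catalogue:
   15 crypt-geometry features (mean/std of area, perimeter, equivalent
   diameter d = √(4A/π), radius, eccentricity, solidity; crypt density per
   mm²; mean/std nearest-neighbour crypt spacing), 60 first-order texture
   statistics (mean, σ, smoothness 1−1/(1+σ²), third moment, uniformity
   Σp², entropy −Σp log₂p over a 256-bin histogram) for each of the five
   modalities over two ROIs (all crypts; mucosa without crypts), and 12
   Michelson-type inter-modality contrasts (m_a−m_b)/(m_a+m_b) between the
   CARS/TPEF channel pairs over both ROIs.
3. **Feature ranking** — Fisher's discriminant ratio
   FDR = (μ₁−μ₂)²/(s₁²+s₂²) per feature and two-class index labelling,
   with family/ROI/modality trend summaries.
4. **Classification** — per index, a two-class Fisher LDA
   (w = S_w⁻¹Δμ with a relative ridge on the pooled covariance, midpoint
   threshold on the LD value w·x) with leave-one-out cross-validation and
   greedy forward feature selection maximising LOO accuracy, with
   geometry-only and geometry+IRP candidate pools.

`TwoClassLDA` and `GreedyLDASelector` follow the scikit-learn estimator
protocol (fit/predict/get_params) and compose with sklearn tooling.

## Worked example

```python
from ibdquant import CohortSpec, generate_cohort, select_features
from ibdquant.preprocess import preprocess_sample
from ibdquant.features import extract_feature_table
from ibdquant.ranking import rank_features

spec = CohortSpec(n_samples=12, seed=0)          # 6 healthy + 6 diseased
cohort = generate_cohort(spec)
pre = [preprocess_sample(sample, roi) for sample, roi, _ in cohort]
table, qc = extract_feature_table(pre)
labels = {sample.sample_id: lab for sample, _, lab in cohort}

ranking = rank_features(table, labels, "architecture")
for name, fdr in ranking.entries[:3]:
    print(f"{name:40s} FDR = {fdr:.2f}")

result = select_features(table, labels, "architecture")
print("selected:", result.selected_features)
print(f"LOO accuracy: {result.loo_accuracy:.2f}")
```

prints

```
eccentricity_mean                        FDR = 408.48
SHG_mean_crypts                          FDR = 137.69
crypt_density                            FDR = 81.94
selected: ['eccentricity_mean']
LOO accuracy: 1.00
```

The top-ranked features are geometry-family, as expected for the
architecture index on this cohort (the diseased preset distorts crypt
shape and lowers density); the FDR magnitudes are large because the
synthetic class contrast is strong and noise is modest. A single selected
feature suffices for perfect leave-one-out accuracy here; on cohorts where
classes differ only in intensity properties, geometry-only models stay
near chance and the selector needs the intensity-related features.

The same stages are available from the shell:

```bash
ibdquant simulate --n 12 --seed 0 --preset mixed --out run/raw
ibdquant preprocess --in run/raw --out run/pre
ibdquant extract --in run/pre --out run/features.csv
ibdquant rank --features run/features.csv --labels run/pre/labels.csv \
              --index architecture --out run/ranking.csv
ibdquant train --features run/features.csv --labels run/pre/labels.csv \
               --index architecture --out run/model.json
ibdquant run --out run_all        # everything, plus report.md
```

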