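# Methods

This note documents the models, conventions and design choices behind
ibdquant, in the order the pipeline runs. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Data model

A sample is five co-registered 2-D intensity channels (CARS2850, CARS2930,
TPEF458, TPEF525, SHG) acquired as an exact grid of tiles; pixel size,
tile grid and tile shape travel with the sample. Regions of interest are a
labelled crypt mask (contiguous labels 1..K) and a mucosa mask on the same
grid; the second ROI, "mucosa without crypts", is always derived as
`mucosa AND NOT crypts`, so the two ROI feature sets are computed on
disjoint pixel sets. Index labels follow the two-level pathologist scheme:
architecture and chronicity in {0, 2}, activity in {0, 1}; readers reject
anything else (e.g. architecture = 1). Storage is deliberately plain:
multi-page TIFF with a fixed page order plus a JSON sidecar, CSV tables,
YAML configs.

## Synthetic cohorts

The generator's purpose is a controllable stand-in for a small clinical
cohort, with exact ground truth. What it emulates, per class:

* **Morphology.** Crypts are ellipses with low-order radial boundary
  harmonics, placed on a jittered lattice inside the mucosa; candidates
  that would overlap or leave the mucosa are skipped, and the lattice is
  sized so the realised count matches the requested density. The healthy
  preset uses 120 crypts/mm², radius 30 µm (cv 0.08), near-zero
  irregularity/jitter/branching; the diseased preset lowers density to
  70 /mm² (atrophy) and raises radius to 36 µm with cv 0.30, shape
  irregularity 0.45, spacing jitter 0.30 and branch probability 0.35
  (each branched crypt is two fused lobes, which drives solidity below
  the convex range). Densities and radii are typical colonic-mucosa
  magnitudes; the diseased offsets are chosen once so that each distortion
  axis (shape, density, arrangement) moves in the direction seen in
  inflamed tissue by an amount well above rasterisation noise.
* **Intensity.** Piecewise levels (lamina propria baseline vs crypt
  epithelium) per channel, dark mucin cores in a fraction of crypts (dark
  in CARS and TPEF), bright lymphocyte-like spots added to the TPEF
  channels (peak height 0.5, twice as strong at 525 nm as at 458 nm;
  30 /mm² healthy vs 250 /mm² diseased), a global TPEF gain over the
  mucosa (1.0 healthy, 1.6 diseased), and SHG-bright patches covering 15%
  of the diseased mucosa (absent in health). The gain is applied last, so
  a gain g scales the mucosal TPEF mean by exactly g. An 8% smooth
  multiplicative texture keeps first-order statistics non-degenerate.
  No quantitative effect sizes exist for these intensity changes in real
  tissue scoring; the preset magnitudes are calibrated only to make
  direction-of-effect comparisons meaningful, not to mimic absolute
  photon counts.
* **Acquisition.** Each tile is multiplied by a vignette
  v(r) = 1 − s·(r/r_max)², r measured from an illumination peak offset by
  5% of the tile size from the tile centre. The offset matters: a
  perfectly centred vignette is mirror-symmetric across tile borders and
  would produce *no* intensity step at the seams, making the mosaic
  artifact invisible to any seam metric; a slightly misaligned peak is
  also the realistic case. Shot noise is Poisson at `poisson_scale`
  photons per intensity unit (60 by default; `None` disables it) plus
  additive Gaussian read noise (σ = 0.01).

Default tiles are 256×256 px at 1.76 µm/px on a 2×2 grid — a scaled
stand-in for full 2048×2048 tiles covering 450 µm, available by config.
The default cohort is n = 40 with a 50/50 class mix; labels are class
presets, healthy → (0, 0, 0), diseased → (2, 2, 1). Everything derives
from one `SeedSequence`, so cohorts are bit-reproducible.

What the generator does **not** model: optical point-spread functions,
coherent CARS non-resonant background, graded (intermediate) severities,
3-D tissue, stitching misregistration, or pathologist segmentation error
(masks are exact). Passing tests therefore demonstrate correctness of the
pipeline's computations and the direction of class effects — not clinical
performance on real tissue.

## Preprocessing

Fixed order: median → downsample → flat-field → contrast. Swapping stages
is not supported; each can only be disabled.

* Median filter 3×3 with reflected edges (smallest kernel that removes
  impulse noise while preserving crypt borders at the post-downsampling
  resolution).
* Downsampling ×4 by block mean (not decimation), preserving channel
  means and photon statistics; pixel size is scaled accordingly. Masks
  follow the image: crypt labels by per-block majority with ties broken
  toward the lower label (background wins ties), mucosa by block-any.
  Objects at least ~8 px across at full resolution survive intact.
* Flat-field correction: the pixel-wise mean over all tiles is an
  estimate of the per-tile illumination profile; it is smoothed, normalised
  to mean 1, floored at 10⁻³, and divided out of every tile, then the
  channel mean is restored exactly. The default smoother is a
  least-squares 2-D polynomial surface (degree 4) fitted to the average
  tile: polynomial fits are unbiased for smooth low-order illumination
  profiles and have no boundary artifacts, whereas Gaussian smoothing
  (available as an option, σ defaulting to tile width/8) systematically
  under-corrects near tile borders because the blur cannot follow the
  profile's gradient at the edge of its support.
* Contrast adjustment: linear rescale of [p1, p99] to [0, 1] with
  clipping; a constant channel maps to zeros with a warning. Because the
  mapping is per-channel affine, any global pre-scaling of the raw data
  cancels here, which is what makes the downstream texture features
  comparable across acquisitions.

## Features

The 87-entry catalogue (15 geometry + 5 modalities × 6 statistics × 2 ROIs
+ 6 CARS/TPEF channel pairs × 2 ROIs) is configuration-driven; the default
composition reflects the families that matter for these indices, and SHG
is carried in the texture features but excluded from contrast pairs.
Conventions that a reimplementation must match to reproduce values:

* Geometry from labelled-region properties; perimeter by weighted
  boundary-step counting (diagonal steps √2); equivalent diameter derived
  from pixel-count area, not from the perimeter; std aggregations are
  population (ddof 0), so a single crypt gives std 0. Nearest-neighbour
  spacing from centroid KD-tree queries, in µm.
* First-order statistics on a 256-bin histogram over [0, 1] with z at bin
  centres (k + ½)/256. Using bin centres makes a half-0/half-1 region
  give mean exactly 0.5 and keeps every statistic a pure function of the
  histogram. Entropy is in bits with 0·log 0 := 0.
* Inter-modality contrast is (m_a − m_b)/(m_a + m_b) of ROI means of the
  contrast-normalised channels, defined as 0 when both means vanish.
* Degenerate cases never produce NaN: a sample without crypts gets
  all-zero geometry and crypt-ROI features plus QC flags (`no-crypts`,
  `empty-roi:crypts`) recorded alongside the table.

## Ranking

FDR = (μ₁−μ₂)²/(s₁²+s₂²) with sample variances (ddof 1; the choice is
immaterial for equal class sizes because FDR is affine-invariant, and the
property suite pins the behaviour). Zero pooled variance with distinct
means yields +inf: such entries rank first but are flagged and excluded
from family means, since zero-variance separation at n ≈ tens is an
artifact of sample size, not evidence. Ties break alphabetically.

## Classification

Per index, a two-class Fisher LDA on z-scored features: pooled within-class
covariance with denominator n−2, ridge S_w + λ·(tr S_w/d)·I with relative
λ = 10⁻³ (needed because n ≈ 20–40 samples against up to 20 selected
features makes S_w ill-conditioned), w = S_w⁻¹Δμ, midpoint threshold
t = w·(μ₀+μ_alt)/2 (equal priors), LD > t ⇒ the higher level, ties to the
lower. Identical class means give w ≈ 0; prediction then falls back to the
majority training class with a warning. Standardisation constants are
re-derived inside every LOO training fold, so the held-out sample never
influences its own fold's fit; held-out LD values are reported centred as
LD_i − t_i because the threshold varies per fold. Note a known LOO
artifact: on a perfectly balanced cohort the majority fallback always
predicts the opposite of the held-out sample's class, so an uninformative
feature scores 0, not 0.5 — the "majority fraction" intuition holds only
for unbalanced cohorts.

Feature selection is greedy forward search over the allowed candidate pool
(geometry-only or geometry+IRP): at each step the feature whose addition
maximises LOO accuracy is added, with ties broken by larger mean held-out
|LD − t| margin, then better FDR rank, then name; the search stops at the
first step with no strict accuracy improvement over the current value
(which starts at the majority-class fraction) or at the cap
(10 features for architecture, 20 for chronicity and activity). Selection
is performed once on the full cohort with LOO accuracy as the criterion;
this mirrors the single-loop procedure such studies typically report and
carries the usual optimism bias — the strict-improvement stopping rule
limits, but does not remove, it. A nested evaluation (selection repeated
inside an outer CV) would be the unbiased alternative and can be built
from the same primitives; it is intentionally not the default.

## Pipeline and reproducibility

Each stage reads only the previous stage's on-disk artifacts, so stages
re-run independently; a run directory carries its resolved YAML config
(including the seed) and can be replayed bit-identically. The report is a
deterministic markdown rendering of the CSV/JSON artifacts: per-index
top-10 FDR tables, family trend summaries, selected features with LOO
accuracy, centred held-out LD values per class, and confusion counts.

## Problem sizes

The default synthetic conditions used throughout the tests and the
acceptance script are cohorts of n = 40 (n = 24 for the geometry-contrast
ranking check) at the 2×2 × 256×256-px scale — large enough that class
effects dominate rasterisation and shot noise, small enough that a full
pipeline run is a matter of seconds per sample on one CPU. Full-scale
10×15 × 2048×2048 mosaics are a configuration change, not a code change.

## Known limitations

* The feature catalogue is a reconstruction pinned by the named feature
  families and totals; an exact historical feature list for this kind of
  pipeline is not available, so the catalogue is configuration-driven.
* FDR ranking is descriptive; no multiple-testing control is applied or
  intended.
* The LDA is strictly two-class per index and uncalibrated (LD values are
  not probabilities).
* Synthetic realism bounds what green tests prove (see above); in
  particular, segmentation is assumed given — automating crypt/mucosa
  delineation is out of scope.
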