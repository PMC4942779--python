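"""Feature extraction: geometry oracles, first-order statistic identities,
contrast properties and catalogue structure."""
from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ibdquant.errors import EmptyRoiError
from ibdquant.features import (
    aggregate_geometry,
    crypt_density,
    default_catalogue,
    extract_features,
    first_order_stats,
    intermodality_contrast,
    measure_crypts,
)
from ibdquant.synthetic import healthy_morphology, render_crypt_field
from ibdquant.types import CHANNELS, MultimodalSample, RoiSet

N_BINS = 256


def brute_force_stats(values: np.ndarray):
    """Independent recomputation of the six statistics from the histogram."""
    counts = np.zeros(N_BINS)
    for v in values.ravel():
        b = min(int(v * N_BINS), N_BINS - 1)
        counts[b] += 1
    p = counts / counts.sum()
    z = (np.arange(N_BINS) + 0.5) / N_BINS
    m = sum(z[i] * p[i] for i in range(N_BINS))
    var = sum((z[i] - m) ** 2 * p[i] for i in range(N_BINS))
    third = sum((z[i] - m) ** 3 * p[i] for i in range(N_BINS))
    uni = sum(p[i] ** 2 for i in range(N_BINS))
    ent = -sum(p[i] * math.log2(p[i]) for i in range(N_BINS) if p[i] > 0)
    return m, math.sqrt(var), 1 - 1 / (1 + var), third, uni, ent


def test_first_order_stats_match_brute_force():
    rng = np.random.default_rng(0)
    for _ in range(10):
        img = rng.random((64, 64))
        mask = rng.random((64, 64)) < 0.7
        mask[0, 0] = True
        st_ = first_order_stats(img, mask)
        exp = brute_force_stats(img[mask])
        got = (st_.mean, st_.std, st_.smoothness, st_.third_moment,
               st_.uniformity, st_.entropy_bits)
        np.testing.assert_allclose(got, exp, atol=1e-10)


def test_first_order_stats_constant_region():
    img = np.full((16, 16), 0.7)
    st_ = first_order_stats(img, np.ones((16, 16), bool))
    assert st_.std == 0.0
    assert st_.smoothness == 0.0
    assert st_.third_moment == 0.0
    assert st_.uniformity == 1.0
    assert st_.entropy_bits == 0.0
    assert st_.mean == pytest.approx(0.7, abs=1 / N_BINS)


def test_first_order_stats_two_level_example():
    img = np.zeros((2, 64))
    img[1] = 1.0
    st_ = first_order_stats(img, np.ones_like(img, bool))
    assert st_.mean == pytest.approx(0.5, abs=1e-12)
    assert st_.std == pytest.approx(0.5, abs=1 / N_BINS)
    assert st_.smoothness == pytest.approx(0.2, abs=0.005)
    assert st_.third_moment == pytest.approx(0.0, abs=1e-12)
    assert st_.uniformity == pytest.approx(0.5, abs=1e-12)
    assert st_.entropy_bits == pytest.approx(1.0, abs=1e-12)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1))
def test_first_order_stats_bounds(seed):
    rng = np.random.default_rng(seed)
    img = rng.random((16, 16)) ** rng.uniform(0.3, 3.0)
    st_ = first_order_stats(img, np.ones((16, 16), bool))
    assert 0 < st_.uniformity <= 1
    assert 0 <= st_.smoothness < 1
    assert st_.entropy_bits >= 0
    assert 0 <= st_.mean <= 1


def test_first_order_stats_empty_mask():
    with pytest.raises(EmptyRoiError):
        first_order_stats(np.ones((4, 4)), np.zeros((4, 4), bool))


def disk_roi(radius=20, pad=8):
    size = 2 * (radius + pad)
    yy, xx = np.mgrid[0:size, 0:size]
    c = (size - 1) / 2
    disk = ((yy - c) ** 2 + (xx - c) ** 2) <= radius ** 2
    return RoiSet(disk.astype(np.int32), np.ones((size, size), bool))


def test_disk_geometry_oracle():
    roi = disk_roi(radius=20)
    (m,) = measure_crypts(roi, pixel_size_um=1.0)
    assert m.area_um2 == pytest.approx(math.pi * 400, rel=0.02)
    assert m.equivalent_diameter_um == pytest.approx(40.0, rel=0.02)
    assert m.eccentricity < 0.1
    assert m.solidity > 0.97


def test_square_geometry_closed_form():
    labels = np.zeros((20, 20), np.int32)
    labels[5:15, 5:15] = 1
    roi = RoiSet(labels, np.ones((20, 20), bool))
    (m,) = measure_crypts(roi, pixel_size_um=1.0)
    assert m.area_um2 == 100.0
    assert m.equivalent_diameter_um == pytest.approx(math.sqrt(400 / math.pi), rel=1e-6)
    assert m.radius_um == pytest.approx(m.equivalent_diameter_um / 2)


def test_ellipse_eccentricity_rotation_stable():
    for angle in (0.0, 0.4, 1.1):
        size = 120
        yy, xx = np.mgrid[0:size, 0:size].astype(float) - (size - 1) / 2
        u = xx * math.cos(angle) + yy * math.sin(angle)
        v = -xx * math.sin(angle) + yy * math.cos(angle)
        ellipse = (u / 40) ** 2 + (v / 20) ** 2 <= 1
        roi = RoiSet(ellipse.astype(np.int32), np.ones((size, size), bool))
        (m,) = measure_crypts(roi, 1.0)
        assert m.eccentricity == pytest.approx(math.sqrt(1 - 0.25), abs=0.02)


def test_crypt_density_definition():
    labels = np.zeros((100, 100), np.int32)
    for k in range(5):
        labels[10 * k + 2: 10 * k + 6, 2:6] = k + 1
    # 100x100 px at 70.7107 um/px ~ 0.5 mm^2 of mucosa
    px = math.sqrt(0.5e6 / 1e4)
    roi = RoiSet(labels, np.ones((100, 100), bool))
    assert crypt_density(roi, px) == pytest.approx(10.0, rel=1e-9)
    empty = RoiSet(np.zeros((10, 10), np.int32), np.ones((10, 10), bool))
    assert crypt_density(empty, 10.0) == 0.0
    with pytest.raises(EmptyRoiError):
        crypt_density(RoiSet(np.zeros((4, 4), np.int32), np.zeros((4, 4), bool)), 1.0)


def test_aggregate_geometry_degenerate_and_pairs():
    feats, qc = aggregate_geometry([], 0.0)
    assert qc == ["no-crypts"]
    assert all(v == 0.0 for v in feats.values())
    roi = disk_roi(radius=10)
    (m,) = measure_crypts(roi, 1.0)
    feats, qc = aggregate_geometry([m], 5.0)
    assert qc == ["single-crypt"]
    assert feats["area_std"] == 0.0 and feats["nn_distance_mean"] == 0.0
    # two identical crypts 100 um apart
    import dataclasses
    m2 = dataclasses.replace(m, label=2,
                             centroid_um=(m.centroid_um[0], m.centroid_um[1] + 100))
    feats, qc = aggregate_geometry([m, m2], 5.0)
    assert qc == []
    assert feats["nn_distance_mean"] == pytest.approx(100.0)
    assert feats["nn_distance_std"] == pytest.approx(0.0, abs=1e-9)
    assert feats["area_std"] == 0.0


def test_jitter_increases_spacing_variability():
    from ibdquant.synthetic import MorphologySpec
    regular = MorphologySpec(spacing_cv=0.0, shape_irregularity=0.0,
                             branch_prob=0.0)
    jittered = MorphologySpec(spacing_cv=0.25, shape_irregularity=0.0,
                              branch_prob=0.0)
    def nn_std(morph, seed):
        roi = render_crypt_field(morph, (512, 512), 1.76,
                                 np.random.default_rng(seed))
        feats, _ = aggregate_geometry(
            measure_crypts(roi, 1.76), crypt_density(roi, 1.76))
        return feats["nn_distance_std"]
    assert nn_std(jittered, 1) > nn_std(regular, 1)


def test_intermodality_contrast_values_and_antisymmetry():
    mask = np.ones((4, 4), bool)
    a = np.full((4, 4), 0.6)
    b = np.full((4, 4), 0.2)
    assert intermodality_contrast(a, a, mask) == 0.0
    assert intermodality_contrast(a, b, mask) == pytest.approx(0.5)
    assert intermodality_contrast(b, a, mask) == pytest.approx(-0.5)
    zero = np.zeros((4, 4))
    assert intermodality_contrast(zero, zero, mask) == 0.0
    with pytest.raises(EmptyRoiError):
        intermodality_contrast(a, b, np.zeros((4, 4), bool))


def test_catalogue_composition():
    cat = default_catalogue()
    assert len(cat) == 87
    assert len({s.name for s in cat}) == 87
    fams = {"geometry": 0, "irp": 0}
    for s in cat:
        fams[s.family] += 1
    assert fams == {"geometry": 15, "irp": 72}
    stats = [s for s in cat if s.kind == "stat"]
    contrasts = [s for s in cat if s.kind == "contrast"]
    assert len(stats) == 60 and len(contrasts) == 12
    assert not any("SHG" in s.modality for s in contrasts)


def normalized_sample(rng, roi):
    chans = {c: rng.random(roi.shape) for c in CHANNELS}
    return MultimodalSample("s", chans, pixel_size_um=1.76)


def test_extract_features_deterministic_and_complete():
    rng = np.random.default_rng(20)
    roi = render_crypt_field(healthy_morphology(), (256, 256), 1.76, rng)
    sample = normalized_sample(np.random.default_rng(21), roi)
    row1, qc1 = extract_features(sample, roi)
    row2, _ = extract_features(sample, roi)
    assert list(row1) == [s.name for s in default_catalogue()]
    assert row1 == row2
    assert qc1 == []
    assert all(np.isfinite(v) for v in row1.values())


def test_extract_features_no_crypts_flags_qc():
    roi = RoiSet(np.zeros((64, 64), np.int32), np.ones((64, 64), bool))
    sample = normalized_sample(np.random.default_rng(22), roi)
    row, qc = extract_features(sample, roi)
    assert "no-crypts" in qc and "empty-roi:crypts" in qc
    assert row["area_mean"] == 0.0
    assert row["TPEF525_mean_crypts"] == 0.0
    assert row["TPEF525_mean_mucosa_wo_crypts"] > 0


def test_roi_classes_are_disjoint():
    rng = np.random.default_rng(23)
    roi = render_crypt_field(healthy_morphology(), (256, 256), 1.76, rng)
    assert not (roi.crypt_mask & roi.mucosa_without_crypts).any()
    assert ((roi.crypt_mask | roi.mucosa_without_crypts) == roi.mucosa_mask).all()
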