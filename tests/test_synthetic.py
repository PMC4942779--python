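"""Generator contracts: determinism, ground-truth consistency, and the
healthy-vs-inflamed intensity/morphology contrasts."""
from __future__ import annotations

import dataclasses

import numpy as np
import pytest
from scipy import ndimage as ndi
from skimage import measure

from ibdquant import CohortSpec, IndexLabels, generate_cohort
from ibdquant.errors import PackingError, ShapeMismatchError
from ibdquant.features import crypt_density
from ibdquant.synthetic import (
    IntensitySpec,
    MorphologySpec,
    NoiseSpec,
    apply_acquisition,
    diseased_intensity,
    diseased_morphology,
    healthy_morphology,
    render_channels,
    render_crypt_field,
    vignette_field,
)
from ibdquant.types import CHANNELS

from conftest import small_spec


def test_cohort_deterministic_under_seed():
    spec = small_spec()
    a = generate_cohort(spec)
    b = generate_cohort(spec)
    for (sa, ra, la), (sb, rb, lb) in zip(a, b):
        assert la == lb
        np.testing.assert_array_equal(ra.crypt_labels, rb.crypt_labels)
        for c in CHANNELS:
            np.testing.assert_array_equal(sa.channels[c], sb.channels[c])


def test_class_mix_extremes_and_labels():
    all_healthy = generate_cohort(small_spec(class_mix=1.0))
    assert all(lab == IndexLabels.healthy() for _, _, lab in all_healthy)
    mixed = generate_cohort(small_spec(class_mix=0.5))
    labs = [lab for _, _, lab in mixed]
    assert IndexLabels.healthy() in labs and IndexLabels.diseased() in labs


def test_healthy_density_matches_spec():
    rng = np.random.default_rng(3)
    morph = healthy_morphology()
    roi = render_crypt_field(morph, (512, 512), 1.76, rng)
    measured = crypt_density(roi, 1.76)
    assert abs(measured - morph.crypt_density_per_mm2) / morph.crypt_density_per_mm2 < 0.15


def test_regular_crypts_have_equal_area():
    rng = np.random.default_rng(4)
    morph = MorphologySpec(crypt_density_per_mm2=60.0, crypt_radius_um=(30.0, 0.0),
                           shape_irregularity=0.0, spacing_cv=0.0, branch_prob=0.0)
    roi = render_crypt_field(morph, (512, 512), 1.76, rng)
    areas = np.array([p.area for p in measure.regionprops(roi.crypt_labels)])
    assert len(areas) > 10
    assert areas.max() / areas.min() - 1 < 0.04  # +-2% around the mean


def test_branching_makes_crypts_nonconvex():
    rng = np.random.default_rng(5)
    morph = MorphologySpec(crypt_density_per_mm2=25.0, crypt_radius_um=(30.0, 0.0),
                           shape_irregularity=0.0, spacing_cv=0.0, branch_prob=1.0)
    roi = render_crypt_field(morph, (512, 512), 1.76, rng)
    sol = [p.solidity for p in measure.regionprops(roi.crypt_labels)]
    assert len(sol) > 3
    assert max(sol) < 0.98


def test_zero_density_gives_empty_field():
    rng = np.random.default_rng(6)
    morph = MorphologySpec(crypt_density_per_mm2=0.0)
    roi = render_crypt_field(morph, (256, 256), 1.76, rng)
    assert roi.n_crypts == 0
    assert not roi.crypt_mask.any()


def test_infeasible_density_raises_packing_error():
    rng = np.random.default_rng(7)
    morph = MorphologySpec(crypt_density_per_mm2=2000.0, crypt_radius_um=(40.0, 0.0))
    with pytest.raises(PackingError):
        render_crypt_field(morph, (256, 256), 1.76, rng)


def flat_intensity(**over) -> IntensitySpec:
    """Intensity spec with zero texture so levels are piecewise exact."""
    base = dict(texture_cv=0.0, goblet_dark_fraction=0.0,
                lymphocyte_spot_density_per_mm2=0.0)
    base.update(over)
    return IntensitySpec(**base)


def test_no_spots_means_no_peaks_and_spots_make_peaks():
    rng = np.random.default_rng(8)
    roi = render_crypt_field(healthy_morphology(), (256, 256), 1.76, rng)
    muc_wo = roi.mucosa_without_crypts

    def peak_count(img):
        baseline = np.median(img[muc_wo])
        sd = img[muc_wo].std()
        is_max = (img == ndi.maximum_filter(img, size=9)) & muc_wo
        return int((is_max & (img > baseline + 3 * sd + 1e-12)).sum())

    quiet = render_channels(roi, flat_intensity(), np.random.default_rng(9))
    assert peak_count(quiet["TPEF525"]) == 0
    assert peak_count(quiet["TPEF458"]) == 0
    busy = render_channels(
        roi, flat_intensity(lymphocyte_spot_density_per_mm2=100.0),
        np.random.default_rng(9))
    assert peak_count(busy["TPEF525"]) > 5


def test_tpef_background_gain_scales_mucosal_mean():
    rng = np.random.default_rng(10)
    roi = render_crypt_field(healthy_morphology(), (256, 256), 1.76, rng)
    base = render_channels(roi, flat_intensity(), np.random.default_rng(11))
    gained = render_channels(roi, flat_intensity(tpef_background_gain=2.0),
                             np.random.default_rng(11))
    m = roi.mucosa_mask
    ratio = gained["TPEF525"][m].mean() / base["TPEF525"][m].mean()
    assert ratio == pytest.approx(2.0, rel=0.05)


def test_no_fibrosis_means_dark_shg():
    rng = np.random.default_rng(12)
    roi = render_crypt_field(healthy_morphology(), (256, 256), 1.76, rng)
    chans = render_channels(roi, flat_intensity(shg_fibrosis_patch_fraction=0.0),
                            np.random.default_rng(13))
    shg_mean = chans["SHG"][roi.mucosa_mask].mean()
    cars_crypt = chans["CARS2850"][roi.crypt_mask].mean()
    assert shg_mean <= 0.01 * cars_crypt
    with_fibrosis = render_channels(
        roi, flat_intensity(shg_fibrosis_patch_fraction=0.15),
        np.random.default_rng(13))
    assert with_fibrosis["SHG"][roi.mucosa_mask].mean() > 10 * shg_mean


def test_acquisition_identity_when_disabled():
    rng = np.random.default_rng(14)
    chans = {c: np.random.default_rng(15).random((64, 64)) for c in CHANNELS}
    out = apply_acquisition(chans, (2, 2), 0.0,
                            NoiseSpec(poisson_scale=None, gaussian_sd=0.0),
                            rng, sample_id="x", pixel_size_um=1.0,
                            vignette_center=(0.0, 0.0))
    for c in CHANNELS:
        np.testing.assert_array_equal(out.channels[c], chans[c])


def test_vignette_corner_to_center_ratio():
    v = vignette_field((256, 256), 0.3, center_offset=(0.0, 0.0))
    center = v[127:129, 127:129].mean()
    corners = np.mean([v[0, 0], v[0, -1], v[-1, 0], v[-1, -1]])
    assert corners / center == pytest.approx(0.7, abs=0.02)


def test_poisson_noise_variance_matches_mean():
    rng = np.random.default_rng(16)
    level = 20.0
    chans = {c: np.full((256, 256), level) for c in CHANNELS}
    out = apply_acquisition(chans, (1, 1), 0.0,
                            NoiseSpec(poisson_scale=1.0, gaussian_sd=0.0),
                            rng, sample_id="p", pixel_size_um=1.0,
                            vignette_center=(0.0, 0.0))
    img = out.channels["CARS2850"]
    assert img.var() == pytest.approx(img.mean(), rel=0.1)


def test_acquisition_rejects_indivisible_grid():
    chans = {c: np.zeros((65, 64)) for c in CHANNELS}
    with pytest.raises(ShapeMismatchError):
        apply_acquisition(chans, (2, 2), 0.1, NoiseSpec(), np.random.default_rng(0),
                          sample_id="x", pixel_size_um=1.0)


def test_class_contrasts_follow_disease_direction():
    """Diseased presets: fewer crypts, brighter TPEF, more SHG."""
    rng_h = np.random.default_rng(17)
    rng_d = np.random.default_rng(18)
    roi_h = render_crypt_field(healthy_morphology(), (512, 512), 1.76, rng_h)
    roi_d = render_crypt_field(diseased_morphology(), (512, 512), 1.76, rng_d)
    assert crypt_density(roi_h, 1.76) > crypt_density(roi_d, 1.76)
    ch_h = render_channels(roi_h, IntensitySpec(), np.random.default_rng(19))
    ch_d = render_channels(roi_h, diseased_intensity(), np.random.default_rng(19))
    m = roi_h.mucosa_mask
    assert ch_d["TPEF525"][m].mean() > ch_h["TPEF525"][m].mean()
    assert ch_d["SHG"][m].mean() > ch_h["SHG"][m].mean()
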