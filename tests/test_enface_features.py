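"""En-face feature maps: column statistics, regions, resizing, stacks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from stargardt_oct.enface_features import (CANONICAL_FEATURES, INTENSITY_FEATURES,
                                           EnFaceFeatureMap, LayerSurfaces, OctVolume,
                                           build_feature_map, build_feature_stack,
                                           column_samples, column_statistic,
                                           column_thickness, get_region, normalize01,
                                           prepare_mask, reflect_if_od, resize_map)


def _flat_surfaces(shape, elm, ez, irpe, orpe, cs):
    nb, na = shape
    return LayerSurfaces({k: np.full((nb, na), v, dtype=float)
                          for k, v in zip(("ELM", "EZ", "IRPE", "ORPE", "CS"),
                                          (elm, ez, irpe, orpe, cs))})


def _direct_statistic(v, feature):
    """Independent oracle: direct formula / scipy implementation."""
    v = np.asarray(v, dtype=float)
    if feature == "mean":
        return v.sum() / v.size
    if feature == "median":
        s = np.sort(v)
        n = v.size
        return s[n // 2] if n % 2 else (s[n // 2 - 1] + s[n // 2]) / 2
    if feature == "max":
        return sorted(v)[-1]
    if feature == "min":
        return sorted(v)[0]
    if feature == "std":
        return np.sqrt(np.mean(v ** 2) - np.mean(v) ** 2)
    m2 = np.mean((v - v.mean()) ** 2)
    if feature == "skewness":
        return 0.0 if m2 == 0 else sps.skew(v, bias=True)
    if feature == "kurtosis":
        return 0.0 if m2 == 0 else sps.kurtosis(v, fisher=False, bias=True)
    if feature == "gray_level_entropy":
        counts = np.bincount(v.astype(int), minlength=256)
        return sps.entropy(counts[counts > 0], base=2)
    raise AssertionError(feature)


def test_statistics_match_direct_formulas_on_random_columns(rng):
    for _ in range(200):
        v = rng.integers(0, 256, size=rng.integers(1, 65))
        for feat in INTENSITY_FEATURES:
            got = column_statistic(v, feat)
            want = _direct_statistic(v, feat)
            assert got == pytest.approx(want, abs=1e-9), feat


@pytest.mark.parametrize("values,feature,expected", [
    ((2, 4, 6), "mean", 4.0),
    ((1, 1, 1), "std", 0.0),
    ((1, 2, 3), "skewness", 0.0),
    ((-1, 1, -1, 1), "kurtosis", 1.0),
    ((5, 5, 5), "gray_level_entropy", 0.0),
    ((0,) * 8 + (255,) * 8, "gray_level_entropy", 1.0),
    ((3, 1, 2, 4), "median", 2.5),
])
def test_statistic_hand_examples(values, feature, expected):
    assert column_statistic(values, feature) == pytest.approx(expected, abs=1e-12)


def test_statistic_input_validation():
    with pytest.raises(ValueError, match="empty"):
        column_statistic([], "mean")
    with pytest.raises(ValueError, match="non-finite"):
        column_statistic([1.0, np.nan], "mean")
    with pytest.raises(ValueError):
        column_statistic([1, 2], "thickness")


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.integers(0, 200), min_size=2, max_size=40), st.integers(1, 55))
def test_shift_invariance_and_scale_covariance(values, shift):
    """std/skewness/kurtosis/entropy are shift-invariant; std scales linearly."""
    v = np.asarray(values, dtype=float)
    for feat in ("std", "skewness", "kurtosis", "gray_level_entropy"):
        assert column_statistic(v + shift, feat) == pytest.approx(
            column_statistic(v, feat), abs=1e-9)
    assert column_statistic(v * 1.0, "std") * 2 == pytest.approx(
        column_statistic(np.repeat(v, 1) * 2, "std"), abs=1e-9)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.integers(0, 255), min_size=1, max_size=40))
def test_order_statistics_bracket_mean_and_median(values):
    v = np.asarray(values, dtype=float)
    lo, hi = column_statistic(v, "min"), column_statistic(v, "max")
    assert lo <= column_statistic(v, "mean") <= hi
    assert lo <= column_statistic(v, "median") <= hi
    assert column_statistic(v, "std") >= 0
    assert 0 <= column_statistic(v, "gray_level_entropy") <= 8


def test_column_samples_direct_indexing():
    vol = np.zeros((20, 4, 3), dtype=np.uint8)
    vol[10:13, 1, 2] = (5, 7, 9)
    volume = OctVolume(vol)
    surf = _flat_surfaces((3, 4), 2, 10.0, 12.0, 14, 16)
    assert column_samples(volume, surf, "EZ-IRPE", 2, 1).tolist() == [5, 7, 9]


def test_column_samples_rounding_collapses_to_one_voxel():
    vol = np.arange(20, dtype=np.uint8).reshape(20, 1, 1) * 0 + \
        np.arange(20, dtype=np.uint8)[:, None, None]
    volume = OctVolume(vol)
    surf = _flat_surfaces((1, 1), 2, 10.4, 10.4, 14, 16)
    got = column_samples(volume, surf, "EZ-IRPE", 0, 0)
    assert got.tolist() == [10]


def test_ez_band_clamps_to_volume():
    vol = np.zeros((64, 2, 2), dtype=np.uint8)
    volume = OctVolume(vol)
    surf = _flat_surfaces((2, 2), 1, 3.0, 5, 7, 9)
    got = column_samples(volume, surf, "EZ+-5", 0, 0)
    assert got.size == 9  # z in [0, 8]


def test_thickness_examples_and_exclusion():
    surf = _flat_surfaces((2, 2), 2, 4.0, 10.0, 12, 16)
    assert column_thickness(surf, "EZ-IRPE", 0, 0) == pytest.approx(6.0)
    surf_eq = _flat_surfaces((2, 2), 2, 4.0, 4.0, 12, 16)
    assert column_thickness(surf_eq, "EZ-IRPE", 0, 0) == 0.0
    with pytest.raises(ValueError, match="excluded"):
        column_thickness(surf, "EZ+-5", 0, 0)
    with pytest.raises(ValueError, match="excluded"):
        column_thickness(surf, "ORPE-CS", 0, 0)


def test_constant_volume_gives_constant_mean_map():
    volume = OctVolume(np.full((32, 8, 4), 77, dtype=np.uint8))
    surf = _flat_surfaces((4, 8), 5, 10, 15, 20, 25)
    m = build_feature_map(volume, surf, "ELM-IRPE", "mean")
    assert np.allclose(m.data, 77.0)


def test_feature_map_equals_columnwise_composition(small_eye, rng):
    """Whole-map construction agrees with per-column sampling + statistic."""
    eye = small_eye
    for feat in ("mean", "median", "std", "skewness", "kurtosis",
                 "gray_level_entropy", "min", "max"):
        m = build_feature_map(eye.volume, eye.surfaces, "EZ-IRPE", feat).data
        for _ in range(20):
            b = int(rng.integers(eye.volume.n_bscans))
            a = int(rng.integers(eye.volume.n_ascans))
            col = column_samples(eye.volume, eye.surfaces, "EZ-IRPE", b, a)
            assert m[b, a] == pytest.approx(column_statistic(col, feat), abs=1e-9)


def test_float_volume_falls_back_to_columnwise_path(small_eye):
    eye = small_eye
    fvol = OctVolume(eye.volume.data.astype(np.float64), eye.laterality)
    a = build_feature_map(eye.volume, eye.surfaces, "ELM-EZ", "mean").data
    b = build_feature_map(fvol, eye.surfaces, "ELM-EZ", "mean").data
    assert np.allclose(a, b, atol=1e-9)


def test_thickness_map_minimum_inside_lesion(medium_eye):
    eye = medium_eye
    m = build_feature_map(eye.volume, eye.surfaces, "EZ-IRPE", "thickness").data
    bmin, amin = np.unravel_index(np.argmin(m), m.shape)
    assert eye.mask_baseline[bmin, amin] == 1


def test_resize_constant_and_binary_behaviour():
    const = np.full((5, 9), 3.5)
    assert np.allclose(resize_map(const, (7, 7)), 3.5)
    mask = (np.arange(36).reshape(6, 6) % 5 == 0).astype(np.uint8)
    out = resize_map(mask, (9, 9), mode="label")
    assert set(np.unique(out)) <= {0, 1}
    with pytest.raises(ValueError, match="binary"):
        resize_map(np.array([[0.2, 1.0], [0.0, 1.0]]), (4, 4), mode="label")


def test_bilinear_upsample_is_row_constant_column_monotone():
    m = np.array([[0.0, 0.0], [1.0, 1.0]])
    out = resize_map(m, (4, 4))
    assert np.allclose(out, out[:, :1])           # constant along rows
    assert (np.diff(out[:, 0]) >= -1e-12).all()   # monotone down columns
    assert out[0, 0] == pytest.approx(0.0, abs=1e-9)
    assert out[-1, 0] == pytest.approx(1.0, abs=1e-9)


def test_reflection_conventions():
    m = np.zeros((3, 5))
    m[1, 1] = 1.0
    assert np.array_equal(reflect_if_od(m, "OS"), m)
    flipped = reflect_if_od(m, "OD")
    assert flipped[1, 3] == 1.0
    assert np.array_equal(reflect_if_od(flipped, "OD"), m)  # involution
    assert np.allclose(reflect_if_od(np.full((2, 4), 7.0), "OD"), 7.0)


def test_stack_channel_counts_and_normalization(small_eye):
    eye = small_eye
    full = build_feature_stack(eye.volume, eye.surfaces, "ELM-IRPE", (32, 32))
    assert full.data.shape == (9, 32, 32)
    assert full.features == CANONICAL_FEATURES
    banded = build_feature_stack(eye.volume, eye.surfaces, "EZ+-5", (32, 32))
    assert banded.data.shape == (8, 32, 32)
    assert "thickness" not in banded.features
    assert full.data.min() >= 0.0 and full.data.max() <= 1.0
    with pytest.raises(ValueError, match="not allowed"):
        build_feature_stack(eye.volume, eye.surfaces, "EZ+-5", (32, 32),
                            features=("mean", "thickness"))


def test_constant_volume_stack_is_all_zero():
    volume = OctVolume(np.full((32, 8, 4), 50, dtype=np.uint8))
    surf = _flat_surfaces((4, 8), 5, 10, 15, 20, 25)
    stack = build_feature_stack(volume, surf, "ELM-EZ", (8, 8))
    assert np.allclose(stack.data, 0.0)


def test_surface_validation_rejects_disorder():
    with pytest.raises(ValueError, match="ordering"):
        _flat_surfaces((2, 2), 10, 5, 15, 20, 25)


def test_region_alias_lookup():
    assert get_region("EZ±5").name == "EZ+-5"
    with pytest.raises(KeyError):
        get_region("RNFL-GCL")


def test_prepare_mask_reflects_and_stays_binary(small_eye):
    m = prepare_mask(small_eye.mask_6mo, "OD", (32, 32))
    assert m.shape == (32, 32)
    assert set(np.unique(m)) <= {0, 1}
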