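"""Vegetation-index formulas against an independently coded oracle."""

import numpy as np
import pytest

import uavyield as uy
from uavyield.errors import FeatureError
from uavyield.vegindex import INDEX_NAMES, VI_FEATURE_NAMES


def _oracle_pixel(R, G, B, Rm, Gm, Bm):
    """Straight transliteration of the index formulas for one pixel, coded
    independently of the array implementation."""
    Rn, Gn, Bn = R / Rm, G / Gm, B / Bm
    s = Rn + Gn + Bn
    r, g, b = Rn / s, Gn / s, Bn / s
    exg = 2 * g - r - b
    exgr = exg - 1.4 * r - g
    cive = 18.78745 + 0.44 * r - 0.88 * g + 0.385 * b
    veg = g / (r**0.667 * b ** (1 - 0.667)) if r > 0 and b > 0 else np.nan
    out = {
        "ExG": exg,
        "EXGR": exgr,
        "CIVE": cive,
        "VEG": veg,
        "COMB1": 0.25 * exg + 0.3 * exgr + 0.33 * cive + 0.12 * veg,
        "COMB2": 0.36 * exg + 0.47 * cive + 0.17 * veg,
        "GRI": G / R if R != 0 else np.nan,
        "GRVI": (G - R) / (G + R) if G + R != 0 else np.nan,
        "MGRVI": (G**2 - R**2) / (G**2 + R**2) if G or R else np.nan,
        "PPRb": (G - B) / (G + B) if G + B != 0 else np.nan,
        "RGBVI": (G**2 - R * B) / (G**2 + R * B) if G**2 + R * B != 0 else np.nan,
        "SAVI": 1.5 * (G - R) / (G + R + 0.5),
        "VARI": (G - R) / (G + R - B) if G + R - B != 0 else np.nan,
        "VDVI": (2 * G - R - B) / (2 * G + R + B) if 2 * G + R + B != 0 else np.nan,
        "WI": (g - b) / abs(r - g) if abs(r - g) > 1e-12 else np.nan,
    }
    return out


def test_all_indices_match_oracle_on_random_pixels(rng):
    """Each of the 15 named indices agrees with the per-pixel oracle to 1e-10
    on 1,000 random pixels."""
    n = 1000
    pix = rng.integers(1, 256, (n, 1, 3)).astype(float)
    block = pix.reshape(n, 1, 3)
    maxima = (255.0, 255.0, 255.0)
    bands = uy.normalize_bands(block, maxima=maxima)
    grids = {name: uy.compute_index(name, bands).ravel() for name in INDEX_NAMES}
    for i in range(n):
        R, G, B = pix[i, 0]
        expect = _oracle_pixel(R, G, B, *maxima)
        for name in INDEX_NAMES:
            got, want = grids[name][i], expect[name]
            if np.isnan(want):
                assert np.isnan(got), name
            else:
                assert got == pytest.approx(want, abs=1e-10), name


def test_hand_checked_values_at_reference_pixel():
    """(R,G,B)=(100,200,50) with equal maxima: chromatic coordinates and the
    hand-evaluated ExG / WI / CIVE / GRVI / GRI / MGRVI values."""
    block = np.array([[[100.0, 200.0, 50.0]]])
    bands = uy.normalize_bands(block, maxima=(255.0, 255.0, 255.0))
    assert bands.r[0, 0] == pytest.approx(0.2857, abs=1e-4)
    assert bands.g[0, 0] == pytest.approx(0.5714, abs=1e-4)
    assert bands.b[0, 0] == pytest.approx(0.1429, abs=1e-4)
    assert uy.compute_index("ExG", bands)[0, 0] == pytest.approx(0.7143, abs=1e-4)
    assert uy.compute_index("WI", bands)[0, 0] == pytest.approx(1.5, abs=1e-4)
    assert uy.compute_index("CIVE", bands)[0, 0] == pytest.approx(18.4653, abs=1e-4)
    assert uy.compute_index("GRVI", bands)[0, 0] == pytest.approx(1.0 / 3.0, abs=1e-4)
    assert uy.compute_index("GRI", bands)[0, 0] == pytest.approx(2.0)
    assert uy.compute_index("MGRVI", bands)[0, 0] == pytest.approx(0.6)


def test_gray_pixel_symmetry():
    block = np.full((1, 1, 3), 120.0)
    bands = uy.normalize_bands(block, maxima=(255.0, 255.0, 255.0))
    assert bands.r[0, 0] == pytest.approx(1 / 3)
    for name in ("ExG", "GRVI", "MGRVI", "VDVI"):
        assert uy.compute_index(name, bands)[0, 0] == pytest.approx(0.0)


def test_chromatic_closure_property(rng):
    block = rng.integers(1, 256, (40, 40, 3)).astype(float)
    bands = uy.normalize_bands(block)
    total = bands.r + bands.g + bands.b
    assert np.allclose(total[bands.valid], 1.0, atol=1e-12)


def test_ratio_indices_are_scale_invariant(rng):
    """Multiplying all DNs by a constant leaves the ratio-based indices and
    chromatic coordinates unchanged."""
    block = rng.integers(1, 128, (20, 20, 3)).astype(float)
    b1 = uy.normalize_bands(block)
    b2 = uy.normalize_bands(block * 1.7)
    for name in ("VEG", "WI", "GRI", "GRVI", "MGRVI", "PPRb", "VARI", "VDVI"):
        v1, v2 = uy.compute_index(name, b1), uy.compute_index(name, b2)
        assert np.allclose(v1, v2, atol=1e-10, equal_nan=True), name
    assert np.allclose(b1.r, b2.r, atol=1e-12)
    # SAVI is not scale invariant (additive soil constant); re-evaluate directly
    s1 = uy.compute_index("SAVI", b1)
    s2 = uy.compute_index("SAVI", b2)
    assert not np.allclose(s1, s2)


def test_plot_features_are_24_means_in_stable_order(rng):
    block = rng.integers(1, 256, (30, 20, 3)).astype(float)
    feats = uy.plot_vi_features(block)
    assert tuple(feats.keys()) == VI_FEATURE_NAMES
    assert len(feats) == 24
    # constant plot: means equal single-pixel values
    const = np.tile(np.array([[[100.0, 200.0, 50.0]]]), (5, 5, 1))
    f2 = uy.plot_vi_features(const, maxima=(255.0, 255.0, 255.0))
    assert f2["ExG"] == pytest.approx(0.7143, abs=1e-4)
    assert f2["R"] == pytest.approx(100.0)


def test_plot_mean_is_linear_in_pixels():
    half = np.zeros((2, 1, 3))
    half[0, 0] = (120.0, 120.0, 120.0)  # gray: ExG = 0
    half[1, 0] = (100.0, 200.0, 50.0)  # reference: ExG = 0.7143
    feats = uy.plot_vi_features(half, maxima=(255.0, 255.0, 255.0))
    assert feats["ExG"] == pytest.approx(0.7143 / 2, abs=1e-4)


def test_black_pixels_flagged_and_all_black_rejected():
    block = np.zeros((2, 2, 3))
    block[0, 0] = (10.0, 20.0, 30.0)
    bands = uy.normalize_bands(block)
    assert bands.valid.sum() == 1
    with pytest.raises(FeatureError):
        uy.normalize_bands(np.zeros((3, 3, 3)))


def test_unknown_index_name_lists_valid_names():
    bands = uy.normalize_bands(np.full((2, 2, 3), 99.0))
    with pytest.raises(FeatureError) as err:
        uy.compute_index("NDVI", bands)
    assert "ExG" in str(err.value)


def test_canopy_cover_hand_values_and_monotonicity(rng):
    # EGI of (100,200,50) = (400-100-50)/200 = 1.25 -> canopy
    frac, mask = uy.canopy_cover(np.array([[[100, 200, 50]]], dtype=np.uint8))
    assert frac == 1.0 and mask.all()
    # gray pixel: EGI = 0 <= 0.05 -> soil
    frac, mask = uy.canopy_cover(np.full((1, 1, 3), 80, dtype=np.uint8))
    assert frac == 0.0 and not mask.any()
    # raising the threshold never increases coverage
    block = rng.integers(0, 256, (30, 30, 3)).astype(np.uint8)
    covers = [uy.canopy_cover(block, threshold=t)[0] for t in (-0.5, 0.0, 0.05, 0.2, 1.0)]
    assert all(a >= b for a, b in zip(covers, covers[1:]))
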