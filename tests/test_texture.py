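"""GLCM construction and metrics against brute-force enumeration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import uavyield as uy
from uavyield.errors import FeatureError
from uavyield.texture import (
    GLCMConfig,
    METRIC_NAMES,
    _window_metrics,
    band_texture_features,
)


def brute_glcm(window, config):
    """Independent pair-counting oracle: enumerate every pixel pair for every
    offset, pool counts (plus transposes when symmetric), normalize."""
    q = np.asarray(window)
    L = config.levels
    counts = np.zeros((L, L))
    h, w = q.shape
    for dr, dc in config.offsets:
        for r in range(h):
            for c in range(w):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < h and 0 <= c2 < w:
                    counts[q[r, c], q[r2, c2]] += 1
                    if config.symmetric:
                        counts[q[r2, c2], q[r, c]] += 1
    if counts.sum() == 0:
        raise ValueError("no pairs")
    return counts / counts.sum()


def brute_metrics(p):
    """Direct double-sum oracle for the nine metrics."""
    L = p.shape[0]
    mu = sum(i * p[i, j] for i in range(L) for j in range(L))
    var = sum((i - mu) ** 2 * p[i, j] for i in range(L) for j in range(L))
    out = {
        "mean": mu,
        "variance": var,
        "homogeneity": sum(p[i, j] / (1 + (i - j) ** 2) for i in range(L) for j in range(L)),
        "contrast": sum((i - j) ** 2 * p[i, j] for i in range(L) for j in range(L)),
        "dissimilarity": sum(abs(i - j) * p[i, j] for i in range(L) for j in range(L)),
        "entropy": -sum(
            p[i, j] * np.log(p[i, j]) for i in range(L) for j in range(L) if p[i, j] > 0
        ),
        "energy": sum(p[i, j] ** 2 for i in range(L) for j in range(L)),
        "autocorrelation": sum(i * j * p[i, j] for i in range(L) for j in range(L)),
    }
    if var <= 1e-12:
        out["correlation"] = 1.0
    else:
        out["correlation"] = (
            sum((i - mu) * (j - mu) * p[i, j] for i in range(L) for j in range(L)) / var
        )
    return out


def test_quantize_linear_binning():
    assert uy.quantize(np.array([[0, 255]]), 2).tolist() == [[0, 1]]
    assert uy.quantize(np.full((3, 3), 9.0), 8).tolist() == np.zeros((3, 3)).tolist()
    assert uy.quantize(np.array([[0, 85, 170, 255]]), 4).tolist() == [[0, 1, 2, 3]]


def test_constant_window_degenerate_matrix_and_metrics():
    cfg = GLCMConfig(levels=4)
    p = uy.glcm(np.zeros((3, 3), dtype=int), cfg)
    assert p[0, 0] == pytest.approx(1.0)
    m = uy.glcm_metrics(p)
    assert m["energy"] == pytest.approx(1.0)
    assert m["entropy"] == pytest.approx(0.0)
    assert m["contrast"] == pytest.approx(0.0)
    assert m["homogeneity"] == pytest.approx(1.0)
    assert m["correlation"] == 1.0


def test_vertical_stripes_concentrate_offdiagonal():
    cfg = GLCMConfig(levels=2, offsets=((0, 1),))
    stripes = np.tile([0, 1, 0], (3, 1))
    p = uy.glcm(stripes, cfg)
    assert p[0, 1] + p[1, 0] == pytest.approx(1.0)


def test_uniform_matrix_metrics():
    p = np.zeros((4, 4))
    p[0, 0] = p[0, 1] = p[1, 0] = p[1, 1] = 0.25
    m = uy.glcm_metrics(p)
    assert m["entropy"] == pytest.approx(np.log(4))
    assert m["energy"] == pytest.approx(0.25)


def test_glcm_matches_brute_force_on_random_windows(rng):
    cfg = GLCMConfig(levels=4)
    for _ in range(20):
        win = rng.integers(0, 4, (5, 5))
        assert np.allclose(uy.glcm(win, cfg), brute_glcm(win, cfg))


def test_metrics_match_double_sum_oracle(rng):
    for _ in range(10):
        raw = rng.random((8, 8))
        p = (raw + raw.T) / (2 * raw.sum())
        got = uy.glcm_metrics(p)
        want = brute_metrics(p)
        for name in METRIC_NAMES:
            assert got[name] == pytest.approx(want[name], abs=1e-12), name


def test_unnormalized_matrix_rejected():
    with pytest.raises(FeatureError):
        uy.glcm_metrics(np.ones((3, 3)))


def test_window_smaller_than_offset_reach_rejected():
    with pytest.raises(FeatureError):
        uy.glcm(np.zeros((1, 1), dtype=int), GLCMConfig(levels=2, offsets=((0, 2),), window=(3, 3)))


def test_sliding_windows_match_per_window_reference(rng):
    """The vectorized all-windows path reproduces per-window glcm+metrics on
    random 16x16 images (oracle equivalence on every interior window)."""
    cfg = GLCMConfig(levels=4)
    img = rng.integers(0, 256, (16, 16))
    q = uy.quantize(img, cfg.levels)
    fast = _window_metrics(q, cfg)
    k = 0
    for i in range(14):
        for j in range(14):
            ref = brute_metrics(brute_glcm(q[i : i + 3, j : j + 3], cfg))
            for name in METRIC_NAMES:
                assert fast[name][k] == pytest.approx(ref[name], abs=1e-10), (name, i, j)
            k += 1


def test_feature_counts_per_band(rng):
    block = rng.integers(0, 256, (12, 10, 3)).astype(np.uint8)
    assert len(uy.plot_texture_features(block)) == 135
    assert len(uy.plot_texture_features(block, bands=("R",))) == 45
    tiny = rng.integers(0, 256, (5, 4, 3)).astype(np.uint8)
    assert len(uy.plot_texture_features(tiny, bands=("G",))) == 45


def test_constant_plot_statistics_collapse():
    feats = band_texture_features(np.full((6, 6), 50.0))
    for m in METRIC_NAMES:
        assert feats[f"{m}_min"] == feats[f"{m}_max"] == feats[f"{m}_mean"]
        assert feats[f"{m}_sd"] == 0.0
    assert feats["energy_mean"] == pytest.approx(1.0)
    assert feats["entropy_mean"] == pytest.approx(0.0)


def test_plot_smaller_than_window_rejected():
    with pytest.raises(FeatureError):
        band_texture_features(np.zeros((2, 5)))


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_noise_increases_entropy(seed):
    """Salt-and-pepper corruption of a smooth full-range plot raises mean
    window entropy (same quantization range for both images)."""
    rng = np.random.default_rng(seed)
    base = np.tile(np.linspace(0.0, 255.0, 12), (12, 1))  # smooth gradient
    noisy = base.copy()
    idx = rng.choice(base.size, 25, replace=False)
    noisy.ravel()[idx] = rng.choice([0.0, 255.0], 25)
    clean_e = band_texture_features(base)["entropy_mean"]
    noisy_e = band_texture_features(noisy)["entropy_mean"]
    assert noisy_e > clean_e
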