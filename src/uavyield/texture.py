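"""Gray-level co-occurrence (GLCM) texture features.

Per band, each plot is quantized to a small number of gray levels and a
symmetric co-occurrence matrix is accumulated inside every fully interior
3 x 3 window, pooling the four unit-distance orientations (0, 45, 90, 135
degrees) before normalization.  Nine scalar metrics summarize each window's
matrix; five statistics (mean, min, max, SD, CV) summarize the window metric
over the plot, giving 9 x 5 = 45 texture features per band and 135 for all
three bands.

Metric definitions (p the normalized symmetric matrix, i row / j column
levels, mu and sigma^2 the marginal mean and variance):

==============  ==========================================
mean            sum_ij i p(i,j)
variance        sum_ij (i - mu)^2 p(i,j)
homogeneity     sum_ij p(i,j) / (1 + (i - j)^2)
contrast        sum_ij (i - j)^2 p(i,j)
dissimilarity   sum_ij |i - j| p(i,j)
entropy         -sum_ij p ln p            (0 ln 0 := 0)
energy          sum_ij p^2                (angular second moment)
correlation     sum_ij (i-mu)(j-mu) p / sigma^2   (:= 1 when sigma^2 = 0)
autocorrelation sum_ij i j p(i,j)
==============  ==========================================

``plot_texture_features`` evaluates all windows of a plot with a vectorized
pair-enumeration path; ``glcm`` / ``glcm_metrics`` provide the per-window
reference API with the same conventions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ConfigurationError, FeatureError

#: the nine window metrics, in output order
METRIC_NAMES = (
    "mean",
    "variance",
    "homogeneity",
    "contrast",
    "dissimilarity",
    "entropy",
    "energy",
    "correlation",
    "autocorrelation",
)

#: the five plot statistics over window metrics
STAT_NAMES = ("mean", "min", "max", "sd", "cv")

_VAR_EPS = 1e-12


@dataclass(frozen=True)
class GLCMConfig:
    """Quantization, window and offset configuration."""

    levels: int = 32
    window: tuple[int, int] = (3, 3)
    offsets: tuple[tuple[int, int], ...] = ((0, 1), (-1, 1), (-1, 0), (-1, -1))
    symmetric: bool = True
    normalized: bool = True

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ConfigurationError("levels must be >= 2")
        if any(s < 1 or s % 2 == 0 for s in self.window):
            raise ConfigurationError("window must be odd-sized")
        if not self.offsets:
            raise ConfigurationError("at least one offset is required")


def quantize(band: np.ndarray, levels: int) -> np.ndarray:
    """Linear binning of a band's DN range to integer levels 0..levels-1.

    Constant grids map to level 0.
    """
    if levels < 2:
        raise ConfigurationError("levels must be >= 2")
    band = np.asarray(band, dtype=float)
    lo, hi = band.min(), band.max()
    if hi <= lo:
        return np.zeros(band.shape, dtype=np.intp)
    q = np.floor((band - lo) / (hi - lo) * levels).astype(np.intp)
    return np.clip(q, 0, levels - 1)


def glcm(window_grid: np.ndarray, config: GLCMConfig = GLCMConfig()) -> np.ndarray:
    """Normalized symmetric co-occurrence matrix of one (already quantized)
    window, pooled over the configured offsets."""
    q = np.asarray(window_grid, dtype=np.intp)
    if q.ndim != 2:
        raise FeatureError("window grid must be 2-D")
    L = config.levels
    if q.max(initial=0) >= L:
        raise FeatureError("window contains levels outside 0..levels-1")
    h, w = q.shape
    counts = np.zeros((L, L), dtype=float)
    n_pairs = 0
    for dr, dc in config.offsets:
        if abs(dr) >= h or abs(dc) >= w:
            continue
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        a = q[r0:r1, c0:c1].ravel()
        b = q[r0 + dr : r1 + dr, c0 + dc : c1 + dc].ravel()
        np.add.at(counts, (a, b), 1.0)
        n_pairs += a.size
        if config.symmetric:
            np.add.at(counts, (b, a), 1.0)
            n_pairs += a.size
    if n_pairs == 0:
        raise FeatureError("window smaller than every offset reach (no valid pairs)")
    if config.normalized:
        counts /= counts.sum()
    return counts


def glcm_metrics(p: np.ndarray) -> dict[str, float]:
    """The nine scalar metrics of one normalized co-occurrence matrix."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise FeatureError("co-occurrence matrix must be square")
    total = p.sum()
    if not np.isclose(total, 1.0, atol=1e-8):
        raise FeatureError(f"matrix is not normalized (sum = {total:.6g})")
    L = p.shape[0]
    i = np.arange(L, dtype=float)[:, None]
    j = np.arange(L, dtype=float)[None, :]
    mu = float((i * p).sum())
    var = float(((i - mu) ** 2 * p).sum())
    homog = float((p / (1.0 + (i - j) ** 2)).sum())
    contrast = float(((i - j) ** 2 * p).sum())
    dissim = float((np.abs(i - j) * p).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.where(p > 0, np.log(np.where(p > 0, p, 1.0)), 0.0)
    entropy = float(-(p * logs).sum())
    energy = float((p**2).sum())
    autocorr = float((i * j * p).sum())
    if var <= _VAR_EPS:
        corr = 1.0
    else:
        corr = float((((i - mu) * (j - mu) * p).sum()) / var)
    return {
        "mean": mu,
        "variance": var,
        "homogeneity": homog,
        "contrast": contrast,
        "dissimilarity": dissim,
        "entropy": entropy,
        "energy": energy,
        "correlation": corr,
        "autocorrelation": autocorr,
    }


# ---------------------------------------------------------------------------
# Vectorized all-windows path


def _window_pair_codes(q: np.ndarray, config: GLCMConfig) -> np.ndarray:
    """Pair codes i*L+j for every interior window, shape (n_windows, n_pairs).

    Only the default 3x3 window with unit-distance offsets is needed by the
    pipeline, but the construction is generic over the configured offsets: a
    pair belongs to a window when both pixels lie inside it.
    """
    L = config.levels
    wh, ww = config.window
    H, W = q.shape
    n_r, n_c = H - wh + 1, W - ww + 1
    chunks = []
    for dr, dc in config.offsets:
        if dr > 0 or (dr == 0 and dc < 0):
            dr, dc, flipped = -dr, -dc, True  # canonical direction; swap a/b below
        else:
            flipped = False
        adr, adc = -dr, abs(dc)
        if adr >= wh or adc >= ww or adr >= H or adc >= W:
            continue
        # index pair codes by the top-left corner of the pair's bounding box:
        # a = lower pixel (row rmin+adr), b = upper pixel (row rmin)
        if dc >= 0:
            a = q[adr:, : W - adc] if adc else q[adr:, :]
            b = q[: H - adr, adc:] if adc else q[: H - adr, :]
        else:
            a = q[adr:, adc:] if adr else q[:, adc:]
            b = q[: H - adr, : W - adc]
        if flipped:
            a, b = b, a
        codes = a.astype(np.int64) * L + b.astype(np.int64)
        # a pair lies inside a window exactly when its bounding box does
        view = sliding_window_view(codes, (wh - adr, ww - adc))[:n_r, :n_c]
        chunks.append(view.reshape(n_r * n_c, -1))
    if not chunks:
        raise FeatureError("window smaller than every offset reach (no valid pairs)")
    pair = np.concatenate(chunks, axis=1)
    if config.symmetric:
        i, jj = pair // L, pair % L
        pair = np.concatenate([pair, jj * L + i], axis=1)
    return pair


def _window_metrics(q: np.ndarray, config: GLCMConfig) -> dict[str, np.ndarray]:
    """All nine metrics for every interior window of a quantized grid."""
    L = config.levels
    codes = _window_pair_codes(q, config)
    n_win, n_entries = codes.shape
    i = (codes // L).astype(float)
    j = (codes % L).astype(float)

    mu = i.mean(axis=1)
    e_i2 = (i * i).mean(axis=1)
    var = np.maximum(e_i2 - mu * mu, 0.0)
    d = i - j
    contrast = (d * d).mean(axis=1)
    dissim = np.abs(d).mean(axis=1)
    homog = (1.0 / (1.0 + d * d)).mean(axis=1)
    e_ij = (i * j).mean(axis=1)
    autocorr = e_ij
    cov = e_ij - mu * mu
    corr = np.where(var > _VAR_EPS, cov / np.where(var > _VAR_EPS, var, 1.0), 1.0)

    # energy / entropy need per-window histograms: run-length over sorted codes,
    # rows kept disjoint by a per-window code offset
    offs = (np.arange(n_win, dtype=np.int64) * (L * L))[:, None]
    flat = np.sort(codes + offs, axis=1).ravel()
    starts = np.empty(flat.size, dtype=bool)
    starts[0] = True
    np.not_equal(flat[1:], flat[:-1], out=starts[1:])
    start_idx = np.flatnonzero(starts)
    run_len = np.diff(np.append(start_idx, flat.size))
    per_entry = np.repeat(run_len, run_len).reshape(n_win, n_entries)
    T = float(n_entries)
    energy = per_entry.sum(axis=1) / (T * T)
    entropy = -np.log(per_entry / T).sum(axis=1) / T

    return {
        "mean": mu,
        "variance": var,
        "homogeneity": homog,
        "contrast": contrast,
        "dissimilarity": dissim,
        "entropy": entropy,
        "energy": energy,
        "correlation": corr,
        "autocorrelation": autocorr,
    }


def band_texture_features(
    band: np.ndarray, config: GLCMConfig = GLCMConfig()
) -> dict[str, float]:
    """45 texture features (9 metrics x 5 statistics) for one band's plot block.

    Sliding windows are fully interior to the plot (no padding).  CV = SD/mean
    is NaN when the metric's plot mean is exactly zero.
    """
    band = np.asarray(band)
    wh, ww = config.window
    if band.ndim != 2 or band.shape[0] < wh or band.shape[1] < ww:
        raise FeatureError(
            f"plot block {band.shape} smaller than the {wh}x{ww} processing window"
        )
    q = quantize(band, config.levels)
    metrics = _window_metrics(q, config)
    out: dict[str, float] = {}
    for m in METRIC_NAMES:
        vals = metrics[m]
        mean = float(vals.mean())
        sd = float(vals.std())
        out[f"{m}_mean"] = mean
        out[f"{m}_min"] = float(vals.min())
        out[f"{m}_max"] = float(vals.max())
        out[f"{m}_sd"] = sd
        out[f"{m}_cv"] = sd / mean if mean != 0 else float("nan")
    return out


def plot_texture_features(
    rgb_block: np.ndarray,
    bands: tuple[str, ...] = ("R", "G", "B"),
    config: GLCMConfig = GLCMConfig(),
) -> dict[str, float]:
    """Texture block for a plot: 45 features per requested band.

    With all three bands this is the 135-variable texture block; the red band
    alone gives the 45-variable block used at the modeling date.
    """
    block = np.asarray(rgb_block)
    if block.ndim != 3 or block.shape[2] != 3:
        raise FeatureError("expected a (rows, cols, 3) pixel block")
    band_index = {"R": 0, "G": 1, "B": 2}
    out: dict[str, float] = {}
    for band in bands:
        if band not in band_index:
            raise FeatureError(f"unknown band {band!r}; valid: R, G, B")
        feats = band_texture_features(block[:, :, band_index[band]], config)
        for k, v in feats.items():
            out[f"{band}_{k}"] = v
    return out
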