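"""RGB vegetation indices and excess-green canopy cover.

The plot-level spectral block holds 24 values: the raw band means (R, G, B),
the per-scene-maximum normalized bands (Rn, Gn, Bn), the chromatic
coordinates (r, g, b, which sum to 1 per pixel), and 15 named visible-band
vegetation indices.  Indices written with capital letters operate on raw
digital numbers; lower-case formulas operate on chromatic coordinates.

Canopy cover is the fraction of plot pixels whose excess green index
EGI = (2G - R - B) / G exceeds a threshold (default 0.05); the binary mask is
also returned for height masking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import FeatureError

#: the 15 named visible-band vegetation indices
INDEX_NAMES = (
    "CIVE",
    "COMB1",
    "COMB2",
    "ExG",
    "EXGR",
    "GRI",
    "GRVI",
    "MGRVI",
    "PPRb",
    "RGBVI",
    "SAVI",
    "VARI",
    "VDVI",
    "VEG",
    "WI",
)

#: ordering of the 24-column spectral feature block
VI_FEATURE_NAMES = ("R", "G", "B", "Rn", "Gn", "Bn", "r", "g", "b") + INDEX_NAMES

_EPS = 1e-12


@dataclass
class BandSet:
    """Raw, normalized and chromatic band grids for one pixel block."""

    R: np.ndarray
    G: np.ndarray
    B: np.ndarray
    R_max: float
    G_max: float
    B_max: float
    Rn: np.ndarray
    Gn: np.ndarray
    Bn: np.ndarray
    r: np.ndarray
    g: np.ndarray
    b: np.ndarray
    valid: np.ndarray  # pixels participating in plot means (non-black)


def normalize_bands(
    rgb_block: np.ndarray, maxima: tuple[float, float, float] | None = None
) -> BandSet:
    """Build normalized bands and chromatic coordinates for a pixel block.

    ``maxima`` are the per-scene band maxima; by default the block's own
    maxima are used.  All-zero (black) pixels carry no chromatic information
    and are flagged invalid, excluded from plot means.
    """
    block = np.asarray(rgb_block, dtype=float)
    if block.ndim != 3 or block.shape[2] != 3 or block.size == 0:
        raise FeatureError("expected a non-empty (rows, cols, 3) pixel block")
    R, G, B = block[:, :, 0], block[:, :, 1], block[:, :, 2]
    if maxima is None:
        maxima = (R.max(), G.max(), B.max())
    r_max, g_max, b_max = (float(m) for m in maxima)
    if min(r_max, g_max, b_max) <= 0:
        raise FeatureError("band maxima must be positive (all-black plot?)")
    Rn, Gn, Bn = R / r_max, G / g_max, B / b_max
    total = Rn + Gn + Bn
    valid = total > _EPS
    if not valid.any():
        raise FeatureError("no valid pixels in plot (all black)")
    safe = np.where(valid, total, 1.0)
    with np.errstate(invalid="ignore"):
        r = np.where(valid, Rn / safe, np.nan)
        g = np.where(valid, Gn / safe, np.nan)
        b = np.where(valid, Bn / safe, np.nan)
    return BandSet(
        R=R, G=G, B=B, R_max=r_max, G_max=g_max, B_max=b_max,
        Rn=Rn, Gn=Gn, Bn=Bn, r=r, g=g, b=b, valid=valid,
    )


def _ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    """Element-wise ratio; zero denominators yield NaN (excluded later)."""
    den = np.asarray(den, dtype=float)
    bad = np.abs(den) < _EPS
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(bad, np.nan, num / np.where(bad, 1.0, den))
    return out


def compute_index(name: str, bands: BandSet) -> np.ndarray:
    """Evaluate one named vegetation index per pixel.

    Undefined pixels (zero denominators, zero chromatic bases) are NaN and
    excluded from aggregation.
    """
    R, G, B = bands.R, bands.G, bands.B
    r, g, b = bands.r, bands.g, bands.b
    if name == "ExG":
        return 2 * g - r - b
    if name == "EXGR":
        return (2 * g - r - b) - 1.4 * r - g
    if name == "CIVE":
        return 18.78745 + 0.44 * r - 0.88 * g + 0.385 * b
    if name == "VEG":
        a = 0.667
        base = np.where((r > _EPS) & (b > _EPS), r**a * b ** (1 - a), np.nan)
        return _ratio(g, base)
    if name == "COMB1":
        exg = compute_index("ExG", bands)
        return (
            0.25 * exg
            + 0.3 * compute_index("EXGR", bands)
            + 0.33 * compute_index("CIVE", bands)
            + 0.12 * compute_index("VEG", bands)
        )
    if name == "COMB2":
        return (
            0.36 * compute_index("ExG", bands)
            + 0.47 * compute_index("CIVE", bands)
            + 0.17 * compute_index("VEG", bands)
        )
    if name == "GRI":
        return _ratio(G, R)
    if name == "GRVI":
        return _ratio(G - R, G + R)
    if name == "MGRVI":
        return _ratio(G**2 - R**2, G**2 + R**2)
    if name == "PPRb":
        return _ratio(G - B, G + B)
    if name == "RGBVI":
        return _ratio(G**2 - R * B, G**2 + R * B)
    if name == "SAVI":
        return 1.5 * (G - R) / (G + R + 0.5)
    if name == "VARI":
        return _ratio(G - R, G + R - B)
    if name == "VDVI":
        return _ratio(2 * G - R - B, 2 * G + R + B)
    if name == "WI":
        return _ratio(g - b, np.abs(r - g))
    raise FeatureError(f"unknown vegetation index {name!r}; valid names: {INDEX_NAMES}")


def plot_vi_features(
    rgb_block: np.ndarray,
    maxima: tuple[float, float, float] | None = None,
    mask: np.ndarray | None = None,
) -> dict[str, float]:
    """The 24-value spectral block for one plot, means over valid pixels.

    ``mask`` optionally restricts aggregation (e.g. to canopy pixels); the
    default aggregates over all valid plot pixels.
    """
    bands = normalize_bands(rgb_block, maxima=maxima)
    valid = bands.valid if mask is None else (bands.valid & np.asarray(mask, dtype=bool))
    if not valid.any():
        raise FeatureError("no valid pixels to aggregate")

    def agg(grid: np.ndarray) -> float:
        vals = grid[valid]
        vals = vals[np.isfinite(vals)]
        return float(vals.mean()) if vals.size else float("nan")

    out: dict[str, float] = {
        "R": agg(bands.R),
        "G": agg(bands.G),
        "B": agg(bands.B),
        "Rn": agg(bands.Rn),
        "Gn": agg(bands.Gn),
        "Bn": agg(bands.Bn),
        "r": agg(bands.r),
        "g": agg(bands.g),
        "b": agg(bands.b),
    }
    for name in INDEX_NAMES:
        out[name] = agg(compute_index(name, bands))
    return out


def excess_green_index(rgb_block: np.ndarray) -> np.ndarray:
    """EGI = (2G - R - B) / G per pixel; G = 0 pixels are soil (-inf here)."""
    block = np.asarray(rgb_block, dtype=float)
    R, G, B = block[:, :, 0], block[:, :, 1], block[:, :, 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        egi = np.where(G > 0, (2 * G - R - B) / np.where(G > 0, G, 1.0), -np.inf)
    return egi


def canopy_cover(
    rgb_block: np.ndarray, threshold: float = 0.05
) -> tuple[float, np.ndarray]:
    """Fraction of pixels classified canopy by EGI thresholding, plus mask."""
    block = np.asarray(rgb_block)
    if block.size == 0:
        raise FeatureError("empty pixel block")
    mask = excess_green_index(block) > threshold
    return float(mask.mean()), mask
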