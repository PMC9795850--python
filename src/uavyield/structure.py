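"""Canopy structure: bare-ground DEM, crop height model, height validation.

The bare-ground elevation of each plot is estimated from the pre-emergence
scene by Otsu-splitting the plot's DSM heights and averaging the lower class
(a per-plot constant DEM).  The crop height model is the pixel-wise
difference CHM = DSM - DEM with negative values clipped to zero, and the
plot-level height is the mean CHM over canopy pixels.
"""

from __future__ import annotations

import numpy as np
from skimage.filters import threshold_otsu

from .errors import FeatureError, ModelError
from .raster import SceneStack, PlotRecord, clip_plot

#: height ranges below this (meters) are treated as bare, skipping Otsu
DEGENERATE_HEIGHT_RANGE = 0.05


def estimate_bare_dem(
    early_scene: SceneStack,
    plot: PlotRecord,
    degenerate_range: float = DEGENERATE_HEIGHT_RANGE,
) -> float:
    """Bare-ground elevation (m) of one plot from a pre-emergence scene.

    Otsu's threshold (256-bin histogram over the plot's height range) splits
    the DSM heights into two classes and the lower-class mean is the DEM.
    Near-constant plots (range below ``degenerate_range``) short-circuit to
    the plot mean.
    """
    block = clip_plot(early_scene, plot)
    heights = block.dsm.astype(float).ravel()
    if heights.size == 0:
        raise FeatureError(f"plot {plot.plot_id}: empty pixel block")
    if np.ptp(heights) < degenerate_range:
        return float(heights.mean())
    t = threshold_otsu(heights, nbins=256)
    lower = heights[heights <= t]
    if lower.size == 0:  # pathological histogram; fall back to plot mean
        return float(heights.mean())
    return float(lower.mean())


def compute_chm(scene: SceneStack, dem: float | np.ndarray) -> np.ndarray:
    """Crop height model: DSM - DEM, negatives clipped to zero (meters)."""
    dem = np.asarray(dem, dtype=float)
    if not np.all(np.isfinite(dem)):
        raise FeatureError("DEM must be finite")
    return np.maximum(scene.dsm.astype(float) - dem, 0.0)


def plot_height(
    chm_block: np.ndarray, canopy_mask: np.ndarray | None = None
) -> tuple[float, bool]:
    """Plot-level height: mean CHM over canopy pixels.

    Returns ``(height, fallback)`` where ``fallback`` is True when canopy
    coverage was zero and the plain plot mean was used instead.
    """
    chm_block = np.asarray(chm_block, dtype=float)
    if canopy_mask is not None:
        canopy_mask = np.asarray(canopy_mask, dtype=bool)
        if canopy_mask.any():
            return float(chm_block[canopy_mask].mean()), False
    return float(chm_block.mean()), True


def validate_heights(
    estimates: np.ndarray, observations: np.ndarray
) -> tuple[float, float]:
    """Agreement between estimated and observed heights: (R^2, RMSE).

    R^2 is that of the ordinary least-squares fit of estimates on
    observations (squared Pearson correlation), so a constant offset keeps
    R^2 = 1 while inflating the RMSE.
    """
    est = np.asarray(estimates, dtype=float)
    obs = np.asarray(observations, dtype=float)
    if est.shape != obs.shape:
        raise ModelError(f"length mismatch: {est.shape} vs {obs.shape}")
    if est.size < 3:
        raise ModelError("need at least 3 paired heights")
    rmse = float(np.sqrt(np.mean((est - obs) ** 2)))
    if np.std(est) == 0 or np.std(obs) == 0:
        r2 = 1.0 if rmse == 0 else 0.0
    else:
        r2 = float(np.corrcoef(est, obs)[0, 1] ** 2)
    return r2, rmse
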