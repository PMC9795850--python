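"""Registered raster scenes, plot geometry and per-plot clipping.

A *scene* is a registered pair of rasters sharing one pixel grid: a 3-band
byte RGB orthomosaic and a single-band float digital surface model (DSM,
meters).  Georeferencing is a simple north-up affine grid (``GridTransform``);
rasters are read and written as GeoTIFF with the standard ModelPixelScale /
ModelTiepoint tags.

Plots are axis-aligned rectangles in map coordinates.  Clipping follows the
pixel-center inclusion rule with half-open windows, so a 1.8 m x 0.8 m plot at
0.01 m ground sampling distance is exactly a 180 x 80 block.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import ConfigurationError, PlotClipError, RasterFormatError

_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922

#: columns of the plot-geometry / ground-truth CSV table
PLOT_TABLE_COLUMNS = (
    "plot_id",
    "cultivar_id",
    "xmin",
    "ymin",
    "xmax",
    "ymax",
    "lodging",
    "grain_number",
    "grain_weight",
)


@dataclass(frozen=True)
class GridTransform:
    """North-up affine transform between pixel and map coordinates.

    ``x0, y0`` are the map coordinates of the *outer top-left corner* of pixel
    (0, 0); ``sx, sy`` are positive pixel sizes.  Rows increase downward
    (decreasing map y), columns increase with map x.
    """

    x0: float
    y0: float
    sx: float
    sy: float

    def __post_init__(self) -> None:
        if self.sx <= 0 or self.sy <= 0:
            raise ConfigurationError("pixel sizes must be positive")

    def pixel_center(self, row: float, col: float) -> tuple[float, float]:
        return (self.x0 + (col + 0.5) * self.sx, self.y0 - (row + 0.5) * self.sy)

    def world_to_pixel(self, x: float, y: float) -> tuple[float, float]:
        """Fractional (row, col) of a map point."""
        return ((self.y0 - y) / self.sy - 0.5, (x - self.x0) / self.sx - 0.5)

    def bounds(self, shape: tuple[int, int]) -> tuple[float, float, float, float]:
        h, w = shape
        return (self.x0, self.y0 - h * self.sy, self.x0 + w * self.sx, self.y0)


@dataclass
class SceneStack:
    """One acquisition date: registered RGB + DSM sharing a pixel grid."""

    date: int
    rgb: np.ndarray  # (H, W, 3) uint8, bands ordered R, G, B
    dsm: np.ndarray  # (H, W) float32 meters
    transform: GridTransform
    nodata: float = float("nan")

    def __post_init__(self) -> None:
        self.rgb = np.asarray(self.rgb)
        self.dsm = np.asarray(self.dsm, dtype=np.float32)
        if self.rgb.ndim != 3 or self.rgb.shape[2] != 3:
            raise RasterFormatError("rgb raster must be (rows, cols, 3)")
        if self.rgb.dtype != np.uint8:
            raise RasterFormatError("rgb raster must be 8-bit DN")
        if self.dsm.shape != self.rgb.shape[:2]:
            raise RasterFormatError(
                f"rgb {self.rgb.shape[:2]} and dsm {self.dsm.shape} grids differ"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.dsm.shape


@dataclass(frozen=True)
class PlotRecord:
    """One field plot: identity, rectangle geometry and ground observations."""

    plot_id: str
    cultivar_id: str
    rect: tuple[float, float, float, float]  # (xmin, ymin, xmax, ymax) map coords
    lodging: int | None = None  # ordinal severity 1 (upright) .. 5 (all lodged)
    grain_number: float | None = None  # seeds per plant
    grain_weight: float | None = None  # grams per plant

    def __post_init__(self) -> None:
        xmin, ymin, xmax, ymax = self.rect
        if not (xmax > xmin and ymax > ymin):
            raise ConfigurationError(f"plot {self.plot_id}: rectangle area must be positive")
        if self.lodging is not None and self.lodging not in (1, 2, 3, 4, 5):
            raise ConfigurationError(f"plot {self.plot_id}: lodging must be in 1..5")

    @property
    def area(self) -> float:
        xmin, ymin, xmax, ymax = self.rect
        return (xmax - xmin) * (ymax - ymin)


@dataclass
class PlotBlock:
    """Per-plot pixel block clipped from a scene."""

    plot_id: str
    rgb: np.ndarray  # (h, w, 3) uint8
    dsm: np.ndarray  # (h, w) float32
    window: tuple[int, int, int, int] = field(default=(0, 0, 0, 0))  # row0,row1,col0,col1


# ---------------------------------------------------------------------------
# GeoTIFF I/O


def _geo_tags(transform: GridTransform) -> list:
    scale = (float(transform.sx), float(transform.sy), 0.0)
    tiepoint = (0.0, 0.0, 0.0, float(transform.x0), float(transform.y0), 0.0)
    return [
        (_MODEL_PIXEL_SCALE, "d", 3, scale),
        (_MODEL_TIEPOINT, "d", 6, tiepoint),
    ]


def _read_transform(page: tifffile.TiffPage, path) -> GridTransform:
    try:
        scale = page.tags[_MODEL_PIXEL_SCALE].value
        tie = page.tags[_MODEL_TIEPOINT].value
    except KeyError as exc:
        raise RasterFormatError(f"{path}: missing GeoTIFF georeferencing tags") from exc
    return GridTransform(x0=float(tie[3]), y0=float(tie[4]), sx=float(scale[0]), sy=float(scale[1]))


def write_scene(scene: SceneStack, rgb_path, dsm_path) -> None:
    """Write a scene as a GeoTIFF pair (byte RGB + float32 DSM)."""
    tags = _geo_tags(scene.transform)
    tifffile.imwrite(rgb_path, scene.rgb, photometric="rgb", extratags=tags)
    tifffile.imwrite(dsm_path, scene.dsm.astype(np.float32), extratags=tags)


def read_scene(rgb_path, dsm_path, date: int = 0) -> SceneStack:
    """Read a registered GeoTIFF pair, rejecting mismatched grids.

    Bands are returned in R, G, B order; the two rasters must share shape and
    affine transform.
    """
    rgb_path, dsm_path = Path(rgb_path), Path(dsm_path)
    for p in (rgb_path, dsm_path):
        if not p.exists():
            raise FileNotFoundError(p)
    with tifffile.TiffFile(rgb_path) as tf:
        rgb = tf.pages[0].asarray()
        t_rgb = _read_transform(tf.pages[0], rgb_path)
    with tifffile.TiffFile(dsm_path) as tf:
        dsm = tf.pages[0].asarray()
        t_dsm = _read_transform(tf.pages[0], dsm_path)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise RasterFormatError(f"{rgb_path}: expected a 3-band RGB raster, got shape {rgb.shape}")
    if dsm.ndim != 2:
        raise RasterFormatError(f"{dsm_path}: expected a single-band DSM, got shape {dsm.shape}")
    if rgb.shape[:2] != dsm.shape:
        raise RasterFormatError(
            f"grid mismatch: rgb {rgb.shape[:2]} vs dsm {dsm.shape}"
        )
    if t_rgb != t_dsm:
        raise RasterFormatError("rgb and dsm transforms differ; rasters are not co-registered")
    return SceneStack(date=date, rgb=rgb.astype(np.uint8), dsm=dsm, transform=t_rgb)


# ---------------------------------------------------------------------------
# Plot table I/O


def plots_to_frame(plots: list[PlotRecord]) -> pd.DataFrame:
    rows = []
    for p in plots:
        xmin, ymin, xmax, ymax = p.rect
        rows.append(
            dict(
                plot_id=p.plot_id,
                cultivar_id=p.cultivar_id,
                xmin=xmin,
                ymin=ymin,
                xmax=xmax,
                ymax=ymax,
                lodging=p.lodging,
                grain_number=p.grain_number,
                grain_weight=p.grain_weight,
            )
        )
    return pd.DataFrame(rows, columns=list(PLOT_TABLE_COLUMNS))


def frame_to_plots(frame: pd.DataFrame) -> list[PlotRecord]:
    plots = []
    for row in frame.itertuples(index=False):
        lodging = None if pd.isna(row.lodging) else int(row.lodging)
        gn = None if pd.isna(row.grain_number) else float(row.grain_number)
        gw = None if pd.isna(row.grain_weight) else float(row.grain_weight)
        plots.append(
            PlotRecord(
                plot_id=str(row.plot_id),
                cultivar_id=str(row.cultivar_id),
                rect=(float(row.xmin), float(row.ymin), float(row.xmax), float(row.ymax)),
                lodging=lodging,
                grain_number=gn,
                grain_weight=gw,
            )
        )
    return plots


def write_plot_table(plots: list[PlotRecord], path) -> None:
    plots_to_frame(plots).to_csv(path, index=False)


def read_plot_table(path) -> list[PlotRecord]:
    return frame_to_plots(pd.read_csv(path))


# ---------------------------------------------------------------------------
# Clipping


def window_for_rect(
    transform: GridTransform,
    shape: tuple[int, int],
    rect: tuple[float, float, float, float],
) -> tuple[int, int, int, int]:
    """Half-open pixel window [row0,row1) x [col0,col1) of pixel *centers*
    falling inside an axis-aligned rectangle.

    Boundary arithmetic is snapped to 1e-9 so exactly grid-aligned rectangles
    yield exact block sizes.
    """
    xmin, ymin, xmax, ymax = rect

    def snap(v: float) -> float:
        return round(v, 9)

    col0 = math.ceil(snap((xmin - transform.x0) / transform.sx - 0.5))
    col1 = math.ceil(snap((xmax - transform.x0) / transform.sx - 0.5))
    row0 = math.floor(snap((transform.y0 - ymax) / transform.sy - 0.5)) + 1
    row1 = math.floor(snap((transform.y0 - ymin) / transform.sy - 0.5)) + 1
    h, w = shape
    row0, row1 = max(row0, 0), min(row1, h)
    col0, col1 = max(col0, 0), min(col1, w)
    return row0, row1, col0, col1


def clip_plot(scene: SceneStack, plot: PlotRecord) -> PlotBlock:
    """Clip one plot's pixel block (RGB + DSM) out of a scene.

    Pure function: repeated clips of the same plot return equal blocks.
    Raises :class:`PlotClipError` naming the plot when the rectangle misses
    the raster extent.
    """
    row0, row1, col0, col1 = window_for_rect(scene.transform, scene.shape, plot.rect)
    if row1 <= row0 or col1 <= col0:
        raise PlotClipError(plot.plot_id)
    return PlotBlock(
        plot_id=plot.plot_id,
        rgb=scene.rgb[row0:row1, col0:col1].copy(),
        dsm=scene.dsm[row0:row1, col0:col1].copy(),
        window=(row0, row1, col0, col1),
    )
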