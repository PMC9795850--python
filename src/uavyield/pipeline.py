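"""Per-date feature extraction: plots x features with group labels.

For one scene, every plot is clipped and summarized into:

* ``VI`` — the 24-value spectral block (raw/normalized/chromatic band means
  and 15 vegetation indices);
* ``TI`` — GLCM texture statistics, 45 per configured band;
* ``CC`` — excess-green canopy cover;
* ``CHM`` — plot height from the crop height model (needs a bare-ground DEM
  estimated from the pre-emergence scene);
* ``LODGING`` — the manually scored ordinal lodging level.

At the modeling date with the red-band texture block this is the 72-column
candidate inventory (24 + 45 + 1 + 1 + 1); with all three texture bands it is
the 162-column per-date inventory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FeatureError
from .raster import PlotRecord, SceneStack, clip_plot
from .structure import estimate_bare_dem, plot_height
from .texture import GLCMConfig, plot_texture_features
from .vegindex import canopy_cover, plot_vi_features

#: feature-group labels
GROUPS = ("VI", "TI", "CC", "CHM", "LODGING")


@dataclass(frozen=True)
class ExtractionConfig:
    """Which blocks to extract and how."""

    texture_bands: tuple[str, ...] = ("R",)  # ("R","G","B") for the 135-variable block
    glcm: GLCMConfig = field(default_factory=GLCMConfig)
    egi_threshold: float = 0.05
    canopy_masked_vi: bool = False  # mask VI means to canopy pixels
    per_scene_band_maxima: bool = True  # normalize bands by scene (not block) maxima


@dataclass
class FeatureTable:
    """Plot x feature matrix with a feature -> group mapping."""

    data: pd.DataFrame  # index: plot_id
    groups: dict[str, str]
    date: int | None = None

    def columns_for(self, groups: tuple[str, ...] | list[str]) -> list[str]:
        wanted = set(groups)
        missing = wanted - set(self.groups.values())
        if missing:
            raise ConfigurationError(f"feature group(s) missing from table: {sorted(missing)}")
        return [c for c in self.data.columns if self.groups[c] in wanted]

    def subset(self, columns: list[str]) -> "FeatureTable":
        return FeatureTable(
            data=self.data[columns].copy(),
            groups={c: self.groups[c] for c in columns},
            date=self.date,
        )

    def drop_features(self, columns: list[str]) -> "FeatureTable":
        keep = [c for c in self.data.columns if c not in set(columns)]
        return self.subset(keep)

    @property
    def n_features(self) -> int:
        return self.data.shape[1]


def estimate_field_dem(
    early_scene: SceneStack, plots: list[PlotRecord]
) -> dict[str, float]:
    """Per-plot bare-ground elevation from the pre-emergence scene."""
    return {p.plot_id: estimate_bare_dem(early_scene, p) for p in plots}


def extract_scene_features(
    scene: SceneStack,
    plots: list[PlotRecord],
    dem: dict[str, float] | None = None,
    config: ExtractionConfig = ExtractionConfig(),
) -> FeatureTable:
    """Extract the full per-plot feature block for one acquisition date.

    ``dem`` maps plot_id to bare-ground elevation; when omitted the CHM/height
    block is skipped.  Lodging is taken from the plot records when present.
    """
    if not plots:
        raise FeatureError("no plots to extract")
    maxima = None
    if config.per_scene_band_maxima:
        maxima = tuple(float(scene.rgb[:, :, k].max()) for k in range(3))

    rows: list[dict[str, float]] = []
    groups: dict[str, str] = {}
    have_lodging = all(p.lodging is not None for p in plots)

    for plot in plots:
        block = clip_plot(scene, plot)
        feats: dict[str, float] = {}

        vi_cover, vi_mask = canopy_cover(block.rgb, threshold=config.egi_threshold)
        feats.update(
            plot_vi_features(
                block.rgb,
                maxima=maxima,
                mask=vi_mask if config.canopy_masked_vi else None,
            )
        )
        feats.update(plot_texture_features(block.rgb, bands=config.texture_bands, config=config.glcm))
        feats["canopy_cover"] = vi_cover
        if dem is not None:
            chm_block = np.maximum(block.dsm.astype(float) - dem[plot.plot_id], 0.0)
            height, _fallback = plot_height(chm_block, vi_mask)
            feats["plot_height"] = height
        if have_lodging:
            feats["lodging"] = float(plot.lodging)
        rows.append(feats)

    data = pd.DataFrame(rows, index=pd.Index([p.plot_id for p in plots], name="plot_id"))
    for c in data.columns:
        if c == "canopy_cover":
            groups[c] = "CC"
        elif c == "plot_height":
            groups[c] = "CHM"
        elif c == "lodging":
            groups[c] = "LODGING"
        elif any(c.startswith(f"{b}_") for b in ("R", "G", "B")) and c.count("_") >= 2:
            groups[c] = "TI"
        else:
            groups[c] = "VI"
    return FeatureTable(data=data, groups=groups, date=scene.date)


def features_long_format(table: FeatureTable) -> pd.DataFrame:
    """Long-format (plot_id, date, feature_name, feature_group, value)."""
    long = table.data.reset_index().melt(
        id_vars="plot_id", var_name="feature_name", value_name="value"
    )
    long.insert(1, "date", table.date)
    long.insert(3, "feature_group", long["feature_name"].map(table.groups))
    return long
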