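"""Synthetic multi-date soybean field generator.

No public imagery accompanies the analysis this package implements, so every
downstream stage is exercised on a simulated germplasm trial with the same
statistical structure: a grid of small two-row plots (defaults: 1,615 cultivar
plots + 190 control plots of 1.8 m x 0.8 m), a 17-date acquisition schedule at
a 3-day cadence, logistic canopy growth and plant-height curves driven by a
latent per-plot vigor, an ordinal lodging score increasing with final height,
and per-plant yield components (grain number, grain weight) generated by a
linear model on vigor, height and lodging.

Rendered scenes are registered RGB + DSM raster pairs.  Canopy pixels are
green-dominant (excess green index > 0.05 by construction), soil pixels are
soil-toned, and each plot carries a clipped constant-dark shadow band along
one edge — as underexposed 8-bit imagery does — so that window-texture
extrema behave like their real-field counterparts.  The first date is
pre-emergence and serves as the bare-ground elevation reference.

All randomness flows from a single integer seed; runs are bit-reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ConfigurationError
from .raster import GridTransform, PlotRecord, SceneStack, window_for_rect

# Palette: fixed base triplets with Gaussian jitter, chosen so the excess
# green index separates canopy from soil at the 0.05 threshold with margin.
SOIL_RGB = (135.0, 95.0, 80.0)
CANOPY_RGB = (55.0, 115.0, 45.0)
GAP_RGB = (45.0, 80.0, 40.0)  # shaded lower-canopy foliage inside a disordered stand
SHADOW_DN = 8  # clipped shadows: constant darkest DN in every band
SOIL_JITTER_SD = 3.0
CANOPY_GREEN_PER_VIGOR = 6.0  # DN of extra green per unit latent vigor
_MIN_LIT_DN = 16  # lit pixels never reach the shadow level

#: appearance traits drawn per plot, in order.  Canopy traits capture stand
#: evenness, streaking, gappiness, pigmentation and brightness; soil traits
#: capture the plot's background color (moisture / organic-matter gradients).
TRAIT_NAMES = (
    "uniformity",
    "streak",
    "gappiness",
    "pigment_red",
    "pigment_blue",
    "brightness",
    "soil_brightness",
    "soil_red",
    "soil_blue",
)


@dataclass(frozen=True)
class RenderStyle:
    """Appearance of the rendered canopy.

    Lodged canopies are visibly disordered — stems and soil glimpse through
    (``gap``), brightness streaks across the rows (``stripe``), and the
    speckle roughens — while vigorous, even stands look smoother.  These
    couplings give the texture block genuine predictive content, the way
    canopy texture reflects stand uniformity and lodging in real imagery.
    """

    canopy_jitter_sd: float = 6.0  # DN speckle inside the canopy
    jitter_per_lodging: float = 1.0  # extra speckle per lodging step
    jitter_per_uniformity: float = -1.5  # even stands are smoother
    gap_base: float = 0.02  # canopy gap fraction at upright, average gappiness
    gap_per_lodging: float = 0.05  # extra gaps per lodging step
    gap_per_gappiness: float = 0.02
    stripe_amp_base: float = 2.0  # DN amplitude of row-wise streaking
    stripe_amp_per_lodging: float = 2.0
    stripe_amp_per_streak: float = 1.5
    stripe_period_px: float = 6.0
    pigment_red_shift: float = 4.0  # DN of red per unit red-pigment trait
    pigment_blue_shift: float = 3.0  # DN of blue per unit blue-pigment trait
    brightness_shift: float = 3.0  # DN on all bands per unit brightness trait
    soil_brightness_shift: float = 4.0  # DN on all soil bands
    soil_red_shift: float = 4.0  # DN on the soil red band
    soil_blue_shift: float = 3.0  # DN on the soil blue band
    plot_color_sd: float = 1.0  # residual per-plot color wobble (R and B)


@dataclass(frozen=True)
class FieldDesign:
    """Geometry and schedule of the simulated trial."""

    n_cultivar_plots: int = 1615
    n_control_plots: int = 190
    plot_length: float = 1.8  # m, along-row (map y)
    plot_width: float = 0.8  # m, across-row (map x)
    ground_sampling_distance: float = 0.025  # m / pixel
    furrow_gap: float = 0.4  # m between plot columns
    end_gap: float = 0.4  # m between plot ends
    days_after_sowing: tuple[int, ...] = tuple(range(6, 55, 3))
    base_elevation: float = 22.0  # m, flat field
    dsm_noise_sd: float = 0.02  # m, photogrammetric surface noise
    canopy_dsm_noise_sd: float = 0.03  # m, within-canopy height variation
    shadow_width: float = 0.075  # m, clipped shadow band inside each plot
    scene_pad: float = 0.6  # m of bare soil around the field

    def __post_init__(self) -> None:
        if self.n_cultivar_plots < 0 or self.n_control_plots < 0:
            raise ConfigurationError("plot counts must be non-negative")
        if self.n_cultivar_plots + self.n_control_plots < 1:
            raise ConfigurationError("design must contain at least one plot")
        if self.ground_sampling_distance <= 0:
            raise ConfigurationError("ground sampling distance must be positive")
        if self.plot_length <= 0 or self.plot_width <= 0:
            raise ConfigurationError("plot dimensions must be positive")
        days = self.days_after_sowing
        if len(days) < 1 or any(b <= a for a, b in zip(days, days[1:])):
            raise ConfigurationError("days_after_sowing must be strictly increasing")

    @property
    def n_dates(self) -> int:
        return len(self.days_after_sowing)

    @property
    def n_plots(self) -> int:
        return self.n_cultivar_plots + self.n_control_plots


@dataclass(frozen=True)
class GrowthParams:
    """Generative parameters for growth, lodging and yield components.

    Yield components follow, per plot i with latent vigor v_i ~ N(0, vigor_sd),
    final height h_i (m) and lodging level l_i in 1..5::

        grain_number_i = a0 + a1 v_i + a2 h_i + a3 (l_i - 1) + eps_i,  >= 0

    and analogously for grain weight.  Default intercepts put the population
    means near 59.3 seeds/plant and 9.26 g/plant with coefficients of
    variation around 40-45%.  The lodging coefficient is negative: lodging
    depresses yield.  The lodging marginal defaults to 50/20/12/10/8% across
    levels 1..5, skewed toward upright stands.
    """

    vigor_sd: float = 1.0
    # appearance traits (unit-normal latents), each visible through a distinct
    # image channel and each loading modestly on yield: stand evenness
    # (speckle), canopy streaking, within-canopy gappiness, red/blue pigment
    # balance, and overall canopy brightness
    trait_sd: float = 1.0
    # canopy cover logistic: fraction(t) = A / (1 + exp(-k (t - t0)))
    canopy_asymptote_base: float = 0.80
    canopy_asymptote_vigor: float = 0.10
    canopy_asymptote_max: float = 0.88  # furrow-edge soil keeps cover below 1
    canopy_midpoint_day: float = 30.0
    canopy_midpoint_vigor: float = -3.0  # vigorous plots close canopy earlier
    canopy_rate: float = 0.22  # 1/day
    # plant height logistic: h(t) = Hmax / (1 + exp(-k (t - t0)))
    height_max_base: float = 0.90  # m
    height_max_vigor: float = 0.18  # m per unit vigor
    height_max_sd: float = 0.15  # m residual spread across cultivars
    height_midpoint_day: float = 28.0
    height_rate: float = 0.20  # 1/day
    # ordinal lodging: latent = slope * standardized(Hmax) + N(0,1), cut to marginal
    lodging_height_slope: float = 1.8
    lodging_marginal: tuple[float, ...] = (0.50, 0.20, 0.12, 0.10, 0.08)
    # yield linear models: (intercept, vigor, height, lodging-step); height is
    # a strong determinant (node number scales with stature)
    grain_number_coef: tuple[float, float, float, float] = (30.0, 17.0, 40.0, -6.0)
    # appearance-trait loadings, ordered as TRAIT_NAMES: physiological and
    # site proxies (soil color tracks moisture / fertility) with modest effects
    grain_number_traits: tuple[float, ...] = (6.0, -4.0, -4.0, 4.0, 3.0, 3.0, 3.0, -2.5, 2.0)
    grain_number_noise_sd: float = 13.0
    grain_weight_coef: tuple[float, float, float, float] = (5.0, 2.8, 6.0, -1.0)
    grain_weight_traits: tuple[float, ...] = (1.0, -0.6, -0.6, 0.6, 0.45, 0.45, 0.45, -0.4, 0.3)
    grain_weight_noise_sd: float = 1.9

    def __post_init__(self) -> None:
        if not (0 < self.canopy_asymptote_max <= 1):
            raise ConfigurationError("canopy asymptote must lie in (0, 1]")
        if self.height_max_base < 0:
            raise ConfigurationError("heights must be non-negative")
        if self.grain_number_coef[3] > 0 or self.grain_weight_coef[3] > 0:
            raise ConfigurationError("lodging coefficient must be <= 0 (lodging depresses yield)")
        if self.grain_number_noise_sd < 0 or self.grain_weight_noise_sd < 0:
            raise ConfigurationError("noise sd must be non-negative")
        if len(self.lodging_marginal) != 5 or abs(sum(self.lodging_marginal) - 1) > 1e-9:
            raise ConfigurationError("lodging marginal must be 5 probabilities summing to 1")


@dataclass
class PlotTruth:
    """Generative ground truth for one plot."""

    plot_id: str
    vigor: float
    traits: dict[str, float]  # uniformity, streak, gappiness, pigment_red,
    # pigment_blue, brightness
    canopy_fraction: np.ndarray  # per date, in [0, 1]
    height: np.ndarray  # per date, meters
    lodging: int  # 1..5
    grain_number: float  # seeds / plant
    grain_weight: float  # g / plant


def generate_layout(design: FieldDesign) -> list[PlotRecord]:
    """Lay the plots out on a near-square grid of exact rectangles.

    Control plots are interleaved at a regular stride, mimicking scattered
    check plots.  The layout is purely geometric and seed-independent.
    """
    total = design.n_plots
    pitch_x = design.plot_width + design.furrow_gap
    pitch_y = design.plot_length + design.end_gap
    n_cols = max(1, round(np.sqrt(total * pitch_y / pitch_x)))
    control_stride = total // design.n_control_plots if design.n_control_plots else 0

    plots: list[PlotRecord] = []
    n_control_assigned = 0
    n_cultivar_assigned = 0
    for idx in range(total):
        r, c = divmod(idx, n_cols)
        xmin = c * pitch_x
        ymin = r * pitch_y
        is_control = (
            design.n_control_plots > 0
            and n_control_assigned < design.n_control_plots
            and (idx % control_stride == control_stride - 1 if control_stride else True)
        )
        if is_control:
            n_control_assigned += 1
            cultivar = f"CK{(n_control_assigned - 1) % 30 + 1:02d}"
        else:
            n_cultivar_assigned += 1
            cultivar = f"C{n_cultivar_assigned:04d}"
        plots.append(
            PlotRecord(
                plot_id=f"P{idx + 1:04d}",
                cultivar_id=cultivar,
                rect=(xmin, ymin, xmin + design.plot_width, ymin + design.plot_length),
            )
        )
    # any shortfall of controls (rounding of the stride) is filled from the tail
    i = total - 1
    while n_control_assigned < design.n_control_plots:
        if not plots[i].cultivar_id.startswith("CK"):
            n_control_assigned += 1
            plots[i] = dataclasses.replace(
                plots[i], cultivar_id=f"CK{(n_control_assigned - 1) % 30 + 1:02d}"
            )
        i -= 1
    return plots


def _logistic(t: np.ndarray, mid: np.ndarray, rate: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-rate * (t - mid)))


def simulate_truth(
    layout: list[PlotRecord],
    params: GrowthParams = GrowthParams(),
    seed: int = 0,
    days: tuple[int, ...] = FieldDesign().days_after_sowing,
) -> list[PlotTruth]:
    """Draw per-plot vigor, growth curves, lodging and yield components."""
    if not layout:
        raise ConfigurationError("layout is empty")
    n = len(layout)
    rng = np.random.default_rng([int(seed), 1])
    t = np.asarray(days, dtype=float)

    v = rng.normal(0.0, params.vigor_sd, n)
    traits = rng.normal(0.0, params.trait_sd, (n, len(TRAIT_NAMES)))
    asym = np.clip(
        params.canopy_asymptote_base + params.canopy_asymptote_vigor * v,
        0.15,
        params.canopy_asymptote_max,
    )
    mid = np.clip(params.canopy_midpoint_day + params.canopy_midpoint_vigor * v, 10.0, 45.0)
    canopy = asym[:, None] * _logistic(t[None, :], mid[:, None], params.canopy_rate)

    hmax = np.clip(
        params.height_max_base
        + params.height_max_vigor * v
        + rng.normal(0.0, params.height_max_sd, n),
        0.2,
        None,
    )
    height = hmax[:, None] * _logistic(
        t[None, :], np.full((n, 1), params.height_midpoint_day), params.height_rate
    )

    # ordinal lodging, increasing with final height; cutpoints are the normal
    # quantiles of the configured marginal under the latent's analytic scale
    h_sd = np.sqrt(
        (params.height_max_vigor * params.vigor_sd) ** 2 + params.height_max_sd**2
    )
    z_h = (hmax - params.height_max_base) / max(h_sd, 1e-12)
    latent = params.lodging_height_slope * z_h + rng.normal(0.0, 1.0, n)
    latent_sd = np.sqrt(params.lodging_height_slope**2 + 1.0)
    cuts = norm.ppf(np.cumsum(params.lodging_marginal)[:4]) * latent_sd
    lodging = 1 + (latent[:, None] > cuts[None, :]).sum(axis=1)

    h_final = height[:, -1]
    a = params.grain_number_coef
    gn = (
        a[0]
        + a[1] * v
        + a[2] * h_final
        + a[3] * (lodging - 1)
        + traits @ np.asarray(params.grain_number_traits)
    )
    if params.grain_number_noise_sd > 0:
        gn = gn + rng.normal(0.0, params.grain_number_noise_sd, n)
    b = params.grain_weight_coef
    gw = (
        b[0]
        + b[1] * v
        + b[2] * h_final
        + b[3] * (lodging - 1)
        + traits @ np.asarray(params.grain_weight_traits)
    )
    if params.grain_weight_noise_sd > 0:
        gw = gw + rng.normal(0.0, params.grain_weight_noise_sd, n)
    gn = np.maximum(gn, 0.0)
    gw = np.maximum(gw, 0.0)

    return [
        PlotTruth(
            plot_id=layout[i].plot_id,
            vigor=float(v[i]),
            traits=dict(zip(TRAIT_NAMES, traits[i].tolist())),
            canopy_fraction=canopy[i].copy(),
            height=height[i].copy(),
            lodging=int(lodging[i]),
            grain_number=float(gn[i]),
            grain_weight=float(gw[i]),
        )
        for i in range(n)
    ]


def attach_truth(layout: list[PlotRecord], truth: list[PlotTruth]) -> list[PlotRecord]:
    """Return plot records with lodging and yield components filled in."""
    by_id = {t.plot_id: t for t in truth}
    return [
        dataclasses.replace(
            p,
            lodging=by_id[p.plot_id].lodging,
            grain_number=by_id[p.plot_id].grain_number,
            grain_weight=by_id[p.plot_id].grain_weight,
        )
        for p in layout
    ]


def ground_table(layout: list[PlotRecord], truth: list[PlotTruth]) -> pd.DataFrame:
    """Per-plot ground observations (lodging level + yield components)."""
    return pd.DataFrame(
        {
            "plot_id": [t.plot_id for t in truth],
            "lodging": [t.lodging for t in truth],
            "grain_number": [t.grain_number for t in truth],
            "grain_weight": [t.grain_weight for t in truth],
        }
    ).set_index("plot_id")


def _scene_grid(layout: list[PlotRecord], design: FieldDesign) -> tuple[GridTransform, int, int]:
    gsd = design.ground_sampling_distance
    xmin = min(p.rect[0] for p in layout) - design.scene_pad
    xmax = max(p.rect[2] for p in layout) + design.scene_pad
    ymin = min(p.rect[1] for p in layout) - design.scene_pad
    ymax = max(p.rect[3] for p in layout) + design.scene_pad
    w = int(np.ceil((xmax - xmin) / gsd))
    h = int(np.ceil((ymax - ymin) / gsd))
    return GridTransform(x0=xmin, y0=ymax, sx=gsd, sy=gsd), h, w


def render_scene(
    layout: list[PlotRecord],
    truth: list[PlotTruth],
    date: int,
    design: FieldDesign,
    seed: int = 0,
    style: RenderStyle = RenderStyle(),
) -> SceneStack:
    """Render the registered RGB + DSM raster pair for one acquisition date.

    Within each plot the canopy mask is grown outward from the two row
    centerlines with jittered edges, so its pixel count equals the plot's
    canopy fraction to within one pixel of rounding.  Canopy pixels receive
    the canopy palette (greener with vigor) and a raised DSM; remaining soil
    keeps the bare elevation, with a constant clipped shadow band along the
    plot's left edge.
    """
    if date not in design.days_after_sowing:
        raise ConfigurationError(
            f"date {date} is not in the acquisition schedule {design.days_after_sowing}"
        )
    d_idx = design.days_after_sowing.index(date)
    rng = np.random.default_rng([int(seed), 2, int(date)])
    transform, h, w = _scene_grid(layout, design)
    gsd = design.ground_sampling_distance

    rgb = np.empty((h, w, 3), dtype=np.float32)
    for band, base in enumerate(SOIL_RGB):
        rgb[:, :, band] = base
    rgb += rng.normal(0.0, SOIL_JITTER_SD, (h, w, 3)).astype(np.float32)
    dsm = design.base_elevation + rng.normal(0.0, design.dsm_noise_sd, (h, w)).astype(np.float32)

    truth_by_id = {t.plot_id: t for t in truth}
    for plot in layout:
        t = truth_by_id[plot.plot_id]
        row0, row1, col0, col1 = window_for_rect(transform, (h, w), plot.rect)
        ph, pw = row1 - row0, col1 - col0
        if ph <= 0 or pw <= 0:
            continue
        n_pix = ph * pw
        frac = float(np.clip(t.canopy_fraction[d_idx], 0.0, 1.0))
        n_canopy = int(round(frac * n_pix))

        # local across-row coordinate of each pixel center, from the plot's left edge
        lx = (np.arange(col0, col1) + 0.5) * gsd + transform.x0 - plot.rect[0]
        row_lines = (0.25 * design.plot_width, 0.75 * design.plot_width)
        dist = np.minimum(np.abs(lx - row_lines[0]), np.abs(lx - row_lines[1]))
        dist2d = np.broadcast_to(dist[None, :], (ph, pw))
        ragged = dist2d + rng.uniform(0.0, 0.08, (ph, pw))
        # the shaded furrow edge stays bare: canopy grows over it last, and the
        # generator's canopy asymptote keeps demand below the remaining area
        in_shadow_band = np.broadcast_to(lx[None, :], (ph, pw)) < design.shadow_width
        ragged = np.where(in_shadow_band, np.inf, ragged)
        order = np.argsort(ragged.ravel(), kind="stable")
        canopy = np.zeros(n_pix, dtype=bool)
        canopy[order[:n_canopy]] = True
        canopy = canopy.reshape(ph, pw)

        shadow = (~canopy) & in_shadow_band

        block = rgb[row0:row1, col0:col1]
        tr = t.traits
        # the plot's soil background carries its own color gradient
        soil_mask = (~canopy) & (~in_shadow_band)
        if soil_mask.any():
            sb = style.soil_brightness_shift * tr["soil_brightness"]
            block[soil_mask] += np.asarray(
                [
                    sb + style.soil_red_shift * tr["soil_red"],
                    sb,
                    sb + style.soil_blue_shift * tr["soil_blue"],
                ],
                dtype=np.float32,
            )
        n_c = int(canopy.sum())
        if n_c:
            lodging_step = t.lodging - 1
            bright = style.brightness_shift * tr["brightness"]
            green = CANOPY_RGB[1] + CANOPY_GREEN_PER_VIGOR * t.vigor + bright
            wobble_r, wobble_b = rng.normal(0.0, style.plot_color_sd, 2)
            shift_r = style.pigment_red_shift * tr["pigment_red"] + bright + wobble_r
            shift_b = style.pigment_blue_shift * tr["pigment_blue"] + bright + wobble_b
            jitter_sd = float(
                np.clip(
                    style.canopy_jitter_sd
                    + style.jitter_per_lodging * lodging_step
                    + style.jitter_per_uniformity * tr["uniformity"],
                    2.0,
                    12.0,
                )
            )
            cano = np.stack(
                [
                    np.full(n_c, CANOPY_RGB[0] + shift_r, dtype=np.float32),
                    np.full(n_c, green, dtype=np.float32),
                    np.full(n_c, CANOPY_RGB[2] + shift_b, dtype=np.float32),
                ],
                axis=1,
            )
            cano += rng.normal(0.0, jitter_sd, (n_c, 3)).astype(np.float32)
            # row-wise brightness streaking, stronger in lodged/streaky canopies
            amp = max(
                style.stripe_amp_base
                + style.stripe_amp_per_lodging * lodging_step
                + style.stripe_amp_per_streak * tr["streak"],
                0.0,
            )
            phase = rng.uniform(0.0, 2 * np.pi)
            stripe = amp * np.sin(
                2 * np.pi * np.arange(ph, dtype=np.float32) / style.stripe_period_px + phase
            )
            cano += stripe[np.nonzero(canopy)[0], None]
            # shaded lower foliage glimpsing through a disordered canopy
            gap_p = float(
                np.clip(
                    style.gap_base
                    + style.gap_per_lodging * lodging_step
                    + style.gap_per_gappiness * tr["gappiness"],
                    0.0,
                    0.5,
                )
            )
            if gap_p > 0:
                gaps = rng.random(n_c) < gap_p
                n_g = int(gaps.sum())
                if n_g:
                    cano[gaps] = np.asarray(GAP_RGB, dtype=np.float32)[None, :] + rng.normal(
                        0.0, SOIL_JITTER_SD, (n_g, 3)
                    ).astype(np.float32)
            block[canopy] = cano
            dsm_block = dsm[row0:row1, col0:col1]
            dsm_block[canopy] = (
                design.base_elevation
                + t.height[d_idx]
                + rng.normal(0.0, design.canopy_dsm_noise_sd, n_c).astype(np.float32)
            )
        np.clip(block, _MIN_LIT_DN, 255, out=block)
        block[shadow] = SHADOW_DN

    rgb8 = np.clip(np.rint(rgb), 0, 255).astype(np.uint8)
    # lit pixels outside plots may round below the floor; shadows stay darkest
    return SceneStack(date=date, rgb=rgb8, dsm=dsm, transform=transform)


def simulate_season(
    design: FieldDesign = FieldDesign(),
    params: GrowthParams = GrowthParams(),
    seed: int = 0,
    dates: tuple[int, ...] | None = None,
) -> tuple[list[PlotRecord], list[PlotTruth], dict[int, SceneStack]]:
    """Generate layout, truth and rendered scenes for the requested dates.

    Returns plot records with ground observations attached.  ``dates``
    defaults to the full acquisition schedule.
    """
    layout = generate_layout(design)
    truth = simulate_truth(layout, params, seed=seed, days=design.days_after_sowing)
    plots = attach_truth(layout, truth)
    scenes = {
        d: render_scene(plots, truth, d, design, seed=seed)
        for d in (dates if dates is not None else design.days_after_sowing)
    }
    return plots, truth, scenes
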