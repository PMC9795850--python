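# Methods

`uavyield` re-creates, end to end, a plot-level phenotyping analysis for a
large soybean germplasm trial observed by a UAV RGB camera: per-plot spectral,
structural and textural features are extracted from registered
orthomosaic/DSM raster pairs across a season of acquisition dates, screened,
and used to estimate two per-plant yield components — grain number and grain
weight — under lodging. Because no public imagery accompanies analyses of
this kind, the package ships a synthetic-field generator that produces
registered scenes and ground truth with the statistical structure the
analysis assumes; every downstream stage is exercised against that generator.

## The synthetic trial

**Layout.** A near-square grid of 1,805 two-row plots (1,615 cultivar + 190
control entries), each exactly 1.8 m × 0.8 m, separated by 0.4 m furrow and
end gaps. Geometry is deterministic; reduced fields for fast experiments
simply use smaller counts.

**Growth.** Each plot carries a latent vigor v ~ N(0, 1). Canopy cover
follows a logistic curve with vigor-dependent asymptote (clipped at 0.88 —
furrow-edge soil keeps a plot from reading 100%) and midpoint; plant height
follows a logistic toward a maximum 0.90 + 0.18 v + N(0, 0.15) m. The
acquisition schedule is 17 dates at a 3-day cadence (days 6–54 after sowing);
the first date is pre-emergence and doubles as the bare-ground reference.

**Lodging.** An ordinal score 1 (all upright) … 5 (all lodged) is drawn from
a latent `1.8 · standardized(height) + N(0,1)` cut at the quantiles of the
configured marginal (default 50/20/12/10/8% — lodging is the minority
condition). Taller stands lodge more, which couples lodging to everything
the camera sees.

**Yield components.** For plot i,

    grain_number_i = 30 + 17 v_i + 40 h_i − 6 (l_i − 1) + Σ_k c_k t_{ik} + ε_i

truncated at zero, and analogously for grain weight (intercept 5.0, height
slope 6.0, lodging −1.0, noise 1.9). t_{ik} are nine unit-normal appearance
traits (below) with modest loadings. Defaults put the population means near
59.3 seeds/plant and 9.26 g/plant with coefficients of variation of ≈ 42%,
the moments a field of this diversity shows. The lodging coefficient is
constrained ≤ 0.

**Appearance traits.** Real canopies expose yield-relevant information
through more channels than mean greenness; the renderer gives each feature
family its own channel. Per plot: stand evenness (canopy speckle
amplitude), streaking (row-wise brightness waves, amplified by lodging),
gappiness (shaded lower foliage glimpsing through a disordered stand, also
amplified by lodging), red/blue pigment balance, canopy brightness, and
three soil-background colors (brightness/red/blue — moisture and
organic-matter gradients). Each trait loads modestly on yield, so texture,
band-ratio and soil-sensitive features all carry genuine, partially
independent signal — the premise under which all-relevant feature screening
is meaningful.

**Rendering.** Canopy masks grow outward from the two row centerlines with
jittered edges until the pixel count matches the plot's canopy fraction
(±1 pixel); canopy pixels are green-dominant (excess green index > 0.05 by
construction with wide margin), soil is soil-toned and robustly below the
threshold, and a 7.5 cm shadow band along each plot's furrow edge is rendered
as a constant darkest DN — as clipped, underexposed shadows in 8-bit imagery
are. The DSM is a flat 22 m base plus canopy height over canopy pixels, with
2 cm surface noise (3 cm within canopies). All randomness descends from one
integer seed; renders are bit-reproducible.

The constant shadow band has a deliberate consequence: within every plot at
least one 3×3 window is constant at the minimum gray level, which pins nine
of the 45 per-band texture statistics (the min of mean, variance, contrast,
dissimilarity, entropy and autocorrelation; the max of homogeneity, energy
and correlation) to the same degenerate value in every plot. These nine
zero-information columns are exactly what the shadow screen must reject —
the synthetic counterpart of the min/max texture features rejected on real
fields.

**What the generator does not emulate.** Registration error, BRDF and
illumination drift between dates, weeds, mixed boundary pixels, perspective
and stitching artifacts, and — importantly — the feature diversity of real
vegetation: all 24 vegetation indices of a rendered scene are deterministic
functions of a handful of latent color dimensions, so they are far more
mutually collinear than on a real field (see *Screening behavior* below).
Passing tests therefore demonstrate the correctness and statistical behavior
of the pipeline, not field-ready accuracy figures.

## Feature extraction

**Clipping.** Plots are axis-aligned rectangles; a plot's block is every
pixel whose center falls in the rectangle, half-open windows, 0-based
row-major pixel coordinates with the origin at the top-left. A 1.8 × 0.8 m
plot at 0.01 m GSD is exactly 180 × 80 pixels.

**Spectral block (24 "VI" features).** Raw band means (R, G, B), per-scene
maximum-normalized bands (Rn, Gn, Bn), chromatic coordinates (r, g, b; they
sum to 1 per pixel), and 15 named visible-band vegetation indices (CIVE,
COMB1, COMB2, ExG, EXGR, GRI, GRVI, MGRVI, PPRb, RGBVI, SAVI, VARI, VDVI,
VEG, WI), evaluated per pixel in their standard literature forms — capital-letter formulas
on raw DN, lower-case on chromatic coordinates — and averaged over all valid
plot pixels. All-black pixels are excluded; pixels where a formula is
undefined (WI at r = g, VEG at r·b = 0, zero denominators) are dropped from
that index's mean. Canopy-masked aggregation is available behind a flag.

**Canopy cover.** Fraction of plot pixels with excess green index
EGI = (2G − R − B)/G above 0.05; G = 0 pixels are soil. The binary mask also
serves the height block.

**Height block.** The bare-ground DEM is one value per plot, estimated from
the pre-emergence scene by Otsu-splitting the plot's DSM heights (256-bin
histogram over the plot's range) and averaging the lower class; near-constant
plots (< 5 cm range) short-circuit to the plot mean. CHM = DSM − DEM with
negatives clipped to zero, and plot height is the canopy-masked mean CHM
(90th-percentile and plain-mean variants configurable; the plain mean is the
fallback at zero coverage, flagged).

**Texture block (45 per band).** Each band is quantized to 32 gray levels
over its plot range; a symmetric gray-level co-occurrence matrix is pooled
over the four unit-distance orientations inside every interior 3×3 window;
nine metrics (mean, variance, homogeneity, contrast, dissimilarity, entropy,
energy, correlation, autocorrelation — standard definitions, natural-log
entropy, correlation := 1 for constant windows) are summarized over windows
by mean, min, max, SD and CV (CV undefined at zero mean). Windows are fully
interior — padding would fabricate co-occurrences. The red band alone gives
the 45-variable modeling block; all three bands give 135. The production
path enumerates pair codes for all windows at once and is verified against a
per-window brute-force oracle.

The day-48 candidate inventory is 24 VI + 45 red-band TI + canopy cover +
plot height + lodging = 72 columns; with three texture bands a date carries
162 columns.

## Screening

**Shadow screen.** The candidate matrix (lodging and canopy cover stand
aside and are always kept) is augmented with one row-permuted shadow copy of
every column; a regression random forest (100 bagged trees, one-third of
features per split, node size 5) is fitted and every column scored by
out-of-bag permutation importance — the mean increase of a tree's OOB squared
error when the column is permuted on that tree's OOB rows (a Z-scored variant
is available). Over 100 independent rounds, a feature whose importance falls
below the round's *best shadow* in ≥ 80 rounds is removed. Constant columns
score exactly zero and are always removed; planted pure-noise columns are
removed with wide margins while informative ones are kept (verified over
master seeds).

**Screening behavior on the synthetic field.** The nine degenerate texture
extrema are rejected in 100/100 rounds, reproducing the qualitative outcome
the rule is meant to produce. Because a rendered field's vegetation indices
are nearly perfect mutual substitutes, the forest additionally dilutes the
importance of weaker collinear variants below the best-shadow bar, so the
screen on synthetic scenes removes more than the nine degenerate columns.
This is a property of synthetic imagery, not of the implementation: softer
bars (shadow mean or percentiles) that would keep the collinear variants
were evaluated and rejected because they break the screen's type-I behavior
on planted noise. Downstream bookkeeping (the ablation ladder) therefore
operates on whatever set the screen actually keeps.

**Row filtering.** Before the train/validation split, a radial-basis
one-class SVM (gamma 0.001, nu 0.03, tolerance 1e-3) fitted on standardized
features flags rows outside the learned boundary; with the default nu the
flagged fraction on clean data is ≈ 3%. Standardization is essential: a
fixed gamma of 0.001 is meaningless across raw feature scales.

## Models and evaluation

Plots are split 70/30 by plot (floor on the training size; 1,805 plots give
1,263/542), reproducibly from a seed. Features are standardized with
training-set statistics only. Five families with fixed reference hyperparameters:

* partial least squares, ≤ 5 components chosen by leave-one-out CV;
* L1-penalized linear regression over a 10-fold cross-validated
  regularization path (the continuous-target analogue of a lambda-path
  penalized GLM — the targets are continuous, so a logistic likelihood does
  not apply);
* random forest, 500 trees, mtry = p/3;
* RBF support-vector regression, gamma = 1/p, epsilon 0.01, tolerance 1e-3;
* a two-hidden-layer (200 + 200) network trained 10 epochs by SGD at
  learning rate 0.005 ("iterations" read as epochs).

Internally every fit standardizes the response and back-transforms its
predictions — the identity for the scale-free fits, and the default
behavior of the reference SVM and deep-learning tools, without which the
fixed C = 1 / epsilon = 0.01 SVR and the fixed-rate SGD network are
ill-conditioned on targets with natural scales of tens of seeds.

Metrics: R² = 1 − SSres/SStot, RMSE, and rRMSE = 100·RMSE/mean(observed)
(flagged undefined at zero mean). rRMSE/RMSE = 100/mean(observed) exactly.
Note the fixed reference hyperparameters leave the SVR and the 10-epoch
network short of interpolation even on noiseless linear targets; the tests
assert the floors the architectures actually reach rather than a universal
near-1 training fit.

## Experiments

**Ablation ladder.** Nested feature sets VIs → +TI → +CC → +CHM → +Lodging
(each step adds one group of the post-screening table), all five methods,
both yield components. On the default synthetic season the training R² is
non-decreasing across the ladder for at least four of five methods, and the
full fused set beats the spectral-only set for most methods — lodging and
height carry real, partially image-invisible signal.

**Date sweep.** Per-date extraction (all-band texture, 162 columns) and
modeling for every acquisition date; the best date per target is the argmax
of the method-averaged validation R². Pre-emergence dates carry almost no
canopy signal and never win; the best date falls in the canopy plateau.

## Numerical choices and problem sizes

Degenerate branches: Otsu short-circuits below 5 cm height range; GLCM
correlation is 1 when the window variance ≤ 1e-12; CV is NaN at zero mean;
WI/VEG/VARI pixels with vanishing denominators are excluded rather than
clipped. Boundary arithmetic in clipping is snapped at 1e-9 so grid-aligned
rectangles give exact block sizes. An unreachable removal cutoff
(cutoff > rounds) is a configuration error.

Tests and the acceptance script run on reduced problem sizes chosen as the
package's own defaults for desk-scale verification: a 300-plot field (the
full 1,805-plot layout and truth tables are still generated where only
geometry/moments matter), two rendered dates for the modeling pipeline,
three dates and a 60-plot field for the sweep, and a 0.025 m GSD (72 × 32
pixel plots). The statistical properties asserted (round-trip accuracy,
screening power, ladder monotonicity) are scale-robust at these sizes.

## Known limitations

* Synthetic imagery cannot reproduce real-data accuracy figures; validation
  R² values here characterize the generator, not soybean fields.
* The vegetation-index block of a rendered scene is low-rank, so the shadow
  screen is harsher on collinear index variants than it is on real fields
  (see *Screening behavior*).
* One plot-geometry table is assumed for all dates (no per-date re-masking).
* Orthomosaic stitching, georeferencing and point-cloud photogrammetry are
  upstream of this package; scenes arrive registered.
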