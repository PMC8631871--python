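# Methods

This note records the models, conventions, parameter defaults and design
choices behind `phenoforecast`, and what the synthetic-data experiments do
and do not demonstrate.

## Time model

Captures are hourly within a 12-hour photoperiod (08:00–19:00), 10–23 days
after sowing (DAS), indexed by a 1-based step 1..165. Decimal DAS appends
the capture hour over 24 (23 DAS at 17:00 → 23.71). Night gaps are absent by
construction: horizons and lags count *measured* steps, so 12 measured hours
≡ 1 day. The six training/testing windows are stored verbatim as step
anchors:

| window | train steps | test steps |
|--------|-------------|------------|
| T1 | 60–140 (15–21 DAS) | 141–165 |
| T2 | 72–140 | 141–165 |
| T3 | 84–140 (17–21 DAS) | 141–165 |
| T4 | 96–140 | 141–165 |
| T5 | 72–127 (16–20 DAS) | 128–165 |
| T6 | 84–127 | 128–165 |

Published anchor tables of this kind are not exactly reconstructible from a
uniform grid formula (e.g. 14 days × 12 steps = 168 ≠ 165), so the anchors
are constants and the grid formula timestamps only synthetic data. The
validation checkpoint defaults to the last measured step (165), the time of
flower-bud formation when the forecast matters most.

## Synthetic-data generator

The generator emulates the statistical structure a rosette HTPP experiment
produces; it is the substrate for every test.

**Growth curves.** Per-plant logistic PA trajectories
`PA(t) = K / (1 + exp(−r (t − t0)))` evaluated at daylight steps, with
per-plant draws K ~ N(1000, 200²) area units (truncated ≥ 300),
r ~ N(0.9, 0.15²) /day (≥ 0.3), t0 ~ N(16, 1.5²) DAS (12–20), and
multiplicative measurement noise (1 + ε), ε ~ N(0, 0.03²). PA units are
arbitrary "area units" — no canonical physical unit exists for projected
area, and all errors are reported on the same scale. Convex-hull area is
PA divided by a per-plant true solidity ~ U(0.6, 1.0]; perimeter is a
per-plant shape factor (~N(4.5, 0.3), ≥ 3.6 = slightly above the disc value
2√π) times √PA. Negative noise draws are clipped to zero and logged. A
degenerate linear law (`linear_config`) exists for exact-recovery tests:
PA affine in decimal DAS, noiseless.

**Rosette rendering.** A rosette is a union of `n_leaves` ellipses placed at
the golden phyllotaxis angle (137.5°) with mildly increasing leaf length;
leaf scale is solved by bisection so the rasterized mask hits the target PA
within 5% (an unreachable target raises rather than undershooting
silently). RGB crops draw the mask in green hues over a smoothed-noise brown
soil texture. Rendering is photometrically simple on purpose: no venation,
shadows, specularity or leaf overlap with neighbours — so segmentation
results on synthetic crops bound the *machinery*, not real-image difficulty.

**Trays.** Crops are pasted row-major into an `rows × cols` grid inside a
margin; four red discs are stamped at the margin corners; the whole tray is
warped by a known 3×3 homography (random warps displace tray corners by up
to 2% of the diagonal — the stated perspective strength for the recovery
guarantees). Ground truth (per-cell masks, marker centers, warped marker
centers) is stored alongside. Marker colors that read as green are rejected
to avoid colliding with plant foreground.

**Fresh weight.** Linear allometry FW = 0.15·PA + 5 + ε mg, ε ~ N(0, 5²),
matching the strongly linear, high-rank-correlation PA–FW relation reported
for rosettes; a power-law form is available behind a flag for sensitivity
checks. Harvests are destructive: a harvested plant emits no later records.

## Segmentation metrics and losses

Hard metrics operate on binary masks via pixel confusion counts:
IoU = TP/(TP+FP+FN), precision, recall, and
Fβ = (1+β²)PR/(β²P+R) with β = 1 by default. Two empty masks have IoU 1
(both agree there is no plant; logged). F1 and IoU satisfy
F1 = 2·IoU/(1+IoU) exactly, which the tests assert.

Training losses are soft variants on the probability map: dice loss is
1 − Fβ with soft counts (probabilities replacing indicators), focal loss is
the mean of −α_t (1−p_t)^γ log p_t with p_t = p for foreground pixels and
1−p otherwise, α = 0.25, γ = 2. The α weight follows the class-balanced
convention (α foreground, 1−α background); an unbalanced form (constant α)
is exposed, in which γ = 0, α = 1 reduces exactly to mean cross-entropy.
The combined training loss is their exact sum. Probabilities are clipped at
1e−7 before logs.

The trainable harness is a deliberately small encoder–decoder: a 3×3-patch
feature encoder (27 inputs per pixel) feeding a 16-unit hidden layer and a
sigmoid pixel head, trained full-image by Adam (lr 0.05) on the combined
loss with analytic gradients (verified against finite differences in the
tests). It trains in seconds on one CPU and separates green-on-soil
synthetic crops nearly perfectly; it is a harness for testing the
loss/split/logging protocol, not a competitor to large pretrained
backbones, which are out of scope.

Mask refinement is deterministic: threshold at 0.5, remove connected
components below a minimum area, fill holes below a maximum area. It is
idempotent and sits behind a plain `array → bool array` contract so a dense
CRF (for which no canonical parameterization exists) can be substituted.

## Shape features

Raster measures differ by convention, so the conventions are fixed and
stated: PA is the foreground pixel count (optionally × a mm²/px scale);
convex-hull area is the pixel count of the rasterized convex hull, which
contains the mask — hence hull ≥ PA always and hull = PA for convex shapes
(a polygon-area convention would undercount versus pixel-count PA and break
solidity ≤ 1); compactness is PA/hull (solidity) in (0, 1]; perimeter
counts exposed pixel edges of the largest 4-connected component (a filled
s×s square has perimeter 4s). Absolute growth rate is the backward finite
difference of PA over a window of measured steps.

## Forecasting

Direct multi-horizon, per-plant: for each horizon h a separate model maps
features observed at a forecast origin o to PA(o+h). Features are lags
1..L of the dynamic columns (PA, hull area, compactness by default; lag 1
is the value at the origin itself) plus calendar features of the *target*
step (decimal DAS, day-of-month, month — always known ahead). L defaults
to 48 and is capped per horizon at `n_train − h` so at least one training
row exists; training origins run over the training window with lags and
targets inside it. A window of `n_train` steps therefore cannot train an
h ≥ n_train model at all (T4 and T6 at h = 48); such models, and any design
with fewer than 5 rows or a constant target, fall back to the
training-window mean predictor with a warning.

Evaluation is rolling-origin and causal: the prediction for test step t at
horizon h conditions only on observations at steps ≤ t−h (tested by
corrupting future values and asserting unchanged predictions). Learners:
`gbt` (XGBoost regression trees, 60 trees, depth 3, learning rate 0.3,
single-threaded and seeded for bit-reproducibility) and `linear` (ordinary
least squares, minimum-norm on collinear designs). OLS is exact on
noiseless linear growth — the closed-form limit the tests pin at 1e−6
relative error. Gradient-boosted trees cannot extrapolate beyond the target
range seen in training; this is intrinsic, documented, and is precisely why
windows that stop training at 20 DAS (T5/T6) underpredict 23-DAS PA while
windows trained to 21 DAS (T1–T4) do not. MAE and RMSE follow their usual
definitions; "global" MAE/RMSE are unweighted means of the per-plant,
per-horizon summaries.

## Fresh-weight chain and validation

FW ~ PA is fitted by OLS on early-stage harvests (14–20 DAS), reported with
the Spearman rank R of the pairs (rank correlation is used wherever an R is
reported), the residual SD, and the slope standard error. Negative FW
estimates clip to zero. The chain score converts checkpoint PA forecasts
(default horizon 24 h) to FW and reports Spearman R and MAE/RMSE in FW
units against simulated harvest weights.

Validation at the checkpoint: one-way ANOVA (F = MS_between/MS_within;
all-equal zero-variance groups defined as F = 0, p = 1) across per-window
predictions plus the observed group; Tukey HSD simultaneous intervals at
95% family-wise confidence; per-window t-tests of observed vs predicted —
paired by plant, since the same plants are observed and predicted (a
two-sample variant is available); Spearman R per window. Significance
flags use α = 0.01 throughout.

## Pipeline and determinism

`run_all` executes simulate → imaging round-trip (render, warp, detect,
rectify, crop, segment, refine, re-measure) → harvests → window forecasts →
FW chain → validation. One root seed derives per-stage seeds via a seed
sequence; with the linear learner the whole run is byte-deterministic
(identical CSV SHA-256 checksums), which the test suite asserts. Each stage
writes its artifacts and updates `manifest.json` immediately, so a partial
failure leaves a resumable state (`resume=True` skips completed stages of
an identical config).

## Problem sizes

Full-scale defaults mirror a real two-experiment campaign (122 and 110
plants, 165 steps). The test suite and acceptance script run the same code
at reduced sizes chosen to keep the whole suite in the low minutes on one
CPU: 3–30 plants for forecasting checks, 20 plants for the six-window
comparison, 110 plants for allometry fitting, 100 64×64 image pairs and 20
epochs for segmenter training, 2×3-cell 96-px trays over 20 random warps
for rectification recovery, and a 12-plant end-to-end determinism run.
These sizes are stated here because they are part of the claims: e.g. the
window-comparison conclusions are statements about 20-plant cohorts under
3% noise.

## Known limitations

- The segmenter harness is a local-texture classifier; it cannot learn
  long-range shape priors and is not meant to benchmark against deep
  encoder–decoder backbones.
- Rasterized convex hulls are only approximately idempotent (re-hulling an
  already-convex raster adds boundary pixels).
- Rectification corrects projective distortion only; no radial lens model.
- Tree-learner forecasts clamp to the trained target range; forecasting
  genuinely unseen growth requires either in-window saturation or a
  trend-capable learner.
- The generator's rosettes do not overlap cell boundaries, and its noise is
  i.i.d. multiplicative; real plants move, occlude neighbours, and have
  temporally correlated measurement error. Passing tests demonstrate
  correctness of the machinery under the stated generative assumptions, not
  performance on any real dataset.
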