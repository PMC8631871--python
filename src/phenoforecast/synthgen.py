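"""Synthetic rosette-phenotyping data generator.

Emulates the statistical structure of a high-throughput phenotyping run on
rosette plants so the whole analysis pipeline is testable without any real
imagery:

* per-plant projected-area (PA) growth trajectories on the daylight grid
  (logistic by default, linear as a degenerate option for exact-recovery
  tests), with plant-to-plant parameter variation and multiplicative
  measurement noise;
* rendered single-plant crops (union-of-ellipses rosettes on a soil-textured
  background) with exact ground-truth masks;
* whole-tray scenes with four red fiducial corner markers, an n-cell grid of
  plants, and an optional perspective warp with stored ground truth;
* destructive fresh-weight harvests linearly allometric in PA.

All randomness flows from explicit integer seeds; identical seeds give
bit-identical output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import draw
from skimage.transform import ProjectiveTransform, warp

from .timegrid import TimeGrid

logger = logging.getLogger(__name__)

#: Column schema of the long-format feature/record table.
RECORD_COLUMNS = (
    "plant_id",
    "experiment",
    "time_step",
    "das",
    "pa",
    "hull_area",
    "perimeter",
    "compactness",
)


@dataclass(frozen=True)
class DistSpec:
    """Normal distribution spec with optional truncation, for per-plant draws."""

    mean: float
    sd: float
    low: float | None = None
    high: float | None = None

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        x = rng.normal(self.mean, self.sd, size=n)
        lo = -np.inf if self.low is None else self.low
        hi = np.inf if self.high is None else self.high
        return np.clip(x, lo, hi)


@dataclass(frozen=True)
class GrowthSimConfig:
    """Study conditions for the trajectory simulator.

    PA is in arbitrary "area units" (the field reports no canonical unit for
    projected area; errors are reported on the same scale).  Defaults emulate
    a rosette cohort growing 10-23 DAS: logistic plateau K ~ 1000 area units,
    intrinsic rate ~0.9/day, inflection ~16 DAS, 3% multiplicative
    measurement noise.
    """

    n_plants: int = 122
    grid: TimeGrid = field(default_factory=TimeGrid)
    plateau: DistSpec = DistSpec(1000.0, 200.0, low=300.0)
    rate: DistSpec = DistSpec(0.9, 0.15, low=0.3)
    midpoint: DistSpec = DistSpec(16.0, 1.5, low=12.0, high=20.0)
    noise_sd: float = 0.03
    law: str = "logistic"  # "logistic" | "linear"
    lin_intercept: DistSpec = DistSpec(60.0, 10.0, low=10.0)
    lin_slope: DistSpec = DistSpec(70.0, 10.0, low=20.0)
    experiment: int = 1
    seed: int = 0


def _logistic(t: np.ndarray, k: float, r: float, t0: float) -> np.ndarray:
    return k / (1.0 + np.exp(-r * (t - t0)))


def simulate_growth_curves(config: GrowthSimConfig) -> pd.DataFrame:
    """Simulate one record per plant per daylight step.

    Returns a long-format DataFrame with :data:`RECORD_COLUMNS`.  Convex hull
    area is PA divided by a per-plant true compactness in (0.6, 1.0];
    perimeter is a per-plant shape factor times sqrt(PA).  With
    ``noise_sd=0`` every trajectory is monotone nondecreasing and bounded by
    its plateau.
    """
    if config.grid.steps_per_day < 1:
        raise ValueError("steps_per_day must be >= 1")
    if config.law not in ("logistic", "linear"):
        raise ValueError(f"unknown growth law {config.law!r}")

    rng = np.random.default_rng(config.seed)
    n = config.n_plants
    grid = config.grid
    steps = np.arange(1, grid.total_steps + 1)
    das = np.array([grid.das_of(int(s)) for s in steps])

    k = config.plateau.sample(rng, n)
    r = config.rate.sample(rng, n)
    t0 = config.midpoint.sample(rng, n)
    b0 = config.lin_intercept.sample(rng, n)
    b1 = config.lin_slope.sample(rng, n)
    # true solidity in (0.6, 1.0]; rosettes are moderately compact
    compact = 1.0 - rng.uniform(0.0, 0.4, size=n)
    # perimeter/sqrt(area) shape factor; a disc gives 2*sqrt(pi) ~ 3.54
    pshape = np.clip(rng.normal(4.5, 0.3, size=n), 3.6, None)

    frames = []
    n_clipped = 0
    for i in range(n):
        if config.law == "logistic":
            pa_true = _logistic(das, k[i], r[i], t0[i])
        else:
            pa_true = b0[i] + b1[i] * (das - grid.first_das)
        if config.noise_sd > 0:
            pa = pa_true * (1.0 + rng.normal(0.0, config.noise_sd, size=pa_true.size))
        else:
            pa = pa_true.copy()
        neg = pa < 0
        if neg.any():
            n_clipped += int(neg.sum())
            pa[neg] = 0.0
        frames.append(
            pd.DataFrame(
                {
                    "plant_id": i + 1,
                    "experiment": config.experiment,
                    "time_step": steps,
                    "das": das,
                    "pa": pa,
                    "hull_area": pa / compact[i],
                    "perimeter": pshape[i] * np.sqrt(pa),
                    "compactness": compact[i],
                }
            )
        )
    if n_clipped:
        logger.info("clipped %d negative PA draws to 0", n_clipped)
    out = pd.concat(frames, ignore_index=True)
    return out[list(RECORD_COLUMNS)]


# ---------------------------------------------------------------------------
# rosette rendering


@dataclass(frozen=True)
class RosetteSpec:
    """Geometry of one synthetic rosette inside a square crop."""

    n_leaves: int = 8
    aspect: float = 0.5  # leaf minor/major axis ratio
    phyllotaxis_deg: float = 137.5
    center: tuple[float, float] | None = None  # (row, col); image center if None
    target_pa: float = 400.0
    image_size: int = 64
    seed: int = 0


class RenderError(ValueError):
    """Requested rosette cannot be rendered to the target area."""


def _rosette_mask(spec: RosetteSpec, scale: float, jitter: np.ndarray) -> np.ndarray:
    size = spec.image_size
    cy, cx = spec.center if spec.center is not None else ((size - 1) / 2,) * 2
    mask = np.zeros((size, size), dtype=bool)
    for i in range(spec.n_leaves):
        ang = np.deg2rad(i * spec.phyllotaxis_deg + jitter[i])
        length = scale * (0.75 + 0.25 * (i + 1) / spec.n_leaves)
        ecy = cy + 0.55 * length * np.sin(ang)
        ecx = cx + 0.55 * length * np.cos(ang)
        rr, cc = draw.ellipse(
            ecy,
            ecx,
            max(length * spec.aspect * 0.5, 0.6),
            max(length * 0.5, 0.6),
            shape=(size, size),
            rotation=-ang,
        )
        mask[rr, cc] = True
    return mask


def _soil_texture(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Brown-hued smoothed-noise background (uint8 RGB)."""
    base = np.array([118.0, 86.0, 60.0])
    noise = ndimage.gaussian_filter(rng.normal(0.0, 1.0, shape), sigma=2.0)
    noise = noise / max(np.abs(noise).max(), 1e-9)
    fine = rng.normal(0.0, 6.0, shape)
    img = base[None, None, :] + 30.0 * noise[..., None] + fine[..., None]
    return np.clip(img, 0, 255).astype(np.uint8)


def render_rosette(spec: RosetteSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render one rosette crop; returns (uint8 RGB image, boolean mask).

    Leaf size is solved by bisection so the mask's pixel count lands within
    5% of ``target_pa``; an unreachable target raises :class:`RenderError`
    rather than silently undershooting.
    """
    size = spec.image_size
    if spec.target_pa > 0.5 * size * size:
        raise RenderError(
            f"target_pa {spec.target_pa} exceeds half the {size}x{size} image area"
        )
    if spec.target_pa < 4:
        raise RenderError("target_pa too small to rasterize")
    rng = np.random.default_rng(spec.seed)
    jitter = rng.uniform(-8.0, 8.0, size=spec.n_leaves)

    lo, hi = 1.0, float(size)
    best = None
    for _ in range(48):
        mid = 0.5 * (lo + hi)
        pa = int(_rosette_mask(spec, mid, jitter).sum())
        if best is None or abs(pa - spec.target_pa) < abs(best[1] - spec.target_pa):
            best = (mid, pa)
        if pa < spec.target_pa:
            lo = mid
        else:
            hi = mid
    scale, pa = best
    if abs(pa - spec.target_pa) > 0.05 * spec.target_pa:
        raise RenderError(
            f"could not reach target_pa {spec.target_pa} "
            f"(closest achievable {pa} px)"
        )
    mask = _rosette_mask(spec, scale, jitter)

    img = _soil_texture((size, size), rng)
    green = np.array([52.0, 148.0, 58.0])
    shade = ndimage.gaussian_filter(rng.normal(0.0, 1.0, (size, size)), sigma=1.5)
    shade = shade / max(np.abs(shade).max(), 1e-9)
    fg = np.clip(green[None, None, :] + 28.0 * shade[..., None], 0, 255)
    img = img.astype(float)
    img[mask] = fg[mask]
    return img.astype(np.uint8), mask


# ---------------------------------------------------------------------------
# tray composition


@dataclass(frozen=True)
class TrayGeometry:
    """Nominal tray layout: grid of square cells inside a marker margin."""

    rows: int = 8
    cols: int = 4
    cell_size: int = 64
    margin: int = 40
    marker_radius: int = 8

    @property
    def height(self) -> int:
        return self.rows * self.cell_size + 2 * self.margin

    @property
    def width(self) -> int:
        return self.cols * self.cell_size + 2 * self.margin

    def cell_origin(self, row: int, col: int) -> tuple[int, int]:
        return (self.margin + row * self.cell_size, self.margin + col * self.cell_size)

    def marker_centers_xy(self) -> np.ndarray:
        """Marker centers as (x, y) in order TL, TR, BR, BL."""
        m = self.margin / 2.0
        return np.array(
            [
                [m, m],
                [self.width - m, m],
                [self.width - m, self.height - m],
                [m, self.height - m],
            ]
        )


@dataclass
class TrayScene:
    """A composed (and possibly warped) tray with its ground truth."""

    rgb: np.ndarray  # uint8, the observable image (post-warp)
    mask: np.ndarray  # float in [0,1], post-warp foreground
    rgb_prewarp: np.ndarray
    mask_prewarp: np.ndarray  # bool
    cell_masks: dict[tuple[int, int], np.ndarray]  # pre-warp, cell-local bool
    markers_xy: np.ndarray  # placement ground truth (x, y), TL TR BR BL
    markers_warped_xy: np.ndarray
    geometry: TrayGeometry
    homography: np.ndarray  # 3x3 forward map


MARKER_RED = (214, 32, 30)


def _is_greenish(color: tuple[int, int, int]) -> bool:
    r, g, b = color
    return g >= r and g >= b


def compose_tray(
    crops: list[tuple[np.ndarray, np.ndarray]],
    geometry: TrayGeometry,
    homography: np.ndarray | None = None,
    marker_color: tuple[int, int, int] = MARKER_RED,
    seed: int = 0,
) -> TrayScene:
    """Assemble crops into a tray, stamp four fiducial markers, warp.

    ``crops`` are (rgb, mask) pairs filled row-major; missing cells stay
    background.  Ground truth (per-cell masks, marker centers) is stored in
    pre-warp coordinates alongside the warped marker coordinates.
    """
    n_cells = geometry.rows * geometry.cols
    if len(crops) > n_cells:
        raise ValueError(f"{len(crops)} crops for {n_cells} cells")
    if _is_greenish(marker_color):
        raise ValueError(
            "marker color collides with plant foreground hues; use a red marker"
        )
    rng = np.random.default_rng(seed)
    tray = _soil_texture((geometry.height, geometry.width), rng).astype(float)
    full_mask = np.zeros((geometry.height, geometry.width), dtype=bool)
    cell_masks: dict[tuple[int, int], np.ndarray] = {}

    for idx, (crop_rgb, crop_mask) in enumerate(crops):
        r, c = divmod(idx, geometry.cols)
        y0, x0 = geometry.cell_origin(r, c)
        cs = geometry.cell_size
        if crop_rgb.shape[:2] != (cs, cs):
            raise ValueError("crop size does not match tray cell size")
        tray[y0 : y0 + cs, x0 : x0 + cs][crop_mask] = crop_rgb[crop_mask]
        full_mask[y0 : y0 + cs, x0 : x0 + cs] = crop_mask
        cell_masks[(r, c)] = crop_mask.astype(bool)

    markers = geometry.marker_centers_xy()
    for x, y in markers:
        rr, cc = draw.disk((y, x), geometry.marker_radius, shape=full_mask.shape)
        tray[rr, cc] = np.array(marker_color, dtype=float)
    tray = tray.astype(np.uint8)

    if homography is None:
        homography = np.eye(3)
    homography = np.asarray(homography, dtype=float)
    if abs(np.linalg.det(homography)) < 1e-12:
        raise ValueError("homography is not invertible")

    if np.allclose(homography, np.eye(3)):
        warped_rgb = tray.copy()
        warped_mask = full_mask.astype(float)
        markers_warped = markers.copy()
    else:
        inv = ProjectiveTransform(matrix=np.linalg.inv(homography))
        warped_rgb = warp(
            tray.astype(float), inv, order=1, preserve_range=True, cval=0.0
        ).astype(np.uint8)
        warped_mask = warp(
            full_mask.astype(float), inv, order=1, preserve_range=True, cval=0.0
        )
        markers_warped = ProjectiveTransform(matrix=homography)(markers)

    return TrayScene(
        rgb=warped_rgb,
        mask=warped_mask,
        rgb_prewarp=tray,
        mask_prewarp=full_mask,
        cell_masks=cell_masks,
        markers_xy=markers,
        markers_warped_xy=markers_warped,
        geometry=geometry,
        homography=homography,
    )


def random_perspective(
    geometry: TrayGeometry, strength: float, rng: np.random.Generator
) -> np.ndarray:
    """Random projective warp displacing tray corners by up to ``strength``
    (fraction of the tray diagonal)."""
    h, w = geometry.height, geometry.width
    src = np.array([[0, 0], [w, 0], [w, h], [0, h]], dtype=float)
    amp = strength * np.hypot(h, w)
    dst = src + rng.uniform(-amp, amp, size=(4, 2))
    tform = ProjectiveTransform.from_estimate(src, dst)
    if not tform:
        raise ValueError("degenerate perspective sample")
    return tform.params


def generate_training_pairs(
    n_pairs: int,
    image_size: int = 64,
    pa_range: tuple[float, float] = (150.0, 900.0),
    seed: int = 0,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded batch of (rgb, mask) rosette crops for segmenter training."""
    rng = np.random.default_rng(seed)
    pairs = []
    lo, hi = pa_range
    hi = min(hi, 0.45 * image_size * image_size)
    for i in range(n_pairs):
        spec = RosetteSpec(
            n_leaves=int(rng.integers(4, 11)),
            aspect=float(rng.uniform(0.35, 0.65)),
            target_pa=float(rng.uniform(lo, hi)),
            image_size=image_size,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        pairs.append(render_rosette(spec))
    return pairs


# ---------------------------------------------------------------------------
# fresh weight


@dataclass(frozen=True)
class AllometryParams:
    """PA -> fresh weight relation.  Linear (FW = slope*PA + intercept + eps)
    by default; a power law FW = slope*PA**exponent + intercept is available
    for sensitivity checks."""

    slope: float = 0.15  # FW units (mg) per area unit
    intercept: float = 5.0  # mg
    noise_sd: float = 5.0  # mg
    exponent: float | None = None

    def mean_fw(self, pa: np.ndarray) -> np.ndarray:
        pa = np.asarray(pa, dtype=float)
        if self.exponent is None:
            return self.slope * pa + self.intercept
        return self.slope * np.power(pa, self.exponent) + self.intercept


def harvest_step(grid: TimeGrid, das: int) -> int:
    """Last measured step of an integer DAS (harvest at end of photoperiod)."""
    step = (das - grid.first_das + 1) * grid.steps_per_day
    return min(step, grid.total_steps)


def simulate_fresh_weight(
    records: pd.DataFrame,
    harvests: dict[int, int],
    params: AllometryParams,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Destructively harvest random plants at the given DAS values.

    ``harvests`` maps integer DAS -> number of plants to harvest that day.
    Returns ``(fw_table, surviving_records)``: the FW table has columns
    (plant_id, das, time_step, pa, fw); surviving_records drops all rows of a
    harvested plant after its harvest step (destructive sampling).
    """
    rng = np.random.default_rng(seed)
    grid = TimeGrid()
    harvested: set[int] = set()
    rows = []
    records = records.copy()
    drop = pd.Series(False, index=records.index)
    for das in sorted(harvests):
        step = harvest_step(grid, das)
        at_step = records[(records.time_step == step) & ~drop]
        pool = [p for p in at_step.plant_id.unique() if p not in harvested]
        n_take = harvests[das]
        if n_take > len(pool):
            raise ValueError(
                f"cannot harvest {n_take} plants at {das} DAS; only {len(pool)} remain"
            )
        chosen = rng.choice(np.array(sorted(pool)), size=n_take, replace=False)
        for pid in chosen:
            if pid in harvested:
                raise ValueError(f"plant {pid} already harvested")
            harvested.add(int(pid))
            pa = float(at_step.loc[at_step.plant_id == pid, "pa"].iloc[0])
            fw = float(params.mean_fw(pa) + rng.normal(0.0, params.noise_sd))
            rows.append(
                {
                    "plant_id": int(pid),
                    "das": das,
                    "time_step": step,
                    "pa": pa,
                    "fw": max(fw, 0.0),
                }
            )
            drop |= (records.plant_id == pid) & (records.time_step > step)
    fw_table = pd.DataFrame(rows, columns=["plant_id", "das", "time_step", "pa", "fw"])
    return fw_table, records[~drop].reset_index(drop=True)


def linear_config(**kwargs) -> GrowthSimConfig:
    """Degenerate linear-growth configuration (for exact-recovery tests)."""
    return replace(GrowthSimConfig(law="linear", noise_sd=0.0), **kwargs)
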