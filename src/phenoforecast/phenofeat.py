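"""Shape features extracted from plant masks: projected area, convex hull
area, perimeter, compactness (solidity), and absolute growth rate.

Conventions (raster measures differ by convention, so they are stated):

* projected area (PA) is the foreground pixel count times an optional
  physical scale (area units are pixels^2 unless a mm^2-per-pixel scale is
  supplied);
* convex hull area is the pixel count of the rasterized convex hull image,
  which contains the mask, so hull >= PA always and hull == PA for convex
  shapes;
* perimeter counts exposed pixel edges of the largest 4-connected component
  (a filled s x s square has perimeter 4s);
* compactness = PA / hull area (solidity), in (0, 1].
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.morphology import convex_hull_image


def _as_bool(mask: np.ndarray) -> np.ndarray:
    return np.asarray(mask).astype(bool)


def projected_area(mask: np.ndarray, px_area_scale: float = 1.0) -> float:
    """Foreground pixel count times the per-pixel area scale."""
    return float(np.count_nonzero(_as_bool(mask))) * px_area_scale


def convex_hull_area(mask: np.ndarray, px_area_scale: float = 1.0) -> float:
    """Pixel area of the convex hull of the foreground."""
    mask = _as_bool(mask)
    if not mask.any():
        raise ValueError("convex hull of an empty mask is undefined")
    return float(np.count_nonzero(convex_hull_image(mask))) * px_area_scale


def perimeter(mask: np.ndarray) -> float:
    """Exposed-edge count of the largest 4-connected foreground component."""
    mask = _as_bool(mask)
    if not mask.any():
        raise ValueError("perimeter of an empty mask is undefined")
    lbl, n = ndimage.label(mask, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    if n > 1:
        sizes = ndimage.sum_labels(mask, lbl, index=np.arange(1, n + 1))
        mask = lbl == (1 + int(np.argmax(sizes)))
    padded = np.pad(mask, 1)
    edges = 0
    for shift in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        edges += int(np.count_nonzero(padded & ~np.roll(padded, shift, axis=(0, 1))))
    return float(edges)


def compactness(mask: np.ndarray) -> float:
    """PA over convex hull area (solidity); in (0, 1] for nonempty masks."""
    return projected_area(mask) / convex_hull_area(mask)


def mask_features(mask: np.ndarray, px_area_scale: float = 1.0) -> dict[str, float]:
    """All four shape features of one mask as a dict."""
    pa = projected_area(mask, px_area_scale)
    hull = convex_hull_area(mask, px_area_scale)
    return {
        "pa": pa,
        "hull_area": hull,
        "perimeter": perimeter(mask),
        "compactness": pa / hull,
    }


def absolute_growth_rate(series: pd.Series | np.ndarray, window_steps: int = 1) -> np.ndarray:
    """AGR(t) = (PA(t) - PA(t - window)) / window, in area units per step.

    The first ``window_steps`` entries are NaN (undefined).  The input must
    be time-ordered.
    """
    if window_steps < 1:
        raise ValueError("window_steps must be >= 1")
    x = np.asarray(series, dtype=float)
    out = np.full_like(x, np.nan)
    if x.size > window_steps:
        out[window_steps:] = (x[window_steps:] - x[:-window_steps]) / window_steps
    return out


def features_table(
    masks: dict[tuple[int, int], np.ndarray],
    time_step: int,
    das: float,
    experiment: int = 1,
    px_area_scale: float = 1.0,
) -> pd.DataFrame:
    """Feature records for a dict of (plant_id-indexable) masks at one step.

    Keys are (row, col) cell positions; plant ids are assigned row-major.
    Empty masks yield PA 0 with NaN hull/perimeter/compactness.
    """
    rows = []
    n_cols = max((c for _, c in masks), default=0) + 1
    for (r, c), mask in sorted(masks.items()):
        pid = r * n_cols + c + 1
        if _as_bool(mask).any():
            feats = mask_features(mask, px_area_scale)
        else:
            feats = {"pa": 0.0, "hull_area": np.nan, "perimeter": np.nan,
                     "compactness": np.nan}
        rows.append(
            {"plant_id": pid, "experiment": experiment, "time_step": time_step,
             "das": das, **feats}
        )
    return pd.DataFrame(rows)
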