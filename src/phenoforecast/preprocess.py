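"""Tray preprocessing: fiducial-marker detection, perspective rectification,
per-cell cropping, and aspect-preserving scale/pad to the segmenter input
size.

Marker detection is HSV-range thresholding plus connected components: the
four largest red components are taken and their intensity centroids ordered
(top-left, top-right, bottom-right, bottom-left).  Rectification estimates
the projective transform mapping the detected centroids onto the nominal
marker rectangle; only a 4-point projective correction is applied (no radial
lens model).  All pixel coordinates are 0-based and crops use half-open
intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2hsv
from skimage.measure import label, regionprops
from skimage.transform import ProjectiveTransform, resize, warp

from .synthgen import TrayGeometry


class MarkerDetectionError(ValueError):
    pass


@dataclass(frozen=True)
class HsvRange:
    """Red-hue detection band (hue wraps around 0)."""

    hue_low: float = 0.95
    hue_high: float = 0.05
    sat_min: float = 0.45
    val_min: float = 0.25


def _order_corners(pts: np.ndarray) -> np.ndarray:
    """Order 4 (x, y) points TL, TR, BR, BL by position around their mean."""
    s = pts.sum(axis=1)
    d = pts[:, 0] - pts[:, 1]  # x - y
    tl = pts[np.argmin(s)]
    br = pts[np.argmax(s)]
    tr = pts[np.argmax(d)]
    bl = pts[np.argmin(d)]
    return np.array([tl, tr, br, bl])


def detect_markers(
    tray_rgb: np.ndarray, color_spec: HsvRange = HsvRange()
) -> np.ndarray:
    """Centroids of the four red fiducial markers as (x, y), TL TR BR BL.

    Centroids are intensity-weighted within each component (weighted by
    saturation) for sub-pixel accuracy.  Fewer than four components is an
    error naming the count found; more than four keeps the four largest.
    """
    if tray_rgb.ndim != 3 or tray_rgb.shape[2] != 3:
        raise MarkerDetectionError("no markers: input is not an RGB image")
    hsv = rgb2hsv(tray_rgb)
    h, s, v = hsv[..., 0], hsv[..., 1], hsv[..., 2]
    red = ((h >= color_spec.hue_low) | (h <= color_spec.hue_high)) & (
        s >= color_spec.sat_min
    ) & (v >= color_spec.val_min)
    lbl = label(red)
    props = sorted(regionprops(lbl), key=lambda p: p.area, reverse=True)
    if len(props) < 4:
        raise MarkerDetectionError(
            f"no markers: found {len(props)} red components, need 4"
        )
    if len(props) > 4:
        import logging

        logging.getLogger(__name__).info(
            "found %d red components; keeping 4 largest", len(props)
        )
    centroids = []
    for p in props[:4]:
        ys, xs = np.nonzero(lbl == p.label)
        w = s[ys, xs]
        w = w / w.sum()
        centroids.append([float((xs * w).sum()), float((ys * w).sum())])
    return _order_corners(np.array(centroids))


def rectify(
    tray_rgb: np.ndarray,
    corners_xy: np.ndarray,
    geometry: TrayGeometry,
    order: int = 1,
) -> np.ndarray:
    """Warp the tray so the detected corners land on the nominal rectangle.

    ``corners_xy`` must be ordered TL, TR, BR, BL.  Output dimensions equal
    the nominal tray size; interpolation is bilinear by default.  Collinear
    corners are rejected.
    """
    corners_xy = np.asarray(corners_xy, dtype=float)
    if corners_xy.shape != (4, 2):
        raise ValueError("need exactly 4 corner points")
    # collinearity: area of the quadrilateral must be non-negligible
    x, y = corners_xy[:, 0], corners_xy[:, 1]
    area = 0.5 * abs(
        np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y)
    )
    if area < 1.0:
        raise ValueError("degenerate (collinear) corner configuration")
    nominal = geometry.marker_centers_xy()
    tform = ProjectiveTransform.from_estimate(nominal, corners_xy)
    if not tform:
        raise ValueError("could not estimate rectifying homography")
    out = warp(
        tray_rgb.astype(float),
        tform,
        output_shape=(geometry.height, geometry.width),
        order=order,
        preserve_range=True,
        cval=0.0,
    )
    if np.issubdtype(tray_rgb.dtype, np.integer):
        return np.clip(out, 0, 255).astype(tray_rgb.dtype)
    return out


@dataclass
class CellCrop:
    """One cell cut from a rectified tray."""

    rgb: np.ndarray
    row: int
    col: int
    plant_id: int  # row-major cell index, 1-based
    tray_id: str = ""
    scale: float = 1.0
    pad: tuple[int, int, int, int] = (0, 0, 0, 0)  # top, bottom, left, right


def crop_cells(
    rect_tray: np.ndarray, geometry: TrayGeometry, tray_id: str = ""
) -> list[CellCrop]:
    """Cut the rectified tray into rows*cols cells, row-major order.

    Empty cells simply yield background-only crops.  Crops are half-open
    [y0, y0+cell) x [x0, x0+cell) windows, so re-tiling them reproduces the
    grid region of the tray exactly.
    """
    crops = []
    cs = geometry.cell_size
    for r in range(geometry.rows):
        for c in range(geometry.cols):
            y0, x0 = geometry.cell_origin(r, c)
            crops.append(
                CellCrop(
                    rgb=rect_tray[y0 : y0 + cs, x0 : x0 + cs].copy(),
                    row=r,
                    col=c,
                    plant_id=r * geometry.cols + c + 1,
                    tray_id=tray_id,
                )
            )
    return crops


def scale_and_pad(crop: CellCrop, target_size: int) -> CellCrop:
    """Aspect-preserving resize so the larger side equals ``target_size``,
    then symmetric zero padding to a square.

    The recorded scale and per-side padding allow exact inverse mapping of
    mask coordinates back into the original crop frame.
    """
    if target_size < 1:
        raise ValueError("target_size must be >= 1")
    h, w = crop.rgb.shape[:2]
    scale = target_size / max(h, w)
    nh, nw = round(h * scale), round(w * scale)
    if (nh, nw) == (h, w):
        scaled = crop.rgb.copy()
    else:
        scaled = resize(
            crop.rgb.astype(float), (nh, nw), order=1, preserve_range=True
        )
        if np.issubdtype(crop.rgb.dtype, np.integer):
            scaled = np.clip(scaled, 0, 255).astype(crop.rgb.dtype)
    pad_v, pad_h = target_size - nh, target_size - nw
    top, bottom = pad_v // 2, pad_v - pad_v // 2
    left, right = pad_h // 2, pad_h - pad_h // 2
    padded = np.pad(
        scaled, ((top, bottom), (left, right), (0, 0)), mode="constant"
    )
    return CellCrop(
        rgb=padded,
        row=crop.row,
        col=crop.col,
        plant_id=crop.plant_id,
        tray_id=crop.tray_id,
        scale=scale,
        pad=(top, bottom, left, right),
    )


def unscale_mask(mask: np.ndarray, crop: CellCrop, orig_shape: tuple[int, int]) -> np.ndarray:
    """Map a mask from the scaled/padded frame back to the original crop."""
    top, bottom, left, right = crop.pad
    h, w = mask.shape
    inner = mask[top : h - bottom or None, left : w - right or None]
    if inner.shape == orig_shape:
        return inner.astype(bool)
    back = resize(inner.astype(float), orig_shape, order=0, preserve_range=True)
    return back > 0.5
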