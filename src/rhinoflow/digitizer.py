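"""Recover numeric pressure-flow points from rendered plot images.

Per-curve RGB thresholding (each channel within an inclusive +-10 of the
curve's colour by default) separates the curves; a 5 x 5 pixel
discretization window turns each occupied cell into one centroid point;
an affine axis calibration (two pixel/data reference points per axis)
converts pixel centroids to (flow, pressure) samples.  Anti-aliased edge
pixels fall outside the strict tolerance and are simply dropped, which is
why the companion renderer draws hard-edged curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .curves import AARCurve

__all__ = ["ColorSpec", "DigitizerConfig", "mask_color", "discretize",
           "calibrate", "digitize_image"]


@dataclass(frozen=True)
class ColorSpec:
    """One curve's colour with its per-channel threshold tolerance."""

    label: str
    rgb: Tuple[int, int, int]
    tolerance: int = 10

    def __post_init__(self):
        if self.tolerance < 0:
            raise ValueError("tolerance must be non-negative")


@dataclass
class DigitizerConfig:
    """Colour specs, window size and axis calibration for one plot image."""

    color_specs: List[ColorSpec]
    window: int = 5
    axis_calibration: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.window < 1:
            raise ValueError("window must be >= 1")
        for axis in ("x", "y"):
            pts = self.axis_calibration.get(axis, {}).get("points")
            if pts is not None and pts[0][0] == pts[1][0]:
                raise ValueError(f"degenerate {axis}-axis calibration: "
                                 "coincident reference pixels")


def mask_color(image: np.ndarray, spec: ColorSpec) -> np.ndarray:
    """Boolean pixel mask: every channel within +-tolerance (inclusive)."""
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] < 3:
        raise ValueError("expected an RGB image array")
    diff = np.abs(img[:, :, :3].astype(int) - np.asarray(spec.rgb, dtype=int))
    return (diff <= spec.tolerance).all(axis=2)


def discretize(mask: np.ndarray, window: int = 5) -> np.ndarray:
    """Tile the mask into window x window cells; one centroid per occupied cell.

    Returns an (n, 2) array of (x_px, y_px) centroids ordered by x then y.
    An empty mask yields an empty array.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    mask = np.asarray(mask, dtype=bool)
    rows, cols = np.nonzero(mask)
    if len(rows) == 0:
        return np.empty((0, 2))
    cell = (rows // window) * ((mask.shape[1] + window - 1) // window) \
        + (cols // window)
    order = np.argsort(cell, kind="stable")
    cell_s, rows_s, cols_s = cell[order], rows[order], cols[order]
    starts = np.flatnonzero(np.r_[True, np.diff(cell_s) > 0])
    counts = np.diff(np.r_[starts, len(cell_s)])
    ysum = np.add.reduceat(rows_s.astype(float), starts)
    xsum = np.add.reduceat(cols_s.astype(float), starts)
    pts = np.column_stack([xsum / counts, ysum / counts])
    return pts[np.lexsort((pts[:, 1], pts[:, 0]))]


def _axis_map(axis_cal: dict):
    (p0, v0), (p1, v1) = axis_cal["points"]
    if p0 == p1:
        raise ValueError("degenerate calibration: coincident reference pixels")
    return lambda px: v0 + (np.asarray(px, dtype=float) - p0) * (v1 - v0) / (p1 - p0)


def calibrate(centroids: np.ndarray, axis_calibration: dict) -> np.ndarray:
    """Affine pixel -> data conversion; returns (flow, pressure) pairs.

    The x axis carries pressure (Pa) and the y axis flow (ml/s), following
    the clinical plot convention.
    """
    centroids = np.asarray(centroids, dtype=float)
    fx = _axis_map(axis_calibration["x"])
    fy = _axis_map(axis_calibration["y"])
    if centroids.size == 0:
        return np.empty((0, 2))
    pressure = fx(centroids[:, 0])
    flow = fy(centroids[:, 1])
    return np.column_stack([flow, pressure])


def digitize_image(image: np.ndarray, config: DigitizerConfig) -> Dict[str, AARCurve]:
    """Full digitization: threshold each colour, discretize, calibrate.

    Returns one curve per colour spec (labels keep their spec names);
    curves with no matching pixels come back empty-handed as zero-length
    curves are invalid, they are simply omitted.
    """
    out: Dict[str, AARCurve] = {}
    for spec in config.color_specs:
        m = mask_color(image, spec)
        pts = discretize(m, config.window)
        data = calibrate(pts, config.axis_calibration)
        if len(data) == 0:
            continue
        out[spec.label] = AARCurve(data[:, 0], data[:, 1], state=spec.label)
    return out
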