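"""Hard-edged rendering of rhinomanometry plots for the digitizer.

Curves are drawn with exact per-curve RGB values and no anti-aliasing so
that colour thresholding can separate them, mirroring how vector plots
rasterised at 200 dpi behave.  Axis convention follows the clinical
presentation: x = pressure (Pa), y = flow (ml/s); inspiration occupies the
upper-right quadrant.  The renderer returns the image together with axis
calibration metadata (two pixel/data reference points per axis) which the
digitizer consumes.
"""

from __future__ import annotations

from typing import Dict, Optional, Tuple

import numpy as np
from PIL import Image, ImageDraw

__all__ = ["PAPER_PALETTE", "render_aar_plot", "ColorAmbiguityError"]

#: Clinical plot palette: per-curve RGB used by the colour thresholding.
PAPER_PALETTE: Dict[str, Tuple[int, int, int]] = {
    "congested_right": (255, 223, 204),
    "congested_left": (103, 148, 198),
    "decongested_right": (232, 138, 135),
    "decongested_left": (193, 218, 242),
}

BACKGROUND = (255, 255, 255)
AXIS_COLOR = (0, 0, 0)


class ColorAmbiguityError(ValueError):
    """Two curve colours fall inside each other's threshold boxes."""


def _check_palette(colors: Dict[str, tuple], tolerance: int):
    labels = list(colors)
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            if all(abs(colors[a][c] - colors[b][c]) <= 2 * tolerance
                   for c in range(3)):
                raise ColorAmbiguityError(
                    f"colours of {a!r} and {b!r} are within +-{tolerance} "
                    "per channel of each other; thresholding cannot "
                    "separate them")


def render_aar_plot(traces: Dict[str, tuple],
                    colors: Optional[Dict[str, tuple]] = None,
                    size_px: Tuple[int, int] = (847, 757),
                    dpi: int = 200,
                    pressure_range: Optional[Tuple[float, float]] = None,
                    flow_range: Optional[Tuple[float, float]] = None,
                    margin_px: int = 40,
                    line_width: int = 4,
                    tolerance: int = 10):
    """Render pressure-flow traces to an RGB image plus calibration.

    ``traces`` maps a curve label to ``(flow, pressure)`` arrays;
    ``colors`` maps labels to RGB triples (defaults to the clinical
    palette).  Returns ``(image, calibration)`` where ``image`` is a
    (H, W, 3) uint8 array at the requested pixel size (847 x 757 mimics a
    200 dpi rasterised report page) and ``calibration`` records two
    (pixel, data) reference points per axis.
    """
    if colors is None:
        if not set(traces) <= set(PAPER_PALETTE):
            raise ValueError("no colour given for "
                             f"{set(traces) - set(PAPER_PALETTE)}")
        colors = {k: PAPER_PALETTE[k] for k in traces}
    if traces:
        _check_palette({k: colors[k] for k in traces}, tolerance)

    # axes auto-scale to the data (symmetric, 5% headroom) as on a
    # clinical report page; explicit ranges override
    def _auto(idx):
        vmax = max((float(np.max(np.abs(np.asarray(tr[idx]))))
                    for tr in traces.values() if len(np.asarray(tr[idx]))),
                   default=1.0)
        vmax = vmax if vmax > 0 else 1.0
        return (-1.05 * vmax, 1.05 * vmax)

    if pressure_range is None:
        pressure_range = _auto(1)
    if flow_range is None:
        flow_range = _auto(0)

    w, h = size_px
    img = Image.new("RGB", (w, h), BACKGROUND)
    draw = ImageDraw.Draw(img)

    x0, x1 = float(pressure_range[0]), float(pressure_range[1])
    y0, y1 = float(flow_range[0]), float(flow_range[1])
    px0, px1 = margin_px, w - 1 - margin_px
    py0, py1 = h - 1 - margin_px, margin_px       # pixel y grows downward

    def to_px(pressure, flow):
        x = px0 + (np.asarray(pressure) - x0) * (px1 - px0) / (x1 - x0)
        y = py0 + (np.asarray(flow) - y0) * (py1 - py0) / (y1 - y0)
        return x, y

    # axes through the origin, black (outside every palette threshold box)
    ox, oy = to_px(0.0, 0.0)
    draw.line([(px0, oy), (px1, oy)], fill=AXIS_COLOR, width=1)
    draw.line([(ox, py0), (ox, py1)], fill=AXIS_COLOR, width=1)

    for label, (flow, pressure) in traces.items():
        x, y = to_px(pressure, flow)
        pts = list(zip(x.tolist(), y.tolist()))
        if len(pts) == 1:
            draw.point(pts[0], fill=tuple(colors[label]))
        elif pts:
            draw.line(pts, fill=tuple(colors[label]), width=line_width)

    calibration = {
        "x": {"quantity": "pressure_pa",
              "points": [(px0, x0), (px1, x1)]},
        "y": {"quantity": "flow_ml_s",
              "points": [(py0, y0), (py1, y1)]},
        "dpi": dpi,
    }
    return np.asarray(img, dtype=np.uint8), calibration
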