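"""Kymograph construction from timelapse stacks along wide polyline ROIs.

An axon is traced as a polyline with a width (default 10 px, the width used
for the segmented-line reslicing of axon movies). The polyline is resampled
at uniform arc length (1 px steps), and at each sample the stack is probed
along the local normal at ``width_px`` centered offsets; the per-sample
reducer (max by default, mean optionally) collapses the width into one
kymograph column. One kymograph row per movie frame.

Coordinates are 0-based with pixel centers at integer positions. The ROI's
``soma_at_start`` flag records whether increasing arc length points away
from the soma, which downstream classification maps onto anterograde.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.ndimage import map_coordinates

from .errors import BoundsError, CalibrationError, GeometryError, ParameterError

__all__ = ["PolylineROI", "Kymograph", "resample_polyline", "extract_kymograph"]


@dataclass(frozen=True)
class PolylineROI:
    """Polyline axon trace: (x, y) vertices in pixels plus a sampling width."""

    vertices: np.ndarray  # (k, 2) as (x, y)
    width_px: int = 10
    soma_at_start: bool = True  # increasing arc length points away from the soma

    def __post_init__(self) -> None:
        verts = np.asarray(self.vertices, dtype=np.float64)
        object.__setattr__(self, "vertices", verts)
        if verts.ndim != 2 or verts.shape[1] != 2 or len(verts) < 2:
            raise GeometryError("polyline needs >= 2 (x, y) vertices")
        if np.any(np.all(np.diff(verts, axis=0) == 0, axis=1)):
            raise GeometryError("consecutive vertices must be distinct")
        if self.width_px < 1:
            raise ParameterError("width_px must be >= 1")

    @property
    def anterograde_sign(self) -> int:
        return 1 if self.soma_at_start else -1


@dataclass
class Kymograph:
    """Calibrated (time, arc-position) intensity matrix."""

    matrix: np.ndarray
    pixel_size_um: float
    frame_interval_s: float
    source_id: str = ""

    @property
    def length_um(self) -> float:
        return self.matrix.shape[1] * self.pixel_size_um

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[0]


def resample_polyline(
    roi: PolylineROI, step_px: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Arc-length-uniform samples along the polyline, with unit normals.

    Returns ``(points, normals)`` of shape (n, 2) as (x, y). Both endpoints
    are preserved; n = round(arc_length / step) + 1, so sample spacing is
    arc_length / (n - 1), within half a step of ``step_px``. Tangents are
    central differences of the sampled points (one-sided at the endpoints),
    which rounds corners slightly but makes the normal field symmetric
    under reversal of the vertex order.
    """
    if step_px <= 0:
        raise ParameterError("step_px must be > 0")
    verts = roi.vertices
    seg = np.diff(verts, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    total = float(seglen.sum())
    if total == 0:
        raise GeometryError("zero-length polyline")
    cum = np.concatenate(([0.0], np.cumsum(seglen)))
    n = int(round(total / step_px)) + 1
    if n < 2:
        n = 2
    s = np.linspace(0.0, total, n)
    x = np.interp(s, cum, verts[:, 0])
    y = np.interp(s, cum, verts[:, 1])
    points = np.column_stack([x, y])
    tangents = np.empty_like(points)
    tangents[1:-1] = points[2:] - points[:-2]
    tangents[0] = points[1] - points[0]
    tangents[-1] = points[-1] - points[-2]
    norms = np.hypot(tangents[:, 0], tangents[:, 1])
    tangents /= norms[:, None]
    normals = np.column_stack([-tangents[:, 1], tangents[:, 0]])
    return points, normals


def extract_kymograph(
    stack: np.ndarray,
    roi: PolylineROI,
    reducer: Literal["max", "mean"] = "max",
    interp: Literal["linear", "nearest"] = "linear",
    pixel_size_um: float | None = None,
    frame_interval_s: float | None = None,
    step_px: float = 1.0,
    source_id: str = "",
) -> Kymograph:
    """Reslice a (time, y, x) stack along the ROI into a kymograph.

    At each arc-length sample, intensities at ``width_px`` offsets along the
    local normal are interpolated (bilinear, or nearest for exact-arithmetic
    tests) and reduced by max or mean. Calibration must be supplied; the
    anterograde direction is carried by the ROI, not the image.
    """
    if pixel_size_um is None or frame_interval_s is None:
        raise CalibrationError("pixel_size_um and frame_interval_s are required")
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ParameterError("stack must be (time, y, x)")
    if reducer not in ("max", "mean"):
        raise ParameterError(f"unknown reducer {reducer!r}")
    points, normals = resample_polyline(roi, step_px=step_px)
    w = roi.width_px
    offsets = np.arange(w, dtype=np.float64) - (w - 1) / 2.0
    # coords shape (w, n, 2) as (x, y)
    coords = points[None, :, :] + offsets[:, None, None] * normals[None, :, :]
    xs = coords[..., 0].ravel()
    ys = coords[..., 1].ravel()
    T, H, W = stack.shape
    if xs.min() < 0 or ys.min() < 0 or xs.max() > W - 1 or ys.max() > H - 1:
        raise BoundsError("ROI (including width offsets) falls outside the stack")
    order = 1 if interp == "linear" else 0
    n = len(points)
    matrix = np.empty((T, n), dtype=np.float64)
    for t in range(T):
        vals = map_coordinates(
            stack[t].astype(np.float64), [ys, xs], order=order, mode="nearest"
        ).reshape(w, n)
        matrix[t] = vals.max(axis=0) if reducer == "max" else vals.mean(axis=0)
    return Kymograph(
        matrix=matrix,
        pixel_size_um=pixel_size_um,
        frame_interval_s=frame_interval_s,
        source_id=source_id,
    )
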