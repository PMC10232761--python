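"""ROI definition, intensity time-series extraction, and the
intensity-threshold baseline.

Once the stack is aligned (target organ at the canvas centre, animal
facing up), a fixed ROI in aligned coordinates covers the same anatomy in
every frame, so per-frame statistics over it form a physiological time
series.  Statistics are computed only over unmasked pixels — pixels the
rigid transform mapped from inside the source frame — and frames with no
usable ROI pixel are flagged, never silently zeroed.

:func:`threshold_baseline` implements the simpler alternative of
segmenting each raw frame at a fixed intensity: it is retained for
comparison because it is *inconsistent* — the brightest connected
component follows whatever exceeds the threshold (pose changes, residual
dye in the tail, low signal-to-background), not the organ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .acquisition import FrameStack
from .align import AlignedStack


def rasterize_polygon(vertices: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Even-odd fill of a polygon sampled at pixel centres.

    ``vertices`` is N×2 in (x, y); the pixel at (row r, col c) is inside
    iff a ray from its centre (c, r) crosses the polygon boundary an odd
    number of times (crossing-number test, half-open edge rule so shared
    vertices are not double-counted).
    """
    vertices = np.asarray(vertices, dtype=float)
    if vertices.ndim != 2 or vertices.shape[0] < 3 or vertices.shape[1] != 2:
        raise ValueError("polygon needs at least 3 (x, y) vertices")
    H, W = shape
    ys, xs = np.mgrid[0:H, 0:W]
    px = xs.ravel().astype(float)
    py = ys.ravel().astype(float)
    inside = np.zeros(px.shape, dtype=bool)
    n = vertices.shape[0]
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        crosses = (y1 <= py) != (y2 <= py)
        with np.errstate(divide="ignore", invalid="ignore"):
            x_at = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
        inside ^= crosses & (px < x_at)
    return inside.reshape(H, W)


@dataclass
class ROISpec:
    """A named region in aligned coordinates: polygon vertices or a mask."""

    name: str
    polygon: np.ndarray | None = None  # N×2 (x, y)
    mask: np.ndarray | None = None  # H×W bool

    def __post_init__(self) -> None:
        if (self.polygon is None) == (self.mask is None):
            raise ValueError("provide exactly one of polygon or mask")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if not self.mask.any():
                raise ValueError(f"ROI {self.name!r} has empty area")

    def to_mask(self, shape: tuple[int, int]) -> np.ndarray:
        if self.mask is not None:
            if self.mask.shape != shape:
                raise ValueError(
                    f"ROI {self.name!r} mask shape {self.mask.shape} != canvas {shape}"
                )
            return self.mask
        mask = rasterize_polygon(self.polygon, shape)
        if not mask.any():
            raise ValueError(f"ROI {self.name!r} covers no pixel centre on the canvas")
        return mask


def extract_series(stack: AlignedStack, roi: ROISpec) -> pd.DataFrame:
    """Per-frame mean/median over the unmasked ROI pixels.

    Returns a DataFrame with columns (frame, mean, median, n_pixels,
    valid), indexed by aligned-frame order.  ``valid`` is False — and the
    statistics NaN — for frames whose ROI is entirely covered by the fill
    mask.  Frames dropped upstream are simply absent.
    """
    shape = stack.data.shape[1:]
    roi_mask = roi.to_mask(shape)
    rows = []
    for i, frame_idx in enumerate(stack.frame_indices):
        usable = roi_mask & ~stack.mask[i]
        n = int(usable.sum())
        if n == 0:
            rows.append(
                {
                    "frame": int(frame_idx),
                    "mean": np.nan,
                    "median": np.nan,
                    "n_pixels": 0,
                    "valid": False,
                }
            )
            continue
        vals = stack.data[i][usable]
        rows.append(
            {
                "frame": int(frame_idx),
                "mean": float(vals.mean()),
                "median": float(np.median(vals)),
                "n_pixels": n,
                "valid": True,
            }
        )
    return pd.DataFrame(rows, columns=["frame", "mean", "median", "n_pixels", "valid"])


def threshold_baseline(stack: FrameStack, level: float) -> tuple[np.ndarray, pd.DataFrame]:
    """Fixed-intensity segmentation baseline (for comparison only).

    Thresholds every raw frame at ``level`` and reports, per frame, the
    largest 8-connected component's pixel area and centroid.  Frames with
    nothing above threshold get ``valid=False`` and NaN centroids.

    This is the approach the marker pipeline replaces: its centroid
    follows any sufficiently bright structure rather than the tracked
    organ.
    """
    masks = stack.data >= level
    structure = np.ones((3, 3), dtype=bool)
    rows = []
    for t in range(stack.n_frames):
        labels, n = ndimage.label(masks[t], structure=structure)
        if n == 0:
            rows.append(
                {
                    "frame": t,
                    "area": 0,
                    "centroid_x": np.nan,
                    "centroid_y": np.nan,
                    "valid": False,
                }
            )
            continue
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
        biggest = int(np.argmax(sizes)) + 1
        cy, cx = ndimage.center_of_mass(masks[t], labels, biggest)
        rows.append(
            {
                "frame": t,
                "area": int(sizes[biggest - 1]),
                "centroid_x": float(cx),
                "centroid_y": float(cy),
                "valid": True,
            }
        )
    report = pd.DataFrame(
        rows, columns=["frame", "area", "centroid_x", "centroid_y", "valid"]
    )
    return masks, report
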