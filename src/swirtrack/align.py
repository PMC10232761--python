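"""Marker-based rigid frame alignment.

Each retained frame is rigidly transformed so that (a) the tracked target
organ's marker sits exactly at the canvas centre and (b) the animal faces
up: the vector from the target marker to a designated anterior marker maps
to the straight-up direction (decreasing y, image convention with the
origin at the top-left, x rightward, y downward).

The forward map of a frame's pixel coordinate p is::

    p' = centre + R(theta) · (p + (dx, dy) − centre)

i.e. translate the target to the centre, then rotate about the centre.
``theta`` comes either from the two-point target→anterior heading
(default, deterministic) or from a least-squares (orthogonal Procrustes)
fit over all peripheral markers against the first valid frame's posture,
which averages down marker noise when many markers exist.

Out-of-canvas content is masked, never wrapped or zero-filled, so
downstream statistics can exclude invalid pixels.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .acquisition import FrameStack
from .markers import (
    DEFAULT_LIKELIHOOD_THRESHOLD,
    MarkerRoles,
    MarkerTable,
    filter_by_likelihood,
)

#: Markers closer than this (px) cannot define a heading.
COINCIDENT_EPS = 1e-6


def _wrap_angle(theta: float) -> float:
    """Wrap to (−π, π]."""
    theta = (theta + math.pi) % (2 * math.pi) - math.pi
    if theta == -math.pi:
        theta = math.pi
    return theta


def _rotation_matrix(theta: float) -> np.ndarray:
    c, s = math.cos(theta), math.sin(theta)
    return np.array([[c, -s], [s, c]])


@dataclass
class RigidTransform:
    """Per-frame rigid map: translate target to centre, rotate about centre."""

    frame: int
    dx: float = 0.0
    dy: float = 0.0
    theta: float = 0.0
    valid: bool = True
    out_shape: tuple[int, int] | None = None  # (H, W)

    def __post_init__(self) -> None:
        if self.valid:
            self.theta = _wrap_angle(self.theta)

    def centre(self) -> np.ndarray:
        if self.out_shape is None:
            raise ValueError("transform has no output shape")
        H, W = self.out_shape
        return np.array([(W - 1) / 2.0, (H - 1) / 2.0])

    def apply_to_points(self, points: np.ndarray) -> np.ndarray:
        """Forward-map N×2 (x, y) raw-frame points into aligned space."""
        if not self.valid:
            raise ValueError(f"transform for frame {self.frame} is invalid")
        points = np.atleast_2d(np.asarray(points, dtype=float))
        c = self.centre()
        shifted = points + np.array([self.dx, self.dy]) - c
        return shifted @ _rotation_matrix(self.theta).T + c

    def invert_points(self, points: np.ndarray) -> np.ndarray:
        """Inverse-map N×2 (x, y) aligned-space points back to the raw frame."""
        if not self.valid:
            raise ValueError(f"transform for frame {self.frame} is invalid")
        points = np.atleast_2d(np.asarray(points, dtype=float))
        c = self.centre()
        return (points - c) @ _rotation_matrix(-self.theta).T + c - np.array(
            [self.dx, self.dy]
        )


def heading_angle(target_xy: np.ndarray, anterior_xy: np.ndarray) -> float:
    """Rotation (about the centre) sending target→anterior to straight up.

    Straight up is the −y direction.  Raises for coincident markers.
    """
    v = np.asarray(anterior_xy, dtype=float) - np.asarray(target_xy, dtype=float)
    norm = float(np.hypot(*v))
    if norm < COINCIDENT_EPS:
        raise ValueError("target and anterior markers coincide")
    return _wrap_angle(-math.pi / 2 - math.atan2(v[1], v[0]))


def compute_transform(
    frame_markers: dict[str, tuple[float, float, float]],
    roles: MarkerRoles,
    out_shape: tuple[int, int],
    frame: int = 0,
) -> RigidTransform:
    """Two-point rigid transform from one frame's markers.

    ``frame_markers`` maps bodypart → (x, y, likelihood) as produced by
    :meth:`MarkerTable.at_frame`.  A coincident target/anterior pair
    yields an *invalid* transform rather than an arbitrary rotation.
    """
    H, W = out_shape
    centre = np.array([(W - 1) / 2.0, (H - 1) / 2.0])
    try:
        tx, ty, _ = frame_markers[roles.target]
        ax, ay, _ = frame_markers[roles.anterior]
    except KeyError as exc:
        raise ValueError(f"frame {frame}: missing marker {exc}") from exc
    if not (np.isfinite([tx, ty, ax, ay]).all()):
        return RigidTransform(frame=frame, valid=False, out_shape=out_shape)
    target = np.array([tx, ty])
    try:
        theta = heading_angle(target, np.array([ax, ay]))
    except ValueError:
        return RigidTransform(frame=frame, valid=False, out_shape=out_shape)
    dx, dy = centre - target
    return RigidTransform(
        frame=frame, dx=float(dx), dy=float(dy), theta=theta, out_shape=out_shape
    )


def _procrustes_theta(
    offsets: np.ndarray, reference: np.ndarray
) -> float:
    """Proper rotation minimising ‖R·offsets − reference‖² (2-D Procrustes)."""
    Hmat = offsets.T @ reference  # 2×2
    U, _, Vt = np.linalg.svd(Hmat)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, d])
    R = Vt.T @ D @ U.T
    return _wrap_angle(math.atan2(R[1, 0], R[0, 0]))


def apply_transform(
    frame: np.ndarray,
    transform: RigidTransform,
    interpolation: str = "bilinear",
) -> tuple[np.ndarray, np.ndarray]:
    """Resample one frame into aligned space.

    Returns ``(aligned, mask)`` where ``mask`` is True at output pixels
    whose inverse-mapped location falls outside the source frame.
    Bilinear (default) or nearest-neighbour interpolation; nearest with an
    integer translation is an exact pixel shift.
    """
    if not transform.valid:
        raise ValueError(f"cannot apply invalid transform (frame {transform.frame})")
    order = {"bilinear": 1, "nearest": 0}.get(interpolation)
    if order is None:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    frame = np.asarray(frame)
    H, W = transform.out_shape if transform.out_shape else frame.shape
    ys, xs = np.mgrid[0:H, 0:W]
    pts = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
    src = transform.invert_points(pts)  # N×2 (x, y)
    sx = src[:, 0].reshape(H, W)
    sy = src[:, 1].reshape(H, W)
    h_in, w_in = frame.shape
    mask = (sx < 0) | (sx > w_in - 1) | (sy < 0) | (sy > h_in - 1)
    out = ndimage.map_coordinates(
        frame.astype(np.float64), [sy, sx], order=order, mode="constant", cval=0.0
    )
    out[mask] = 0.0
    return out, mask


@dataclass
class AlignedStack:
    """Aligned frames plus the fill mask and the transforms that made them."""

    data: np.ndarray  # T'×H×W float
    mask: np.ndarray  # T'×H×W bool, True = no source pixel
    transforms: list[RigidTransform]
    frame_indices: np.ndarray  # raw-frame index of each aligned frame

    def __post_init__(self) -> None:
        if self.data.shape != self.mask.shape:
            raise ValueError("data and mask shapes differ")
        if len(self.transforms) != self.data.shape[0]:
            raise ValueError("one transform required per aligned frame")


def align_stack(
    stack: FrameStack,
    table: MarkerTable,
    roles: MarkerRoles,
    threshold: float = DEFAULT_LIKELIHOOD_THRESHOLD,
    heading: str = "two-point",
    interpolation: str = "bilinear",
    mirror: bool = False,
    out_shape: tuple[int, int] | None = None,
) -> AlignedStack:
    """Filter, compute per-frame transforms, and resample the stack.

    Only frames where target, anterior and peripheral markers all pass the
    likelihood threshold are aligned; the rest are dropped (their indices
    simply do not appear in ``frame_indices``).  ``heading`` selects the
    rotation estimator: ``"two-point"`` (target→anterior) or
    ``"procrustes"`` (least-squares over anterior + peripheral markers
    against the first valid frame's posture).  ``mirror`` flips x first,
    for ventral-view recordings.
    """
    roles.validate(table)
    required = [roles.target, roles.anterior, *roles.peripheral]
    kept, _report = filter_by_likelihood(table, threshold, required)
    kept = kept[(kept >= 0) & (kept < stack.n_frames)]
    if kept.size == 0:
        raise ValueError("no valid frames: every frame failed the likelihood filter")
    if heading not in ("two-point", "procrustes"):
        raise ValueError(f"unknown heading mode {heading!r}")

    data = stack.data
    h_in, w_in = data.shape[1:]
    if mirror:
        data = data[:, :, ::-1]
    H, W = out_shape if out_shape is not None else (h_in, w_in)

    def marker_xy(frame: int, bodypart: str) -> np.ndarray:
        x, y, _ = table.at_frame(frame)[bodypart]
        if mirror:
            x = (w_in - 1) - x
        return np.array([x, y])

    rot_parts = [roles.anterior, *roles.peripheral]
    reference: np.ndarray | None = None

    transforms: list[RigidTransform] = []
    aligned = np.empty((kept.size, H, W), dtype=np.float64)
    fill = np.empty((kept.size, H, W), dtype=bool)
    for i, frame in enumerate(kept):
        target = marker_xy(frame, roles.target)
        anterior = marker_xy(frame, roles.anterior)
        try:
            theta = heading_angle(target, anterior)
        except ValueError:
            t = RigidTransform(frame=int(frame), valid=False, out_shape=(H, W))
            transforms.append(t)
            aligned[i] = 0.0
            fill[i] = True
            continue
        if heading == "procrustes" and rot_parts:
            offsets = np.stack([marker_xy(frame, bp) - target for bp in rot_parts])
            if reference is None:
                # first valid frame, pre-rotated to face up, anchors the posture
                reference = offsets @ _rotation_matrix(theta).T
            theta = _procrustes_theta(offsets, reference)
        centre = np.array([(W - 1) / 2.0, (H - 1) / 2.0])
        dx, dy = centre - target
        t = RigidTransform(
            frame=int(frame), dx=float(dx), dy=float(dy), theta=theta,
            out_shape=(H, W),
        )
        transforms.append(t)
        aligned[i], fill[i] = apply_transform(data[frame], t, interpolation)
    return AlignedStack(
        data=aligned, mask=fill, transforms=transforms, frame_indices=kept
    )


def transforms_to_csv(transforms: list[RigidTransform], path: str | os.PathLike) -> None:
    pd.DataFrame(
        [
            {
                "frame": t.frame,
                "dx": t.dx,
                "dy": t.dy,
                "theta_rad": t.theta,
                "valid": t.valid,
            }
            for t in transforms
        ]
    ).to_csv(path, index=False)


def transforms_from_csv(
    path: str | os.PathLike, out_shape: tuple[int, int] | None = None
) -> list[RigidTransform]:
    df = pd.read_csv(path)
    return [
        RigidTransform(
            frame=int(r.frame),
            dx=float(r.dx),
            dy=float(r.dy),
            theta=float(r.theta_rad),
            valid=bool(r.valid),
            out_shape=out_shape,
        )
        for r in df.itertuples(index=False)
    ]
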