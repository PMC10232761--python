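"""Frame-stack I/O and display rendering.

Stacks are stored as multi-page grayscale TIFF or as a single 3-D HDF5
dataset (named ``frames``) carrying ``exposure_ms`` / ``frame_period_ms``
/ ``channel_label`` attributes.  TIFF pages are read in storage order and
interpreted as time order.

Display scaling is linear between a per-channel (vmin, vmax) pair, as in
raw-count figure captions ("minimum and maximum displayed values");
multi-channel composites are additive per RGB primary.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import h5py
import imageio.v3 as iio
import numpy as np
import tifffile

from .acquisition import FrameStack

_SUPPORTED_DTYPES = ("uint8", "uint16", "uint32", "float32", "float64")

HDF5_DATASET = "frames"

#: Default channel colours in cycle order (magenta, red, green, blue).
DEFAULT_COLORS = (
    (1.0, 0.0, 1.0),
    (1.0, 0.0, 0.0),
    (0.0, 1.0, 0.0),
    (0.0, 0.0, 1.0),
)


class StackFormatError(ValueError):
    """Raised when a file does not hold a well-formed T×H×W stack."""


@dataclass(frozen=True)
class DisplayRange:
    """Linear display window: counts at/below vmin → 0, at/above vmax → 1."""

    vmin: float
    vmax: float

    def __post_init__(self) -> None:
        if not self.vmin < self.vmax:
            raise ValueError(f"require vmin < vmax, got ({self.vmin}, {self.vmax})")


def _check_dtype(arr: np.ndarray, path) -> None:
    if arr.dtype.name not in _SUPPORTED_DTYPES:
        raise StackFormatError(
            f"{path}: unsupported stack dtype {arr.dtype.name!r} "
            f"(supported: {', '.join(_SUPPORTED_DTYPES)})"
        )


def read_stack(path: str | os.PathLike) -> FrameStack:
    """Read a stack from multi-page TIFF or HDF5, preserving dtype and order."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".h5", ".hdf5", ".hdf"):
        with h5py.File(path, "r") as fh:
            if HDF5_DATASET not in fh:
                raise StackFormatError(f"{path}: no dataset {HDF5_DATASET!r}")
            ds = fh[HDF5_DATASET]
            if ds.ndim != 3:
                raise StackFormatError(f"{path}: dataset is {ds.ndim}-D, expected 3-D")
            data = ds[...]
            _check_dtype(data, path)
            exposure = float(ds.attrs.get("exposure_ms", 1.0))
            period = ds.attrs.get("frame_period_ms")
            label = ds.attrs.get("channel_label")
            return FrameStack(
                data=data,
                exposure_ms=exposure,
                frame_period_ms=float(period) if period is not None else None,
                channel_label=str(label) if label is not None else None,
            )
    if suffix in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            shapes = {page.shape for page in tf.pages}
            if len(shapes) > 1:
                raise StackFormatError(
                    f"{path}: TIFF pages differ in size: {sorted(shapes)}"
                )
            data = tf.asarray()
        if data.ndim == 2:
            data = data[None]
        if data.ndim != 3:
            raise StackFormatError(f"{path}: expected grayscale pages, got {data.shape}")
        _check_dtype(data, path)
        # timing metadata is not stored in plain TIFF; default 1 ms
        return FrameStack(data=data, exposure_ms=1.0)
    raise StackFormatError(f"{path}: unrecognised stack format {suffix!r}")


def write_stack(stack: FrameStack, path: str | os.PathLike) -> None:
    """Write a stack; TIFF for integer data, HDF5 for anything (with metadata).

    Round-trips bit-exactly: ``read_stack(write_stack(s)) == s``.
    """
    path = Path(path)
    if not path.parent.is_dir():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    suffix = path.suffix.lower()
    try:
        if suffix in (".h5", ".hdf5", ".hdf"):
            with h5py.File(path, "w") as fh:
                ds = fh.create_dataset(HDF5_DATASET, data=stack.data)
                ds.attrs["exposure_ms"] = stack.exposure_ms
                ds.attrs["frame_period_ms"] = stack.frame_period_ms
                if stack.channel_label is not None:
                    ds.attrs["channel_label"] = stack.channel_label
        elif suffix in (".tif", ".tiff"):
            tifffile.imwrite(path, stack.data)
        else:
            raise StackFormatError(f"{path}: unrecognised stack format {suffix!r}")
    except OSError as exc:
        raise OSError(f"failed writing stack to {path}: {exc}") from exc


def scale_display(frame: np.ndarray, display_range: DisplayRange) -> np.ndarray:
    """Linearly map counts into [0, 1], clipping outside (vmin, vmax)."""
    frame = np.asarray(frame, dtype=float)
    span = display_range.vmax - display_range.vmin
    return np.clip((frame - display_range.vmin) / span, 0.0, 1.0)


def merge_channels(
    frames: list[np.ndarray] | tuple[np.ndarray, ...],
    colors: list[tuple[float, float, float]] | None = None,
) -> np.ndarray:
    """Additive RGB composite of display-scaled channel frames.

    Each channel contributes ``value × colour`` per pixel per primary; the
    per-primary sums are clipped to [0, 1].
    """
    if not frames:
        raise ValueError("no channels to merge")
    if colors is None:
        colors = list(DEFAULT_COLORS[: len(frames)])
    if len(colors) != len(frames):
        raise ValueError(f"{len(frames)} channels but {len(colors)} colours")
    shape = np.asarray(frames[0]).shape
    out = np.zeros(shape + (3,), dtype=float)
    for frame, color in zip(frames, colors):
        frame = np.asarray(frame, dtype=float)
        if frame.shape != shape:
            raise ValueError(f"channel shape {frame.shape} != {shape}")
        out += frame[..., None] * np.asarray(color, dtype=float)
    return np.clip(out, 0.0, 1.0)


def save_composite(rgb: np.ndarray, path: str | os.PathLike) -> None:
    """Save an RGB composite in [0, 1] as an 8-bit image (PNG/TIFF)."""
    rgb8 = np.clip(np.round(np.asarray(rgb) * 255.0), 0, 255).astype(np.uint8)
    iio.imwrite(os.fspath(path), rgb8)
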