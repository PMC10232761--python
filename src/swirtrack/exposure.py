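"""Exposure-time simulation by temporal frame averaging.

A longer exposure is emulated by replacing each frame with the arithmetic
mean of itself and its symmetric temporal neighbours: a window of
``2k + 1`` frames at base exposure ``e`` simulates an exposure of
``(2k + 1) × e``.  Averaging (rather than summing) keeps display ranges
comparable across windows.  Odd multiples of a 3 ms base give the
simulated exposures 9, 21, 33, 99 and 201 ms.
"""

from __future__ import annotations

import math

import numpy as np

from .acquisition import FrameStack


def window_for_exposure(base_ms: float, target_ms: float) -> int:
    """Odd averaging window whose total ``window × base`` best matches target.

    Returns ``round(target / base)`` coerced to the nearest odd integer
    ≥ 1 (ties round up).  ``window_for_exposure(3, 100) == 33`` (99 ms).
    """
    if base_ms <= 0:
        raise ValueError("base_ms must be positive")
    if target_ms < base_ms:
        raise ValueError(f"target {target_ms} ms is below base exposure {base_ms} ms")
    ratio = target_ms / base_ms
    window = 2 * math.floor((ratio - 1.0) / 2.0 + 0.5) + 1
    return max(window, 1)


def simulate_exposure(
    stack: FrameStack, window: int, edge: str = "drop"
) -> FrameStack:
    """Average each frame with its symmetric temporal neighbours.

    Parameters
    ----------
    stack:
        Input video at the base exposure.
    window:
        Odd number of frames to average (``2k + 1``); ``window=1`` is the
        identity.
    edge:
        ``"drop"`` (default) discards the first and last ``k`` frames, for
        which no full window exists; ``"truncate"`` keeps all ``T`` frames
        and averages the available partial window at the edges.

    Returns a real-valued stack whose ``exposure_ms`` (and
    ``frame_period_ms``) are scaled by the window.  Use
    :func:`quantize_counts` to return to integer counts.
    """
    if window % 2 == 0 or window < 1:
        raise ValueError(f"window must be odd and positive, got {window}")
    T = stack.n_frames
    if window > T:
        raise ValueError(f"window {window} exceeds stack length {T}")
    if edge not in ("drop", "truncate"):
        raise ValueError(f"unknown edge mode {edge!r}")
    k = window // 2
    data = stack.data.astype(np.float64)
    # running-sum formulation: mean over [t-k, t+k] from one cumulative sum
    csum = np.cumsum(data, axis=0)
    zero = np.zeros_like(csum[:1])
    csum = np.concatenate([zero, csum], axis=0)  # csum[i] = sum of frames < i
    if edge == "drop":
        lo = np.arange(0, T - 2 * k)
        hi = lo + 2 * k + 1
        counts = np.full(T - 2 * k, float(window))
    else:
        centers = np.arange(T)
        lo = np.maximum(centers - k, 0)
        hi = np.minimum(centers + k + 1, T)
        counts = (hi - lo).astype(float)
    out = (csum[hi] - csum[lo]) / counts[:, None, None]
    return FrameStack(
        data=out,
        exposure_ms=window * stack.exposure_ms,
        frame_period_ms=window * stack.frame_period_ms,
        channel_label=stack.channel_label,
    )


def quantize_counts(stack: FrameStack, dtype=np.uint16) -> FrameStack:
    """Round a real-valued stack back to integer counts (round-half-even)."""
    info = np.iinfo(dtype)
    data = np.clip(np.rint(stack.data), info.min, info.max).astype(dtype)
    return stack.with_data(data)
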