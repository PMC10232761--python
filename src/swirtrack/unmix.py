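"""Linear spectral unmixing of excitation-multiplexed channels.

With excitation multiplexing, fluorophore A partially excited by
fluorophore B's laser bleeds into channel B ("crosstalk").  If the
emission response is linear across excitations, the observed channel
intensities at a pixel are ``y = M a`` where ``M`` is the C×F
channel-by-fluorophore response matrix and ``a`` the fluorophore
abundances; :func:`unmix_pixelwise` inverts this per pixel by (optionally
non-negative) least squares.

Unmixing is an *optional* stage, off by default: an acquisition tuned so
channels are visually distinguishable (dye dose down, laser power up per
wavelength) avoids it entirely, and fluorophore response deviates from
linearity across organ geometries, so unmixed values are not quantitative
across organs.  :func:`crosstalk_report` estimates ``M`` from reference
regions where each fluorophore dominates, as a diagnostic for how much
crosstalk the acquisition left in.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .acquisition import FrameStack
from .demux import ChannelSet


@dataclass
class CrosstalkMatrix:
    """C×F response matrix: rows = excitation channels, cols = fluorophores."""

    matrix: np.ndarray
    channel_labels: tuple[str, ...]
    fluor_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D")
        C, F = self.matrix.shape
        if len(self.channel_labels) != C or len(self.fluor_labels) != F:
            raise ValueError("label lengths must match matrix shape")
        if np.any(self.matrix < 0):
            raise ValueError("crosstalk entries must be non-negative")
        if np.any(self.matrix.max(axis=0) <= 0):
            dead = [
                f for f, m in zip(self.fluor_labels, self.matrix.max(axis=0)) if m <= 0
            ]
            raise ValueError(f"fluorophores with no positive response: {dead}")
        self.channel_labels = tuple(self.channel_labels)
        self.fluor_labels = tuple(self.fluor_labels)

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.matrix))

    def to_csv(self, path: str | os.PathLike) -> None:
        pd.DataFrame(
            self.matrix, index=list(self.channel_labels), columns=list(self.fluor_labels)
        ).to_csv(path)

    @classmethod
    def from_csv(cls, path: str | os.PathLike) -> "CrosstalkMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(
            matrix=df.to_numpy(dtype=float),
            channel_labels=tuple(str(i) for i in df.index),
            fluor_labels=tuple(str(c) for c in df.columns),
        )

    @classmethod
    def identity(cls, labels: tuple[str, ...]) -> "CrosstalkMatrix":
        return cls(np.eye(len(labels)), tuple(labels), tuple(labels))


def _stacked_observations(channels: ChannelSet, order: tuple[str, ...]) -> np.ndarray:
    stacks = []
    lengths = {channels.channels[l].n_frames for l in order}
    if len(lengths) > 1:
        raise ValueError(f"member stacks differ in length: {sorted(lengths)}")
    for label in order:
        stacks.append(channels.channels[label].data.astype(np.float64))
    return np.stack(stacks, axis=0)  # C × T × H × W


def unmix_pixelwise(
    channels: ChannelSet, M: CrosstalkMatrix, nonneg: bool = False
) -> ChannelSet:
    """Solve ``observed = M · abundance`` per pixel and frame.

    Unconstrained solves use ordinary least squares; with ``nonneg`` the
    abundances are constrained ≥ 0 (active-set NNLS per pixel, so the
    result satisfies the KKT conditions).  Requires at least as many
    channels as fluorophores and a full-rank ``M``.
    """
    missing = set(M.channel_labels) - set(channels.channels)
    if missing:
        raise ValueError(f"channels absent from set: {sorted(missing)}")
    C, F = M.matrix.shape
    if C < F:
        raise ValueError(f"underdetermined: {C} channels < {F} fluorophores")
    if np.linalg.matrix_rank(M.matrix) < F:
        raise ValueError(
            f"rank-deficient crosstalk matrix (condition number "
            f"{M.condition_number:.3g})"
        )
    Y = _stacked_observations(channels, M.channel_labels)  # C×T×H×W
    T, H, W = Y.shape[1:]
    Yflat = Y.reshape(C, -1)
    if nonneg:
        A = np.empty((F, Yflat.shape[1]))
        for j in range(Yflat.shape[1]):
            A[:, j] = nnls(M.matrix, Yflat[:, j])[0]
    else:
        A = np.linalg.lstsq(M.matrix, Yflat, rcond=None)[0]
    abundances = A.reshape(F, T, H, W)
    template = channels.channels[M.channel_labels[0]]
    out = {
        fluor: FrameStack(
            data=abundances[f],
            exposure_ms=template.exposure_ms,
            frame_period_ms=template.frame_period_ms,
            channel_label=fluor,
        )
        for f, fluor in enumerate(M.fluor_labels)
    }
    return ChannelSet(channels=out, cycle_length=F, source_offset=0)


def crosstalk_report(
    channels: ChannelSet, reference_rois: dict[str, np.ndarray]
) -> CrosstalkMatrix:
    """Estimate the crosstalk matrix from per-fluorophore reference regions.

    ``reference_rois`` maps each fluorophore label to an H×W boolean mask
    of a region where that fluorophore dominates.  Column *f* of the
    estimate is the mean intensity of region *f* in every channel,
    normalised to the column's maximum (so the dominant channel reads 1).
    """
    channel_labels = tuple(channels.channels)
    fluor_labels = tuple(reference_rois)
    cols = []
    for fluor in fluor_labels:
        mask = np.asarray(reference_rois[fluor], dtype=bool)
        if not mask.any():
            raise ValueError(f"empty reference region for {fluor!r}")
        col = np.array(
            [
                float(channels.channels[label].data[:, mask].mean())
                for label in channel_labels
            ]
        )
        if col.max() <= 0:
            raise ValueError(f"reference region for {fluor!r} contains no signal")
        cols.append(col / col.max())
    return CrosstalkMatrix(
        matrix=np.stack(cols, axis=1),
        channel_labels=channel_labels,
        fluor_labels=fluor_labels,
    )
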