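"""De-interleaving of excitation-multiplexed recordings.

With alternating-laser excitation every raw frame belongs to exactly one
channel: frame ``i`` was illuminated by ``cycle[(i + offset) % C]``.
:func:`deinterleave` splits the interleaved recording into per-channel
stacks; :func:`interleave` is its exact inverse; :func:`estimate_offset`
recovers the cycle phase of a recording that started mid-cycle, using
per-channel brightness differences.

Strict cycle periodicity is assumed (synchronised hardware triggering);
dropped-frame resynchronisation is out of scope, but
:func:`channel_separation_report` flags channels whose intensity
statistics overlap, the symptom of a slipped cycle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .acquisition import AcquisitionConfig, FrameStack


@dataclass
class ChannelSet:
    """Per-channel stacks produced by de-interleaving one recording."""

    channels: dict[str, FrameStack]
    cycle_length: int
    source_offset: int

    def __post_init__(self) -> None:
        shapes = {s.data.shape[1:] for s in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"member stacks differ in H×W: {sorted(shapes)}")
        lengths = [s.n_frames for s in self.channels.values()]
        if lengths and max(lengths) - min(lengths) > 1:
            raise ValueError(f"member lengths differ by more than 1: {lengths}")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.channels)

    @property
    def total_frames(self) -> int:
        return sum(s.n_frames for s in self.channels.values())


def _channel_counts(total: int, cycle_length: int, offset: int) -> list[int]:
    """Number of raw frames each cycle channel receives."""
    idx = (np.arange(total) + offset) % cycle_length
    return [int(np.sum(idx == c)) for c in range(cycle_length)]


def deinterleave(stack: FrameStack, config: AcquisitionConfig) -> ChannelSet:
    """Split an interleaved recording into one stack per cycle channel.

    Partitions the frames: every raw frame is assigned to exactly one
    channel and within-channel order is preserved.  Trailing partial
    cycles are kept, so member lengths may differ by one.
    """
    C = config.cycle_length
    channel_of = (np.arange(stack.n_frames) + config.offset) % C
    channels: dict[str, FrameStack] = {}
    for c, laser in enumerate(config.cycle):
        frames = stack.data[channel_of == c]
        if frames.shape[0] == 0:
            # short recordings may not reach every channel; keep an empty
            # channel out of the set rather than a zero-length stack
            continue
        channels[laser.label] = FrameStack(
            data=frames,
            exposure_ms=laser.exposure_ms,
            frame_period_ms=config.cycle_time_ms,
            channel_label=laser.label,
        )
    return ChannelSet(channels=channels, cycle_length=C, source_offset=config.offset)


def interleave(channels: ChannelSet, config: AcquisitionConfig) -> FrameStack:
    """Rebuild the interleaved recording; exact inverse of :func:`deinterleave`."""
    C = config.cycle_length
    total = channels.total_frames
    expected = _channel_counts(total, C, config.offset)
    stacks: list[np.ndarray | None] = [None] * C
    for c, laser in enumerate(config.cycle):
        member = channels.channels.get(laser.label)
        n = member.n_frames if member is not None else 0
        if n != expected[c]:
            raise ValueError(
                f"channel {laser.label!r} has {n} frames, expected {expected[c]} "
                f"for total {total}, C={C}, offset={config.offset}"
            )
        if member is not None:
            stacks[c] = member.data
    first = next(iter(channels.channels.values()))
    out = np.empty((total,) + first.data.shape[1:], dtype=first.data.dtype)
    channel_of = (np.arange(total) + config.offset) % C
    for c in range(C):
        if stacks[c] is not None:
            out[channel_of == c] = stacks[c]
    return FrameStack(
        data=out,
        exposure_ms=config.cycle[0].exposure_ms,
        frame_period_ms=None,
    )


def estimate_offset(
    stack: FrameStack,
    config: AcquisitionConfig,
    reference: dict[str, float] | None = None,
) -> int:
    """Recover the cycle phase of a recording that started mid-cycle.

    Grouping frames by ``i mod C`` yields the same residue classes for
    every candidate offset — only the channel *labels* move — so the phase
    is identifiable only against an expectation of how bright each channel
    should be.  ``reference`` maps channel label → expected relative mean
    intensity (e.g. measured on a correctly phased calibration recording);
    if omitted, relative laser power densities from the config stand in,
    under the declared assumption that collected emission scales with
    excitation power.

    For every offset in [0, C) the observed per-class mean intensities are
    matched (Pearson correlation, both sides mean-normalised) against the
    reference in that offset's labelling; the best-scoring offset wins,
    ties breaking to the smallest (so a constant stack returns 0).
    """
    C = config.cycle_length
    if C == 1:
        return 0
    if stack.n_frames < 2 * C:
        raise ValueError(
            f"insufficient frames: need ≥ {2 * C} for C={C}, got {stack.n_frames}"
        )
    if reference is None:
        reference = {c.label: c.power_density_mw_cm2 for c in config.cycle}
    missing = set(config.labels) - set(reference)
    if missing:
        raise ValueError(f"reference missing channels: {sorted(missing)}")
    expected = np.array([reference[l] for l in config.labels], dtype=float)
    residue = np.arange(stack.n_frames) % C
    frame_means = stack.data.reshape(stack.n_frames, -1).mean(axis=1)
    class_means = np.array([frame_means[residue == r].mean() for r in range(C)])
    exp_c = expected - expected.mean()
    obs_c = class_means - class_means.mean()
    denom = np.linalg.norm(exp_c) * np.linalg.norm(obs_c)
    if denom < 1e-12:
        return 0  # degenerate: no brightness contrast to match against
    best_offset, best_score = 0, -np.inf
    for offset in range(C):
        # under this offset, channel c receives residue class (c - offset) mod C
        obs = class_means[(np.arange(C) - offset) % C]
        score = float(np.dot(exp_c, obs - obs.mean()) / denom)
        if score > best_score + 1e-12:
            best_offset, best_score = offset, score
    return best_offset


def channel_frame_indices(
    total_frames: int, config: AcquisitionConfig, label: str
) -> np.ndarray:
    """Raw-frame indices belonging to one cycle channel."""
    try:
        c = list(config.labels).index(label)
    except ValueError:
        raise ValueError(f"channel {label!r} not in cycle {config.labels}") from None
    idx = np.arange(total_frames)
    return idx[(idx + config.offset) % config.cycle_length == c]


def markers_for_channel(
    table, total_frames: int, config: AcquisitionConfig, label: str
):
    """Restrict a raw-frame marker table to one channel's frames.

    Marker tables index *raw* recording frames; a de-interleaved channel
    renumbers its frames 0..T_c−1.  Returns a new
    :class:`~swirtrack.markers.MarkerTable` in channel numbering.
    """
    from .markers import MarkerTable

    raw = channel_frame_indices(total_frames, config, label)
    remap = {int(r): i for i, r in enumerate(raw)}
    sub = table.df[table.df["frame"].isin(raw)].copy()
    sub["frame"] = sub["frame"].map(remap)
    return MarkerTable(sub)


def channel_separation_report(channels: ChannelSet) -> list[str]:
    """Flag channel pairs whose mean±std intensity intervals overlap.

    Overlapping per-channel intensity statistics are a symptom of a
    slipped laser cycle (dropped frames); the report is advisory only.
    """
    stats = {
        label: (float(s.data.mean()), float(s.data.std()))
        for label, s in channels.channels.items()
    }
    warnings = []
    labels = list(stats)
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            ma, sa = stats[a]
            mb, sb = stats[b]
            if abs(ma - mb) <= sa + sb:
                warnings.append(
                    f"channels {a!r} and {b!r} overlap in intensity "
                    f"({ma:.1f}±{sa:.1f} vs {mb:.1f}±{sb:.1f})"
                )
    return warnings
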