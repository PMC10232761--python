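"""Synthetic phantom videos of a freely moving, fluorescently labelled mouse.

The generator renders a rigid "phantom mouse" — an elliptical body
carrying 2-D Gaussian organ emitters, each tagged with a fluorophore —
performing a random walk (position and heading) across the canvas, and
records it through an excitation-multiplexing cycle: raw frame *t* sees
only channel ``cycle[(t + offset) % C]``, whose expected pixel value is

    background + Σ_f  M[c, f] · abundance_f(pixel, t)

with ``M`` the channel×fluorophore crosstalk matrix.  Shot (Poisson) and
Gaussian read noise are applied on top, and the result is quantised to
16-bit counts.  Alongside the video the generator returns exact marker
tables (organ centres, an anterior head point and peripheral body points,
all at likelihood 1), per-frame ground-truth pose, and the true
per-fluorophore abundance stacks — so every pipeline stage can be tested
for recovery against known truth, with no downloaded data.

All randomness derives from one integer seed via independent substreams
(trajectory / shot noise / read noise), so identical seeds give
bit-identical phantoms and partial re-runs are reproducible.

What the phantom does *not* emulate: tissue scattering and absorption,
depth-dependent blur, body deformation, and nonlinear fluorophore
response across organ geometries.  Tests passing on phantoms therefore
demonstrate correctness of the processing, not robustness to those
real-data effects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .acquisition import AcquisitionConfig, FrameStack, LaserChannel
from .markers import DEFAULT_LIKELIHOOD_THRESHOLD, MarkerTable
from .unmix import CrosstalkMatrix

ANTERIOR_BODYPART = "head"
PERIPHERAL_BODYPARTS = ("tail_base", "left_flank", "right_flank")


def _rot(theta: float) -> np.ndarray:
    c, s = math.cos(theta), math.sin(theta)
    return np.array([[c, -s], [s, c]])


@dataclass(frozen=True)
class OrganSpec:
    """One Gaussian organ emitter, rigidly attached to the body frame.

    ``offset`` is the organ centre in body coordinates (u rightward,
    v toward the tail; the head lies at negative v).  ``sigma`` gives the
    Gaussian half-widths (σ_u, σ_v) in px; ``peak_counts`` the expected
    counts at the organ centre in its own channel at unit profile.
    ``profile`` optionally modulates emission over time (length = total
    raw frames, or any length resampled by frame index modulo).
    """

    name: str
    fluorophore: str
    offset: tuple[float, float]
    sigma: tuple[float, float]
    peak_counts: float
    profile: tuple[float, ...] | None = None

    def profile_at(self, t: int) -> float:
        if self.profile is None:
            return 1.0
        return self.profile[t % len(self.profile)]


@dataclass
class PhantomSpec:
    """Full description of a phantom recording; every field has a default
    mirroring the four-channel awake-mouse experiment (scaled-down canvas)."""

    height: int = 144
    width: int = 112
    organs: tuple[OrganSpec, ...] = ()
    body_half_width: float = 28.0
    body_half_length: float = 52.0
    anterior_distance: float = 45.0
    step_sigma_px: float = 1.5
    turn_sigma_rad: float = 0.06
    start_position: tuple[float, float] | None = None
    start_heading: float = 0.0
    crosstalk: CrosstalkMatrix | None = None
    poisson_noise: bool = True
    read_noise_sigma: float = 5.0
    background_counts: float = 100.0
    config: AcquisitionConfig | None = None
    duration_frames: int = 240
    seed: int = 0

    def __post_init__(self) -> None:
        if self.config is None:
            self.config = _default_cycle(self.width, self.height)
        if not self.organs:
            self.organs = _default_organs()
        if self.crosstalk is None:
            fluors = tuple(dict.fromkeys(o.fluorophore for o in self.organs))
            self.crosstalk = CrosstalkMatrix.identity(fluors)
        if self.start_position is None:
            self.start_position = ((self.width - 1) / 2.0, (self.height - 1) / 2.0)
        for organ in self.organs:
            u, v = organ.offset
            r = (u / self.body_half_width) ** 2 + (v / self.body_half_length) ** 2
            if r > 1.0:
                raise ValueError(
                    f"organ {organ.name!r} at body offset {organ.offset} lies "
                    "outside the body ellipse"
                )
        fluors = {o.fluorophore for o in self.organs}
        missing = fluors - set(self.crosstalk.fluor_labels)
        if missing:
            raise ValueError(f"fluorophores missing from crosstalk matrix: {missing}")
        if tuple(self.config.labels) != tuple(self.crosstalk.channel_labels):
            raise ValueError(
                "crosstalk channel labels must match the cycle labels in order: "
                f"{self.config.labels} vs {self.crosstalk.channel_labels}"
            )
        if self.duration_frames < 1:
            raise ValueError("duration_frames must be ≥ 1")


def _default_cycle(width: int, height: int) -> AcquisitionConfig:
    """Four-laser cycle at 7.8 ms per frame behind a 1150 nm long-pass."""
    return AcquisitionConfig(
        cycle=(
            LaserChannel("ICG", 785.0, 49.0, 7.8),
            LaserChannel("JuloChrom5", 892.0, 81.0, 7.8),
            LaserChannel("Chrom7", 968.0, 113.0, 7.8),
            LaserChannel("JuloFlav7", 1064.0, 165.0, 7.8),
        ),
        longpass_nm=1150.0,
        detector_width_px=width,
        detector_height_px=height,
        offset=0,
    )


def _default_organs() -> tuple[OrganSpec, ...]:
    """Labelled structures loosely following the four-dye biodistribution:
    ICG in the intestines, JuloChrom5 in the liver, Chrom7 in the
    vasculature, JuloFlav7 in the peritoneal space."""
    return (
        OrganSpec("intestines", "ICG", (0.0, 12.0), (9.0, 8.0), 1800.0),
        OrganSpec("liver", "JuloChrom5", (0.0, -10.0), (8.0, 6.0), 800.0),
        OrganSpec("vasculature", "Chrom7", (-10.0, 0.0), (3.0, 14.0), 1600.0),
        OrganSpec("peritoneum", "JuloFlav7", (10.0, 4.0), (6.0, 9.0), 1500.0),
    )


def paper_preset(duration_frames: int = 240, seed: int = 0) -> PhantomSpec:
    """The default four-fluorophore phantom ("paper-like" conditions)."""
    return PhantomSpec(duration_frames=duration_frames, seed=seed)


@dataclass
class PhantomResult:
    """Everything :func:`generate` knows about a phantom recording."""

    stack: FrameStack  # interleaved uint16 recording
    config: AcquisitionConfig
    markers: MarkerTable  # exact marker positions, likelihood 1.0
    truth: pd.DataFrame  # frame, channel, body_x, body_y, heading_rad
    abundances: dict[str, np.ndarray]  # fluorophore → T×H×W float32
    spec: PhantomSpec

    def organ_centers(self, organ: str) -> np.ndarray:
        """Ground-truth (x, y) centre of one organ per raw frame."""
        sub = self.markers.df[self.markers.df["bodypart"] == organ]
        sub = sub.sort_values("frame")
        return sub[["x", "y"]].to_numpy()


def _simulate_trajectory(
    spec: PhantomSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Random-walk body position and heading; positions reflect off a
    margin so the body stays on canvas."""
    T = spec.duration_frames
    margin = max(spec.body_half_width, spec.body_half_length) * 0.5
    lo = np.array([margin, margin])
    hi = np.array([spec.width - 1 - margin, spec.height - 1 - margin])
    pos = np.empty((T, 2))
    heading = np.empty(T)
    pos[0] = np.clip(np.asarray(spec.start_position, dtype=float), lo, hi)
    heading[0] = spec.start_heading
    steps = rng.normal(0.0, spec.step_sigma_px, size=(T - 1, 2)) if T > 1 else None
    turns = rng.normal(0.0, spec.turn_sigma_rad, size=T - 1) if T > 1 else None
    for t in range(1, T):
        p = pos[t - 1] + steps[t - 1]
        # reflect into the box
        for d in range(2):
            if p[d] < lo[d]:
                p[d] = 2 * lo[d] - p[d]
            elif p[d] > hi[d]:
                p[d] = 2 * hi[d] - p[d]
        pos[t] = np.clip(p, lo, hi)
        h = heading[t - 1] + turns[t - 1]
        heading[t] = (h + math.pi) % (2 * math.pi) - math.pi
    return pos, heading


def generate(spec: PhantomSpec) -> PhantomResult:
    """Render a phantom recording with full ground truth.

    Deterministic in ``spec.seed``: trajectory, shot noise and read noise
    each draw from an independent substream spawned from the one seed.
    """
    ss = np.random.SeedSequence(spec.seed)
    traj_ss, shot_ss, read_ss = ss.spawn(3)
    traj_rng = np.random.default_rng(traj_ss)
    shot_rng = np.random.default_rng(shot_ss)
    read_rng = np.random.default_rng(read_ss)

    config = spec.config
    M = spec.crosstalk
    T, H, W = spec.duration_frames, spec.height, spec.width
    C = config.cycle_length
    pos, heading = _simulate_trajectory(spec, traj_rng)

    ys, xs = np.mgrid[0:H, 0:W].astype(float)

    frames = np.empty((T, H, W), dtype=np.uint16)
    abundances = {f: np.zeros((T, H, W), dtype=np.float32) for f in M.fluor_labels}
    marker_rows = []
    truth_rows = []

    for t in range(T):
        c = (t + config.offset) % C
        channel_label = config.cycle[c].label
        h = heading[t]
        R_inv = _rot(-h)
        dx = xs - pos[t, 0]
        dy = ys - pos[t, 1]
        u = R_inv[0, 0] * dx + R_inv[0, 1] * dy
        v = R_inv[1, 0] * dx + R_inv[1, 1] * dy
        # true abundance per fluorophore at this instant
        for organ in spec.organs:
            amp = organ.peak_counts * organ.profile_at(t)
            if amp == 0.0:
                continue
            su, sv = organ.sigma
            ou, ov = organ.offset
            blob = amp * np.exp(
                -(((u - ou) / su) ** 2 + ((v - ov) / sv) ** 2) / 2.0
            )
            abundances[organ.fluorophore][t] += blob.astype(np.float32)
        # expected counts in the active channel
        ci = list(M.channel_labels).index(channel_label)
        expected = np.full((H, W), spec.background_counts, dtype=np.float64)
        for f, fluor in enumerate(M.fluor_labels):
            coeff = M.matrix[ci, f]
            if coeff:
                expected += coeff * abundances[fluor][t].astype(np.float64)
        if spec.poisson_noise:
            counts = shot_rng.poisson(expected).astype(np.float64)
        else:
            counts = expected
        if spec.read_noise_sigma > 0:
            counts = counts + read_rng.normal(0.0, spec.read_noise_sigma, size=(H, W))
        frames[t] = np.clip(np.rint(counts), 0, 65535).astype(np.uint16)

        R_fwd = _rot(h)
        for organ in spec.organs:
            cx, cy = pos[t] + R_fwd @ np.asarray(organ.offset)
            marker_rows.append(
                {"frame": t, "bodypart": organ.name, "x": cx, "y": cy, "likelihood": 1.0}
            )
        body_points = {
            ANTERIOR_BODYPART: (0.0, -spec.anterior_distance),
            "tail_base": (0.0, spec.body_half_length),
            "left_flank": (-spec.body_half_width, 0.0),
            "right_flank": (spec.body_half_width, 0.0),
        }
        for name, offset in body_points.items():
            px, py = pos[t] + R_fwd @ np.asarray(offset)
            marker_rows.append(
                {"frame": t, "bodypart": name, "x": px, "y": py, "likelihood": 1.0}
            )
        truth_rows.append(
            {
                "frame": t,
                "channel": channel_label,
                "body_x": pos[t, 0],
                "body_y": pos[t, 1],
                "heading_rad": h,
            }
        )

    stack = FrameStack(
        data=frames,
        exposure_ms=config.cycle[0].exposure_ms,
        frame_period_ms=None,
    )
    return PhantomResult(
        stack=stack,
        config=config,
        markers=MarkerTable(pd.DataFrame(marker_rows)),
        truth=pd.DataFrame(truth_rows),
        abundances=abundances,
        spec=spec,
    )


def corrupt_markers(
    table: MarkerTable,
    jitter_sigma_px: float,
    miss_rate: float,
    seed: int,
    threshold: float = DEFAULT_LIKELIHOOD_THRESHOLD,
) -> MarkerTable:
    """Model pose-estimation error on a ground-truth marker table.

    Adds isotropic Gaussian jitter to every coordinate; each row is
    independently "missed" with probability ``miss_rate``, drawing its
    likelihood uniformly below ``threshold`` (so the default filter drops
    it), while hits draw uniformly from [threshold, 1].
    """
    if jitter_sigma_px < 0:
        raise ValueError("jitter_sigma_px must be ≥ 0")
    if not 0 <= miss_rate <= 1:
        raise ValueError("miss_rate must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    df = table.df.copy()
    n = len(df)
    if jitter_sigma_px > 0:
        df["x"] += rng.normal(0.0, jitter_sigma_px, size=n)
        df["y"] += rng.normal(0.0, jitter_sigma_px, size=n)
    missed = rng.random(n) < miss_rate
    like = np.empty(n)
    like[missed] = rng.uniform(0.0, threshold, size=int(missed.sum()))
    like[~missed] = rng.uniform(threshold, 1.0, size=int((~missed).sum()))
    df["likelihood"] = like
    return MarkerTable(df)
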