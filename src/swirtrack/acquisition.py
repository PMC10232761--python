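"""Acquisition data model for excitation-multiplexed SWIR video.

A recording is made by cycling through a fixed sequence of excitation
lasers while a single InGaAs detector collects all emission through one
long-pass filter.  Each camera frame therefore belongs to exactly one
excitation channel, and the merged (all-channel) frame rate is set by the
total cycle time.  This module holds the configuration of that cycle
(:class:`AcquisitionConfig`), the in-memory video container
(:class:`FrameStack`), and the YAML/JSON config (de)serialisation shared
by every pipeline stage.

Conventions fixed here and used throughout the package:

* zero dead time between frames — ``frame_period_ms`` defaults to
  ``exposure_ms``;
* ``offset`` is the index of the cycle channel illuminating frame 0 of
  the recording;
* detector counts are non-negative and fit 16 bits for integer stacks.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

CONFIG_VERSION = 1

#: Maximum count representable by the 16-bit InGaAs detector readout.
DETECTOR_MAX_COUNT = 65535


class ConfigError(ValueError):
    """Raised for an invalid or malformed acquisition configuration."""


@dataclass(frozen=True)
class LaserChannel:
    """One excitation laser line in the multiplexing cycle.

    Parameters
    ----------
    label:
        Free-text channel name, conventionally the fluorophore it excites
        (e.g. ``"ICG"``).
    wavelength_nm:
        Laser peak wavelength in nanometres; must lie in (200, 3000).
    power_density_mw_cm2:
        Incident power density at the sample, mW/cm².
    exposure_ms:
        Detector exposure for frames of this channel, milliseconds.
    """

    label: str
    wavelength_nm: float
    power_density_mw_cm2: float
    exposure_ms: float

    def __post_init__(self) -> None:
        if not self.label:
            raise ConfigError("channel label must be non-empty")
        if not 200 < self.wavelength_nm < 3000:
            raise ConfigError(
                f"channel {self.label!r}: wavelength_nm={self.wavelength_nm} "
                "outside (200, 3000)"
            )
        if self.power_density_mw_cm2 <= 0:
            raise ConfigError(
                f"channel {self.label!r}: power_density_mw_cm2 must be positive"
            )
        if self.exposure_ms <= 0:
            raise ConfigError(f"channel {self.label!r}: exposure_ms must be positive")


@dataclass(frozen=True)
class AcquisitionConfig:
    """The laser cycle, detection filter and detector geometry.

    ``cycle`` is ordered: raw frame ``i`` of a recording is illuminated by
    ``cycle[(i + offset) % len(cycle)]``.
    """

    cycle: tuple[LaserChannel, ...]
    longpass_nm: float
    detector_width_px: int = 640
    detector_height_px: int = 512
    offset: int = 0

    def __post_init__(self) -> None:
        if len(self.cycle) < 1:
            raise ConfigError("cycle must contain at least one channel")
        labels = [c.label for c in self.cycle]
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise ConfigError(f"duplicate channel labels in cycle: {sorted(dupes)}")
        if self.longpass_nm <= 0:
            raise ConfigError("longpass_nm must be positive")
        if self.detector_width_px <= 0 or self.detector_height_px <= 0:
            raise ConfigError("detector geometry must be positive")
        if not 0 <= self.offset < len(self.cycle):
            raise ConfigError(
                f"offset={self.offset} out of range [0, {len(self.cycle)})"
            )
        object.__setattr__(self, "cycle", tuple(self.cycle))

    @property
    def cycle_length(self) -> int:
        return len(self.cycle)

    @property
    def cycle_time_ms(self) -> float:
        """Total time of one full excitation cycle (zero dead time)."""
        return float(sum(c.exposure_ms for c in self.cycle))

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(c.label for c in self.cycle)


def effective_framerate_exact(config: AcquisitionConfig) -> float:
    """Merged frames per second of the full cycle, full precision.

    With zero inter-frame dead time the cycle repeats every
    ``sum(exposure_ms)`` milliseconds, so one merged (all-channel) frame
    is produced every cycle: ``1000 / cycle_time_ms``.
    """
    return 1000.0 / config.cycle_time_ms


def effective_framerate(config: AcquisitionConfig) -> int:
    """Merged frames per second, reported as an integer (floor).

    A four-channel cycle at 7.8 ms per frame gives
    ``floor(1000 / 31.2) = 32`` fps; a single 10 ms channel gives 100 fps.
    """
    return math.floor(effective_framerate_exact(config))


@dataclass
class FrameStack:
    """A T×H×W stack of detector counts with timing metadata.

    ``data`` holds raw integer counts for acquired video, or real values
    for derived stacks (e.g. simulated long exposures).  ``frame_period_ms``
    is the time between consecutive frame starts and defaults to the
    exposure (zero dead time).
    """

    data: np.ndarray
    exposure_ms: float
    frame_period_ms: float | None = None
    channel_label: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.shape[0] < 1:
            raise ValueError(f"stack must be T×H×W with T ≥ 1, got {self.data.shape}")
        if self.exposure_ms <= 0:
            raise ValueError("exposure_ms must be positive")
        if self.frame_period_ms is None:
            self.frame_period_ms = float(self.exposure_ms)
        if self.frame_period_ms < self.exposure_ms:
            raise ValueError("frame_period_ms must be ≥ exposure_ms")
        if np.issubdtype(self.data.dtype, np.integer):
            if self.data.size and int(self.data.min()) < 0:
                raise ValueError("counts must be non-negative")
            if self.data.size and int(self.data.max()) > DETECTOR_MAX_COUNT:
                raise ValueError(
                    f"counts exceed detector bit depth ({DETECTOR_MAX_COUNT})"
                )
        elif np.issubdtype(self.data.dtype, np.floating):
            if self.data.size and not np.all(np.isfinite(self.data)):
                raise ValueError("stack values must be finite")
        else:
            raise ValueError(f"unsupported stack dtype {self.data.dtype}")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def with_data(self, data: np.ndarray, **changes) -> "FrameStack":
        """Copy of this stack with new pixel data (metadata preserved)."""
        return replace(self, data=data, **changes)

    def validate_geometry(self, config: AcquisitionConfig) -> None:
        h, w = self.data.shape[1:]
        if (w, h) != (config.detector_width_px, config.detector_height_px):
            raise ValueError(
                f"stack geometry {w}×{h} px does not match detector "
                f"{config.detector_width_px}×{config.detector_height_px} px"
            )


# --------------------------------------------------------------------------
# configuration file schema
# --------------------------------------------------------------------------

_CHANNEL_KEYS = {"label", "wavelength_nm", "power_density_mw_cm2", "exposure_ms"}


def config_to_dict(config: AcquisitionConfig) -> dict:
    return {
        "version": CONFIG_VERSION,
        "cycle": [
            {
                "label": c.label,
                "wavelength_nm": c.wavelength_nm,
                "power_density_mw_cm2": c.power_density_mw_cm2,
                "exposure_ms": c.exposure_ms,
            }
            for c in config.cycle
        ],
        "longpass_nm": config.longpass_nm,
        "detector": {
            "width_px": config.detector_width_px,
            "height_px": config.detector_height_px,
        },
        "offset": config.offset,
    }


def config_from_dict(doc: dict) -> AcquisitionConfig:
    if not isinstance(doc, dict):
        raise ConfigError("config document must be a mapping")
    if "version" not in doc:
        raise ConfigError("config missing required 'version' field")
    if "cycle" not in doc or not isinstance(doc["cycle"], list) or not doc["cycle"]:
        raise ConfigError("config missing non-empty 'cycle' list")
    channels = []
    for i, entry in enumerate(doc["cycle"]):
        missing = _CHANNEL_KEYS - set(entry)
        if missing:
            raise ConfigError(f"cycle[{i}] missing fields: {sorted(missing)}")
        channels.append(
            LaserChannel(
                label=str(entry["label"]),
                wavelength_nm=float(entry["wavelength_nm"]),
                power_density_mw_cm2=float(entry["power_density_mw_cm2"]),
                exposure_ms=float(entry["exposure_ms"]),
            )
        )
    if "longpass_nm" not in doc:
        raise ConfigError("config missing 'longpass_nm'")
    det = doc.get("detector", {})
    return AcquisitionConfig(
        cycle=tuple(channels),
        longpass_nm=float(doc["longpass_nm"]),
        detector_width_px=int(det.get("width_px", 640)),
        detector_height_px=int(det.get("height_px", 512)),
        offset=int(doc.get("offset", 0)),
    )


def load_config(path: str | os.PathLike) -> AcquisitionConfig:
    """Read and validate an acquisition config (YAML, JSON-compatible)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return config_from_dict(doc)


def save_config(config: AcquisitionConfig, path: str | os.PathLike) -> None:
    """Write a config so that :func:`load_config` round-trips all fields."""
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)
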