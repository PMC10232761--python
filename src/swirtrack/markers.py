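"""Pose-estimation marker tables: ingestion and likelihood filtering.

Organ tracking starts from a pose-estimation model (DeepLabCut or
compatible) that outputs, per video frame and per named bodypart, an
(x, y) pixel coordinate and a confidence ("likelihood") in [0, 1].  Two
on-disk dialects are supported and produce identical tables:

* ``dlc-csv`` — the DeepLabCut export: three header rows (scorer /
  bodyparts / coords) with x, y, likelihood triplets per bodypart and the
  frame index in the first column;
* ``long`` — a plain table with columns frame, bodypart, x, y, likelihood.

Coordinates are 0-based pixel indices: x = column increasing rightward,
y = row increasing downward, origin at the top-left pixel centre.

Frames where any required marker falls below the likelihood threshold are
*excluded* (not interpolated) by default — incorrectly placed markers
would corrupt the rigid alignment downstream; short gaps can optionally
be bridged with linear interpolation.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Conventional pose-estimation confidence cutoff.
DEFAULT_LIKELIHOOD_THRESHOLD = 0.9

_COLUMNS = ["frame", "bodypart", "x", "y", "likelihood"]


class MarkerFormatError(ValueError):
    """Raised for malformed marker files."""


@dataclass
class MarkerTable:
    """Per-frame, per-bodypart marker predictions.

    Wraps a DataFrame with columns frame, bodypart, x, y, likelihood;
    (frame, bodypart) pairs are unique and likelihoods lie in [0, 1].
    Missing predictions are simply absent rows.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(_COLUMNS) - set(self.df.columns)
        if missing:
            raise MarkerFormatError(f"marker table missing columns: {sorted(missing)}")
        df = self.df[_COLUMNS].copy()
        df["frame"] = df["frame"].astype(int)
        df["bodypart"] = df["bodypart"].astype(str)
        for col in ("x", "y", "likelihood"):
            df[col] = df[col].astype(float)
        bad = df[(df["likelihood"] < 0) | (df["likelihood"] > 1)]
        if len(bad):
            row = bad.iloc[0]
            raise MarkerFormatError(
                f"likelihood {row['likelihood']} outside [0, 1] "
                f"(frame {int(row['frame'])}, bodypart {row['bodypart']!r})"
            )
        if df.duplicated(subset=["frame", "bodypart"]).any():
            dup = df[df.duplicated(subset=["frame", "bodypart"])].iloc[0]
            raise MarkerFormatError(
                f"duplicate (frame, bodypart) pair: "
                f"({int(dup['frame'])}, {dup['bodypart']!r})"
            )
        self.df = df.sort_values(["frame", "bodypart"]).reset_index(drop=True)

    @property
    def bodyparts(self) -> tuple[str, ...]:
        return tuple(sorted(self.df["bodypart"].unique()))

    @property
    def frames(self) -> np.ndarray:
        return np.sort(self.df["frame"].unique())

    def at_frame(self, frame: int) -> dict[str, tuple[float, float, float]]:
        """Mapping bodypart → (x, y, likelihood) for one frame."""
        sub = self.df[self.df["frame"] == frame]
        return {
            r.bodypart: (r.x, r.y, r.likelihood) for r in sub.itertuples(index=False)
        }

    def validate_geometry(self, width_px: int, height_px: int) -> None:
        out = self.df[
            (self.df["x"] < 0)
            | (self.df["x"] >= width_px)
            | (self.df["y"] < 0)
            | (self.df["y"] >= height_px)
        ]
        if len(out):
            row = out.iloc[0]
            raise MarkerFormatError(
                f"marker ({row['x']}, {row['y']}) outside detector "
                f"{width_px}×{height_px} px (frame {int(row['frame'])})"
            )


@dataclass(frozen=True)
class MarkerRoles:
    """Which bodyparts drive the alignment.

    ``target`` is the organ translated to the canvas centre; ``anterior``
    defines the animal's facing direction (target→anterior maps to
    straight up); ``peripheral`` markers optionally refine the rotation.
    """

    target: str
    anterior: str
    peripheral: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.target == self.anterior:
            raise ValueError("target and anterior roles must differ")
        object.__setattr__(self, "peripheral", tuple(self.peripheral))

    def validate(self, table: MarkerTable) -> None:
        known = set(table.bodyparts)
        for role in (self.target, self.anterior, *self.peripheral):
            if role not in known:
                raise ValueError(f"role bodypart {role!r} not present in table")


def read_markers(path: str | os.PathLike, dialect: str = "auto") -> MarkerTable:
    """Read a marker table in the DLC CSV or long-format dialect.

    ``dialect="auto"`` sniffs the first cell ("scorer" ⇒ dlc-csv).
    Both dialects yield identical tables for equivalent content.
    """
    if dialect == "auto":
        with open(path) as fh:
            first = fh.readline()
        dialect = "dlc-csv" if first.split(",")[0].strip() == "scorer" else "long"
    if dialect == "long":
        df = pd.read_csv(path)
        missing = set(_COLUMNS) - set(df.columns)
        if missing:
            raise MarkerFormatError(
                f"{path}: long-format header missing columns {sorted(missing)}"
            )
        return MarkerTable(df)
    if dialect == "dlc-csv":
        return _read_dlc_csv(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_dlc_csv(path: str | os.PathLike) -> MarkerTable:
    try:
        df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    except (ValueError, pd.errors.ParserError) as exc:
        raise MarkerFormatError(f"{path}: cannot parse DLC header rows: {exc}") from exc
    if df.columns.nlevels != 3:
        raise MarkerFormatError(f"{path}: expected 3 header rows (scorer/bodyparts/coords)")
    records = []
    for frame, row in df.iterrows():
        per_bp: dict[str, dict[str, float]] = {}
        for (_scorer, bodypart, coord), value in row.items():
            if coord not in ("x", "y", "likelihood"):
                raise MarkerFormatError(
                    f"{path}: unexpected coords entry {coord!r} under bodypart "
                    f"{bodypart!r}"
                )
            per_bp.setdefault(str(bodypart), {})[coord] = float(value)
        for bodypart, vals in per_bp.items():
            missing = {"x", "y", "likelihood"} - set(vals)
            if missing:
                raise MarkerFormatError(
                    f"{path}: bodypart {bodypart!r} missing {sorted(missing)} columns"
                )
            records.append(
                {
                    "frame": int(frame),
                    "bodypart": bodypart,
                    "x": vals["x"],
                    "y": vals["y"],
                    "likelihood": vals["likelihood"],
                }
            )
    return MarkerTable(pd.DataFrame.from_records(records, columns=_COLUMNS))


def write_markers(
    table: MarkerTable,
    path: str | os.PathLike,
    dialect: str = "long",
    scorer: str = "swirtrack",
) -> None:
    """Write a marker table in either supported dialect."""
    if dialect == "long":
        table.df.to_csv(path, index=False)
        return
    if dialect == "dlc-csv":
        wide = table.df.pivot(index="frame", columns="bodypart")
        bodyparts = sorted(table.df["bodypart"].unique())
        cols = pd.MultiIndex.from_tuples(
            [(scorer, bp, coord) for bp in bodyparts for coord in ("x", "y", "likelihood")],
            names=["scorer", "bodyparts", "coords"],
        )
        out = pd.DataFrame(index=wide.index, columns=cols, dtype=float)
        for bp in bodyparts:
            for coord in ("x", "y", "likelihood"):
                out[(scorer, bp, coord)] = wide[(coord, bp)]
        out.to_csv(path, index_label=None)
        return
    raise ValueError(f"unknown dialect {dialect!r}")


def filter_by_likelihood(
    table: MarkerTable,
    threshold: float = DEFAULT_LIKELIHOOD_THRESHOLD,
    required: list[str] | tuple[str, ...] | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Keep frames where every required bodypart reaches the threshold.

    Returns ``(kept_frames, report)``: the sorted array of kept frame
    indices, and a DataFrame (frame, bodypart, likelihood) listing each
    dropped frame with the bodypart(s) that failed.  A bodypart absent
    from a frame counts as failing.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    if required is None:
        required = list(table.bodyparts)
    unknown = set(required) - set(table.bodyparts)
    if unknown:
        raise ValueError(f"required bodyparts not in table: {sorted(unknown)}")
    frames = table.frames
    sub = table.df[table.df["bodypart"].isin(required)]
    ok = sub[sub["likelihood"] >= threshold]
    counts = ok.groupby("frame").size().reindex(frames, fill_value=0)
    kept = frames[counts.to_numpy() == len(required)]
    dropped_mask = ~np.isin(frames, kept)
    fail_rows = []
    for frame in frames[dropped_mask]:
        present = sub[sub["frame"] == frame].set_index("bodypart")
        for bp in required:
            if bp not in present.index:
                fail_rows.append({"frame": frame, "bodypart": bp, "likelihood": np.nan})
            elif present.loc[bp, "likelihood"] < threshold:
                fail_rows.append(
                    {
                        "frame": frame,
                        "bodypart": bp,
                        "likelihood": float(present.loc[bp, "likelihood"]),
                    }
                )
    report = pd.DataFrame(fail_rows, columns=["frame", "bodypart", "likelihood"])
    return kept, report


def interpolate_gaps(table: MarkerTable, max_gap: int = 5) -> MarkerTable:
    """Linearly interpolate marker positions across short missing runs.

    Only gaps of at most ``max_gap`` consecutive missing frames (per
    bodypart) are filled; interpolated rows carry likelihood 0 so they
    remain distinguishable from predictions.
    """
    if max_gap < 1:
        return table
    frames = table.frames
    full = np.arange(frames.min(), frames.max() + 1)
    pieces = [table.df]
    for bp in table.bodyparts:
        sub = table.df[table.df["bodypart"] == bp].set_index("frame")
        have = sub.index.to_numpy()
        missing = np.setdiff1d(full, have)
        if missing.size == 0:
            continue
        fill = []
        for frame in missing:
            before = have[have < frame]
            after = have[have > frame]
            if before.size == 0 or after.size == 0:
                continue
            lo, hi = before.max(), after.min()
            if hi - lo - 1 > max_gap:
                continue
            t = (frame - lo) / (hi - lo)
            fill.append(
                {
                    "frame": int(frame),
                    "bodypart": bp,
                    "x": float((1 - t) * sub.loc[lo, "x"] + t * sub.loc[hi, "x"]),
                    "y": float((1 - t) * sub.loc[lo, "y"] + t * sub.loc[hi, "y"]),
                    "likelihood": 0.0,
                }
            )
        if fill:
            pieces.append(pd.DataFrame(fill, columns=_COLUMNS))
    return MarkerTable(pd.concat(pieces, ignore_index=True))
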