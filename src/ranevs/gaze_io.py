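"""Gaze sample I/O, strict binocular averaging and visual-angle conversion.

Raw traces arrive as delimited text with one row per sample: run-relative
timestamp in seconds plus left/right eye coordinates (screen pixels) and
per-eye validity flags, nominally at 60 Hz.  A sample has a usable gaze point
only when *both* eyes are valid (a "strict average"): monocular samples count
as track loss, which keeps the track-loss statistic conservative for
populations where partial loss is common.

Invalid coordinates are blank fields on disk; in memory validity is an
explicit boolean mask, never a sentinel coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd

from .stimuli import ScreenGeometry, RunSpec

__all__ = [
    "GazeTrace",
    "GazeFormatError",
    "read_gaze_table",
    "write_gaze_table",
    "binocular_point",
    "angular_distance",
    "track_loss_fraction",
]

GAZE_COLUMNS = ["t", "lx", "ly", "lvalid", "rx", "ry", "rvalid"]


class GazeFormatError(ValueError):
    """Raised for malformed gaze tables (missing columns, bad timestamps)."""


@dataclass
class GazeTrace:
    """Time-ordered binocular gaze samples for one run (struct-of-arrays).

    Timestamps are seconds from run onset and strictly increasing.  The
    binocular point arrays (``bx``, ``by``, ``bvalid``) are derived once at
    construction: mean of the two eyes where both are valid, NaN elsewhere.
    """

    run_spec: RunSpec
    t: np.ndarray
    lx: np.ndarray
    ly: np.ndarray
    lvalid: np.ndarray
    rx: np.ndarray
    ry: np.ndarray
    rvalid: np.ndarray
    nominal_rate_hz: float = 60.0
    bx: np.ndarray = field(init=False, repr=False)
    by: np.ndarray = field(init=False, repr=False)
    bvalid: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        for name in ("lx", "ly", "rx", "ry"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.lvalid = np.asarray(self.lvalid, dtype=bool)
        self.rvalid = np.asarray(self.rvalid, dtype=bool)
        if self.nominal_rate_hz <= 0:
            raise ValueError("nominal_rate_hz must be positive")
        if self.t.size and not np.all(np.isfinite(self.t)):
            raise GazeFormatError("non-finite timestamps")
        if self.t.size > 1 and not np.all(np.diff(self.t) > 0):
            raise GazeFormatError("timestamps must be strictly increasing")
        valid = self.lvalid & self.rvalid
        for x, v in ((self.lx, self.lvalid), (self.ly, self.lvalid),
                     (self.rx, self.rvalid), (self.ry, self.rvalid)):
            if np.any(~np.isfinite(x[v])):
                raise GazeFormatError("non-finite coordinates on valid samples")
        self.bvalid = valid
        self.bx = np.where(valid, (self.lx + self.rx) / 2.0, np.nan)
        self.by = np.where(valid, (self.ly + self.ry) / 2.0, np.nan)

    def __len__(self) -> int:
        return self.t.size

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self) > 1 else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t": self.t,
            "lx": np.where(self.lvalid, self.lx, np.nan),
            "ly": np.where(self.lvalid, self.ly, np.nan),
            "lvalid": self.lvalid.astype(int),
            "rx": np.where(self.rvalid, self.rx, np.nan),
            "ry": np.where(self.rvalid, self.ry, np.nan),
            "rvalid": self.rvalid.astype(int),
        })


def binocular_point(lx: float, ly: float, lvalid: bool,
                    rx: float, ry: float, rvalid: bool) -> Optional[tuple[float, float]]:
    """Strict binocular average of one sample.

    Returns the mean of the two eye points iff *both* eyes are valid,
    otherwise ``None`` (the sample is track loss).
    """
    if not (lvalid and rvalid):
        return None
    return ((lx + rx) / 2.0, (ly + ry) / 2.0)


def read_gaze_table(path, run_spec: RunSpec, nominal_rate_hz: float = 60.0,
                    sep: str = ",",
                    columns: Optional[dict] = None) -> GazeTrace:
    """Read a delimited gaze table into a :class:`GazeTrace`.

    ``columns`` optionally maps the canonical names (``t, lx, ly, lvalid,
    rx, ry, rvalid``) to the file's header names.  Rows are sorted by
    timestamp; duplicate timestamps are rejected.
    """
    df = pd.read_csv(path, sep=sep)
    colmap = {k: k for k in GAZE_COLUMNS}
    if columns:
        colmap.update(columns)
    missing = [k for k, v in colmap.items() if v not in df.columns]
    if missing:
        raise GazeFormatError(f"gaze table missing column(s): {missing}")
    df = df.rename(columns={v: k for k, v in colmap.items()})
    df = df.sort_values("t", kind="stable").reset_index(drop=True)
    t = df["t"].to_numpy(dtype=float)
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise GazeFormatError("duplicate or non-increasing timestamps")
    lvalid = df["lvalid"].to_numpy().astype(bool)
    rvalid = df["rvalid"].to_numpy().astype(bool)
    # blank coordinate fields parse as NaN; zero-fill them on invalid samples
    # so the in-memory representation is mask + finite arrays
    lx = np.nan_to_num(df["lx"].to_numpy(dtype=float), nan=0.0)
    ly = np.nan_to_num(df["ly"].to_numpy(dtype=float), nan=0.0)
    rx = np.nan_to_num(df["rx"].to_numpy(dtype=float), nan=0.0)
    ry = np.nan_to_num(df["ry"].to_numpy(dtype=float), nan=0.0)
    return GazeTrace(run_spec=run_spec, t=t, lx=lx, ly=ly, lvalid=lvalid,
                     rx=rx, ry=ry, rvalid=rvalid, nominal_rate_hz=nominal_rate_hz)


def write_gaze_table(trace: GazeTrace, path, sep: str = ",") -> None:
    """Write a trace as delimited text (invalid coordinates left blank)."""
    trace.to_frame().to_csv(path, sep=sep, index=False, float_format="%.6f")


Point = Union[tuple, np.ndarray]


def angular_distance(p1: Point, p2: Point, geometry: ScreenGeometry) -> float:
    """Visual angle in degrees subtended between two on-screen pixel points.

    Pixel offsets are converted to centimetres via the physical pixel pitch
    and the angle computed as ``2*atan(chord / (2*D))`` with D the viewing
    distance — the planar small-scene approximation for a viewer facing the
    screen.  Symmetric, non-negative, zero iff the points coincide.
    """
    if geometry.viewing_distance_cm <= 0:
        raise ValueError("viewing distance must be positive")
    dx_cm = (np.asarray(p2)[..., 0] - np.asarray(p1)[..., 0]) * geometry.px_pitch_x_cm
    dy_cm = (np.asarray(p2)[..., 1] - np.asarray(p1)[..., 1]) * geometry.px_pitch_y_cm
    chord = np.hypot(dx_cm, dy_cm)
    ang = np.degrees(2.0 * np.arctan2(chord, 2.0 * geometry.viewing_distance_cm))
    return float(ang) if np.ndim(ang) == 0 else ang


def angular_distance_px(dx_px: np.ndarray, dy_px: np.ndarray,
                        geometry: ScreenGeometry) -> np.ndarray:
    """Vectorised visual angle for pixel displacement components."""
    chord = np.hypot(dx_px * geometry.px_pitch_x_cm, dy_px * geometry.px_pitch_y_cm)
    return np.degrees(2.0 * np.arctan2(chord, 2.0 * geometry.viewing_distance_cm))


def track_loss_fraction(trace: GazeTrace) -> float:
    """Share of samples lacking a valid binocular point, in [0, 1]."""
    if len(trace) == 0:
        return 1.0
    return float(np.mean(~trace.bvalid))
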