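"""Velocity-threshold (I-VT) fixation classification.

Samples whose angular velocity falls below a threshold (default 35 deg/s)
are fixation samples; the rest are saccade samples.  Maximal runs of
consecutive valid fixation samples form candidate fixations, candidates that
are close in both time (<= 100 ms gap) and space (<= 0.5 deg between
centroids) are merged, and candidates shorter than a minimum duration
(100 ms) are discarded.  These defaults reproduce a standard research-grade
remote-tracker filter configuration for developmental populations.

Velocity at sample *i* uses a central difference over the neighbours
``(i-1, i+1)`` when both are valid, falling back to a one-sided difference
when only one neighbour is valid; invalid samples break velocity windows, and
no gap-filling of lost samples is performed before classification.  A sample
whose velocity equals the threshold exactly is a saccade sample (the
threshold is exclusive for fixations).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gaze_io import GazeTrace, angular_distance_px
from .stimuli import ScreenGeometry

__all__ = ["IVTParams", "Fixation", "ivt_classify", "ClassificationError",
           "fixations_frame"]


class ClassificationError(ValueError):
    """The trace has too few valid samples to classify."""


@dataclass(frozen=True)
class IVTParams:
    """I-VT filter parameters.

    velocity_threshold_deg_s : angular velocity separating fixation from
        saccade samples (deg/s).
    merge_max_gap_ms : maximum temporal gap between adjacent candidate
        fixations that may be merged.
    merge_max_angle_deg : maximum centroid separation for merging.
    min_fixation_ms : minimum duration of a reported fixation.
    """

    velocity_threshold_deg_s: float = 35.0
    merge_max_gap_ms: float = 100.0
    merge_max_angle_deg: float = 0.5
    min_fixation_ms: float = 100.0

    def __post_init__(self) -> None:
        if min(self.velocity_threshold_deg_s, self.merge_max_gap_ms,
               self.merge_max_angle_deg, self.min_fixation_ms) <= 0:
            raise ValueError("all I-VT parameters must be strictly positive")


@dataclass(frozen=True)
class Fixation:
    """One detected fixation: time span, centroid and member-sample count."""

    start_t: float
    end_t: float
    centroid_x_px: float
    centroid_y_px: float
    n_samples: int

    @property
    def duration_s(self) -> float:
        return self.end_t - self.start_t


def _sample_velocities(trace: GazeTrace, geometry: ScreenGeometry) -> np.ndarray:
    """Angular velocity (deg/s) per sample; +inf where undefined/invalid."""
    n = len(trace)
    v = np.full(n, np.inf)
    if n < 2:
        return v
    t, x, y, ok = trace.t, trace.bx, trace.by, trace.bvalid

    prev_ok = np.zeros(n, dtype=bool)
    next_ok = np.zeros(n, dtype=bool)
    prev_ok[1:] = ok[:-1]
    next_ok[:-1] = ok[1:]

    # central difference over (i-1, i+1)
    central = np.full(n, np.nan)
    m = ok & prev_ok & next_ok
    if m.any():
        i = np.nonzero(m)[0]
        ang = angular_distance_px(x[i + 1] - x[i - 1], y[i + 1] - y[i - 1], geometry)
        central[i] = ang / (t[i + 1] - t[i - 1])

    fwd = np.full(n, np.nan)
    m = ok & next_ok & ~prev_ok
    if m.any():
        i = np.nonzero(m)[0]
        fwd[i] = angular_distance_px(x[i + 1] - x[i], y[i + 1] - y[i], geometry) / (t[i + 1] - t[i])

    bwd = np.full(n, np.nan)
    m = ok & prev_ok & ~next_ok
    if m.any():
        i = np.nonzero(m)[0]
        bwd[i] = angular_distance_px(x[i] - x[i - 1], y[i] - y[i - 1], geometry) / (t[i] - t[i - 1])

    for cand in (central, fwd, bwd):
        take = np.isnan(v) | np.isinf(v)
        v = np.where(take & ~np.isnan(cand), cand, v)
    return v


def ivt_classify(trace: GazeTrace, geometry: ScreenGeometry,
                 params: IVTParams = IVTParams()) -> list[Fixation]:
    """Classify a gaze trace into time-ordered, non-overlapping fixations.

    Raises
    ------
    ClassificationError
        If the trace has fewer than two valid binocular samples.
    """
    if int(np.sum(trace.bvalid)) < 2:
        raise ClassificationError("trace has fewer than 2 valid binocular samples")

    v = _sample_velocities(trace, geometry)
    is_fix = trace.bvalid & (v < params.velocity_threshold_deg_s)

    # maximal runs of consecutive fixation samples -> candidates
    padded = np.concatenate(([False], is_fix, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0]  # exclusive

    t, x, y = trace.t, trace.bx, trace.by
    # candidate accumulators: (start_t, end_t, sum_x, sum_y, n)
    cands = []
    for s, e in zip(starts, ends):
        cands.append([t[s], t[e - 1], float(x[s:e].sum()), float(y[s:e].sum()), int(e - s)])

    # merge adjacent candidates: gap <= merge_max_gap AND centroid distance
    # <= merge_max_angle; gap samples never contribute to the merged centroid
    max_gap_s = params.merge_max_gap_ms / 1000.0
    merged: list[list] = []
    for c in cands:
        if merged:
            p = merged[-1]
            gap = c[0] - p[1]
            if gap <= max_gap_s:
                pc = (p[2] / p[4], p[3] / p[4])
                cc = (c[2] / c[4], c[3] / c[4])
                ang = angular_distance_px(np.array(cc[0] - pc[0]),
                                          np.array(cc[1] - pc[1]), geometry)
                if float(ang) <= params.merge_max_angle_deg:
                    p[1] = c[1]
                    p[2] += c[2]
                    p[3] += c[3]
                    p[4] += c[4]
                    continue
        merged.append(list(c))

    min_dur = params.min_fixation_ms / 1000.0
    out = []
    for s_t, e_t, sx, sy, n in merged:
        if (e_t - s_t) >= min_dur:
            out.append(Fixation(start_t=float(s_t), end_t=float(e_t),
                                centroid_x_px=sx / n, centroid_y_px=sy / n,
                                n_samples=n))
    return out


def fixations_frame(fixations: list[Fixation],
                    aoi: list | None = None) -> pd.DataFrame:
    """Tidy audit table of fixations (start, end, duration, centroid[, AOI])."""
    df = pd.DataFrame({
        "start_t": [f.start_t for f in fixations],
        "end_t": [f.end_t for f in fixations],
        "duration_s": [f.duration_s for f in fixations],
        "centroid_x_px": [f.centroid_x_px for f in fixations],
        "centroid_y_px": [f.centroid_y_px for f in fixations],
        "n_samples": [f.n_samples for f in fixations],
    })
    if aoi is not None:
        df["aoi"] = aoi
    return df
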