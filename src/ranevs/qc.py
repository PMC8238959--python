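"""Run-level quality control, positional exclusion and condition aggregation.

A run is excluded when any of the following hold (reasons accumulate rather
than short-circuit):

* ``track_loss`` — more than 35% of samples lack a valid binocular point;
* ``fixation_gap`` — any fixation-free interval longer than 10 s (including
  the stretches before the first and after the last fixation);
* ``fixation_count`` — the number of detected fixations falls outside the
  per-condition plausibility bounds, 15-50 for symbolic (number/letter) runs
  and 20-55 for non-symbolic (color/object) runs;
* ``classification`` — fixation detection failed outright (e.g. an
  essentially empty trace).

Eye-movement metrics additionally exclude the first two and last four items
of each array (row-start mistargeting and end-of-array return sweeps make
those eye movements uninterpretable); naming time and errors keep all 36
items.  Per-participant condition summaries are two-stage means: first over
the (up to two) runs of each stimulus type, then over the two stimulus types
of each condition (symbolic = numbers+letters, non-symbolic = colors+objects).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .fixation import Fixation
from .gaze_io import GazeTrace, track_loss_fraction
from .stimuli import Condition, RunSpec, N_ITEMS

__all__ = ["QCParams", "RunMetrics", "positional_exclusion_mask",
           "evaluate_run_qc", "aggregate_conditions", "exclusion_accounting",
           "METRIC_COLUMNS"]


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class QCParams:
    """Exclusion thresholds (defaults follow standard remote-tracker QC)."""

    max_track_loss_frac: float = 0.35
    max_no_fixation_gap_s: float = 10.0
    fixation_bounds: dict = field(default_factory=lambda: {
        Condition.SYMBOLIC: (15, 50),
        Condition.NON_SYMBOLIC: (20, 55),
    })
    exclude_first_items: int = 2
    exclude_last_items: int = 4

    def __post_init__(self) -> None:
        if not (0.0 <= self.max_track_loss_frac <= 1.0):
            raise ConfigurationError("max_track_loss_frac must be in [0, 1]")
        if self.max_no_fixation_gap_s <= 0:
            raise ConfigurationError("max_no_fixation_gap_s must be positive")
        for cond, (lo, hi) in self.fixation_bounds.items():
            if lo > hi:
                raise ConfigurationError(f"fixation bounds for {cond} not ordered")


@dataclass
class RunMetrics:
    """Per-run scores plus the QC verdict."""

    run_spec: RunSpec
    naming_time_s: Optional[float] = None
    n_errors: Optional[int] = None
    mean_evs_items: Optional[float] = None
    total_fixations: Optional[int] = None
    pooled_fixations: Optional[int] = None
    perseverations: Optional[int] = None
    regressions: Optional[int] = None
    refixations: Optional[int] = None
    off_array_fixations: Optional[int] = None
    qc_pass: bool = True
    qc_reasons: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.qc_pass = not self.qc_reasons
        if (self.refixations is not None and self.perseverations is not None
                and self.regressions is not None
                and self.refixations != self.perseverations + self.regressions):
            raise ValueError("refixations must equal perseverations + regressions")


#: metric columns averaged into condition summaries
METRIC_COLUMNS = ["naming_time_s", "n_errors", "mean_evs_items",
                  "total_fixations", "perseverations", "regressions",
                  "refixations"]


def positional_exclusion_mask(n_items: int = N_ITEMS,
                              params: QCParams = QCParams()) -> np.ndarray:
    """Boolean retention mask over serial indices.

    The first ``exclude_first_items`` and last ``exclude_last_items`` indices
    are False; with the defaults a 36-item array retains indices 2..31.
    """
    first, last = params.exclude_first_items, params.exclude_last_items
    if n_items <= first + last:
        raise ConfigurationError(
            f"cannot exclude {first}+{last} items from an array of {n_items}")
    mask = np.ones(n_items, dtype=bool)
    if first:
        mask[:first] = False
    if last:
        mask[-last:] = False
    return mask


def evaluate_run_qc(trace: GazeTrace, fixations: Optional[Sequence[Fixation]],
                    run_spec: RunSpec,
                    params: QCParams = QCParams()) -> tuple[bool, list[str]]:
    """Apply the run-exclusion rules; returns (passed, reasons).

    ``fixations`` may be None to signal that classification itself failed.
    All applicable reasons are reported, not just the first.
    """
    reasons: list[str] = []

    if track_loss_fraction(trace) > params.max_track_loss_frac:
        reasons.append("track_loss")

    if fixations is None:
        reasons.append("classification")
        return (False, reasons)

    # fixation-free intervals: trace start -> first fixation, between
    # consecutive fixations, last fixation -> trace end
    if len(trace) > 0:
        edges = [trace.t[0]]
        for f in fixations:
            edges.extend((f.start_t, f.end_t))
        edges.append(trace.t[-1])
        gaps = [edges[i + 1] - edges[i] for i in range(0, len(edges) - 1, 2)]
        if gaps and max(gaps) > params.max_no_fixation_gap_s:
            reasons.append("fixation_gap")

    lo, hi = params.fixation_bounds[run_spec.condition]
    if not (lo <= len(fixations) <= hi):
        reasons.append("fixation_count")

    return (len(reasons) == 0, reasons)


def run_metrics_frame(metrics: Sequence[RunMetrics],
                      extra: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Tidy table of run metrics (one row per run)."""
    rows = []
    for m in metrics:
        rows.append({
            "participant_id": m.run_spec.participant_id,
            "stimulus_type": m.run_spec.stimulus_type.value,
            "run_index": m.run_spec.run_index,
            "condition": m.run_spec.condition.value,
            **{c: getattr(m, c) for c in METRIC_COLUMNS},
            "qc_pass": m.qc_pass,
            "qc_reasons": ";".join(m.qc_reasons),
        })
    df = pd.DataFrame(rows)
    if extra is not None:
        df = df.merge(extra, on="participant_id", how="left")
    return df


def aggregate_conditions(run_metrics: Sequence[RunMetrics] | pd.DataFrame) -> pd.DataFrame:
    """Two-stage mean of QC-passing runs into participant x condition rows.

    Stage 1 averages the runs of each stimulus type; stage 2 averages the
    stimulus-type means within each condition, so a missing run never lets
    one stimulus type dominate the condition mean.  Participants with zero
    passing runs in a condition yield no row.
    """
    df = run_metrics if isinstance(run_metrics, pd.DataFrame) else run_metrics_frame(run_metrics)
    if df.empty:
        return pd.DataFrame(columns=["participant_id", "condition"] + METRIC_COLUMNS)
    kept = df[df["qc_pass"]].copy()
    if kept.empty:
        return pd.DataFrame(columns=["participant_id", "condition"] + METRIC_COLUMNS)
    by_type = (kept.groupby(["participant_id", "condition", "stimulus_type"],
                            sort=True, observed=True)[METRIC_COLUMNS]
               .mean().reset_index())
    by_cond = (by_type.groupby(["participant_id", "condition"],
                               sort=True, observed=True)[METRIC_COLUMNS]
               .mean().reset_index())
    return by_cond


def exclusion_accounting(run_table: pd.DataFrame,
                         group_cols: Sequence[str] = ("diagnosis", "culture")) -> pd.DataFrame:
    """Excluded/included run counts and exclusion fraction per group.

    ``run_table`` is a run-metrics table (one row per run) carrying a
    ``qc_pass`` column plus the grouping columns (e.g. diagnosis, culture).
    """
    g = run_table.groupby(list(group_cols), sort=True, observed=True)["qc_pass"]
    out = g.agg(n_included="sum", n_total="count").reset_index()
    out["n_excluded"] = out["n_total"] - out["n_included"]
    out["fraction_excluded"] = np.where(
        out["n_total"] > 0, out["n_excluded"] / out["n_total"], 0.0)
    return out[list(group_cols) + ["n_excluded", "n_included", "n_total",
                                   "fraction_excluded"]]
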