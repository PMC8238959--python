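"""End-to-end scoring: gaze + voice -> run metrics -> condition summaries.

``score_run`` runs the full per-run chain (I-VT classification, AOI
assignment, positional exclusion, EVS, scanpath metrics, naming metrics,
QC), and the cohort helpers stream simulated cohorts through it into the
tidy tables the statistics layer consumes.
"""

from __future__ import annotations

from typing import Optional, Sequence

import pandas as pd

from .evs import UndefinedMetricError, run_evs
from .fixation import ClassificationError, IVTParams, ivt_classify
from .gaze_io import GazeTrace
from .qc import (QCParams, RunMetrics, aggregate_conditions, evaluate_run_qc,
                 positional_exclusion_mask, run_metrics_frame)
from .scanpath import (assign_fixations, count_perseverations,
                       count_regressions, count_total_fixations,
                       fixation_aois, pooled_fixation_count)
from .stimuli import DEFAULT_SCREEN, ScreenGeometry, StimulusArray
from .voice import VoiceTrack, count_errors, naming_time

__all__ = ["score_run", "score_cohort", "cohort_table"]


def score_run(trace: GazeTrace, track: VoiceTrack, array: StimulusArray,
              geometry: ScreenGeometry = DEFAULT_SCREEN,
              ivt_params: IVTParams = IVTParams(),
              qc_params: QCParams = QCParams()) -> RunMetrics:
    """Score one run and attach its QC verdict.

    Metric conventions: naming time and errors cover all 36 items; EVS and
    the scanpath metrics see only positionally retained items (first two and
    last four excluded).  Metrics that cannot be computed are left None and
    the run is flagged with a corresponding QC reason.
    """
    run_spec = trace.run_spec
    reasons: list[str] = []

    m = RunMetrics(run_spec=run_spec)
    try:
        m.naming_time_s = naming_time(track)
    except ValueError:
        reasons.append("empty_voice")
    m.n_errors = count_errors(track)

    try:
        fixations = ivt_classify(trace, geometry, ivt_params)
    except ClassificationError:
        fixations = None

    passed, qc_reasons = evaluate_run_qc(trace, fixations, run_spec, qc_params)
    reasons.extend(qc_reasons)

    if fixations is not None:
        mask = positional_exclusion_mask(array.n_items, qc_params)
        aoi_all = fixation_aois(fixations, array)
        seq = assign_fixations(fixations, array, retained_mask=mask)
        m.total_fixations = count_total_fixations(seq)
        m.pooled_fixations = pooled_fixation_count(seq)
        m.perseverations = count_perseverations(seq)
        m.regressions = count_regressions(seq)
        m.refixations = m.perseverations + m.regressions
        m.off_array_fixations = seq.n_off_array
        try:
            m.mean_evs_items = run_evs(fixations, list(aoi_all), track,
                                       retained_mask=mask)
        except UndefinedMetricError:
            reasons.append("evs_undefined")

    m.qc_reasons = reasons
    m.qc_pass = not reasons
    return m


def score_cohort(runs, participants: Optional[pd.DataFrame] = None,
                 arrays: Optional[dict] = None,
                 geometry: ScreenGeometry = DEFAULT_SCREEN,
                 ivt_params: IVTParams = IVTParams(),
                 qc_params: QCParams = QCParams()) -> pd.DataFrame:
    """Score a sequence of runs into a tidy run-metrics table.

    ``runs`` may be ``SimRun`` objects (which carry their own trace/track)
    or ``(trace, track, array)`` triples; with ``SimRun`` inputs ``arrays``
    must map ``(stimulus_type, run_index)`` to layouts.
    """
    from .stimuli import build_array_layout  # local to avoid cycle at import

    metrics: list[RunMetrics] = []
    cache = dict(arrays) if arrays else {}
    for item in runs:
        if hasattr(item, "trace"):
            key = (item.run_spec.stimulus_type, item.run_spec.run_index)
            if key not in cache:
                cache[key] = build_array_layout(*key, geometry)
            trace, track, array = item.trace, item.track, cache[key]
        else:
            trace, track, array = item
        metrics.append(score_run(trace, track, array, geometry,
                                 ivt_params, qc_params))
    extra = None
    if participants is not None:
        extra = participants
    return run_metrics_frame(metrics, extra=extra)


def cohort_table(run_table: pd.DataFrame,
                 participants: pd.DataFrame) -> pd.DataFrame:
    """Participant x condition summary table with demographics attached."""
    summary = aggregate_conditions(run_table)
    return summary.merge(participants, on="participant_id", how="left")
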