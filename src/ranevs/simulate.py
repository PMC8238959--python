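"""Synthetic RAN runs with known ground truth.

The generator emulates the data structure the analysis assumes: a serial
left-to-right, top-to-bottom naming sweep in which the eyes lead the voice
by a fixed number of items, occasionally refixating the current item
(perseveration) or revisiting an earlier one (regression), with Gaussian
gaze noise and sample-level track loss.  Everything the pipeline later
measures — per-onset lead, injected perseverations/regressions, naming time,
error tags — is recorded at generation time, so parameter recovery can be
checked exactly.

Timeline model
--------------
Item *i* is articulated over a lognormal duration (floored at 0.2 s) with a
fixed inter-item pause.  The eyes land on the led item ``min(i + lead, 35)``
``voice_after_gaze_s`` before the vocal onset and stay there until the next
item's gaze window.  Injected refixations subdivide the window into abrupt
sub-fixations of at least 0.18 s each; a perseveration refixates the same
item displaced ~1.7 deg (large enough that the velocity filter sees a
saccade, small enough to stay inside the AOI), a regression jumps to a
previously visited retained item up to ``regression_depth`` items back.
Refixations are only injected where the positional-exclusion mask retains
the fixated item and the window has room, and eligibility tallies are
recorded so injection probabilities can be estimated without bias.

Track loss invalidates samples independently; noise is added to the
binocular point and the two eyes are emitted at a fixed +/-2 px vergence
offset around it, so the strict binocular average recovers the point
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Optional

import numpy as np
import pandas as pd

from .gaze_io import GazeTrace
from .qc import positional_exclusion_mask
from .stimuli import (DEFAULT_SCREEN, N_ITEMS, RunSpec, ScreenGeometry,
                      StimulusArray, StimulusType, build_array_layout,
                      condition_of, Condition)
from .voice import VocalEvent, VoiceTrack

__all__ = ["SimParams", "GroundTruth", "SimRun", "simulate_run",
           "simulate_cohort", "default_group_params", "GROUPS"]

#: duration of each injected refixation (s); chosen so that a 60 Hz I-VT
#: filter with a 100 ms minimum always retains it after boundary losses
_EXTRA_FIX_S = 0.18
#: perseveration displacement (deg); must exceed the saccade-velocity
#: threshold over two sample intervals yet remain inside one AOI
_PERSEVERATION_SHIFT_DEG = 1.7
#: articulation floor (s) — even the fastest naming occupies ~200 ms
_MIN_ITEM_S = 0.2


@dataclass(frozen=True)
class SimParams:
    """Generative parameters of one synthetic run (seeded, reproducible)."""

    seed: int = 0
    rate_hz: float = 60.0
    item_duration_mean_s: float = 0.55
    item_duration_cv: float = 0.25
    inter_item_pause_s: float = 0.12
    evs_lead_items: float = 1.0
    p_perseveration: float = 0.15
    p_regression: float = 0.12
    regression_depth: int = 5
    gaze_noise_deg: float = 0.2
    track_loss_frac: float = 0.05
    error_rate: float = 0.03
    voice_after_gaze_s: float = 0.08
    symbolic_duration_scale: float = 0.6

    def __post_init__(self) -> None:
        for p in (self.p_perseveration, self.p_regression,
                  self.track_loss_frac, self.error_rate):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        if min(self.rate_hz, self.item_duration_mean_s,
               self.inter_item_pause_s) <= 0:
            raise ValueError("rate and durations must be positive")
        if self.evs_lead_items < 0:
            raise ValueError("evs_lead_items must be non-negative")


@dataclass
class GroundTruth:
    """What was injected into one run (restricted to retained items)."""

    lead_items: int
    per_onset_lead: np.ndarray = field(repr=False, default=None)
    true_naming_time_s: float = np.nan
    n_errors: int = 0
    perseverations: int = 0
    regressions: int = 0
    perseveration_eligible: int = 0
    regression_eligible: int = 0
    retained_main_fixations: int = 0
    perseveration_items: list = field(default_factory=list)
    regression_items: list = field(default_factory=list)


@dataclass
class SimRun:
    run_spec: RunSpec
    trace: GazeTrace
    track: VoiceTrack
    truth: GroundTruth


def _lognormal(rng: np.random.Generator, mean: float, cv: float, n: int) -> np.ndarray:
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), n)


def simulate_run(params: SimParams, array: StimulusArray,
                 run_spec: Optional[RunSpec] = None,
                 geometry: ScreenGeometry = DEFAULT_SCREEN,
                 retained_mask: Optional[np.ndarray] = None,
                 rng: Optional[np.random.Generator] = None) -> SimRun:
    """Simulate one run: gaze trace, voice track and its ground truth."""
    if run_spec is None:
        run_spec = RunSpec("sim", array.stimulus_type, array.run_index)
    if retained_mask is None:
        retained_mask = positional_exclusion_mask(array.n_items)
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n = array.n_items

    # --- voice timeline -------------------------------------------------
    mean = params.item_duration_mean_s
    if condition_of(array.stimulus_type) is Condition.SYMBOLIC:
        mean = mean * params.symbolic_duration_scale
    durations = np.maximum(_lognormal(rng, mean, params.item_duration_cv, n),
                           _MIN_ITEM_S)
    start_t = 0.5
    onsets = start_t + np.concatenate(
        ([0.0], np.cumsum(durations[:-1] + params.inter_item_pause_s)))
    offsets = onsets + durations

    err_draw = rng.random(n) < params.error_rate
    err_kind = rng.integers(0, 2, n)  # 0 = substitution, 1 = self-correction
    events = []
    labels = array.labels
    for i in range(n):
        tags: frozenset = frozenset()
        label = labels[i]
        if err_draw[i]:
            if err_kind[i] == 0:
                tags = frozenset({"substitution"})
                label = labels[(i + 1) % n]
            else:
                tags = frozenset({"self_correction"})
        events.append(VocalEvent(serial_index=i, onset_t=float(onsets[i]),
                                 offset_t=float(offsets[i]),
                                 produced_label=label, error_tags=tags))
    track = VoiceTrack(run_spec=run_spec, events=events)
    truth = GroundTruth(lead_items=int(round(params.evs_lead_items)))
    truth.true_naming_time_s = float(offsets[-1] - onsets[0])
    truth.n_errors = int(err_draw.sum())

    # --- gaze sub-fixation plan ----------------------------------------
    lead = int(round(params.evs_lead_items))
    targets = np.minimum(np.arange(n) + lead, n - 1)
    truth.per_onset_lead = targets - np.arange(n)
    win_starts = onsets - params.voice_after_gaze_s
    win_starts[0] = 0.0  # eyes wait on the first target from trace start
    win_ends = np.concatenate((win_starts[1:], [offsets[-1] + 0.3]))

    shift_px = _deg_to_px_x(_PERSEVERATION_SHIFT_DEG, geometry)
    pers_draw = rng.random(n) < params.p_perseveration
    regr_draw = rng.random(n) < params.p_regression

    fix_x: list[float] = []
    fix_y: list[float] = []
    fix_start: list[float] = []
    for i in range(n):
        g = int(targets[i])
        w0, w1 = win_starts[i], win_ends[i]
        capacity = int(np.floor((w1 - w0) / _EXTRA_FIX_S)) - 1
        retained = bool(retained_mask[g])
        if retained:
            truth.retained_main_fixations += 1

        do_pers = False
        if retained and capacity >= 1:
            truth.perseveration_eligible += 1
            do_pers = bool(pers_draw[i])

        lo = max(2, lead, g - params.regression_depth)
        do_regr = False
        if retained and lo <= g - 1 and capacity >= 1 + int(do_pers):
            truth.regression_eligible += 1
            do_regr = bool(regr_draw[i])

        n_extra = int(do_pers) + int(do_regr)
        fix_start.append(float(w0))
        fix_x.append(float(array.centers_x[g]))
        fix_y.append(float(array.centers_y[g]))
        cursor = w1 - n_extra * _EXTRA_FIX_S
        if do_pers:
            truth.perseverations += 1
            truth.perseveration_items.append(g)
            fix_start.append(float(cursor))
            fix_x.append(float(array.centers_x[g] + shift_px))
            fix_y.append(float(array.centers_y[g]))
            cursor += _EXTRA_FIX_S
        if do_regr:
            truth.regressions += 1
            r = int(rng.integers(lo, g))
            truth.regression_items.append((g, r))
            fix_start.append(float(cursor))
            fix_x.append(float(array.centers_x[r]))
            fix_y.append(float(array.centers_y[r]))

    # --- sample synthesis ----------------------------------------------
    dt = 1.0 / params.rate_hz
    end_t = win_ends[-1]
    t = np.arange(0.0, end_t, dt)
    idx = np.searchsorted(np.asarray(fix_start), t, side="right") - 1
    x = np.asarray(fix_x)[idx]
    y = np.asarray(fix_y)[idx]
    if params.gaze_noise_deg > 0:
        sx = _deg_to_px_x(params.gaze_noise_deg, geometry)
        sy = _deg_to_px_y(params.gaze_noise_deg, geometry)
        x = x + rng.normal(0.0, sx, t.size)
        y = y + rng.normal(0.0, sy, t.size)
    valid = rng.random(t.size) >= params.track_loss_frac
    lx = np.where(valid, x - 2.0, 0.0)
    rx = np.where(valid, x + 2.0, 0.0)
    ly = np.where(valid, y, 0.0)
    ry = np.where(valid, y, 0.0)
    trace = GazeTrace(run_spec=run_spec, t=t, lx=lx, ly=ly, lvalid=valid,
                      rx=rx, ry=ry, rvalid=valid,
                      nominal_rate_hz=params.rate_hz)
    return SimRun(run_spec=run_spec, trace=trace, track=track, truth=truth)


def _deg_to_px_x(deg: float, geometry: ScreenGeometry) -> float:
    cm = 2.0 * geometry.viewing_distance_cm * np.tan(np.radians(deg) / 2.0)
    return cm / geometry.px_pitch_x_cm


def _deg_to_px_y(deg: float, geometry: ScreenGeometry) -> float:
    cm = 2.0 * geometry.viewing_distance_cm * np.tan(np.radians(deg) / 2.0)
    return cm / geometry.px_pitch_y_cm


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

GROUPS = (("control", "HK"), ("ASD", "HK"), ("control", "US"), ("ASD", "US"))

_RUN_PLAN = [(st, ri) for st in StimulusType for ri in (1, 2)]


def default_group_params(base: SimParams = SimParams(),
                         asd_extra_p_perseveration: float = 0.0,
                         asd_extra_p_regression: float = 0.0,
                         hk_extra_p_regression: float = 0.0) -> dict:
    """Per-group parameter map with optional diagnosis/culture offsets."""
    out = {}
    for dx, cu in GROUPS:
        p = base
        if dx == "ASD":
            p = replace(p,
                        p_perseveration=min(1.0, p.p_perseveration + asd_extra_p_perseveration),
                        p_regression=min(1.0, p.p_regression + asd_extra_p_regression))
        if cu == "HK":
            p = replace(p, p_regression=min(1.0, p.p_regression + hk_extra_p_regression))
        out[(dx, cu)] = p
    return out


def _demographics(rng: np.random.Generator, pid: str, dx: str, cu: str) -> dict:
    """Nuisance covariates: realistic ranges, no effect on gaze by default."""
    return {
        "participant_id": pid, "diagnosis": dx, "culture": cu,
        "sex": "M" if rng.random() < 0.6 else "F",
        "age": float(np.clip(rng.normal(19.0, 6.0), 10.0, 35.0)),
        "iq": float(np.clip(rng.normal(110.0, 14.0), 70.0, 145.0)),
    }


def iter_cohort_runs(group_params: dict, n_per_group: int, seed: int,
                     arrays: Optional[dict] = None,
                     geometry: ScreenGeometry = DEFAULT_SCREEN
                     ) -> Iterator[tuple[dict, SimRun]]:
    """Yield ``(participant_record, SimRun)`` pairs for a full cohort.

    Each participant completes all 8 runs (4 stimulus types x 2 runs).
    Randomness derives entirely from ``seed`` via independent child streams.
    """
    if len(group_params) < 2:
        raise ValueError("need at least 2 groups")
    if arrays is None:
        arrays = {(st, ri): build_array_layout(st, ri, geometry)
                  for st, ri in _RUN_PLAN}
    ss = np.random.SeedSequence(seed)
    for (dx, cu), params in sorted(group_params.items()):
        for k in range(n_per_group):
            child = ss.spawn(1)[0]
            rng = np.random.default_rng(child)
            pid = f"{cu}-{dx}-{k:03d}"
            person = _demographics(rng, pid, dx, cu)
            for st, ri in _RUN_PLAN:
                spec = RunSpec(pid, st, ri)
                yield person, simulate_run(params, arrays[(st, ri)],
                                           run_spec=spec, geometry=geometry,
                                           rng=rng)


def simulate_cohort(group_params: dict, n_per_group: int, seed: int = 0,
                    geometry: ScreenGeometry = DEFAULT_SCREEN
                    ) -> tuple[pd.DataFrame, list[SimRun]]:
    """Materialised cohort: participant table plus every simulated run."""
    people: dict[str, dict] = {}
    runs: list[SimRun] = []
    for person, run in iter_cohort_runs(group_params, n_per_group, seed,
                                        geometry=geometry):
        people[person["participant_id"]] = person
        runs.append(run)
    participants = pd.DataFrame(list(people.values()))
    return participants, runs
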