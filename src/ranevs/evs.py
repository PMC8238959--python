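"""Eye-voice span (EVS): how far the eyes lead the voice at each onset.

At the onset of each named item, EVS is the signed difference in serial
position between the currently fixated item and the item being spoken
(positive = eyes ahead of the voice).  Onsets that land during a saccade or
momentary track loss are resolved by carrying forward the most recent
fixation's AOI; onsets that precede the first fixation yield no sample.
The run-level EVS is the arithmetic mean over eligible onsets — items not
positionally excluded, with an interval (not omitted), and with a resolvable
fixated item.

Substituted items still anchor to their intended array position, because the
span is defined over array positions, not over what was actually said.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .fixation import Fixation
from .voice import VocalEvent, VoiceTrack

__all__ = ["EvsSample", "UndefinedMetricError", "fixated_item_at",
           "evs_at_onset", "run_evs", "evs_table"]


class UndefinedMetricError(ValueError):
    """A run-level metric has no eligible samples (run must be flagged)."""


@dataclass(frozen=True)
class EvsSample:
    """EVS at one vocal onset: spoken item, fixated item, signed span."""

    serial_spoken: int
    serial_fixated: int

    @property
    def evs_items(self) -> int:
        return self.serial_fixated - self.serial_spoken


def fixated_item_at(fixations: Sequence[Fixation], aoi: Sequence[int],
                    t: float) -> Optional[int]:
    """AOI serial index gazed at time ``t``, with carry-forward.

    ``aoi`` gives each fixation's AOI (-1/None for off-array).  If ``t``
    falls inside a fixation's ``[start_t, end_t)`` the fixation's AOI is
    returned; between fixations the most recent preceding fixation's AOI is
    carried forward; before any fixation the result is None.  Off-array
    fixations resolve to None as well (the eyes were not on any item).
    """
    last = None
    for f, a in zip(fixations, aoi):
        if f.start_t > t:
            break
        # t >= start: inside [start, end) or past the fixation — either way
        # this is the most recent fixation at or before t
        last = a
    if last is None or last < 0:
        return None
    return int(last)


def evs_at_onset(fixations: Sequence[Fixation], aoi: Sequence[int],
                 event: VocalEvent) -> Optional[EvsSample]:
    """EVS sample at one vocal onset, or None when unresolvable.

    Omissions carry no onset and produce no sample.
    """
    if not event.has_interval:
        return None
    fixated = fixated_item_at(fixations, aoi, event.onset_t)
    if fixated is None:
        return None
    return EvsSample(serial_spoken=event.serial_index, serial_fixated=fixated)


def evs_samples(fixations: Sequence[Fixation], aoi: Sequence[int],
                track: VoiceTrack,
                retained_mask: Optional[np.ndarray] = None) -> list[EvsSample]:
    """All eligible per-onset EVS samples for a run.

    ``retained_mask`` (boolean per serial index) applies the positional
    exclusion to the *spoken* item: onsets of excluded items yield no sample.
    """
    out = []
    for ev in track.events:
        if retained_mask is not None and not retained_mask[ev.serial_index]:
            continue
        s = evs_at_onset(fixations, aoi, ev)
        if s is not None:
            out.append(s)
    return out


def run_evs(fixations: Sequence[Fixation], aoi: Sequence[int],
            track: VoiceTrack,
            retained_mask: Optional[np.ndarray] = None) -> float:
    """Mean signed EVS (in items) over eligible onsets of a run.

    Raises
    ------
    UndefinedMetricError
        When no onset is eligible (all masked, omitted or unresolvable).
    """
    samples = evs_samples(fixations, aoi, track, retained_mask)
    if not samples:
        raise UndefinedMetricError("no eligible EVS samples in run")
    return float(np.mean([s.evs_items for s in samples]))


def evs_table(fixations: Sequence[Fixation], aoi: Sequence[int],
              track: VoiceTrack,
              retained_mask: Optional[np.ndarray] = None) -> pd.DataFrame:
    """Per-onset EVS audit table (spoken, fixated, span)."""
    samples = evs_samples(fixations, aoi, track, retained_mask)
    return pd.DataFrame({
        "serial_spoken": [s.serial_spoken for s in samples],
        "serial_fixated": [s.serial_fixated for s in samples],
        "evs_items": [s.evs_items for s in samples],
    })
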