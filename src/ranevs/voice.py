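"""Vocal articulation intervals, naming time and error counts.

Each named item arrives as an onset/offset interval on the run-relative
clock (typically produced by a forced aligner and checked by human coders),
carrying the intended serial index and any error annotations among
``repetition``, ``omission``, ``substitution`` and ``self_correction``.
Omitted items are represented as interval-free events at their serial index
so the item bookkeeping stays in register with the stimulus array.

Two on-disk forms are supported: a delimited table with the event columns,
and a Praat TextGrid with an interval tier named ``word`` whose labels are
``serial_index:produced_label[:tag1;tag2]`` (empty intervals are silence).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .stimuli import RunSpec, N_ITEMS

__all__ = ["VocalEvent", "VoiceTrack", "VoiceFormatError", "ERROR_TAGS",
           "read_vocal_events", "write_vocal_events", "naming_time",
           "count_errors", "read_textgrid_events", "write_textgrid_events"]

ERROR_TAGS = frozenset({"repetition", "omission", "substitution", "self_correction"})


class VoiceFormatError(ValueError):
    """Malformed vocal-event file (bad columns, overlapping intervals...)."""


@dataclass(frozen=True)
class VocalEvent:
    """One articulation: intended item, interval, produced label, error tags.

    Omissions have ``onset_t is None`` and ``offset_t is None`` — the item
    was skipped, so there is no interval and no eye-voice sample for it.
    """

    serial_index: int
    onset_t: Optional[float]
    offset_t: Optional[float]
    produced_label: str = ""
    error_tags: frozenset = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "error_tags", frozenset(self.error_tags))
        bad = self.error_tags - ERROR_TAGS
        if bad:
            raise VoiceFormatError(f"unknown error tag(s): {sorted(bad)}")
        if (self.onset_t is None) != (self.offset_t is None):
            raise VoiceFormatError("onset and offset must both be present or both absent")
        if self.onset_t is None:
            if "omission" not in self.error_tags:
                raise VoiceFormatError("interval-free event must be tagged as omission")
        elif self.offset_t <= self.onset_t:
            raise VoiceFormatError(
                f"offset {self.offset_t} must exceed onset {self.onset_t}")

    @property
    def has_interval(self) -> bool:
        return self.onset_t is not None


@dataclass
class VoiceTrack:
    """Ordered vocal events of one run."""

    run_spec: RunSpec
    events: list[VocalEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        for ev in self.events:
            if not (0 <= ev.serial_index < N_ITEMS):
                raise VoiceFormatError(
                    f"serial_index {ev.serial_index} outside 0..{N_ITEMS - 1}")
        timed = [e for e in self.events if e.has_interval]
        if any(b.onset_t < a.onset_t for a, b in zip(timed, timed[1:])):
            raise VoiceFormatError("events must be ordered by onset")
        # at most one non-repetition event per item; overlapping same-item
        # intervals are only legal when marked as repetitions
        seen: set[int] = set()
        for ev in self.events:
            if "repetition" in ev.error_tags:
                continue
            if ev.serial_index in seen:
                raise VoiceFormatError(
                    f"multiple non-repetition events for item {ev.serial_index}")
            seen.add(ev.serial_index)

    def __len__(self) -> int:
        return len(self.events)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "serial_index": [e.serial_index for e in self.events],
            "onset_t": [e.onset_t for e in self.events],
            "offset_t": [e.offset_t for e in self.events],
            "produced_label": [e.produced_label for e in self.events],
            "error_tags": [";".join(sorted(e.error_tags)) for e in self.events],
        })


_VOICE_COLUMNS = ["serial_index", "onset_t", "offset_t", "produced_label", "error_tags"]


def _parse_tags(cell) -> frozenset:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or cell == "":
        return frozenset()
    return frozenset(t for t in str(cell).split(";") if t)


def read_vocal_events(path, run_spec: RunSpec, sep: str = ",") -> VoiceTrack:
    """Read a delimited vocal-event table into a :class:`VoiceTrack`."""
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in _VOICE_COLUMNS if c not in df.columns]
    if missing:
        raise VoiceFormatError(f"vocal table missing column(s): {missing}")
    events = []
    for row in df.itertuples(index=False):
        onset = None if pd.isna(row.onset_t) else float(row.onset_t)
        offset = None if pd.isna(row.offset_t) else float(row.offset_t)
        label = "" if pd.isna(row.produced_label) else str(row.produced_label)
        events.append(VocalEvent(
            serial_index=int(row.serial_index), onset_t=onset, offset_t=offset,
            produced_label=label, error_tags=_parse_tags(row.error_tags)))
    return VoiceTrack(run_spec=run_spec, events=events)


def write_vocal_events(track: VoiceTrack, path, sep: str = ",") -> None:
    track.to_frame().to_csv(path, sep=sep, index=False)


def naming_time(track: VoiceTrack) -> float:
    """Total naming time of a run in seconds.

    Defined as the offset of the last articulation minus the onset of the
    first, so internal pauses and error productions are included.

    Raises
    ------
    ValueError
        If the track has no timed events (the metric is undefined; the run
        should be flagged by QC).
    """
    timed = [e for e in track.events if e.has_interval]
    if not timed:
        raise ValueError("naming time undefined: track has no timed events")
    return max(e.offset_t for e in timed) - min(e.onset_t for e in timed)


def count_errors(track: VoiceTrack) -> int:
    """Total error annotations: repetitions, omissions, substitutions and
    self-corrections summed over events (an event with two tags counts twice).
    """
    return sum(len(e.error_tags) for e in track.events)


# ---------------------------------------------------------------------------
# Praat TextGrid (interval tier "word")
# ---------------------------------------------------------------------------

_TG_HEADER = """File type = "ooTextFile"
Object class = "TextGrid"

xmin = 0
xmax = {xmax}
tiers? <exists>
size = 1
item []:
    item [1]:
        class = "IntervalTier"
        name = "word"
        xmin = 0
        xmax = {xmax}
        intervals: size = {size}
"""


def write_textgrid_events(track: VoiceTrack, path) -> None:
    """Write timed events as a long-form TextGrid with a ``word`` tier.

    Interval labels encode ``serial:label[:tag1;tag2]``; gaps between
    articulations become empty (silence) intervals.  Omissions carry no
    interval and are not representable on the tier; use the delimited format
    to round-trip tracks containing omissions.
    """
    timed = sorted((e for e in track.events if e.has_interval), key=lambda e: e.onset_t)
    if not timed:
        raise VoiceFormatError("cannot write a TextGrid without timed events")
    xmax = timed[-1].offset_t + 0.5
    intervals = []
    cursor = 0.0
    for e in timed:
        if e.onset_t > cursor:
            intervals.append((cursor, e.onset_t, ""))
        label = f"{e.serial_index}:{e.produced_label}"
        if e.error_tags:
            label += ":" + ";".join(sorted(e.error_tags))
        intervals.append((e.onset_t, e.offset_t, label))
        cursor = e.offset_t
    if cursor < xmax:
        intervals.append((cursor, xmax, ""))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_TG_HEADER.format(xmax=f"{xmax:.6f}", size=len(intervals)))
        for i, (a, b, lab) in enumerate(intervals, 1):
            fh.write(f"        intervals [{i}]:\n")
            fh.write(f"            xmin = {a:.6f}\n")
            fh.write(f"            xmax = {b:.6f}\n")
            fh.write(f'            text = "{lab}"\n')


_TG_ITEM_RE = re.compile(
    r'class\s*=\s*"IntervalTier"\s*\n\s*name\s*=\s*"(?P<name>[^"]*)"', re.S)
_TG_INT_RE = re.compile(
    r"intervals\s*\[\d+\]:\s*\n"
    r'\s*xmin\s*=\s*(?P<xmin>[\d.eE+-]+)\s*\n'
    r'\s*xmax\s*=\s*(?P<xmax>[\d.eE+-]+)\s*\n'
    r'\s*text\s*=\s*"(?P<text>[^"]*)"')


def read_textgrid_events(path, run_spec: RunSpec, tier: str = "word") -> VoiceTrack:
    """Read the ``word`` interval tier of a long-form TextGrid."""
    with open(path, encoding="utf-8") as fh:
        text = fh.read()
    # split into tier blocks on 'item [k]:' boundaries and keep the named one
    blocks = re.split(r"\n\s*item \[\d+\]:", text)
    target = None
    for block in blocks:
        m = _TG_ITEM_RE.search(block)
        if m and m.group("name") == tier:
            target = block
            break
    if target is None:
        raise VoiceFormatError(f'TextGrid has no interval tier named "{tier}"')
    events = []
    for m in _TG_INT_RE.finditer(target):
        label = m.group("text").strip()
        if not label:
            continue
        parts = label.split(":")
        if len(parts) < 2:
            raise VoiceFormatError(f"unparseable interval label {label!r}")
        serial = int(parts[0])
        tags = _parse_tags(parts[2]) if len(parts) > 2 else frozenset()
        events.append(VocalEvent(
            serial_index=serial, onset_t=float(m.group("xmin")),
            offset_t=float(m.group("xmax")), produced_label=parts[1],
            error_tags=tags))
    return VoiceTrack(run_spec=run_spec, events=events)


def concat_tracks(tracks: Iterable[VoiceTrack]) -> list[VocalEvent]:
    """Flatten events of several tracks (used by additivity checks)."""
    out: list[VocalEvent] = []
    for tr in tracks:
        out.extend(tr.events)
    return out
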