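"""AOI scanpath metrics: total fixations, perseverations, regressions.

After fixations are assigned to item AOIs and the positional exclusion is
applied, the AOI visit sequence is an ordered list of serial indices.  The
run metrics are order statistics of that sequence:

* **total fixations** — raw entry count, before any pooling;
* **perseverations** — consecutively repeated fixations within the same
  item: each maximal block of m equal entries contributes m - 1;
* **regressions** — backward transitions to an item that was already visited
  earlier in the sequence (a backward saccade to a never-visited item counts
  as neither);
* **refixations** — perseverations + regressions.

Off-array fixations are dropped from the sequence (tallied separately) and
do not break perseveration blocks; the pooled count is also reported since
"number of fixations" is sometimes defined post-pooling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .fixation import Fixation
from .stimuli import StimulusArray, aoi_at_points

__all__ = ["AoiVisitSequence", "assign_fixations", "count_total_fixations",
           "count_perseverations", "count_regressions", "count_refixations",
           "pooled_fixation_count"]


@dataclass
class AoiVisitSequence:
    """Time-ordered AOI visits of retained fixations, plus drop tallies."""

    entries: list[tuple[Fixation, int]] = field(default_factory=list)
    n_off_array: int = 0
    n_position_excluded: int = 0

    @property
    def aoi_sequence(self) -> list[int]:
        return [a for _, a in self.entries]

    def __len__(self) -> int:
        return len(self.entries)


def assign_fixations(fixations: Sequence[Fixation], array: StimulusArray,
                     retained_mask: Optional[np.ndarray] = None) -> AoiVisitSequence:
    """Assign each fixation's centroid to an AOI and build the visit sequence.

    Fixations whose centroid lies outside every AOI are dropped and counted
    as off-array; with ``retained_mask`` given, fixations on positionally
    excluded items are dropped and counted separately.
    """
    seq = AoiVisitSequence()
    if not fixations:
        return seq
    cx = np.array([f.centroid_x_px for f in fixations])
    cy = np.array([f.centroid_y_px for f in fixations])
    idx = aoi_at_points(array, cx, cy)
    for f, a in zip(fixations, idx):
        a = int(a)
        if a < 0:
            seq.n_off_array += 1
        elif retained_mask is not None and not retained_mask[a]:
            seq.n_position_excluded += 1
        else:
            seq.entries.append((f, a))
    return seq


def fixation_aois(fixations: Sequence[Fixation], array: StimulusArray) -> np.ndarray:
    """Per-fixation AOI index (-1 off-array), with no filtering."""
    if not fixations:
        return np.empty(0, dtype=int)
    cx = np.array([f.centroid_x_px for f in fixations])
    cy = np.array([f.centroid_y_px for f in fixations])
    return aoi_at_points(array, cx, cy)


def _seq(seq) -> list[int]:
    return seq.aoi_sequence if isinstance(seq, AoiVisitSequence) else list(seq)


def count_total_fixations(seq) -> int:
    """Raw (pre-pooling) number of retained fixations."""
    return len(_seq(seq))


def pooled_fixation_count(seq) -> int:
    """Number of maximal same-AOI blocks (post-pooling visit count)."""
    s = _seq(seq)
    if not s:
        return 0
    return 1 + int(np.sum(np.diff(np.asarray(s)) != 0))


def count_perseverations(seq) -> int:
    """Consecutively repeated same-item fixations: sum of (m - 1) over blocks.

    Equivalently the number of adjacent equal pairs in the sequence.
    """
    s = np.asarray(_seq(seq))
    if s.size < 2:
        return 0
    return int(np.sum(s[1:] == s[:-1]))


def count_regressions(seq) -> int:
    """Backward transitions onto previously visited items.

    A transition counts when the next entry's serial index is strictly lower
    than the current entry's AND that index already appeared earlier in the
    sequence.
    """
    s = _seq(seq)
    visited: set[int] = set()
    count = 0
    for prev, nxt in zip(s, s[1:]):
        visited.add(prev)
        if nxt < prev and nxt in visited:
            count += 1
    return count


def count_refixations(seq) -> int:
    """Perseverations plus regressions."""
    return count_perseverations(seq) + count_regressions(seq)
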