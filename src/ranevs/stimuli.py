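"""RAN stimulus arrays and their area-of-interest (AOI) tiling.

A rapid-automatized-naming (RAN) run presents a grid of 36 familiar items
(colors, objects, numbers or letters) that the participant names serially,
left-to-right within each row and top-to-bottom across rows.  Every other
module addresses items by their *serial index* in that reading order, so this
module owns the coordinate system: item centers on a regular grid, and one
axis-aligned AOI rectangle per item extending from the item center to the
midpoint between adjacent centers (edge AOIs are clipped half a spacing
beyond the outer centers, so off-array gaze is recognisable as such).

Coordinates are screen pixels with the origin at the top-left corner and y
increasing downward; AOI rectangles are half-open, ``[left, right) x
[top, bottom)``, which makes AOI membership a partition of the grid region.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "ScreenGeometry",
    "StimulusType",
    "Condition",
    "RunSpec",
    "AoiRect",
    "StimulusArray",
    "build_array_layout",
    "aoi_at_point",
    "DEFAULT_SCREEN",
    "N_ITEMS",
]

#: Items per RAN array (fixed by the task design).
N_ITEMS = 36


class ConfigurationError(ValueError):
    """A layout or geometry parameter is inconsistent or does not fit."""


class StimulusType(str, Enum):
    COLOR = "color"
    OBJECT = "object"
    NUMBER = "number"
    LETTER = "letter"


class Condition(str, Enum):
    SYMBOLIC = "symbolic"
    NON_SYMBOLIC = "non_symbolic"


#: Condition membership: numbers and letters are symbolic stimuli.
_SYMBOLIC_TYPES = {StimulusType.NUMBER, StimulusType.LETTER}


def condition_of(stimulus_type: StimulusType) -> Condition:
    """Map a stimulus type to its analysis condition."""
    st = StimulusType(stimulus_type)
    return Condition.SYMBOLIC if st in _SYMBOLIC_TYPES else Condition.NON_SYMBOLIC


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical display description used to convert pixels to visual angle.

    Parameters
    ----------
    width_px, height_px
        Display resolution in pixels.
    width_cm, height_cm
        Physical size of the displayed area in centimetres.
    viewing_distance_cm
        Eye-to-screen distance.  The study seated participants roughly
        50-60 cm from the display; the default below uses the midpoint.
    """

    width_px: int = 1280
    height_px: int = 1024
    width_cm: float = 43.3
    height_cm: float = 34.6
    viewing_distance_cm: float = 57.0

    def __post_init__(self) -> None:
        vals = (self.width_px, self.height_px, self.width_cm,
                self.height_cm, self.viewing_distance_cm)
        if any(v <= 0 for v in vals):
            raise ConfigurationError("all screen geometry fields must be positive")
        aspect_px = self.width_px / self.height_px
        aspect_cm = self.width_cm / self.height_cm
        if abs(aspect_px - aspect_cm) / aspect_px > 0.05:
            raise ConfigurationError(
                f"pixel aspect {aspect_px:.3f} and physical aspect {aspect_cm:.3f} "
                "disagree by more than 5% (non-square pixels?)"
            )

    @property
    def px_pitch_x_cm(self) -> float:
        return self.width_cm / self.width_px

    @property
    def px_pitch_y_cm(self) -> float:
        return self.height_cm / self.height_px


#: 1280x1024 on a 21" 5:4 panel, 57 cm viewing distance.
DEFAULT_SCREEN = ScreenGeometry()


@dataclass(frozen=True)
class RunSpec:
    """Identity of one RAN run: who, which stimulus type, which repetition."""

    participant_id: str
    stimulus_type: StimulusType
    run_index: int  # 1 or 2

    def __post_init__(self) -> None:
        object.__setattr__(self, "stimulus_type", StimulusType(self.stimulus_type))
        if self.run_index not in (1, 2):
            raise ValueError(f"run_index must be 1 or 2, got {self.run_index}")

    @property
    def condition(self) -> Condition:
        return condition_of(self.stimulus_type)


@dataclass(frozen=True)
class AoiRect:
    """Half-open AOI rectangle ``[left, right) x [top, bottom)`` in pixels."""

    left: float
    right: float
    top: float
    bottom: float

    def contains(self, x: float, y: float) -> bool:
        return self.left <= x < self.right and self.top <= y < self.bottom


@dataclass(frozen=True)
class StimulusArray:
    """A 36-item RAN array with its AOI tiling.

    ``centers_x``/``centers_y`` are indexed by serial index (row-major reading
    order).  ``col_edges``/``row_edges`` are the sorted AOI boundary
    coordinates, so AOI lookup is a pair of binary searches.
    """

    stimulus_type: StimulusType
    run_index: int
    n_rows: int
    n_cols: int
    labels: tuple
    centers_x: np.ndarray = field(repr=False)
    centers_y: np.ndarray = field(repr=False)
    col_edges: np.ndarray = field(repr=False)
    row_edges: np.ndarray = field(repr=False)

    @property
    def n_items(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def condition(self) -> Condition:
        return condition_of(self.stimulus_type)

    def serial_index(self, row: int, col: int) -> int:
        """Row-major reading-order index of the (row, col) cell."""
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise IndexError(f"cell ({row}, {col}) outside {self.n_rows}x{self.n_cols} grid")
        return row * self.n_cols + col

    def aois(self) -> list[AoiRect]:
        """One AOI rectangle per item, in serial order."""
        out = []
        for r in range(self.n_rows):
            for c in range(self.n_cols):
                out.append(AoiRect(
                    left=float(self.col_edges[c]), right=float(self.col_edges[c + 1]),
                    top=float(self.row_edges[r]), bottom=float(self.row_edges[r + 1]),
                ))
        return out

    # -- serialization -----------------------------------------------------

    def to_json(self) -> str:
        doc = {
            "stimulus_type": self.stimulus_type.value,
            "run_index": self.run_index,
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "items": [
                {"serial_index": i, "label": self.labels[i],
                 "center_x_px": float(self.centers_x[i]),
                 "center_y_px": float(self.centers_y[i])}
                for i in range(self.n_items)
            ],
            "aois": [
                {"left": a.left, "right": a.right, "top": a.top, "bottom": a.bottom}
                for a in self.aois()
            ],
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "StimulusArray":
        doc = json.loads(text)
        n_rows, n_cols = doc["n_rows"], doc["n_cols"]
        items = sorted(doc["items"], key=lambda d: d["serial_index"])
        cx = np.array([d["center_x_px"] for d in items])
        cy = np.array([d["center_y_px"] for d in items])
        aois = doc["aois"]
        col_edges = np.array([aois[c]["left"] for c in range(n_cols)] + [aois[n_cols - 1]["right"]])
        row_edges = np.array([aois[r * n_cols]["top"] for r in range(n_rows)]
                             + [aois[(n_rows - 1) * n_cols]["bottom"]])
        return cls(
            stimulus_type=StimulusType(doc["stimulus_type"]),
            run_index=doc["run_index"], n_rows=n_rows, n_cols=n_cols,
            labels=tuple(d["label"] for d in items),
            centers_x=cx, centers_y=cy, col_edges=col_edges, row_edges=row_edges,
        )


_DEFAULT_LABELS = {
    StimulusType.COLOR: ["red", "green", "blue", "yellow", "black", "brown"],
    StimulusType.OBJECT: ["boat", "star", "fish", "key", "chair", "pencil"],
    StimulusType.NUMBER: ["2", "4", "7", "8", "3", "5"],
    StimulusType.LETTER: ["a", "d", "k", "n", "s", "t"],
}


def build_array_layout(
    stimulus_type: StimulusType | str,
    run_index: int,
    screen: ScreenGeometry = DEFAULT_SCREEN,
    n_rows: int = 4,
    n_cols: int = 9,
    labels: Optional[Sequence[str]] = None,
    margin_frac: float = 0.08,
) -> StimulusArray:
    """Lay out a RAN array of ``n_rows x n_cols`` items centred on the screen.

    Item centers form a regular grid inside the screen minus a fractional
    margin; AOI boundaries between adjacent items fall at the midpoints of
    their centers, and edge AOIs extend outward by the same half-spacing.
    The grid defaults to 4 rows of 9 items (36 items, mirroring the task's
    nine-symbol practice row).

    Raises
    ------
    ConfigurationError
        If the grid does not fit the screen or ``n_rows * n_cols != 36``.
    """
    stimulus_type = StimulusType(stimulus_type)
    if n_rows * n_cols != N_ITEMS:
        raise ConfigurationError(
            f"grid must contain {N_ITEMS} items, got {n_rows}x{n_cols}")
    if not (0 <= margin_frac < 0.5):
        raise ConfigurationError("margin_frac must be in [0, 0.5)")

    usable_w = screen.width_px * (1 - 2 * margin_frac)
    usable_h = screen.height_px * (1 - 2 * margin_frac)
    sx = usable_w / n_cols
    sy = usable_h / n_rows
    if sx <= 1 or sy <= 1:
        raise ConfigurationError("item spacing does not fit within screen bounds")

    x0 = screen.width_px * margin_frac + sx / 2.0
    y0 = screen.height_px * margin_frac + sy / 2.0
    cols_x = x0 + sx * np.arange(n_cols)
    rows_y = y0 + sy * np.arange(n_rows)
    if cols_x[-1] + sx / 2 > screen.width_px or rows_y[-1] + sy / 2 > screen.height_px:
        raise ConfigurationError("grid does not fit screen")

    centers_x = np.tile(cols_x, n_rows)
    centers_y = np.repeat(rows_y, n_cols)
    col_edges = np.concatenate(([cols_x[0] - sx / 2], (cols_x[:-1] + cols_x[1:]) / 2,
                                [cols_x[-1] + sx / 2]))
    row_edges = np.concatenate(([rows_y[0] - sy / 2], (rows_y[:-1] + rows_y[1:]) / 2,
                                [rows_y[-1] + sy / 2]))

    if labels is None:
        pool = _DEFAULT_LABELS[stimulus_type]
        # deterministic label cycle; actual vocabulary is irrelevant to scoring
        labels = tuple(pool[i % len(pool)] for i in range(N_ITEMS))
    else:
        labels = tuple(labels)
        if len(labels) != n_rows * n_cols:
            raise ConfigurationError("labels length must equal item count")

    return StimulusArray(
        stimulus_type=stimulus_type, run_index=run_index,
        n_rows=n_rows, n_cols=n_cols, labels=labels,
        centers_x=centers_x, centers_y=centers_y,
        col_edges=col_edges, row_edges=row_edges,
    )


def aoi_at_point(array: StimulusArray, x_px: float, y_px: float) -> Optional[int]:
    """Serial index of the AOI containing a point, or None when off-array.

    Boundary points resolve by the half-open rectangle convention, so every
    in-grid point belongs to exactly one AOI.
    """
    c = int(np.searchsorted(array.col_edges, x_px, side="right")) - 1
    r = int(np.searchsorted(array.row_edges, y_px, side="right")) - 1
    if not (0 <= c < array.n_cols and 0 <= r < array.n_rows):
        return None
    return r * array.n_cols + c


def aoi_at_points(array: StimulusArray, x_px: np.ndarray, y_px: np.ndarray) -> np.ndarray:
    """Vectorised :func:`aoi_at_point`; -1 marks off-array points."""
    c = np.searchsorted(array.col_edges, x_px, side="right") - 1
    r = np.searchsorted(array.row_edges, y_px, side="right") - 1
    idx = r * array.n_cols + c
    off = (c < 0) | (c >= array.n_cols) | (r < 0) | (r >= array.n_rows)
    return np.where(off, -1, idx)
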