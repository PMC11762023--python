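"""Domain types and shared geometry for reading eye-tracking data.

Coordinate convention (inherited by every module): pixel units, origin at
the top-left of the stimulus, y increasing downward.  A *fixation* is a
(x, y, duration) triple; a *line assignment* maps each fixation to the
1-based index of the text line it was directed at.  Correction here means
line snapping only: the corrected fixation keeps its x and duration and
takes the assigned line's center y.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "Fixation",
    "FixationSequence",
    "AOI",
    "AOISet",
    "LineGeometry",
    "LineAssignment",
    "Trial",
    "line_centers",
    "apply_assignment",
    "accuracy",
]


@dataclass(frozen=True)
class Fixation:
    """A single fixation: position in pixels and duration in milliseconds."""

    x: float
    y: float
    duration: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"fixation position must be finite, got ({self.x}, {self.y})")
        if not (math.isfinite(self.duration) and self.duration > 0):
            raise ValueError(f"fixation duration must be positive, got {self.duration}")

    def replace(self, x: float | None = None, y: float | None = None,
                duration: float | None = None) -> "Fixation":
        return Fixation(
            self.x if x is None else x,
            self.y if y is None else y,
            self.duration if duration is None else duration,
        )


class FixationSequence(Sequence[Fixation]):
    """Chronologically ordered sequence of fixations.

    Transformations that neither delete nor merge fixations preserve order.
    """

    def __init__(self, fixations: Iterable[Fixation] = ()) -> None:
        self._fixations: tuple[Fixation, ...] = tuple(fixations)

    @classmethod
    def from_arrays(cls, xs, ys, durations) -> "FixationSequence":
        return cls(Fixation(float(x), float(y), float(d))
                   for x, y, d in zip(xs, ys, durations, strict=True))

    def __len__(self) -> int:
        return len(self._fixations)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return FixationSequence(self._fixations[i])
        return self._fixations[i]

    def __iter__(self) -> Iterator[Fixation]:
        return iter(self._fixations)

    def __eq__(self, other) -> bool:
        if not isinstance(other, FixationSequence):
            return NotImplemented
        return self._fixations == other._fixations

    def __repr__(self) -> str:
        return f"FixationSequence(n={len(self)})"

    @property
    def xs(self) -> np.ndarray:
        return np.array([f.x for f in self._fixations], dtype=float)

    @property
    def ys(self) -> np.ndarray:
        return np.array([f.y for f in self._fixations], dtype=float)

    @property
    def durations(self) -> np.ndarray:
        return np.array([f.duration for f in self._fixations], dtype=float)


@dataclass(frozen=True)
class AOI:
    """Rectangular area of interest at letter, word, or line granularity.

    Containment is half-open: (px, py) is inside iff
    x <= px < x + width and y <= py < y + height, so a point on the shared
    edge of two adjacent AOIs belongs only to the later one.
    """

    kind: str  # "letter" | "word" | "line"
    x: float
    y: float
    width: float
    height: float
    line: int  # 1-based line index
    part: int  # 1-based within-line index
    image: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("letter", "word", "line"):
            raise ValueError(f"unknown AOI kind {self.kind!r}")
        if self.width <= 0 or self.height <= 0:
            raise ValueError("AOI width and height must be positive")
        if self.line < 1 or self.part < 1:
            raise ValueError("line and part indices are 1-based")

    def contains(self, px: float, py: float) -> bool:
        return (self.x <= px < self.x + self.width
                and self.y <= py < self.y + self.height)

    @property
    def center(self) -> tuple[float, float]:
        return (self.x + self.width / 2.0, self.y + self.height / 2.0)


class AOISet(Sequence[AOI]):
    """A set of AOIs of one kind over a stimulus; iterates in (line, part) order."""

    def __init__(self, aois: Iterable[AOI],
                 screen_width: float | None = None,
                 screen_height: float | None = None) -> None:
        aois = sorted(aois, key=lambda a: (a.line, a.part))
        kinds = {a.kind for a in aois}
        if len(kinds) > 1:
            raise ValueError(f"AOISet must hold one kind, got {sorted(kinds)}")
        seen = set()
        for a in aois:
            key = (a.line, a.part)
            if key in seen:
                raise ValueError(f"duplicate (line, part) {key} in AOISet")
            seen.add(key)
        self._aois = tuple(aois)
        self.screen_width = screen_width
        self.screen_height = screen_height

    def __len__(self) -> int:
        return len(self._aois)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return AOISet(self._aois[i], self.screen_width, self.screen_height)
        return self._aois[i]

    def __iter__(self) -> Iterator[AOI]:
        return iter(self._aois)

    @property
    def kind(self) -> str:
        return self._aois[0].kind if self._aois else "word"

    @property
    def n_lines(self) -> int:
        return len({a.line for a in self._aois})

    def find(self, px: float, py: float) -> AOI | None:
        """First AOI containing the point, or None (at most one when disjoint)."""
        for a in self._aois:
            if a.contains(px, py):
                return a
        return None


@dataclass(frozen=True)
class LineGeometry:
    """Vertical centers of the text lines, ascending (line 1 first)."""

    centers: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.centers) == 0:
            raise ValueError("no line centers")
        if any(b <= a for a, b in zip(self.centers, self.centers[1:])):
            raise ValueError("line centers must be strictly ascending")

    def __len__(self) -> int:
        return len(self.centers)

    def nearest_line(self, y: float) -> int:
        """1-based index of the line whose center is nearest to y.

        A tie (y midway between two centers) goes to the smaller index.
        """
        diffs = [abs(y - c) for c in self.centers]
        return int(np.argmin(diffs)) + 1

    def center_of(self, line: int) -> float:
        if not 1 <= line <= len(self.centers):
            raise ValueError(f"line {line} out of range 1..{len(self.centers)}")
        return self.centers[line - 1]


class LineAssignment(Sequence[int]):
    """One 1-based line index per fixation."""

    def __init__(self, lines: Iterable[int], n_lines: int | None = None) -> None:
        lines = tuple(int(v) for v in lines)
        if any(v < 1 for v in lines):
            raise ValueError("line indices are 1-based")
        if n_lines is not None and any(v > n_lines for v in lines):
            raise ValueError(f"line index exceeds number of lines {n_lines}")
        self._lines = lines

    def __len__(self) -> int:
        return len(self._lines)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return LineAssignment(self._lines[i])
        return self._lines[i]

    def __iter__(self) -> Iterator[int]:
        return iter(self._lines)

    def __eq__(self, other) -> bool:
        if isinstance(other, LineAssignment):
            return self._lines == other._lines
        return tuple(other) == self._lines

    def __repr__(self) -> str:
        return f"LineAssignment({list(self._lines)!r})"


@dataclass
class Trial:
    """A fixation sequence bound to its stimulus AOIs plus free metadata."""

    seq: FixationSequence
    aois: AOISet
    image: str = ""
    metadata: Mapping = field(default_factory=dict)


def line_centers(aois: AOISet) -> LineGeometry:
    """Derive line-center geometry from an AOISet.

    The center of a line is the mean vertical midpoint (y + height/2) of
    that line's AOIs.
    """
    if len(aois) == 0:
        raise ValueError("no AOIs")
    by_line: dict[int, list[float]] = {}
    for a in aois:
        by_line.setdefault(a.line, []).append(a.y + a.height / 2.0)
    centers = [float(np.mean(by_line[k])) for k in sorted(by_line)]
    return LineGeometry(tuple(centers))


def apply_assignment(seq: FixationSequence, asg: LineAssignment,
                     geom: LineGeometry) -> FixationSequence:
    """Snap each fixation's y to its assigned line center; x and duration unchanged."""
    if len(seq) != len(asg):
        raise ValueError(f"length mismatch: {len(seq)} fixations vs {len(asg)} assignments")
    return FixationSequence(
        f.replace(y=geom.center_of(line)) for f, line in zip(seq, asg)
    )


def accuracy(corrected: LineAssignment, truth: LineAssignment) -> float:
    """Fraction of fixations placed on their true line.

    This is the benchmark metric for drift correction: the proportion of
    fixations returned to the line they were generated on.
    """
    if len(corrected) != len(truth):
        raise ValueError(f"length mismatch: {len(corrected)} vs {len(truth)}")
    if len(corrected) == 0:
        raise ValueError("accuracy undefined for empty assignments")
    hits = sum(1 for a, b in zip(corrected, truth) if a == b)
    return hits / len(corrected)
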