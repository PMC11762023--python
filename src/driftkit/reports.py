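"""Hit-testing and eye-movement metric reports.

``hit_test`` assigns each fixation to the AOI it lies over (half-open
containment) and emits one record per fixation with the AOI's geometry,
line, and part — the AOI report.  ``aoi_metrics`` computes per-AOI
reading measures:

* fixation count;
* FFD, first-fixation duration — the duration of the first fixation to
  land on the AOI;
* GD, gaze duration — the summed durations of the contiguous first-pass
  run starting at that first fixation and ending before the first
  departure to a different AOI (or off any AOI; momentary departures are
  not bridged);
* TT, total time — the sum of all fixation durations on the AOI,
  regressions included.

Invariant: summed TT over AOIs plus the off-AOI duration equals the total
duration of the sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .core import AOISet, FixationSequence
from .io_formats import AscEvent

__all__ = ["HitRecord", "hit_test", "hit_test_frame", "aoi_metrics",
           "fixation_report", "saccade_report"]

#: column order of the AOI (hit-test) report
HIT_COLUMNS = ["fix_x", "fix_y", "duration", "aoi_x", "aoi_y",
               "aoi_width", "aoi_height", "line", "part", "image"]


@dataclass(frozen=True)
class HitRecord:
    fix_x: float
    fix_y: float
    duration: float
    aoi_x: float | None = None
    aoi_y: float | None = None
    aoi_width: float | None = None
    aoi_height: float | None = None
    line: int | None = None
    part: int | None = None
    image: str = ""

    @property
    def hit(self) -> bool:
        return self.line is not None


def hit_test(seq: FixationSequence, aois: AOISet) -> list[HitRecord]:
    """One record per fixation, in order; non-hits carry empty AOI fields."""
    records = []
    for f in seq:
        a = aois.find(f.x, f.y)
        if a is None:
            records.append(HitRecord(f.x, f.y, f.duration))
        else:
            records.append(HitRecord(f.x, f.y, f.duration, a.x, a.y,
                                     a.width, a.height, a.line, a.part,
                                     a.image))
    return records


def hit_test_frame(seq: FixationSequence, aois: AOISet) -> pd.DataFrame:
    """Hit-test report as a DataFrame with the canonical column order."""
    rows = [{c: getattr(r, c) for c in HIT_COLUMNS} for r in hit_test(seq, aois)]
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def aoi_metrics(seq: FixationSequence, aois: AOISet) -> pd.DataFrame:
    """Per-AOI fixation count, FFD, GD, and TT (ms); never-fixated AOIs
    report zeros."""
    hit_keys = []  # (line, part) or None per fixation, chronological
    for f in seq:
        a = aois.find(f.x, f.y)
        hit_keys.append((a.line, a.part) if a is not None else None)

    rows = []
    for a in aois:
        key = (a.line, a.part)
        indices = [i for i, k in enumerate(hit_keys) if k == key]
        if not indices:
            ffd = gd = tt = 0.0
        else:
            first = indices[0]
            ffd = seq[first].duration
            gd = 0.0
            for i in range(first, len(seq)):
                if hit_keys[i] != key:
                    break
                gd += seq[i].duration
            tt = sum(seq[i].duration for i in indices)
        rows.append({"kind": a.kind, "aoi_x": a.x, "aoi_y": a.y,
                     "aoi_width": a.width, "aoi_height": a.height,
                     "line": a.line, "part": a.part, "image": a.image,
                     "fixation_count": len(indices),
                     "FFD": ffd, "GD": gd, "TT": tt})
    return pd.DataFrame(rows)


def fixation_report(seq: FixationSequence) -> pd.DataFrame:
    """Lossless tabular dump of a fixation sequence."""
    return pd.DataFrame(
        [{"x": f.x, "y": f.y, "duration": f.duration} for f in seq],
        columns=["x", "y", "duration"],
    )


def saccade_report(events: list[AscEvent]) -> pd.DataFrame:
    """Tabular dump of the saccade events from a parsed recording."""
    rows = [{"timestamp": e.timestamp, "x": e.x, "y": e.y,
             "duration": e.duration, "amplitude": e.amplitude,
             "peak_velocity": e.peak_velocity}
            for e in events if e.kind == "saccade"]
    return pd.DataFrame(rows, columns=["timestamp", "x", "y", "duration",
                                       "amplitude", "peak_velocity"])
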