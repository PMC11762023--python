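"""Readers, writers, and converters for fixation data formats.

Three interchange formats are supported:

* **EyeLink ASCII (.asc)** — read-only.  Trials are segmented by MSG
  marker lines (default: a ``TRIALID`` message opens a trial, the next
  one or end-of-file closes it); EFIX / ESACC / EBLINK event lines are
  parsed, anything unrecognized is skipped and counted.
* **CSV** — two dialects: an 8-column event table carrying everything in
  the ASC file (timestamp, event, x, y, duration, pupil, amplitude,
  peak_velocity), and a minimal x,y,duration fixation table.
* **JSON** — a deliberately minimal dialect: a top-level ``fixations``
  key holding an ordered list of ``[x, y, duration]`` triples.  Any other
  top-level keys (participant ID, trial number, timestamps, ...) are
  preserved verbatim on write, so enriched files round-trip without the
  reader knowing their schema.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .core import AOI, AOISet, Fixation, FixationSequence

__all__ = [
    "AscEvent", "read_asc", "asc_to_csv", "asc_to_json",
    "read_json", "write_json", "read_csv_fixations", "write_csv_fixations",
    "read_aoi_csv", "write_aoi_csv", "fixations_from_events",
]

CSV_COLUMNS = ["timestamp", "event", "x", "y", "duration", "pupil",
               "amplitude", "peak_velocity"]


@dataclass(frozen=True)
class AscEvent:
    """One parsed eye event; saccade-only fields are None otherwise."""

    timestamp: float
    kind: str  # "fixation" | "saccade" | "blink"
    x: float | None = None
    y: float | None = None
    duration: float | None = None
    pupil: float | None = None
    amplitude: float | None = None
    peak_velocity: float | None = None


def _floats(tokens, n):
    return [float(t) for t in tokens[:n]]


def read_asc(path, trial_start: str = r"TRIALID\s+(\S+)",
             trial_end: str | None = None, eye: str | None = None,
             ) -> list[tuple[str, list[AscEvent]]]:
    """Parse an EyeLink ASCII export into per-trial event lists.

    ``trial_start`` is a regex applied to MSG lines; its first group (if
    any) names the trial.  A trial ends at the next start match, at a
    ``trial_end`` match if given, or at end-of-file.  ``eye`` selects
    'L' or 'R' in binocular files (default: first eye encountered).
    Malformed event lines are skipped; their count is attached to the
    function as ``read_asc.last_skipped``.
    """
    start_re = re.compile(trial_start)
    end_re = re.compile(trial_end) if trial_end else None
    trials: list[tuple[str, list[AscEvent]]] = []
    current: list[AscEvent] | None = None
    chosen_eye = eye
    skipped = 0

    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        tokens = line.split()
        tag = tokens[0]
        if tag == "MSG" and len(tokens) >= 3:
            msg = " ".join(tokens[2:])
            if end_re and end_re.search(msg) and current is not None:
                current = None
                continue
            m = start_re.search(msg)
            if m:
                name = m.group(1) if m.groups() else str(len(trials) + 1)
                current = []
                trials.append((name, current))
            continue
        if current is None or tag not in ("EFIX", "ESACC", "EBLINK"):
            continue
        try:
            this_eye = tokens[1]
            if chosen_eye is None:
                chosen_eye = this_eye
            if this_eye != chosen_eye:
                continue
            if tag == "EFIX":
                start, end, dur, x, y, pupil = _floats(tokens[2:], 6)
                current.append(AscEvent(start, "fixation", x, y, dur, pupil))
            elif tag == "ESACC":
                vals = _floats(tokens[2:], 9)
                start, end, dur, sx, sy, ex, ey, ampl, pv = vals
                current.append(AscEvent(start, "saccade", sx, sy, dur,
                                        amplitude=ampl, peak_velocity=pv))
            else:  # EBLINK
                start, end, dur = _floats(tokens[2:], 3)
                current.append(AscEvent(start, "blink", duration=dur))
        except (ValueError, IndexError):
            skipped += 1
    read_asc.last_skipped = skipped
    if not trials:
        raise ValueError(
            f"no trials found in {path}: no MSG line matched {trial_start!r}")
    return trials


def fixations_from_events(events: list[AscEvent]) -> FixationSequence:
    """Fixation events as a FixationSequence (saccades/blinks dropped)."""
    return FixationSequence(
        Fixation(e.x, e.y, e.duration) for e in events if e.kind == "fixation"
    )


def asc_to_csv(events: list[AscEvent]) -> pd.DataFrame:
    """All events as the 8-column table (one row per event)."""
    rows = [{"timestamp": e.timestamp, "event": e.kind, "x": e.x, "y": e.y,
             "duration": e.duration, "pupil": e.pupil,
             "amplitude": e.amplitude, "peak_velocity": e.peak_velocity}
            for e in events]
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def asc_to_json(events: list[AscEvent]) -> dict:
    """Minimal JSON representation: ordered [x, y, duration] fixation
    triples only (saccades and blinks are excluded by design)."""
    return {"fixations": [[e.x, e.y, e.duration]
                          for e in events if e.kind == "fixation"]}


def read_json(path) -> tuple[FixationSequence, dict]:
    """Read the JSON dialect; returns the fixations plus every other
    top-level key untouched (for round-tripping)."""
    data = json.loads(Path(path).read_text())
    if not isinstance(data, dict) or "fixations" not in data:
        raise ValueError(f"{path}: missing top-level 'fixations' list")
    triples = data["fixations"]
    fixations = []
    for i, t in enumerate(triples):
        if not isinstance(t, (list, tuple)) or len(t) != 3:
            raise ValueError(f"{path}: fixation {i} is not an [x, y, duration] triple")
        fixations.append(Fixation(float(t[0]), float(t[1]), float(t[2])))
    extra = {k: v for k, v in data.items() if k != "fixations"}
    return FixationSequence(fixations), extra


def write_json(seq: FixationSequence, path, extra: dict | None = None) -> None:
    """Write the JSON dialect, carrying any extra top-level keys verbatim."""
    data = dict(extra or {})
    data["fixations"] = [[f.x, f.y, f.duration] for f in seq]
    Path(path).write_text(json.dumps(data, indent=1))


def read_csv_fixations(path) -> FixationSequence:
    """Read a minimal fixation CSV (columns x, y, duration)."""
    df = pd.read_csv(path)
    missing = {"x", "y", "duration"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return FixationSequence.from_arrays(df["x"], df["y"], df["duration"])


def write_csv_fixations(seq: FixationSequence, path) -> None:
    pd.DataFrame({"x": seq.xs, "y": seq.ys,
                  "duration": seq.durations}).to_csv(path, index=False)


_NAME_RE = re.compile(r"line\s*(\d+)\s*part\s*(\d+)")


def write_aoi_csv(aois: AOISet, path) -> None:
    """Write an AOISet as an externally editable CSV
    (kind, name, x, y, width, height, image; name = 'line L part P')."""
    rows = [{"kind": a.kind, "name": f"line {a.line} part {a.part}",
             "x": a.x, "y": a.y, "width": a.width, "height": a.height,
             "image": a.image} for a in aois]
    pd.DataFrame(rows, columns=["kind", "name", "x", "y", "width",
                                "height", "image"]).to_csv(path, index=False)


def read_aoi_csv(path, screen_width: float | None = None,
                 screen_height: float | None = None) -> AOISet:
    """Read an AOI CSV written by :func:`write_aoi_csv` (possibly edited)."""
    df = pd.read_csv(path)
    aois = []
    for _, row in df.iterrows():
        m = _NAME_RE.search(str(row["name"]))
        if not m:
            raise ValueError(f"{path}: cannot parse AOI name {row['name']!r}")
        aois.append(AOI(kind=str(row["kind"]), x=float(row["x"]),
                        y=float(row["y"]), width=float(row["width"]),
                        height=float(row["height"]), line=int(m.group(1)),
                        part=int(m.group(2)),
                        image=str(row.get("image", "") or "")))
    return AOISet(aois, screen_width, screen_height)
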