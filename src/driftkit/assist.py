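"""Assisted (semi-automated) drift correction.

A :class:`CorrectionSession` walks the fixations of a trial one at a time
in chronological order.  At each step an automatic corrector proposes a
line for the current fixation; the user either accepts the suggestion
(space bar in the GUI analogue) or intervenes — dragging the fixation to
explicit coordinates, nudging it one line up or down ('a' / 'z'), or
jumping it straight to line k (the 1–9 keys).  Every intervention pins
the fixation and triggers a recompute: the corrector is rerun on a copy
of the sequence in which all decided fixations carry their decided
coordinates, so the extra human information improves the remaining
suggestions.  Accepting adds no new information and does not recompute.

Decided fixations are never altered by later recomputes.  Every action is
appended to a timestamped :class:`EventLog`, from which per-trial active
correction time can be recovered (long inactivity gaps excluded).
"""

from __future__ import annotations

import itertools
import json
import math
import time
from dataclasses import dataclass, field
from typing import Callable

from .algorithms import ALGORITHMS, AlgoParams, DEFAULT_PARAMS, WordCenters
from .core import (FixationSequence, LineAssignment, LineGeometry, Trial,
                   line_centers)

__all__ = ["EventLog", "CorrectionSession", "start_session", "run_oracle",
           "replay"]

ACTIONS = ("start", "accept", "override", "line_up", "line_down",
           "line_jump", "back", "next", "finish")


@dataclass(frozen=True)
class Event:
    timestamp: float
    action: str
    index: int | None = None
    payload: dict = field(default_factory=dict)


class EventLog:
    """Append-only, serializable record of every session interaction."""

    def __init__(self) -> None:
        self._events: list[Event] = []

    def append(self, timestamp: float, action: str, index: int | None = None,
               **payload) -> None:
        if action not in ACTIONS:
            raise ValueError(f"unknown action {action!r}")
        self._events.append(Event(timestamp, action, index, payload))

    def __len__(self) -> int:
        return len(self._events)

    def __iter__(self):
        return iter(self._events)

    def __getitem__(self, i) -> Event:
        return self._events[i]

    def count(self, action: str) -> int:
        return sum(1 for e in self._events if e.action == action)

    def active_time(self, gap_cutoff: float = math.inf) -> float:
        """Total interaction time, skipping inter-event gaps above the
        cutoff (breaks); with an infinite cutoff this is last - first."""
        if len(self._events) < 2:
            return 0.0
        total = 0.0
        for a, b in itertools.pairwise(self._events):
            delta = b.timestamp - a.timestamp
            if delta <= gap_cutoff:
                total += delta
        return total

    def to_json_lines(self) -> str:
        return "\n".join(
            json.dumps({"timestamp": e.timestamp, "action": e.action,
                        "index": e.index, "payload": e.payload})
            for e in self._events
        )

    @classmethod
    def from_json_lines(cls, text: str) -> "EventLog":
        log = cls()
        for line in text.splitlines():
            if not line.strip():
                continue
            d = json.loads(line)
            log.append(d["timestamp"], d["action"], d["index"], **d["payload"])
        return log


@dataclass
class Decision:
    x: float
    y: float
    line: int
    action: str
    timestamp: float


class CorrectionSession:
    """Stateful assisted-correction walk over one trial.

    Parameters
    ----------
    trial : Trial
        Fixations plus AOIs of the stimulus.
    algo : str
        Name of the suggesting corrector (any of the 13 automatic ones).
    params : AlgoParams
        Corrector tunables.
    clock : callable
        Returns the current time in seconds; injectable for testing.
    recompute_on_intervention : bool
        Disable to ablate the human-machine collaboration (suggestions are
        then frozen at their initial values).
    """

    def __init__(self, trial: Trial, algo: str = "attach",
                 params: AlgoParams = DEFAULT_PARAMS,
                 clock: Callable[[], float] | None = None,
                 recompute_on_intervention: bool = True) -> None:
        if len(trial.seq) == 0:
            raise ValueError("trial has no fixations")
        if len(trial.aois) == 0:
            raise ValueError("trial has no AOIs")
        if algo not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {algo!r}")
        self.trial = trial
        self.algo = algo
        self.params = params
        self.clock = clock or time.monotonic
        self.recompute_on_intervention = recompute_on_intervention
        self.geom: LineGeometry = line_centers(trial.aois)
        self._needs_words, self._fn = ALGORITHMS[algo]
        self._words = (WordCenters.from_aois(trial.aois)
                       if self._needs_words else None)
        self.cursor = 0
        self.decided: dict[int, Decision] = {}
        self.log = EventLog()
        self.suggestions: LineAssignment = self._run_algo(trial.seq)
        self.log.append(self.clock(), "start",
                        algo=algo, n_fixations=len(trial.seq))

    # ------------------------------------------------------------- helpers

    def _run_algo(self, seq: FixationSequence) -> LineAssignment:
        return self._fn(seq, self.geom, self._words, self.params)

    def _current_seq(self) -> FixationSequence:
        """The sequence with every decided fixation at its decided coords."""
        fixations = list(self.trial.seq)
        for i, d in self.decided.items():
            fixations[i] = fixations[i].replace(x=d.x, y=d.y)
        return FixationSequence(fixations)

    def _recompute(self) -> None:
        if not self.recompute_on_intervention:
            return
        fresh = self._run_algo(self._current_seq())
        merged = [self.decided[i].line if i in self.decided else fresh[i]
                  for i in range(len(fresh))]
        self.suggestions = LineAssignment(merged)

    def _require_active(self) -> None:
        if self.complete:
            raise RuntimeError("session complete: all fixations decided")

    def _pin(self, x: float, y: float, action: str) -> None:
        line = self.geom.nearest_line(y)
        self.decided[self.cursor] = Decision(x, y, line, action, self.clock())
        self.cursor += 1

    # ------------------------------------------------------------ interface

    @property
    def n(self) -> int:
        return len(self.trial.seq)

    @property
    def complete(self) -> bool:
        return self.cursor >= self.n

    @property
    def progress(self) -> float:
        return self.cursor / self.n

    @property
    def current_suggestion(self) -> int:
        self._require_active()
        return self.suggestions[self.cursor]

    def accept(self) -> "CorrectionSession":
        """Take the current suggestion as-is (no recompute: the suggestion
        already came from the algorithm)."""
        self._require_active()
        f = self.trial.seq[self.cursor]
        line = self.suggestions[self.cursor]
        t = self.clock()
        self.log.append(t, "accept", self.cursor, line=line)
        self.decided[self.cursor] = Decision(
            f.x, self.geom.center_of(line), line, "accept", t)
        self.cursor += 1
        return self

    def override(self, new_x: float, new_y: float) -> "CorrectionSession":
        """Pin the current fixation at explicit coordinates (drag-and-drop
        analogue) and recompute the remaining suggestions."""
        self._require_active()
        payload = {"x": new_x, "y": new_y}
        sw, sh = self.trial.aois.screen_width, self.trial.aois.screen_height
        if (sw is not None and sh is not None
                and not (0 <= new_x < sw and 0 <= new_y < sh)):
            payload["offscreen"] = True  # allowed: user may intend the margin
        self.log.append(self.clock(), "override", self.cursor, **payload)
        self._pin(new_x, new_y, "override")
        self._recompute()
        return self

    def _line_step(self, action: str, delta: int) -> "CorrectionSession":
        self._require_active()
        f = self.trial.seq[self.cursor]
        current = self.geom.nearest_line(f.y)
        target = current + delta
        if not 1 <= target <= len(self.geom):
            self.log.append(self.clock(), action, self.cursor, noop=True)
            return self
        self.log.append(self.clock(), action, self.cursor, line=target)
        self._pin(f.x, self.geom.center_of(target), action)
        self._recompute()
        return self

    def line_up(self) -> "CorrectionSession":
        """Move the current fixation to the line above and advance ('a')."""
        return self._line_step("line_up", -1)

    def line_down(self) -> "CorrectionSession":
        """Move the current fixation to the line below and advance ('z')."""
        return self._line_step("line_down", +1)

    def line_jump(self, k: int) -> "CorrectionSession":
        """Move the current fixation straight to line k and advance (keys
        1-9; a no-op when the trial has fewer than k lines)."""
        self._require_active()
        if not 1 <= k <= 9:
            raise ValueError("line_jump takes k in 1..9")
        if k > len(self.geom):
            self.log.append(self.clock(), "line_jump", self.cursor,
                            line=k, noop=True)
            return self
        f = self.trial.seq[self.cursor]
        self.log.append(self.clock(), "line_jump", self.cursor, line=k)
        self._pin(f.x, self.geom.center_of(k), "line_jump")
        self._recompute()
        return self

    def back(self) -> int:
        """Step the progress view back one fixation (read-only); returns
        the index now in view."""
        idx = max(0, min(self.cursor, self.n - 1) - 1)
        self.log.append(self.clock(), "back", idx)
        return idx

    def redecide(self, index: int, new_x: float, new_y: float) -> "CorrectionSession":
        """Re-decide a past fixation; all later decisions reopen and their
        suggestions are recomputed once."""
        if index not in self.decided:
            raise ValueError(f"fixation {index} is not decided yet")
        for i in list(self.decided):
            if i >= index:
                del self.decided[i]
        self.cursor = index
        return self.override(new_x, new_y)

    def finalize(self) -> tuple[FixationSequence, EventLog]:
        """Corrected sequence and the event log; errors listing any
        undecided fixation indices."""
        undecided = [i for i in range(self.n) if i not in self.decided]
        if undecided:
            raise RuntimeError(f"undecided fixations: {undecided}")
        self.log.append(self.clock(), "finish")
        corrected = FixationSequence(
            self.trial.seq[i].replace(x=self.decided[i].x, y=self.decided[i].y)
            for i in range(self.n)
        )
        return corrected, self.log

    def final_assignment(self) -> LineAssignment:
        """Line of every decided fixation (requires a complete session)."""
        undecided = [i for i in range(self.n) if i not in self.decided]
        if undecided:
            raise RuntimeError(f"undecided fixations: {undecided}")
        return LineAssignment(self.decided[i].line for i in range(self.n))


def start_session(trial: Trial, algo: str = "attach",
                  params: AlgoParams = DEFAULT_PARAMS,
                  clock: Callable[[], float] | None = None,
                  recompute_on_intervention: bool = True) -> CorrectionSession:
    """Open an assisted-correction session over the trial."""
    return CorrectionSession(trial, algo, params, clock,
                             recompute_on_intervention)


def run_oracle(trial: Trial, algo: str, truth: LineAssignment,
               params: AlgoParams = DEFAULT_PARAMS,
               recompute: bool = True) -> tuple[CorrectionSession, int]:
    """Simulate an ideal user: accept a suggestion iff it matches the true
    line, otherwise drag the fixation to the true line's center.

    Returns the finished session and the number of overrides; used to
    measure how much recompute-on-intervention saves the corrector.
    """
    session = CorrectionSession(trial, algo, params,
                                clock=_counter_clock(),
                                recompute_on_intervention=recompute)
    overrides = 0
    while not session.complete:
        i = session.cursor
        if session.current_suggestion == truth[i]:
            session.accept()
        else:
            overrides += 1
            session.override(trial.seq[i].x,
                             session.geom.center_of(truth[i]))
    return session, overrides


def replay(trial: Trial, actions, algo: str = "attach",
           params: AlgoParams = DEFAULT_PARAMS,
           clock: Callable[[], float] | None = None) -> CorrectionSession:
    """Drive a session from a scripted action list (non-interactive mode).

    Each action is a dict: {"action": "accept"} | {"action": "override",
    "x": ..., "y": ...} | {"action": "line_up"|"line_down"} |
    {"action": "line_jump", "k": ...}.
    """
    session = CorrectionSession(trial, algo, params, clock or _counter_clock())
    for a in actions:
        kind = a["action"]
        if kind == "accept":
            session.accept()
        elif kind == "override":
            session.override(a["x"], a["y"])
        elif kind == "line_up":
            session.line_up()
        elif kind == "line_down":
            session.line_down()
        elif kind == "line_jump":
            session.line_jump(a["k"])
        else:
            raise ValueError(f"unknown scripted action {kind!r}")
    return session


def _counter_clock() -> Callable[[], float]:
    c = itertools.count()
    return lambda: float(next(c))
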