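"""Data-cleaning filters for fixation sequences.

Four standard cleaning steps for reading eye-tracking data: temporal
cut-offs (overlong / too-short fixations), statistical outlier removal on
duration, merging short fixations into a nearby larger neighbor, and
dropping fixations outside the stimulus.  Common temporal cut-offs are
800 ms (upper) and 80 ms (lower).

Boundary conventions: ``remove_long`` drops strictly above the threshold
(a fixation at exactly the threshold survives); ``remove_short`` drops
strictly below; ``remove_offscreen`` keeps 0 <= x < width and
0 <= y < height.  Outlier statistics are computed once over the input,
not iteratively.
"""

from __future__ import annotations

import math

import numpy as np

from .core import FixationSequence

__all__ = ["remove_long", "remove_short", "remove_outliers",
           "merge_short_nearby", "remove_offscreen"]


def remove_long(seq: FixationSequence, threshold_ms: float = 800.0) -> FixationSequence:
    """Drop fixations with duration strictly above the threshold."""
    return FixationSequence(f for f in seq if f.duration <= threshold_ms)


def remove_short(seq: FixationSequence, threshold_ms: float = 80.0) -> FixationSequence:
    """Drop fixations with duration strictly below the threshold."""
    return FixationSequence(f for f in seq if f.duration >= threshold_ms)


def remove_outliers(seq: FixationSequence, n_sd: float = 2.5) -> FixationSequence:
    """Drop fixations whose duration deviates from the mean by more than
    n_sd standard deviations (single pass; population sd)."""
    if len(seq) == 0:
        return seq
    durations = seq.durations
    mu = float(durations.mean())
    sigma = float(durations.std())
    if sigma == 0 or math.isinf(n_sd):
        return FixationSequence(seq)
    return FixationSequence(
        f for f in seq if abs(f.duration - mu) <= n_sd * sigma
    )


def merge_short_nearby(seq: FixationSequence, max_dur_ms: float = 80.0,
                       max_dist_px: float = 20.0) -> FixationSequence:
    """Merge each short fixation into a close temporal neighbor.

    A fixation with duration <= max_dur_ms whose nearest temporal neighbor
    (the previous surviving fixation, else the next) lies within
    max_dist_px Euclidean distance is absorbed by that neighbor: the
    neighbor keeps its position and the durations sum.  Single
    left-to-right pass; total duration of merged groups is conserved.
    """
    out: list = []
    fixations = list(seq)
    i = 0
    while i < len(fixations):
        f = fixations[i]
        if f.duration <= max_dur_ms:
            prev = out[-1] if out else None
            nxt = fixations[i + 1] if i + 1 < len(fixations) else None
            d_prev = math.hypot(f.x - prev.x, f.y - prev.y) if prev else math.inf
            d_next = math.hypot(f.x - nxt.x, f.y - nxt.y) if nxt else math.inf
            # prefer the previous neighbor on ties
            if d_prev <= d_next and d_prev <= max_dist_px:
                out[-1] = prev.replace(duration=prev.duration + f.duration)
                i += 1
                continue
            if d_next < d_prev and d_next <= max_dist_px:
                fixations[i + 1] = nxt.replace(duration=nxt.duration + f.duration)
                i += 1
                continue
        out.append(f)
        i += 1
    return FixationSequence(out)


def remove_offscreen(seq: FixationSequence, screen_width: float,
                     screen_height: float) -> FixationSequence:
    """Drop fixations outside the stimulus dimensions (half-open bounds)."""
    if screen_width <= 0 or screen_height <= 0:
        raise ValueError("screen dimensions must be positive")
    return FixationSequence(
        f for f in seq if 0 <= f.x < screen_width and 0 <= f.y < screen_height
    )
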