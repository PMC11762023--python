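"""Parametric distortion generators for benchmarking drift correction.

Each distortion is a pure function of a fixation sequence:

* ``noise``  — independent Gaussian displacement of every fixation;
* ``slope``  — vertical displacement growing linearly left-to-right,
  emulating a tilted calibration;
* ``shift``  — vertical displacement growing top-to-bottom, the topmost
  fixation staying put;
* ``offset`` — a uniform signed vertical shift of the whole trial.

``magnitude`` is in pixels.  For slope and shift it is the *maximum*
displacement, reached at the rightmost/bottommost fixation (normalization
is by the observed fixation span, not the screen).  Durations, ordering,
and sequence length are never altered; only noise touches x.
"""

from __future__ import annotations

import numpy as np

from .core import FixationSequence

__all__ = ["noise", "slope", "shift", "offset", "DISTORTIONS", "apply_distortion"]


def noise(seq: FixationSequence, magnitude: float, seed: int = 0) -> FixationSequence:
    """Displace each fixation independently; per-axis Gaussian sd = magnitude."""
    if magnitude < 0:
        raise ValueError("magnitude must be non-negative")
    if magnitude == 0:
        return FixationSequence(seq)
    rng = np.random.default_rng(seed)
    deltas = rng.normal(0.0, magnitude, size=(len(seq), 2))
    return FixationSequence(
        f.replace(x=f.x + dx, y=f.y + dy) for f, (dx, dy) in zip(seq, deltas)
    )


def slope(seq: FixationSequence, magnitude: float) -> FixationSequence:
    """Add magnitude * (x - min_x) / (max_x - min_x) to each y."""
    if len(seq) == 0:
        return seq
    xs = seq.xs
    span = xs.max() - xs.min()
    if span == 0:
        return FixationSequence(seq)
    lo = xs.min()
    return FixationSequence(
        f.replace(y=f.y + magnitude * (f.x - lo) / span) for f in seq
    )


def shift(seq: FixationSequence, magnitude: float) -> FixationSequence:
    """Add magnitude * (y - y_top) / (y_bottom - y_top); topmost unchanged."""
    if len(seq) == 0:
        return seq
    ys = seq.ys
    span = ys.max() - ys.min()
    if span == 0:
        return FixationSequence(seq)
    top = ys.min()
    return FixationSequence(
        f.replace(y=f.y + magnitude * (f.y - top) / span) for f in seq
    )


def offset(seq: FixationSequence, magnitude: float) -> FixationSequence:
    """Add the signed magnitude to every fixation's y."""
    return FixationSequence(f.replace(y=f.y + magnitude) for f in seq)


DISTORTIONS = {"noise": noise, "slope": slope, "shift": shift, "offset": offset}


def apply_distortion(kind: str, seq: FixationSequence, magnitude: float,
                     seed: int = 0) -> FixationSequence:
    """Dispatch by distortion name (noise takes the seed; others ignore it)."""
    if kind not in DISTORTIONS:
        raise ValueError(f"unknown distortion {kind!r}; choose from {sorted(DISTORTIONS)}")
    if kind == "noise":
        return noise(seq, magnitude, seed)
    return DISTORTIONS[kind](seq, magnitude)
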