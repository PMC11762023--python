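"""Synthetic reading-data generators and stimulus fixtures.

Four generators of increasing realism place fixations over word AOIs:

* ``gen_basic`` — one fixation at the optimal viewing position (OVP) of
  every word, with Gaussian dispersion.
* ``gen_with_skips`` — adds word skipping; the probability that a word of
  ``L`` letters is skipped decays exponentially with length,
  ``p(L) = k * exp(-lambda * L)``, the classic length/skipping relation.
* ``gen_within_line_regressions`` — inserts revisits to earlier words on
  the same line with a user-chosen probability.
* ``gen_between_line_regressions`` — inserts revisits to words on earlier
  lines.

Every generator also emits the generating line of each fixation, the
ground truth against which drift-correction accuracy is scored.  Fixation
durations follow the length effect: ``duration = base + L * per_letter``
milliseconds (defaults 100 + 40 L).  Word frequency is deliberately
ignored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .aoi_detect import StimulusImage
from .core import AOI, AOISet, Fixation, FixationSequence, LineAssignment

__all__ = [
    "DurationModel", "SkipModel", "GenParams",
    "synth_duration", "token_length_from_width", "skip_probability",
    "gen_basic", "gen_with_skips",
    "gen_within_line_regressions", "gen_between_line_regressions",
    "make_stimulus_fixture",
]

#: OVP as a fraction of word width from the left edge; readers' preferred
#: landing site sits slightly left of the word center.
OVP_FRACTION = 0.40


@dataclass(frozen=True)
class DurationModel:
    """Linear length-effect model of fixation duration (milliseconds)."""

    base_ms: float = 100.0
    per_letter_ms: float = 40.0

    def __post_init__(self) -> None:
        if self.base_ms <= 0 or self.per_letter_ms <= 0:
            raise ValueError("duration model parameters must be positive")


@dataclass(frozen=True)
class SkipModel:
    """Exponential word-skipping model: p(L) = k * exp(-lam * L).

    ``letter_width_px`` approximates letters-per-word from AOI width.
    Defaults approximate published length/skipping curves and are fully
    overridable.
    """

    k: float = 0.95
    lam: float = 0.35
    letter_width_px: float = 15.0

    def __post_init__(self) -> None:
        if self.k < 0 or self.lam < 0:
            raise ValueError("k and lam must be non-negative")
        if self.letter_width_px <= 0:
            raise ValueError("letter width must be positive")


@dataclass(frozen=True)
class GenParams:
    dispersion_sd: float = 5.0
    regression_prob: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dispersion_sd < 0:
            raise ValueError("dispersion must be non-negative")
        if not 0.0 <= self.regression_prob <= 1.0:
            raise ValueError("regression probability must lie in [0, 1]")


def synth_duration(token_length: int, model: DurationModel = DurationModel()) -> float:
    """Fixation duration in ms for a word of ``token_length`` letters."""
    if token_length < 0:
        raise ValueError("token length must be non-negative")
    return model.base_ms + token_length * model.per_letter_ms


def token_length_from_width(aoi: AOI, letter_width_px: float = 15.0) -> int:
    """Approximate letter count of a word AOI from its pixel width (min 1)."""
    if letter_width_px <= 0:
        raise ValueError("letter width must be positive")
    return max(1, round(aoi.width / letter_width_px))


def skip_probability(length: int, model: SkipModel = SkipModel()) -> float:
    """Probability that a word of ``length`` letters is skipped, in [0, 1]."""
    if length < 0:
        raise ValueError("length must be non-negative")
    return float(min(1.0, max(0.0, model.k * math.exp(-model.lam * length))))


def _word_fixation(aoi: AOI, rng: np.ndarray, dispersion_sd: float,
                   duration_model: DurationModel, letter_width_px: float) -> Fixation:
    ovp_x = aoi.x + OVP_FRACTION * aoi.width
    ovp_y = aoi.y + aoi.height / 2.0
    jx, jy = (rng.normal(0.0, dispersion_sd, size=2) if dispersion_sd > 0
              else (0.0, 0.0))
    length = token_length_from_width(aoi, letter_width_px)
    return Fixation(ovp_x + jx, ovp_y + jy,
                    synth_duration(length, duration_model))


def _require_words(aois: AOISet) -> list[AOI]:
    if len(aois) == 0:
        raise ValueError("empty AOISet")
    return list(aois)  # AOISet iterates in (line, part) reading order


def gen_basic(aois: AOISet, params: GenParams = GenParams(),
              duration_model: DurationModel = DurationModel(),
              letter_width_px: float = 15.0,
              ) -> tuple[FixationSequence, LineAssignment]:
    """One fixation per word in reading order at the OVP plus jitter."""
    words = _require_words(aois)
    rng = np.random.default_rng(params.seed)
    fixations, truth = [], []
    for w in words:
        fixations.append(_word_fixation(w, rng, params.dispersion_sd,
                                        duration_model, letter_width_px))
        truth.append(w.line)
    return FixationSequence(fixations), LineAssignment(truth)


def gen_with_skips(aois: AOISet, params: GenParams = GenParams(),
                   skip_model: SkipModel = SkipModel(),
                   duration_model: DurationModel = DurationModel(),
                   draw: Callable[[np.random.Generator], float] | None = None,
                   ) -> tuple[FixationSequence, LineAssignment]:
    """As ``gen_basic`` but each word is independently skipped with
    probability ``skip_probability(length)``.

    ``draw`` produces the per-word random number compared against the skip
    probability; the default is a uniform(0, 1) draw, which makes the
    comparison realize the stated probability exactly.
    """
    words = _require_words(aois)
    rng = np.random.default_rng(params.seed)
    # separate stream for skip decisions so that k=0 reproduces gen_basic
    rng_skip = np.random.default_rng([params.seed, 1])
    if draw is None:
        draw = lambda r: float(r.uniform())
    fixations, truth = [], []
    for w in words:
        length = token_length_from_width(w, skip_model.letter_width_px)
        if draw(rng_skip) < skip_probability(length, skip_model):
            continue
        fixations.append(_word_fixation(w, rng, params.dispersion_sd,
                                        duration_model, skip_model.letter_width_px))
        truth.append(w.line)
    return FixationSequence(fixations), LineAssignment(truth)


def _gen_with_regressions(aois: AOISet, params: GenParams,
                          duration_model: DurationModel,
                          letter_width_px: float,
                          between_lines: bool,
                          ) -> tuple[FixationSequence, LineAssignment]:
    words = _require_words(aois)
    rng = np.random.default_rng(params.seed)
    # regression decisions, target choice and revisit jitter come from a
    # separate stream so that regression_prob=0 reproduces gen_basic
    rng_reg = np.random.default_rng([params.seed, 2])
    fixations, truth = [], []
    for i, w in enumerate(words):
        fixations.append(_word_fixation(w, rng, params.dispersion_sd,
                                        duration_model, letter_width_px))
        truth.append(w.line)
        if between_lines:
            targets = [v for v in words[:i + 1] if v.line < w.line]
        else:
            # earlier words on the same line; none for the first word of a line
            targets = [v for v in words[:i] if v.line == w.line]
        if targets and rng_reg.uniform() < params.regression_prob:
            back = targets[int(rng_reg.integers(len(targets)))]
            fixations.append(_word_fixation(back, rng_reg, params.dispersion_sd,
                                            duration_model, letter_width_px))
            truth.append(back.line)
    return FixationSequence(fixations), LineAssignment(truth)


def gen_within_line_regressions(aois: AOISet, params: GenParams = GenParams(),
                                duration_model: DurationModel = DurationModel(),
                                letter_width_px: float = 15.0,
                                ) -> tuple[FixationSequence, LineAssignment]:
    """Progressive pass with probabilistic revisits to earlier same-line words."""
    return _gen_with_regressions(aois, params, duration_model,
                                 letter_width_px, between_lines=False)


def gen_between_line_regressions(aois: AOISet, params: GenParams = GenParams(),
                                 duration_model: DurationModel = DurationModel(),
                                 letter_width_px: float = 15.0,
                                 ) -> tuple[FixationSequence, LineAssignment]:
    """Progressive pass with probabilistic revisits to words on earlier lines."""
    return _gen_with_regressions(aois, params, duration_model,
                                 letter_width_px, between_lines=True)


def make_stimulus_fixture(n_lines: int = 3, words_per_line: int = 5,
                          word_width: int = 60, word_height: int = 20,
                          word_gap: int = 20, line_gap: int = 40,
                          margin: int = 30, seed: int = 0,
                          jitter_width: int = 0, image: str = "synthetic.png",
                          ) -> tuple[StimulusImage, AOISet]:
    """Render a synthetic page of black word boxes on white and return the
    exact word AOIs used, enabling offline end-to-end tests.

    ``jitter_width`` varies word widths uniformly in [-jitter_width, +jitter_width]
    so word lengths (and hence synthetic durations/skip rates) differ.
    """
    if n_lines < 1 or words_per_line < 1:
        raise ValueError("need at least one line and one word per line")
    rng = np.random.default_rng(seed)
    aois = []
    max_right = 0
    for line in range(1, n_lines + 1):
        y = margin + (line - 1) * (word_height + line_gap)
        x = margin
        for part in range(1, words_per_line + 1):
            w = word_width
            if jitter_width:
                w = max(8, word_width + int(rng.integers(-jitter_width, jitter_width + 1)))
            aois.append(AOI(kind="word", x=float(x), y=float(y),
                            width=float(w), height=float(word_height),
                            line=line, part=part, image=image))
            x += w + word_gap
        max_right = max(max_right, x - word_gap)
    width = max_right + margin
    height = margin + n_lines * word_height + (n_lines - 1) * line_gap + margin
    pixels = np.full((height, width), 255, dtype=np.uint8)
    for a in aois:
        pixels[int(a.y):int(a.y + a.height), int(a.x):int(a.x + a.width)] = 0
    return StimulusImage(pixels), AOISet(aois, screen_width=width, screen_height=height)
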