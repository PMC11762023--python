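"""Detect areas of interest in a text stimulus image by threshold scanning.

The stimulus is binarized into an ink mask, then scanned vertically: runs
of blank rows longer than ``height_threshold`` separate line bands.  Each
band is scanned horizontally: runs of blank columns longer than
``width_threshold`` separate AOIs.  Small width thresholds give letter
AOIs, larger ones word AOIs, and a very large one merges a whole band into
a single line AOI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import AOI, AOISet

__all__ = ["StimulusImage", "DetectParams", "binarize", "detect_aois",
           "load_stimulus", "DEFAULT_THRESHOLDS"]

#: default horizontal gap thresholds (px) per granularity level, and the
#: vertical gap threshold separating lines
DEFAULT_THRESHOLDS = {"letter": 2, "word": 8, "line_height": 10}


@dataclass(frozen=True)
class StimulusImage:
    """Grayscale stimulus bitmap (intensities 0-255, row-major)."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("stimulus must be a non-empty 2-D grid")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("intensities must lie in [0, 255]")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class DetectParams:
    """Thresholds steering the AOI scan.

    width_threshold / height_threshold: a blank run must *exceed* the
    threshold (strict) to split; binarize_cutoff: intensities below it
    count as ink; height_pad: extra vertical padding applied to every AOI
    (the "tailor AOI height" control); invert: treat light-on-dark stimuli.
    """

    width_threshold: int = DEFAULT_THRESHOLDS["word"]
    height_threshold: int = DEFAULT_THRESHOLDS["line_height"]
    binarize_cutoff: int = 128
    height_pad: int = 0
    invert: bool = False

    def __post_init__(self) -> None:
        if self.width_threshold < 1 or self.height_threshold < 1:
            raise ValueError("thresholds must be >= 1")


def load_stimulus(path) -> StimulusImage:
    """Read an image file (PNG/BMP/TIFF/...) as a grayscale stimulus."""
    from PIL import Image

    with Image.open(path) as im:
        gray = np.asarray(im.convert("L"), dtype=np.uint8)
    return StimulusImage(gray)


def binarize(img: StimulusImage, cutoff: int = 128, invert: bool = False) -> np.ndarray:
    """Boolean ink mask: True where intensity < cutoff (inverted: >= cutoff)."""
    mask = img.pixels < cutoff
    return ~mask if invert else mask


def _segments(flags: np.ndarray, gap_threshold: int) -> list[tuple[int, int]]:
    """Group True positions into [start, stop) runs, merging across gaps
    of blank positions whose length does not exceed gap_threshold."""
    idx = np.flatnonzero(flags)
    if idx.size == 0:
        return []
    segments = []
    start = prev = int(idx[0])
    for i in idx[1:]:
        i = int(i)
        if i - prev - 1 > gap_threshold:  # strict: gap must exceed threshold
            segments.append((start, prev + 1))
            start = i
        prev = i
    segments.append((start, prev + 1))
    return segments


def detect_aois(img: StimulusImage, params: DetectParams = DetectParams(),
                level: str = "word", image: str = "") -> AOISet:
    """Scan the stimulus and return the detected AOIs at the given level.

    Every AOI in a band shares the band's vertical extent; ``line`` runs
    top to bottom and ``part`` left to right, both 1-based.
    """
    if level not in ("letter", "word", "line"):
        raise ValueError(f"unknown level {level!r}")
    mask = binarize(img, params.binarize_cutoff, params.invert)
    if not mask.any():
        raise ValueError("no ink regions in stimulus")

    row_ink = mask.any(axis=1)
    bands = _segments(row_ink, params.height_threshold)

    aois = []
    for line_no, (top, bottom) in enumerate(bands, start=1):
        band = mask[top:bottom]
        col_ink = band.any(axis=0)
        if level == "line":
            cols = np.flatnonzero(col_ink)
            spans = [(int(cols[0]), int(cols[-1]) + 1)]
        else:
            spans = _segments(col_ink, params.width_threshold)
        y = top - params.height_pad
        h = (bottom - top) + 2 * params.height_pad
        for part_no, (left, right) in enumerate(spans, start=1):
            aois.append(AOI(kind=level, x=float(left), y=float(y),
                            width=float(right - left), height=float(h),
                            line=line_no, part=part_no, image=image))
    return AOISet(aois, screen_width=img.width, screen_height=img.height)
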