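"""Automatic vertical-drift correction algorithms.

Thirteen correctors, each mapping a fixation sequence plus text geometry
to a line assignment (one 1-based line index per fixation):

========== =====================================================
attach      nearest line center per fixation (positional)
chain       link nearby fixations into chains; assign each chain
            to the line nearest its mean y
cluster     k-means on y with k = number of lines
merge       agglomerate progressive subsequences until one per line
regress     fit a bounded (slope, offset, sd) Gaussian mixture of
            candidate text lines to the fixation cloud
stretch     find the y scale/offset minimizing distance to line centers
segment     split at the m-1 largest return sweeps; map top to bottom
slice       cluster progressive runs by height; map top to bottom
warp        dynamic time warping of the fixation sequence onto the
            reading-order word-center sequence
warp+attach / warp+chain / warp+regress / warp+stretch
            hybrids: warp the progressive subsequence, reinsert
            regressions, finish with the base algorithm
========== =====================================================

The sequential algorithms (segment, slice, warp) exploit chronology and
survive distortions as large as a full line spacing; the positional ones
cannot.  All are pure functions given their parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.optimize import minimize
from scipy.stats import norm

from .core import (AOISet, FixationSequence, LineAssignment, LineGeometry,
                   apply_assignment, line_centers)

__all__ = [
    "WordCenters", "AlgoParams", "ALGORITHMS",
    "attach", "chain", "cluster", "merge", "regress", "stretch",
    "segment", "slice_", "warp", "split_regressions", "hybrid",
    "correct", "word_centers",
]


class WordCenters:
    """Word-AOI midpoints in reading order (line-major, then part)."""

    def __init__(self, centers, lines) -> None:
        self.centers = np.asarray(centers, dtype=float).reshape(-1, 2)
        self.lines = [int(v) for v in lines]
        if len(self.centers) != len(self.lines):
            raise ValueError("centers and lines must have equal length")
        if len(self.centers) == 0:
            raise ValueError("no word centers")

    @classmethod
    def from_aois(cls, aois: AOISet) -> "WordCenters":
        return cls([a.center for a in aois], [a.line for a in aois])

    def __len__(self) -> int:
        return len(self.lines)


def word_centers(aois: AOISet) -> WordCenters:
    return WordCenters.from_aois(aois)


@dataclass(frozen=True)
class AlgoParams:
    """Tunables for the correctors, with reproducible defaults.

    chain_x_link / chain_y_link: max |dx| / |dy| (px) between consecutive
    fixations in one chain.  cluster_seed / cluster_restarts: k-means
    initialization.  regress_*: search bounds for the line-fit slope,
    vertical offset (px), and Gaussian sd (px).  stretch_*: bounds for the
    y scaling factor and offset (px).
    """

    chain_x_link: float = 192.0
    chain_y_link: float = 32.0
    cluster_seed: int = 0
    cluster_restarts: int = 10
    regress_slope_bounds: tuple[float, float] = (-0.1, 0.1)
    regress_offset_bounds: tuple[float, float] = (-50.0, 50.0)
    regress_sd_bounds: tuple[float, float] = (1.0, 20.0)
    stretch_scale_bounds: tuple[float, float] = (0.9, 1.1)
    stretch_offset_bounds: tuple[float, float] = (-50.0, 50.0)


DEFAULT_PARAMS = AlgoParams()


def _check_input(seq: FixationSequence, geom: LineGeometry) -> None:
    if len(seq) == 0:
        raise ValueError("empty fixation sequence")
    if len(geom) == 0:
        raise ValueError("no text lines")


# ---------------------------------------------------------------- positional

def attach(seq: FixationSequence, geom: LineGeometry) -> LineAssignment:
    """Assign every fixation to its closest line (ties to the upper line)."""
    _check_input(seq, geom)
    return LineAssignment(geom.nearest_line(f.y) for f in seq)


def _chains(seq: FixationSequence, x_link: float, y_link: float) -> list[list[int]]:
    """Indices grouped into chains; a link requires |dx| <= x_link and
    |dy| <= y_link between consecutive fixations."""
    groups: list[list[int]] = [[0]]
    for i in range(1, len(seq)):
        a, b = seq[i - 1], seq[i]
        if abs(b.x - a.x) <= x_link and abs(b.y - a.y) <= y_link:
            groups[-1].append(i)
        else:
            groups.append([i])
    return groups


def chain(seq: FixationSequence, geom: LineGeometry,
          params: AlgoParams = DEFAULT_PARAMS) -> LineAssignment:
    """Chain consecutive nearby fixations; each chain takes the line
    nearest the mean y of its members."""
    _check_input(seq, geom)
    out = [0] * len(seq)
    for group in _chains(seq, params.chain_x_link, params.chain_y_link):
        mean_y = float(np.mean([seq[i].y for i in group]))
        line = geom.nearest_line(mean_y)
        for i in group:
            out[i] = line
    return LineAssignment(out, n_lines=len(geom))


def cluster(seq: FixationSequence, geom: LineGeometry,
            params: AlgoParams = DEFAULT_PARAMS) -> LineAssignment:
    """k-means on fixation y values, k = number of lines; clusters map to
    lines in ascending mean-y order."""
    from sklearn.cluster import KMeans

    _check_input(seq, geom)
    m = len(geom)
    if m == 1:
        return LineAssignment([1] * len(seq))
    ys = seq.ys.reshape(-1, 1)
    k = min(m, len(np.unique(ys)))
    if k == 1:
        line = geom.nearest_line(float(ys[0, 0]))
        return LineAssignment([line] * len(seq))
    km = KMeans(n_clusters=k, n_init=params.cluster_restarts,
                random_state=params.cluster_seed).fit(ys)
    order = np.argsort(km.cluster_centers_.ravel())
    # cluster label -> line index; with k < m, map by nearest center
    label_to_line = {}
    for rank, label in enumerate(order):
        center_y = float(km.cluster_centers_[label, 0])
        label_to_line[int(label)] = (rank + 1 if k == m
                                     else geom.nearest_line(center_y))
    return LineAssignment(label_to_line[int(l)] for l in km.labels_)


def merge(seq: FixationSequence, geom: LineGeometry,
          params: AlgoParams = DEFAULT_PARAMS) -> LineAssignment:
    """Build progressive subsequences, then agglomerate the two sequences
    with the closest mean y until one sequence per line remains; map the
    survivors to lines in ascending mean-y order."""
    _check_input(seq, geom)
    m = len(geom)
    if m == 1:
        return LineAssignment([1] * len(seq))
    # progressive runs: break on a return sweep (large leftward jump) or
    # a vertical jump beyond the chain linking threshold
    groups = []
    current = [0]
    for i in range(1, len(seq)):
        a, b = seq[i - 1], seq[i]
        if (b.x - a.x) < -params.chain_x_link or abs(b.y - a.y) > params.chain_y_link:
            groups.append(current)
            current = [i]
        else:
            current.append(i)
    groups.append(current)

    def mean_y(g):
        return float(np.mean([seq[i].y for i in g]))

    while len(groups) > m:
        ys = [mean_y(g) for g in groups]
        order = np.argsort(ys)
        gaps = [(ys[order[j + 1]] - ys[order[j]], j) for j in range(len(order) - 1)]
        _, j = min(gaps)
        a, b = order[j], order[j + 1]
        merged = sorted(groups[a] + groups[b])
        groups = [g for idx, g in enumerate(groups) if idx not in (a, b)]
        groups.append(merged)

    out = [0] * len(seq)
    ranked = sorted(groups, key=mean_y)
    for rank, g in enumerate(ranked):
        line = rank + 1 if len(ranked) == m else geom.nearest_line(mean_y(g))
        for i in g:
            out[i] = line
    return LineAssignment(out, n_lines=m)


def regress(seq: FixationSequence, geom: LineGeometry,
            params: AlgoParams = DEFAULT_PARAMS) -> LineAssignment:
    """Fit candidate regression lines through the fixation cloud.

    Every text line contributes a candidate line
    ``y = center + slope * x + offset``; a shared slope, vertical offset,
    and Gaussian sd are optimized to maximize the total likelihood of each
    fixation under its best candidate, then fixations take the line of
    their most likely candidate.
    """
    _check_input(seq, geom)
    if len(geom) == 1:
        return LineAssignment([1] * len(seq))
    xs = seq.xs.reshape(-1, 1)
    ys = seq.ys.reshape(-1, 1)
    centers = np.asarray(geom.centers).reshape(1, -1)
    kb, ob, sb = (params.regress_slope_bounds, params.regress_offset_bounds,
                  params.regress_sd_bounds)

    def unpack(p):
        k = kb[0] + (kb[1] - kb[0]) * norm.cdf(p[0])
        o = ob[0] + (ob[1] - ob[0]) * norm.cdf(p[1])
        s = sb[0] + (sb[1] - sb[0]) * norm.cdf(p[2])
        return k, o, s

    def negloglik(p):
        k, o, s = unpack(p)
        predicted = k * xs + centers + o  # n x m
        loglik = norm.logpdf(ys, predicted, s)
        return -float(loglik.max(axis=1).sum())

    best = minimize(negloglik, np.zeros(3), method="powell")
    k, o, s = unpack(best.x)
    predicted = k * xs + centers + o
    lines = np.argmax(norm.logpdf(ys, predicted, s), axis=1) + 1
    return LineAssignment(lines, n_lines=len(geom))


def stretch(seq: FixationSequence, geom: LineGeometry,
            params: AlgoParams = DEFAULT_PARAMS) -> LineAssignment:
    """Find the vertical scaling factor and offset minimizing the total
    distance between transformed fixations and their nearest line centers;
    assign by nearest center of the transformed y."""
    _check_input(seq, geom)
    if len(geom) == 1:
        return LineAssignment([1] * len(seq))
    ys = seq.ys.reshape(-1, 1)
    centers = np.asarray(geom.centers).reshape(1, -1)
    sb, ob = params.stretch_scale_bounds, params.stretch_offset_bounds

    def unpack(p):
        s = sb[0] + (sb[1] - sb[0]) * norm.cdf(p[0])
        o = ob[0] + (ob[1] - ob[0]) * norm.cdf(p[1])
        return s, o

    def cost(p):
        s, o = unpack(p)
        return float(np.abs(ys * s + o - centers).min(axis=1).sum())

    best = minimize(cost, np.zeros(2), method="powell")
    s, o = unpack(best.x)
    lines = np.argmin(np.abs(ys * s + o - centers), axis=1) + 1
    return LineAssignment(lines, n_lines=len(geom))


# ---------------------------------------------------------------- sequential

def segment(seq: FixationSequence, geom: LineGeometry) -> LineAssignment:
    """Split the sequence at the m-1 largest leftward x jumps (return
    sweeps) and map the resulting segments to lines 1..m top to bottom."""
    _check_input(seq, geom)
    m = len(geom)
    if m == 1 or len(seq) == 1:
        return LineAssignment([min(m, 1)] * len(seq)) if m == 1 else \
            LineAssignment([geom.nearest_line(seq[0].y)])
    dx = np.diff(seq.xs)
    n_breaks = min(m - 1, len(dx))
    break_after = np.sort(np.argsort(dx)[:n_breaks])  # most negative jumps
    out, line = [], 1
    breaks = set(int(b) for b in break_after)
    for i in range(len(seq)):
        out.append(min(line, m))
        if i in breaks:
            line += 1
    return LineAssignment(out, n_lines=m)


def slice_(seq: FixationSequence, geom: LineGeometry,
           params: AlgoParams = DEFAULT_PARAMS) -> LineAssignment:
    """Find runs of fixations likely on one line, fuse runs at similar
    heights, and map the fused groups to lines top to bottom."""
    _check_input(seq, geom)
    m = len(geom)
    if m == 1:
        return LineAssignment([1] * len(seq))
    # runs: break on return sweeps or large vertical jumps
    runs = []
    current = [0]
    for i in range(1, len(seq)):
        a, b = seq[i - 1], seq[i]
        if (b.x - a.x) < -params.chain_x_link or abs(b.y - a.y) > params.chain_y_link:
            runs.append(current)
            current = [i]
        else:
            current.append(i)
    runs.append(current)

    mean_ys = [float(np.mean([seq[i].y for i in r])) for r in runs]
    # fuse the closest pair of run heights until one group per line
    groups = [[j] for j in range(len(runs))]
    def group_y(g):
        total = sum(len(runs[j]) for j in g)
        return sum(mean_ys[j] * len(runs[j]) for j in g) / total
    while len(groups) > m:
        ys = [group_y(g) for g in groups]
        order = np.argsort(ys)
        gaps = [(ys[order[j + 1]] - ys[order[j]], j) for j in range(len(order) - 1)]
        _, j = min(gaps)
        a, b = order[j], order[j + 1]
        groups = ([g for idx, g in enumerate(groups) if idx not in (a, b)]
                  + [groups[a] + groups[b]])
    out = [0] * len(seq)
    ranked = sorted(groups, key=group_y)
    for rank, g in enumerate(ranked):
        line = rank + 1 if len(ranked) == m else geom.nearest_line(group_y(g))
        for j in g:
            for i in runs[j]:
                out[i] = line
    return LineAssignment(out, n_lines=m)


def _dtw_path(cost: np.ndarray) -> list[tuple[int, int]]:
    """Boundary-matched monotone DTW path minimizing total cost.

    Tie-breaking during backtrack prefers the diagonal, then the step that
    keeps the word index smaller, yielding the path through earlier words.
    """
    n, w = cost.shape
    acc = np.full((n, w), np.inf)
    acc[0, 0] = cost[0, 0]
    for i in range(n):
        for j in range(w):
            if i == 0 and j == 0:
                continue
            best = np.inf
            if i > 0 and j > 0:
                best = acc[i - 1, j - 1]
            if i > 0:
                best = min(best, acc[i - 1, j])
            if j > 0:
                best = min(best, acc[i, j - 1])
            acc[i, j] = cost[i, j] + best
    path = [(n - 1, w - 1)]
    i, j = n - 1, w - 1
    while (i, j) != (0, 0):
        candidates = []
        if i > 0 and j > 0:
            candidates.append((acc[i - 1, j - 1], 0, (i - 1, j - 1)))
        if i > 0:
            candidates.append((acc[i - 1, j], 1, (i - 1, j)))
        if j > 0:
            candidates.append((acc[i, j - 1], 2, (i, j - 1)))
        _, _, (i, j) = min(candidates)
        path.append((i, j))
    path.reverse()
    return path


def warp(seq: FixationSequence, words: WordCenters) -> LineAssignment:
    """Dynamic-time-warp the fixation sequence onto the reading-order word
    centers; each fixation takes the line of its matched word(s) — the
    modal line over matches, resolved toward the earlier word on ties."""
    if len(seq) == 0:
        raise ValueError("empty fixation sequence")
    pts = np.column_stack([seq.xs, seq.ys])
    cost = np.linalg.norm(pts[:, None, :] - words.centers[None, :, :], axis=2)
    path = _dtw_path(cost)
    matches: list[list[int]] = [[] for _ in range(len(seq))]
    for i, j in path:
        matches[i].append(j)
    out = []
    for js in matches:
        counts: dict[int, int] = {}
        for j in js:  # first occurrence order = earlier word first
            counts[words.lines[j]] = counts.get(words.lines[j], 0) + 1
        best = max(counts.values())
        for j in js:
            if counts[words.lines[j]] == best:
                out.append(words.lines[j])
                break
    return LineAssignment(out)


# ------------------------------------------------------------------ hybrids

def split_regressions(seq: FixationSequence, geom: LineGeometry,
                      word_width: float | None = None,
                      ) -> tuple[list[int], list[int]]:
    """Partition fixation indices into (progressive, regressive).

    A fixation is regressive when its nearest line (by current y) lies
    above the furthest line reached so far, or when it jumps leftward by
    more than one word width while staying on that furthest line.
    """
    _check_input(seq, geom)
    if word_width is None:
        word_width = 60.0
    progressive, regressive = [], []
    max_line = 0
    prev_x = None
    for i, f in enumerate(seq):
        line = geom.nearest_line(f.y)
        if line < max_line:
            regressive.append(i)
            continue
        if (line == max_line and prev_x is not None
                and f.x < prev_x - word_width):
            regressive.append(i)
            continue
        progressive.append(i)
        max_line = max(max_line, line)
        prev_x = f.x
    return progressive, regressive


def hybrid(seq: FixationSequence, geom: LineGeometry, words: WordCenters,
           base: str, params: AlgoParams = DEFAULT_PARAMS) -> LineAssignment:
    """Warp the progressive subsequence, snap it, reinsert the regressive
    fixations at their original coordinates, then finish with ``base``
    (attach, chain, regress, or stretch) on the recombined sequence."""
    _check_input(seq, geom)
    bases: dict[str, Callable] = {
        "attach": lambda s: attach(s, geom),
        "chain": lambda s: chain(s, geom, params),
        "regress": lambda s: regress(s, geom, params),
        "stretch": lambda s: stretch(s, geom, params),
    }
    if base not in bases:
        raise ValueError(f"unknown hybrid base {base!r}; choose from {sorted(bases)}")
    prog_idx, _ = split_regressions(seq, geom)
    fixations = list(seq)
    if prog_idx:
        prog_seq = FixationSequence(fixations[i] for i in prog_idx)
        prog_asg = warp(prog_seq, words)
        snapped = apply_assignment(prog_seq, prog_asg, geom)
        for pos, i in enumerate(prog_idx):
            fixations[i] = snapped[pos]
    return bases[base](FixationSequence(fixations))


# ----------------------------------------------------------------- registry

def _make_hybrid(base: str):
    def run(seq, geom, words, params=DEFAULT_PARAMS):
        return hybrid(seq, geom, words, base, params)
    run.__name__ = f"warp_{base}"
    return run


#: algorithm name -> (needs_words, callable); the public catalogue of the
#: thirteen correctors
ALGORITHMS: dict[str, tuple[bool, Callable]] = {
    "attach": (False, lambda seq, geom, words=None, params=DEFAULT_PARAMS: attach(seq, geom)),
    "chain": (False, lambda seq, geom, words=None, params=DEFAULT_PARAMS: chain(seq, geom, params)),
    "cluster": (False, lambda seq, geom, words=None, params=DEFAULT_PARAMS: cluster(seq, geom, params)),
    "merge": (False, lambda seq, geom, words=None, params=DEFAULT_PARAMS: merge(seq, geom, params)),
    "regress": (False, lambda seq, geom, words=None, params=DEFAULT_PARAMS: regress(seq, geom, params)),
    "stretch": (False, lambda seq, geom, words=None, params=DEFAULT_PARAMS: stretch(seq, geom, params)),
    "segment": (False, lambda seq, geom, words=None, params=DEFAULT_PARAMS: segment(seq, geom)),
    "slice": (False, lambda seq, geom, words=None, params=DEFAULT_PARAMS: slice_(seq, geom, params)),
    "warp": (True, lambda seq, geom, words, params=DEFAULT_PARAMS: warp(seq, words)),
    "warp+attach": (True, lambda seq, geom, words, params=DEFAULT_PARAMS: hybrid(seq, geom, words, "attach", params)),
    "warp+chain": (True, lambda seq, geom, words, params=DEFAULT_PARAMS: hybrid(seq, geom, words, "chain", params)),
    "warp+regress": (True, lambda seq, geom, words, params=DEFAULT_PARAMS: hybrid(seq, geom, words, "regress", params)),
    "warp+stretch": (True, lambda seq, geom, words, params=DEFAULT_PARAMS: hybrid(seq, geom, words, "stretch", params)),
}


def correct(seq: FixationSequence, aois: AOISet, algo: str = "attach",
            params: AlgoParams = DEFAULT_PARAMS) -> LineAssignment:
    """Run a named corrector against the geometry derived from ``aois``."""
    if algo not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algo!r}; choose from {sorted(ALGORITHMS)}")
    geom = line_centers(aois)
    needs_words, fn = ALGORITHMS[algo]
    words = WordCenters.from_aois(aois) if needs_words else None
    return fn(seq, geom, words, params)
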