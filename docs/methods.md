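# Methods

This note documents the models implemented in `driftkit`, the defaults
and the reasoning behind them, what the synthetic-data generators do and
do not emulate, and the numerical choices made where the published
algorithm descriptions leave latitude.

## Coordinates and the correction contract

All positions are in pixels with the origin at the stimulus top-left and
y increasing downward.  Every corrector returns a *line assignment* — one
1-based line index per fixation — and correction itself is vertical
snapping only: the corrected fixation keeps its x and duration and takes
the assigned line's center y.  Drift in reading data is predominantly
vertical, and reading analyses key on the line/word a fixation belongs
to, not on its exact vertical position; horizontal repositioning is out
of scope.

Line centers are derived from the word AOIs as the mean vertical midpoint
`y + height/2` per line.  Nearest-line queries resolve exact midway ties
to the smaller (upper) line index, a fixed rule so every algorithm is a
pure function of its inputs.

AOI containment is half-open (`x ≤ px < x+width`, `y ≤ py < y+height`),
so a point on the shared edge of two abutting AOIs belongs to exactly
one of them.

## Accuracy

Benchmark accuracy is the fraction of fixations assigned to the line
they were generated on (for synthetic data the generator emits this
ground truth).  It is symmetric and invariant under relabeling applied
to both assignments.

## The thirteen correctors

The algorithms follow their published one-paragraph descriptions; where
those descriptions omit internals, the realization chosen here is stated
below and validated by fixture-recovery tests.  All tunables live in
`AlgoParams` with fixed defaults, because reproducibility requires the
tunables to be explicit even when a GUI would hide them.

* **attach** — nearest line center per fixation.  No parameters.
* **chain** — consecutive fixations within `x_link = 192` px and
  `y_link = 32` px form a chain; each chain takes the line nearest its
  mean y.  The defaults are roughly a long saccade's width and half a
  typical line spacing.
* **cluster** — k-means on the y values with k = number of lines
  (scikit-learn, 10 restarts, fixed seed 0); clusters map to lines in
  ascending mean-y order.  If fewer distinct y values than lines exist,
  surplus clusters map to their nearest center.
* **merge** — progressive subsequences (broken at return sweeps larger
  than `x_link` or vertical jumps larger than `y_link`) are agglomerated
  by repeatedly fusing the two sequences with the closest mean y until
  one sequence per line remains, then mapped to lines in ascending
  mean-y order.
* **regress** — every text line contributes a candidate regression line
  `y = c_k + slope·x + offset`; a shared slope ∈ [−0.1, 0.1], offset ∈
  [−50, 50] px and Gaussian sd ∈ (1, 20] px are fitted by Powell search
  (bounds imposed through a normal-CDF reparameterization) maximizing
  each fixation's best-candidate log-likelihood; fixations take their
  most likely candidate's line.
* **stretch** — Powell search for a vertical scale ∈ [0.9, 1.1] and
  offset ∈ [−50, 50] px minimizing the summed distance between
  transformed fixations and their nearest line centers; assignment by
  nearest center of the transformed y.  The fitted transform is *not*
  propagated to the output coordinates — the contract is line
  assignment, and snapping already determines the output.
* **segment** — the sequence is split at the m−1 most negative x jumps
  (return sweeps) and segments map to lines 1..m top to bottom.
* **slice** — progressive runs (as in merge) are fused by closest mean
  height until m groups remain, which map to lines top to bottom.
* **warp** — dynamic time warping between the fixation sequence and the
  reading-order word-center sequence with Euclidean cost,
  boundary-matched and monotone.  Each fixation takes the modal line of
  its matched words, ties resolved toward the earlier word; backtracking
  prefers the diagonal step, making the path deterministic.  A
  brute-force enumeration of all monotone paths on small instances is
  kept as the test oracle.
* **warp+{attach,chain,regress,stretch}** — regressive fixations are
  split off, warp corrects and snaps the progressive remainder, the
  regressive fixations are reinserted at their original coordinates, and
  the base algorithm corrects the recombined sequence.

**Regression marking.** The published hybrid description says only that
regressions are split off.  Here fixation *i* is regressive when its
nearest line (by current y) lies above the furthest line reached so far,
or when it jumps leftward by more than one word width (default 60 px)
while staying on that furthest line.  This captures exactly the
between-line and within-line regressions the synthetic generators
produce, which makes the hybrids testable against generator ground
truth.  Under distortions approaching a full line spacing the
nearest-line estimate itself degrades and return sweeps can be
misclassified; the hybrids inherit this limitation (their bases are
positional), while plain warp does not.

## Assisted correction

The session walks fixations chronologically.  `accept` pins the current
fixation at the suggested line's center and advances; it does **not**
trigger recomputation, because the suggestion already came from the
algorithm — accepting adds no information.  `override` (drag-and-drop
analogue), `line_up`/`line_down` (the 'a'/'z' shortcuts, realized as an
override at the adjacent line's center), and `line_jump` (the 1–9 keys;
a logged no-op beyond the last line, hence full coverage only below ten
lines) all pin the fixation and trigger recomputation.

Recomputation reruns the full algorithm on a copy of the sequence in
which every decided fixation carries its decided coordinates, then keeps
the fresh output only for undecided fixations — decided fixations are
immutable.  A full rerun is the simplest faithful realization of
"the algorithm updates its internal state", and for the sequence-aware
algorithms it demonstrably propagates the correction: in the worked
3-line example (uniform +31 px offset, chain suggestions one line too
low), one drag per misled chain corrects the whole chain, cutting an
ideal user's interventions from 10 to 2.  `attach` is the documented
exception — it looks at one fixation at a time, so overrides cannot
improve its remaining suggestions.

Re-deciding a past fixation reopens all later decisions with a single
recomputation.  Plain back-navigation is read-only.

Every interaction is appended to a timestamped event log (injectable
clock, so tests are deterministic); active correction time is the sum of
inter-event gaps not exceeding an inactivity cutoff.

## Synthetic data

The generators emulate first-pass reading over word AOIs:

* placement at the optimal viewing position, realized as
  `x = aoi.x + 0.40·width` — slightly left of center, the standard OVP
  finding; the vertical placement is the AOI's vertical center;
* Gaussian dispersion around the placement point (default sd 5 px);
* durations `100 + 40·L` ms for an `L`-letter word (the length effect),
  with `L` approximated as `round(width / letter_width)` and
  `letter_width = 15` px by default;
* skipping with probability `k·e^{−λL}`, clamped to [0, 1].  Defaults
  `k = 0.95`, `λ = 0.35` approximate published length/skipping curves;
  no authoritative numeric defaults exist, so these are documented
  approximations and fully overridable.  The skip decision draws a
  uniform(0, 1) number per word — a Gaussian draw cannot realize the
  stated probability — and the draw distribution is a pluggable
  parameter for users who want to experiment;
* within-line regressions: after each word with a same-line predecessor,
  with the chosen probability a revisit to a uniformly chosen earlier
  same-line word is inserted; between-line regressions do the same with
  targets on strictly earlier lines.

Decision and revisit randomness comes from a stream separate from the
placement jitter, so setting a probability to zero reproduces the basic
generator draw-for-draw under the same seed.

Word frequency, parafoveal preview, saccade dynamics, blinks, and
binocular disparity are *not* modeled.  Passing tests on this synthetic
data therefore show that the correctors recover a known geometric ground
truth under controlled distortion — not that they handle every
idiosyncrasy of real recordings.

The stimulus fixture renders black word boxes on white with configurable
box sizes, gaps, and per-word width jitter, returning the exact AOIs
used; this closes the loop for AOI-detection tests (detection must
recover the generating boxes box-for-box).

## Distortions

`noise` displaces both axes with independent per-axis Gaussian sd equal
to the magnitude.  `slope` and `shift` add a vertical displacement
growing linearly with x (respectively y), normalized by the *observed
fixation span* so the magnitude is the maximum displacement — anchoring
at the span rather than the screen makes the parameter interpretable and
testable.  `offset` adds a signed constant to every y.  All preserve
length, order, and durations.

## AOI detection

The stimulus is converted to grayscale and binarized (ink = intensity
below 128 by default; an `invert` flag handles light-on-dark).  Rows
containing ink are grouped into line bands, split where a blank-row run
*strictly exceeds* the height threshold (default 10 px); columns within
a band are grouped the same way with the width threshold (letter default
2 px, word default 8 px).  Strict comparison was chosen because the gap
must "exceed" the threshold to split; the tests pin this choice.  All
AOIs in a band share the band's vertical extent, optionally padded by a
height-tweak parameter (default 0).

## Reports

Gaze duration ends at the first fixation on *any* other AOI or off all
AOIs; momentary off-AOI samples are not bridged.  The one-line standard
definition admits variants; this one is stated and tested (TT ≥ GD ≥ FFD
always holds, and summed TT plus off-AOI duration equals the sequence's
total duration).  Off-AOI fixations appear in the hit-test report with
empty AOI fields but are excluded from AOI metrics.

## Filters

Outlier statistics (mean, population sd of duration) are computed once
before any removal, not iteratively — the simplest defensible reading,
and idempotence of the selection filters is tested.  The merge filter
scans left to right once, prefers the previous neighbor on distance
ties, sums durations into the absorbing neighbor, and conserves total
duration.  Boundary rules: the long filter removes strictly above, the
short filter strictly below, off-screen keeps `0 ≤ x < width`,
`0 ≤ y < height`.

## Formats

The JSON dialect requires only a top-level `fixations` list of
`[x, y, duration]` triples; every other top-level key is preserved
verbatim on write, so enriched files round-trip without schema changes.
The ASCII reader segments trials on MSG lines matching a configurable
regex (default `TRIALID`), parses EFIX/ESACC/EBLINK events, selects the
first eye seen in binocular files (overridable), and skips malformed
lines with a count rather than aborting.  EDF binary and vendor-native
formats are out of scope.

## Problem sizes and determinism

The test suite and the acceptance script run on 3-line × 5-word fixture
pages (15 fixations), small random instances for the oracle comparisons
(≤ 8×8 DTW alignments), and a 10,000-word Monte-Carlo for the skip-rate
check — sizes at which every expected value is exactly computable or
tightly bounded (3 binomial standard errors for the Monte-Carlo).  Every
random draw flows through an explicit seed; algorithms with internal
randomness (k-means) carry a fixed default seed, making all thirteen
correctors pure functions of their inputs and parameters.

## Known limitations

* `merge` and `slice` are simplified agglomerative realizations of their
  published one-line descriptions; they satisfy the documented contract
  and fixture-recovery tests but are not line-for-line ports of the
  original implementations.
* Regression splitting degrades when drift approaches a full line
  spacing (see above).
* No GUI; the assisted session is exposed as an API and a scripted
  replay mode, which is what makes its guarantees testable.
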