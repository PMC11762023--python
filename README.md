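# driftkit

Correction, synthesis, and analysis of eye-tracking fixation data from
reading experiments.

In reading studies, calibration drift moves recorded fixations vertically —
often onto the wrong line of text — which corrupts word-level measures.
`driftkit` is a headless toolkit for dealing with this: it implements
thirteen automatic vertical-drift correction algorithms, an **assisted
(semi-automated) correction session** in which an algorithm proposes a line
for each fixation and human interventions feed back into the remaining
suggestions, plus everything needed to benchmark them offline: synthetic
fixation generators with realistic skipping and regressions, parametric
distortion generators, AOI detection from stimulus images, cleaning
filters, reading-measure reports (FFD/GD/TT), and converters between
EyeLink ASCII, CSV, and a minimal JSON dialect.

## The core model

A trial is a chronological fixation sequence `(x_i, y_i, d_i)` over a text
stimulus with lines `1..m` whose vertical centers are `c_1 < … < c_m`.
Correction is **line assignment**: find `l_i ∈ {1..m}` for each fixation
and snap `y_i → c_{l_i}` (x and duration untouched).  Accuracy against a
known assignment is the fraction of fixations placed on their true line.

Correctors range from positional (`attach`: `l_i = argmin_k |y_i − c_k|`)
through relative-positional (`chain`, `cluster`, `merge`, `regress`,
`stretch`) to sequential (`segment`, `slice`, `warp`) and hybrids
(`warp+attach`, `warp+chain`, `warp+regress`, `warp+stretch`).  `warp`
aligns the fixation sequence to the reading-order word-center sequence by
dynamic time warping with Euclidean cost, which makes it robust to
distortions as large as a whole line spacing — positional algorithms
necessarily fail there.

Synthetic data places one fixation at each word's optimal viewing
position with Gaussian dispersion.  Word skipping follows
`p(L) = k·e^{−λL}` for a word of `L` letters (defaults `k = 0.95`,
`λ = 0.35`), and durations follow the length effect
`duration = 100 + 40·L` ms.

## Worked example

```python
from driftkit import synthgen, distort, algorithms
from driftkit.core import Trial, line_centers, accuracy
from driftkit.assist import run_oracle

# a 3-line, 5-words-per-line stimulus with known word AOIs
img, aois = synthgen.make_stimulus_fixture(n_lines=3, words_per_line=5)
seq, truth = synthgen.gen_basic(aois, synthgen.GenParams(dispersion_sd=2, seed=22))

# shift the whole trial down by one full line spacing (60 px)
bad = distort.offset(seq, 60.0)

for algo in ("attach", "chain", "warp"):
    asg = algorithms.correct(bad, aois, algo)
    print(f"{algo:6s} accuracy = {accuracy(asg, truth):.2f}")

# assisted correction: an ideal user accepts correct suggestions and
# drags wrong ones; recomputation saves most of the dragging
trial = Trial(distort.offset(seq, 31.0), aois)
_, n_with = run_oracle(trial, "chain", truth, recompute=True)
_, n_without = run_oracle(trial, "chain", truth, recompute=False)
print(f"overrides: {n_with} with recompute, {n_without} without")
```

Output:

```
attach accuracy = 0.33
chain  accuracy = 0.33
warp   accuracy = 1.00
overrides: 2 with recompute, 5 without
```

A full line-spacing offset defeats the positional correctors (every
fixation lands nearest the wrong line) while the sequential `warp` still
recovers every line.  In the assisted session, the first manual fix of a
misled chain pulls the whole chain's mean back to the right line, so the
recomputed suggestions need far fewer interventions.

The same pipeline is available from the shell:

```sh
driftkit synth --generator basic --aoi aois.csv --out t.json --truth truth.csv
driftkit distort --kind offset --magnitude 60 --in t.json --out t_off.json
driftkit correct --algo warp --trial t_off.json --aoi aois.csv --out t_corr.json
driftkit accuracy --corrected t_corr.json --truth truth.csv --aoi aois.csv
```

## Layout

| module | contents |
|---|---|
| `driftkit.core` | Fixation/AOI/Trial types, line geometry, accuracy metric |
| `driftkit.algorithms` | the 13 automatic correctors |
| `driftkit.assist` | assisted-correction session, event log, oracle/replay drivers |
| `driftkit.synthgen` | synthetic fixation generators + stimulus fixtures |
| `driftkit.distort` | noise / slope / shift / offset distortions |
| `driftkit.aoi_detect` | AOI detection from stimulus bitmaps |
| `driftkit.filters` | temporal, outlier, merge, off-screen cleaning |
| `driftkit.reports` | hit-testing, FFD/GD/TT metrics, tabular reports |
| `driftkit.io_formats` | EyeLink ASCII, CSV, JSON readers/writers |
| `driftkit.cli` | `driftkit` command-line entry point |

See `docs/methods.md` for the models, parameter defaults, and design
choices in detail.
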