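import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from driftkit import distort, synthgen
from driftkit.algorithms import (ALGORITHMS, AlgoParams, WordCenters, attach,
                                 chain, cluster, correct, hybrid, merge,
                                 regress, segment, slice_, split_regressions,
                                 stretch, warp)
from driftkit.core import (Fixation, FixationSequence, LineGeometry, accuracy,
                           line_centers)

GEOM2 = LineGeometry((100.0, 200.0))


def seq_of(*xyd):
    return FixationSequence(Fixation(*t) for t in xyd)


# ---------------------------------------------------------------- oracles

def brute_force_nearest(seq, geom):
    out = []
    for f in seq:
        best = min(range(len(geom.centers)),
                   key=lambda i: (abs(f.y - geom.centers[i]), i))
        out.append(best + 1)
    return out


def brute_force_dtw(points, centers):
    """Minimum-cost boundary-matched monotone alignment by exhaustive
    enumeration of all DTW paths (small instances only)."""
    n, w = len(points), len(centers)
    cost = np.linalg.norm(points[:, None, :] - centers[None, :, :], axis=2)
    best = [np.inf]

    def walk(i, j, total):
        total += cost[i, j]
        if total >= best[0]:
            return
        if (i, j) == (n - 1, w - 1):
            best[0] = total
            return
        if i + 1 < n and j + 1 < w:
            walk(i + 1, j + 1, total)
        if i + 1 < n:
            walk(i + 1, j, total)
        if j + 1 < w:
            walk(i, j + 1, total)

    walk(0, 0, 0.0)
    return best[0]


class TestAttach:
    def test_exact_center(self):
        assert list(attach(seq_of((0, 200, 100)), GEOM2)) == [2]

    def test_tie_goes_to_upper_line(self):
        assert list(attach(seq_of((0, 150, 100)), GEOM2)) == [1]

    def test_small_offset_recovered(self, aois3x5, geom3x5):
        seq, truth = synthgen.gen_basic(aois3x5, synthgen.GenParams(0, seed=2))
        shifted = distort.offset(seq, 15.0)  # < half the 60 px line spacing
        assert accuracy(attach(shifted, geom3x5), truth) == 1.0

    @given(st.lists(st.floats(0, 400), min_size=1, max_size=40))
    @settings(derandomize=True, deadline=None, max_examples=60)
    def test_matches_brute_force_nearest(self, ys):
        seq = FixationSequence(Fixation(10, y, 100) for y in ys)
        geom = LineGeometry((60.0, 170.0, 280.0))
        assert list(attach(seq, geom)) == brute_force_nearest(seq, geom)


class TestChain:
    def test_single_chain_single_line(self):
        seq = seq_of((0, 102, 100), (30, 98, 100), (60, 104, 100))
        assert list(chain(seq, GEOM2)) == [1, 1, 1]

    def test_stray_fixation_inherits_chain_line(self):
        # third fixation is nearest line 2 on its own but stays linked
        geom = LineGeometry((100.0, 160.0))
        seq = seq_of((0, 100, 100), (30, 100, 100), (60, 135, 100), (90, 100, 100))
        params = AlgoParams(chain_y_link=40.0)
        assert list(attach(seq, geom))[2] == 2
        assert list(chain(seq, geom, params)) == [1, 1, 1, 1]

    def test_large_x_jump_splits_chains(self):
        seq = seq_of((0, 110, 100), (40, 112, 100), (400, 195, 100), (440, 197, 100))
        assert list(chain(seq, GEOM2)) == [1, 1, 2, 2]


class TestCluster:
    def test_separated_bands_map_top_to_bottom(self):
        geom = LineGeometry((50.0, 150.0, 250.0))
        ys = [48, 52, 251, 249, 148, 152]
        seq = FixationSequence(Fixation(i * 30, y, 100) for i, y in enumerate(ys))
        assert list(cluster(seq, geom)) == [1, 1, 3, 3, 2, 2]

    def test_single_line(self):
        seq = seq_of((0, 90, 100), (10, 110, 100))
        assert list(cluster(seq, LineGeometry((100.0,)))) == [1, 1]

    def test_identical_points_identical_labels(self):
        seq = seq_of((0, 100, 100), (10, 100, 100), (20, 200, 100))
        out = list(cluster(seq, GEOM2))
        assert out[0] == out[1]


class TestMergeSegmentSlice:
    def test_merge_clean_progressive_sequences(self, aois3x5, geom3x5, clean_trial):
        seq, truth = clean_trial
        assert accuracy(merge(seq, geom3x5), truth) == 1.0

    def test_merge_single_line(self):
        seq = seq_of((0, 100, 100), (30, 105, 100))
        assert list(merge(seq, LineGeometry((100.0,)))) == [1, 1]

    def test_segment_line_by_line_reading(self, geom3x5, aois3x5, clean_trial):
        seq, truth = clean_trial
        assert accuracy(segment(seq, geom3x5), truth) == 1.0

    def test_segment_monotone_identity(self):
        geom = LineGeometry((50.0, 150.0, 250.0))
        seq = seq_of((0, 50, 100), (10, 150, 100), (20, 250, 100))
        assert list(segment(seq, geom)) == [1, 2, 3]

    def test_slice_clean_and_shifted(self, aois3x5, geom3x5, clean_trial):
        seq, truth = clean_trial
        assert accuracy(slice_(seq, geom3x5), truth) == 1.0
        shifted = distort.offset(seq, 25.0)
        assert accuracy(slice_(shifted, geom3x5), truth) == 1.0

    @pytest.mark.parametrize("algo", [merge, segment, slice_])
    def test_m1_everything_line_one(self, algo):
        seq = seq_of((0, 80, 100), (30, 120, 100))
        assert list(algo(seq, LineGeometry((100.0,)))) == [1, 1]


class TestRegressStretch:
    def test_regress_recovers_sloped_lines(self):
        geom = LineGeometry((100.0, 200.0))
        slope_true = 0.05
        fixations = []
        truth = []
        for line, center in enumerate(geom.centers, start=1):
            for x in range(0, 301, 60):
                fixations.append(Fixation(x, center + slope_true * x + 10, 100))
                truth.append(line)
        seq = FixationSequence(fixations)
        assert list(regress(seq, geom)) == truth

    def test_regress_zero_slope_equals_attach(self, aois3x5, geom3x5, clean_trial):
        seq, _ = clean_trial
        assert list(regress(seq, geom3x5)) == list(attach(seq, geom3x5))

    def test_stretch_undoes_uniform_offset(self, aois3x5, geom3x5):
        seq, truth = synthgen.gen_basic(aois3x5, synthgen.GenParams(0, seed=3))
        shifted = distort.offset(seq, 30.0)
        assert accuracy(stretch(shifted, geom3x5), truth) == 1.0

    def test_stretch_identity_matches_attach(self, aois3x5, geom3x5, clean_trial):
        seq, _ = clean_trial
        assert list(stretch(seq, geom3x5)) == list(attach(seq, geom3x5))

    @pytest.mark.parametrize("algo", [regress, stretch])
    def test_m1_everything_line_one(self, algo):
        seq = seq_of((0, 80, 100), (30, 120, 100))
        assert list(algo(seq, LineGeometry((100.0,)))) == [1, 1]


class TestWarp:
    def test_single_fixation_single_word(self):
        words = WordCenters([(50, 100)], [1])
        assert list(warp(seq_of((48, 98, 100)), words)) == [1]

    def test_one_fixation_per_word_in_order(self, aois3x5):
        seq, truth = synthgen.gen_basic(aois3x5, synthgen.GenParams(2, seed=5))
        words = WordCenters.from_aois(aois3x5)
        assert list(warp(seq, words)) == list(truth)

    def test_survives_full_line_offset_where_attach_fails(
            self, aois3x5, geom3x5):
        seq, truth = synthgen.gen_basic(aois3x5, synthgen.GenParams(2, seed=6))
        shifted = distort.offset(seq, 60.0)  # a full line spacing
        words = WordCenters.from_aois(aois3x5)
        assert accuracy(warp(shifted, words), truth) == 1.0
        assert accuracy(attach(shifted, geom3x5), truth) < 1.0

    def test_cost_matches_exhaustive_path_enumeration(self):
        rng = np.random.default_rng(11)
        for n, w in [(3, 5), (5, 5), (8, 8), (8, 4), (2, 7)]:
            points = rng.uniform(0, 300, size=(n, 2))
            centers = rng.uniform(0, 300, size=(w, 2))
            cost = np.linalg.norm(points[:, None, :] - centers[None, :, :],
                                  axis=2)
            from driftkit.algorithms import _dtw_path
            path = _dtw_path(cost)
            dp_cost = sum(cost[i, j] for i, j in path)
            assert dp_cost == pytest.approx(brute_force_dtw(points, centers))
            assert path[0] == (0, 0) and path[-1] == (n - 1, w - 1)


class TestSplitRegressions:
    def test_progressive_data_unmarked(self, aois3x5, geom3x5, clean_trial):
        seq, _ = clean_trial
        prog, reg = split_regressions(seq, geom3x5)
        assert reg == []
        assert prog == list(range(len(seq)))

    def test_single_between_line_return_marked(self, geom3x5):
        centers = geom3x5.centers
        ys = [centers[0]] * 3 + [centers[1], centers[0], centers[1]]
        xs = [10, 80, 150, 10, 80, 80]
        seq = FixationSequence(Fixation(x, y, 100) for x, y in zip(xs, ys))
        _, reg = split_regressions(seq, geom3x5)
        assert reg == [4]

    def test_reversed_second_half_marked(self, geom3x5):
        centers = geom3x5.centers
        forward = [(10 + 70 * i, centers[i // 2], 100) for i in range(6)]
        backward = list(reversed(forward[:3]))
        seq = FixationSequence(Fixation(*t) for t in forward + backward)
        _, reg = split_regressions(seq, geom3x5)
        assert reg == [6, 7, 8]


class TestHybrids:
    def test_no_regressions_hybrid_equals_warp(self, aois3x5, geom3x5):
        seq, _ = synthgen.gen_basic(aois3x5, synthgen.GenParams(2, seed=8))
        words = WordCenters.from_aois(aois3x5)
        reference = list(warp(seq, words))
        for base in ("attach", "chain", "regress", "stretch"):
            assert list(hybrid(seq, geom3x5, words, base)) == reference

    def test_regression_recovered_under_offset(self, aois3x5, geom3x5):
        seq, truth = synthgen.gen_between_line_regressions(
            aois3x5, synthgen.GenParams(dispersion_sd=0, regression_prob=0.4,
                                        seed=9))
        shifted = distort.offset(seq, 20.0)
        asg = correct(shifted, aois3x5, "warp+attach")
        assert accuracy(asg, truth) == 1.0

    def test_empty_regressive_single_line(self):
        words = WordCenters([(50, 100), (150, 100)], [1, 1])
        geom = LineGeometry((100.0,))
        seq = seq_of((48, 98, 100), (152, 103, 100))
        assert list(hybrid(seq, geom, words, "attach")) == [1, 1]


class TestAllAlgorithms:
    @pytest.mark.parametrize("algo", sorted(ALGORITHMS))
    def test_accuracy_one_on_clean_fixture(self, algo, aois3x5, clean_trial):
        seq, truth = clean_trial
        assert accuracy(correct(seq, aois3x5, algo), truth) == 1.0

    @pytest.mark.parametrize("algo", sorted(ALGORITHMS))
    def test_in_range_and_length_preserving(self, algo, aois3x5):
        rng = np.random.default_rng(13)
        n = 17
        seq = FixationSequence(
            Fixation(float(x), float(y), float(d))
            for x, y, d in zip(rng.uniform(0, 440, n), rng.uniform(0, 200, n),
                               rng.uniform(50, 500, n)))
        asg = correct(seq, aois3x5, algo)
        assert len(asg) == len(seq)
        assert all(1 <= v <= 3 for v in asg)

    @pytest.mark.parametrize("algo", sorted(ALGORITHMS))
    def test_deterministic(self, algo, aois3x5, clean_trial):
        seq, _ = clean_trial
        assert list(correct(seq, aois3x5, algo)) == \
            list(correct(seq, aois3x5, algo))

    def test_empty_sequence_rejected(self, aois3x5):
        with pytest.raises(ValueError, match="empty"):
            correct(FixationSequence(), aois3x5, "attach")

    def test_unknown_name_rejected(self, aois3x5, clean_trial):
        with pytest.raises(ValueError, match="unknown algorithm"):
            correct(clean_trial[0], aois3x5, "nope")
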