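"""Interval merging, shuffles, meta-profiles and proximity statistics."""

import numpy as np
import pytest

from breakscape.core import (
    Breakend,
    BreakpointPair,
    GenomicInterval,
    PreconditionError,
    SignalTrack,
)
from breakscape.breakpoints import (
    distance_to_nearest,
    filter_pairs_by_region,
    merge_intervals,
    meta_profile,
    pairs_to_intervals,
    proximity_null_test,
    relative_distance_test,
    sample_random_intervals,
)

IV = GenomicInterval


class TestMerge:
    def test_overlap(self):
        assert merge_intervals([IV("c", 100, 200), IV("c", 150, 300)]) == [IV("c", 100, 300)]

    def test_book_ended(self):
        assert merge_intervals([IV("c", 100, 200), IV("c", 200, 300)]) == [IV("c", 100, 300)]

    def test_disjoint_unchanged(self):
        out = merge_intervals([IV("c", 300, 400), IV("c", 100, 200)])
        assert out == [IV("c", 100, 200), IV("c", 300, 400)]

    def test_idempotent(self, rng):
        ivs = [
            IV("c", int(s), int(s) + int(l))
            for s, l in zip(rng.integers(0, 1000, 50), rng.integers(1, 60, 50))
        ]
        once = merge_intervals(ivs)
        assert merge_intervals(once) == once


class TestFilterPairs:
    region = IV("c1", 100, 200)

    def make(self, pa, pb, ca="c1", cb="c2"):
        return BreakpointPair(Breakend(ca, pa), Breakend(cb, pb))

    def test_one_end_inside_retained(self):
        p = self.make(150, 5000)
        assert filter_pairs_by_region([p], self.region) == [p]

    def test_both_outside_dropped(self):
        assert filter_pairs_by_region([self.make(50, 5000)], self.region) == []

    def test_exclusive_end_boundary(self):
        assert filter_pairs_by_region([self.make(200, 5000)], self.region) == []


class TestShuffle:
    sizes = {"c1": 10_000, "c2": 5_000}
    intervals = [IV("c1", 0, 100), IV("c1", 500, 750), IV("c2", 10, 15)]

    def test_preserves_counts_and_lengths_per_chromosome(self):
        draws = sample_random_intervals(self.intervals, self.sizes, 20, seed=1)
        want = {
            c: sorted(len(iv) for iv in self.intervals if iv.chrom == c)
            for c in self.sizes
        }
        for draw in draws:
            got = {
                c: sorted(len(iv) for iv in draw if iv.chrom == c) for c in self.sizes
            }
            assert got == want
            for iv in draw:
                assert 0 <= iv.start and iv.end <= self.sizes[iv.chrom]

    def test_seed_determinism(self):
        a = sample_random_intervals(self.intervals, self.sizes, 5, seed=7)
        b = sample_random_intervals(self.intervals, self.sizes, 5, seed=7)
        c = sample_random_intervals(self.intervals, self.sizes, 5, seed=8)
        assert a == b and a != c

    def test_oversized_interval_rejected(self):
        with pytest.raises(PreconditionError):
            sample_random_intervals([IV("c2", 0, 6000)], self.sizes, 1, seed=0)


def constant_track(c: float, sizes={"c1": 10_000}, bw=100) -> SignalTrack:
    return SignalTrack(bw, {k: np.full(-(-L // bw), c) for k, L in sizes.items()})


class TestMetaProfile:
    anchors = [IV("c1", 4_000, 4_010), IV("c1", 6_000, 6_020)]

    def test_constant_track_gives_constant_profile(self):
        prof = meta_profile(self.anchors, constant_track(3.5), 1_000)
        assert prof.mean_signal == pytest.approx(np.full(21, 3.5))
        assert prof.n_anchors == 2

    def test_planted_bump_peaks_at_zero_offset(self):
        track = constant_track(0.0)
        for a in self.anchors:
            track.values["c1"][a.midpoint // 100] = 10.0
        prof = meta_profile(self.anchors, track, 500)
        assert np.argmax(prof.mean_signal) == len(prof.offsets) // 2

    def test_non_fitting_anchors_dropped_and_counted(self):
        prof = meta_profile(self.anchors + [IV("c1", 0, 10)], constant_track(1.0), 1_000)
        assert prof.n_anchors == 2 and prof.n_dropped == 1

    def test_no_fitting_anchor_is_error(self):
        with pytest.raises(PreconditionError):
            meta_profile([IV("c1", 0, 10)], constant_track(1.0), 1_000)

    def test_window_not_multiple_of_bin(self):
        with pytest.raises(PreconditionError):
            meta_profile(self.anchors, constant_track(1.0), 1_050)

    def test_background_close_to_signal_for_shuffled_anchors(self, rng):
        # anchors vs a shuffle of themselves on a noisy track: background
        # mean must track the signal mean
        track = SignalTrack(100, {"c1": rng.normal(5, 1, 100)})
        anchors = [
            IV("c1", int(p), int(p) + 10) for p in rng.integers(2_000, 8_000, 40)
        ]
        draws = sample_random_intervals(anchors, {"c1": 10_000}, 50, seed=3)
        prof = meta_profile(anchors, track, 1_000, background=draws)
        assert prof.background_mean == pytest.approx(prof.mean_signal, abs=1.0)

    def test_offset_zero_equals_track_mean_over_all_bins(self):
        # whole-genome anchor set at half_window 0 recovers the track mean
        vals = np.arange(100, dtype=float)
        track = SignalTrack(100, {"c1": vals})
        anchors = [IV("c1", b * 100 + 50, b * 100 + 51) for b in range(100)]
        prof = meta_profile(anchors, track, 0)
        assert prof.mean_signal[0] == pytest.approx(vals.mean())


class TestDistance:
    def test_gap_arithmetic(self):
        d = distance_to_nearest([IV("c", 250, 251)], [IV("c", 100, 200)])
        assert d == [50]

    def test_overlap_is_zero(self):
        assert distance_to_nearest([IV("c", 150, 160)], [IV("c", 100, 200)]) == [0]

    def test_book_ended_is_zero(self):
        assert distance_to_nearest([IV("c", 200, 210)], [IV("c", 100, 200)]) == [0]

    def test_feature_free_chromosome_excluded(self):
        d = distance_to_nearest(
            [IV("c", 250, 251), IV("cX", 0, 10)], [IV("c", 100, 200)]
        )
        assert list(d) == [50] and d.n_missing == 1

    def test_all_queries_missing_is_error(self):
        with pytest.raises(PreconditionError):
            distance_to_nearest([IV("cX", 0, 10)], [IV("c", 100, 200)])

    def test_reflection_symmetry(self, rng):
        L = 10_000
        queries = [IV("c", int(p), int(p) + 5) for p in rng.integers(0, L - 5, 30)]
        feats = [IV("c", int(p), int(p) + 50) for p in rng.integers(0, L - 50, 10)]
        refl = lambda ivs: [IV("c", L - iv.end, L - iv.start) for iv in ivs]
        assert distance_to_nearest(queries, feats) == distance_to_nearest(
            refl(queries), refl(feats)
        )


class TestProximityNull:
    def test_planted_proximity_detected(self, rng):
        L = 2_000_000
        feats = [IV("c", int(p), int(p) + 500) for p in rng.integers(0, L - 500, 15)]
        queries = []
        for _ in range(40):
            f = feats[rng.integers(len(feats))]
            pos = int(np.clip(f.end + abs(rng.normal(0, 500)), 0, L - 1))
            queries.append(IV("c", pos, pos + 1))
        res = proximity_null_test(queries, feats, {"c": L}, n_draws=50, seed=4)
        assert res.wilcoxon.p_value < 0.01
        assert res.observed_median < res.null_median

    def test_null_queries_not_significant(self, rng):
        L = 2_000_000
        feats = [IV("c", int(p), int(p) + 500) for p in rng.integers(0, L - 500, 15)]
        (queries,) = sample_random_intervals(
            [IV("c", 0, 1)] * 40, {"c": L}, 1, seed=9
        )
        res = proximity_null_test(queries, feats, {"c": L}, n_draws=50, seed=5)
        assert res.wilcoxon.p_value > 0.001  # no systematic proximity


class TestRelativeDistance:
    feats = [IV("c", 1_000, 1_001), IV("c", 2_000, 2_001), IV("c", 3_000, 3_001)]

    def test_query_at_feature_midpoint(self):
        res = relative_distance_test([IV("c", 1_000, 1_001)], self.feats, n_bins=5)
        assert res.reldists == pytest.approx([0.0])

    def test_query_midway(self):
        res = relative_distance_test([IV("c", 1_500, 1_501)], self.feats, n_bins=5)
        assert res.reldists == pytest.approx([0.5])

    def test_outside_span_excluded(self):
        res = relative_distance_test(
            [IV("c", 1_500, 1_501), IV("c", 100, 101)], self.feats, n_bins=5
        )
        assert res.n_used == 1 and res.n_excluded == 1

    def test_uniform_queries_calibrated(self, rng):
        L = 1_000_000
        feats = [IV("c", p, p + 1) for p in sorted(rng.integers(0, L, 40))]
        rejections = 0
        for rep in range(40):
            queries = [
                IV("c", int(p), int(p) + 1)
                for p in rng.integers(0, L, 200)
            ]
            res = relative_distance_test(queries, feats, n_bins=10)
            rejections += res.chi2.p_value < 0.05
        assert rejections <= 8  # ~5% nominal

    def test_too_few_features_is_error(self):
        with pytest.raises(PreconditionError):
            relative_distance_test([IV("c", 0, 1)], [IV("c", 10, 20)])


def test_pairs_to_intervals_emits_both_ends():
    p = BreakpointPair(Breakend("c1", 5), Breakend("c2", 9), id="x")
    ivs = pairs_to_intervals([p])
    assert ivs == [IV("c1", 5, 6, name="x"), IV("c2", 9, 10, name="x")]
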