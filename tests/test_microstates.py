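"""Microstate clustering, model-order selection, back-fitting and smoothing."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microsyn import microstates, synthetic
from microsyn.containers import MicrostateSet, Recording, Segmentation, run_list


def _avg_ref(maps):
    return maps - maps.mean(axis=1, keepdims=True)


def _orthonormal_maps(k, c, seed=0):
    rng = np.random.default_rng(seed)
    m = _avg_ref(rng.standard_normal((k, c)))
    q, _ = np.linalg.qr(m.T)
    return _avg_ref(q.T[:k])


class TestGFP:
    def test_zero_sample(self):
        assert microstates.gfp(np.zeros((3, 1)))[0] == 0.0

    def test_two_channel_hand_value(self):
        # population SD of (1, -1) around mean 0 is 1
        assert microstates.gfp(np.array([[1.0], [-1.0]]))[0] == pytest.approx(1.0)

    @given(st.floats(min_value=-10, max_value=10, allow_nan=False))
    @settings(deadline=None, max_examples=25)
    def test_homogeneity(self, c):
        data = np.array([[1.0, 2.0], [3.0, -1.0], [0.5, 0.0]])
        np.testing.assert_allclose(microstates.gfp(c * data),
                                   abs(c) * microstates.gfp(data), atol=1e-12)

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError):
            microstates.gfp(np.ones((1, 10)))


class TestGFPPeaks:
    def test_monotone_ramp_has_no_peaks(self):
        assert microstates.find_gfp_peaks(np.arange(10.0)).size == 0

    def test_hand_case(self):
        peaks = microstates.find_gfp_peaks(np.array([0.0, 1.0, 0.0, 2.0, 0.0]))
        np.testing.assert_array_equal(peaks, [1, 3])

    def test_simulated_eeg_peak_rate_matches_carrier(self, truth4):
        rec, labels = synthetic.simulate_eeg(truth4, 10.0, 128.0, 1e9, seed=3)
        g = microstates.gfp(rec.data - rec.data.mean(axis=0, keepdims=True))
        peaks = microstates.find_gfp_peaks(g)
        n_dwell = len(run_list(labels))
        assert peaks.size >= n_dwell        # >= 1 GFP peak per dwell period


def _exhaustive_partition_ev(maps, k):
    """Brute-force optimum of the polarity-invariant clustering objective."""
    n = maps.shape[0]
    total = np.sum(maps ** 2)
    best = -1.0
    for assignment in itertools.product(range(k), repeat=n):
        if len(set(assignment)) < k:
            continue
        captured = 0.0
        for j in range(k):
            members = maps[np.array(assignment) == j]
            cov = members.T @ members
            captured += np.linalg.eigvalsh(cov)[-1]
        best = max(best, captured / total)
    return best


class TestModifiedKMeans:
    def test_separable_orthogonal_maps_recovered_exactly(self):
        templates = _orthonormal_maps(3, 16, seed=1)
        maps = np.repeat(templates, 10, axis=0)
        msset, assignment, ev = microstates.modified_kmeans(maps, 3, n_init=5,
                                                            seed=0)
        assert ev == pytest.approx(1.0, abs=1e-10)
        table = np.abs(msset.maps @ templates.T)
        assert np.allclose(np.sort(table.max(axis=1)), 1.0, atol=1e-8)

    def test_polarity_of_inputs_ignored(self):
        m = _avg_ref(np.random.default_rng(2).standard_normal((1, 8)))
        maps = np.vstack([m, -m, m, -m])
        _msset, assignment, ev = microstates.modified_kmeans(maps, 1, seed=0)
        assert len(set(assignment.tolist())) == 1
        assert ev == pytest.approx(1.0, abs=1e-12)

    def test_matches_exhaustive_partition_optimum(self):
        rng = np.random.default_rng(7)
        maps = _avg_ref(rng.standard_normal((6, 8)))
        oracle = _exhaustive_partition_ev(maps, 2)
        _msset, _a, ev = microstates.modified_kmeans(maps, 2, n_init=50, seed=1)
        assert ev == pytest.approx(oracle, abs=1e-6)

    def test_negating_all_maps_changes_nothing(self):
        rng = np.random.default_rng(8)
        maps = _avg_ref(rng.standard_normal((30, 12)))
        s1, a1, ev1 = microstates.modified_kmeans(maps, 3, n_init=8, seed=4)
        s2, a2, ev2 = microstates.modified_kmeans(-maps, 3, n_init=8, seed=4)
        assert ev1 == pytest.approx(ev2, abs=1e-10)
        np.testing.assert_array_equal(a1, a2)
        cv1 = microstates.cv_criterion(maps, s1)
        cv2 = microstates.cv_criterion(-maps, s2)
        assert cv1 == pytest.approx(cv2, abs=1e-10)

    def test_explained_variance_non_decreasing_in_k(self):
        rng = np.random.default_rng(9)
        maps = _avg_ref(rng.standard_normal((60, 10)))
        evs = [microstates.modified_kmeans(maps, k, n_init=10, seed=2)[2]
               for k in range(2, 7)]
        assert all(b >= a - 1e-9 for a, b in zip(evs, evs[1:]))

    def test_too_many_clusters_rejected(self):
        maps = _avg_ref(np.random.default_rng(1).standard_normal((3, 8)))
        with pytest.raises(ValueError):
            microstates.modified_kmeans(maps, 4, seed=0)


class TestCVCriterion:
    def test_perfect_fit_gives_zero(self):
        templates = _orthonormal_maps(2, 8, seed=3)
        maps = np.vstack([3.0 * templates[0], -2.0 * templates[1],
                          5.0 * templates[0]])
        msset = MicrostateSet(maps=templates, labels=["A", "B"])
        assert microstates.cv_criterion(maps, msset) == pytest.approx(0.0,
                                                                      abs=1e-12)

    def test_tiny_hand_case(self):
        # 2 maps, 3 channels, 1 unit template t = (1,0,-1)/sqrt(2)
        t = np.array([[1.0, 0.0, -1.0]]) / np.sqrt(2.0)
        maps = np.array([[1.0, 0.0, -1.0], [0.0, 1.0, -1.0]])
        # residuals: ||x1||^2 - (x1.t)^2 = 2 - 2 = 0
        #            ||x2||^2 - (x2.t)^2 = 2 - 1/2 = 3/2
        # sigma2 = mean(0, 3/2) / (C-1) = 3/8 ; CV = 3/8 * ((C-1)/(C-1-K))^2
        #        = 3/8 * (2/1)^2 = 3/2
        msset = MicrostateSet(maps=t, labels=["A"])
        assert microstates.cv_criterion(maps, msset) == pytest.approx(1.5)

    def test_k_too_large_rejected(self):
        t = _orthonormal_maps(2, 3, seed=0)
        with pytest.raises(ValueError):
            microstates.cv_criterion(np.eye(3), MicrostateSet(maps=t,
                                                              labels=["A", "B"]))


class TestSelectK:
    def test_recovers_true_state_count(self, resting_eeg):
        rec, _labels = resting_eeg
        maps = microstates.peak_maps(rec)
        msset, curve = microstates.select_k(maps, range(2, 9), n_init=5, seed=0)
        assert msset.n_states == 4
        assert curve[4] == min(curve.values())

    def test_degenerate_single_state_selects_smallest_k(self):
        m = _orthonormal_maps(1, 8, seed=5)[0]
        rng = np.random.default_rng(6)
        maps = np.outer(rng.standard_normal(40), m)
        maps += 1e-9 * _avg_ref(rng.standard_normal(maps.shape))
        msset, _curve = microstates.select_k(maps, range(2, 6), n_init=4,
                                             seed=0)
        assert msset.n_states == 2

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError):
            microstates.select_k(np.zeros((5, 4)), [], seed=0)


class TestBackfit:
    def _rec(self, data, rate=128.0):
        return Recording(data=data, rate=rate,
                         labels=[f"ch{i}" for i in range(data.shape[0])])

    def test_scaled_template_labels_that_state(self):
        templates = _orthonormal_maps(3, 8, seed=6)
        data = np.outer(templates[1], np.linspace(1, 3, 50)).reshape(8, 50)
        seg = microstates.backfit(self._rec(data),
                                  MicrostateSet(maps=templates,
                                                labels=["A", "B", "C"]))
        assert (seg.labels == 1).all()

    def test_sign_flipped_data_same_state(self):
        templates = _orthonormal_maps(3, 8, seed=6)
        data = np.outer(-templates[1], np.ones(20))
        seg = microstates.backfit(self._rec(data),
                                  MicrostateSet(maps=templates,
                                                labels=["A", "B", "C"]))
        assert (seg.labels == 1).all()

    def test_noiseless_synthetic_agreement(self, truth4):
        rec, labels = synthetic.simulate_eeg(truth4, 10.0, 128.0, 1e9, seed=9)
        msset = MicrostateSet(maps=truth4.topographies,
                              labels=list("ABCD"))
        seg = microstates.backfit(rec, msset)
        assert (seg.labels == labels).mean() >= 0.99

    def test_zero_variance_sample_carries_previous_label(self):
        templates = _orthonormal_maps(2, 6, seed=7)
        data = np.outer(templates[0], np.ones(10))
        data[:, 4] = 0.0
        seg = microstates.backfit(self._rec(data),
                                  MicrostateSet(maps=templates,
                                                labels=["A", "B"]))
        assert seg.labels[4] == seg.labels[3]


class TestSmoothing:
    def _seg(self, labels, corr=None, rate=128.0):
        labels = np.asarray(labels)
        return Segmentation(labels=labels, gfp=np.ones(labels.size), rate=rate,
                            correlations=corr)

    def test_hand_case_short_run_absorbed(self):
        labels = [0] * 10 + [1] + [0] * 10
        out = microstates.smooth_segmentation(self._seg(labels), 23.0)
        np.testing.assert_array_equal(out.labels, 0)

    def test_already_smooth_unchanged(self):
        labels = [0] * 10 + [1] * 10 + [0] * 10
        out = microstates.smooth_segmentation(self._seg(labels), 23.0)
        np.testing.assert_array_equal(out.labels, labels)

    @pytest.mark.parametrize("rate", [128.0, 256.0, 1000.0])
    def test_no_short_segment_survives_random_input(self, rate, rng):
        min_len = microstates.min_duration_samples(23.0, rate)
        for _trial in range(34):
            n = int(rng.integers(min_len, 400))
            labels = rng.integers(0, 4, size=n)
            corr = rng.random((4, n))
            out = microstates.smooth_segmentation(self._seg(labels, corr,
                                                            rate), 23.0)
            runs = out.segments
            if len(runs) > 1:
                assert min(e - s for s, e, _ in runs) >= min_len

    def test_whole_recording_too_short_rejected(self):
        with pytest.raises(ValueError):
            microstates.smooth_segmentation(self._seg([0, 1]), 23.0, rate=1000.0)


class TestMatchSets:
    def _sets(self, seed=0, k=3, c=10):
        maps = _orthonormal_maps(k, c, seed=seed)
        labels = [microstates.STATE_NAMES[i] for i in range(k)]
        return MicrostateSet(maps=maps, labels=labels)

    def test_self_match_is_identity(self):
        s = self._sets()
        mapping, unmatched, table = microstates.match_sets(s, s)
        assert mapping == {0: 0, 1: 1, 2: 2}
        assert unmatched == []
        np.testing.assert_allclose(np.diag(table), 1.0, atol=1e-10)

    def test_sign_flip_still_identity(self):
        s = self._sets(seed=1)
        flipped = MicrostateSet(maps=-s.maps, labels=s.labels)
        mapping, unmatched, _t = microstates.match_sets(flipped, s)
        assert mapping == {0: 0, 1: 1, 2: 2}

    def test_matches_exhaustive_permutation_optimum(self, rng):
        a = MicrostateSet(maps=_avg_ref(rng.standard_normal((3, 12))),
                          labels=["A", "B", "C"])
        b = MicrostateSet(maps=_avg_ref(rng.standard_normal((3, 12))),
                          labels=["A", "B", "C"])
        _m, _u, table = microstates.match_sets(a, b, threshold=0.0)
        best = max(sum(table[i, p[i]] for i in range(3))
                   for p in itertools.permutations(range(3)))
        rows, cols = zip(*microstates.match_sets(a, b, threshold=0.0)[0].items())
        achieved = table[list(rows), list(cols)].sum()
        assert achieved == pytest.approx(best, abs=1e-12)

    def test_below_threshold_reported_unmatched(self):
        a = self._sets(seed=2, k=2, c=16)
        b = MicrostateSet(maps=_orthonormal_maps(4, 16, seed=2)[2:],
                          labels=["A", "B"])
        mapping, unmatched, _t = microstates.match_sets(a, b, threshold=0.65)
        assert mapping == {}
        assert unmatched == [0, 1]


class TestGroupCluster:
    def test_identical_subjects_give_those_maps(self):
        maps = _orthonormal_maps(3, 10, seed=4)
        sets = [MicrostateSet(maps=maps.copy(), labels=["A", "B", "C"])
                for _ in range(4)]
        group, assignments = microstates.group_cluster(sets, 3, seed=0)
        table = np.abs(group.maps @ maps.T)
        assert np.allclose(np.sort(table.max(axis=1)), 1.0, atol=1e-8)
        first = assignments[0]
        assert all(a == first for a in assignments)

    def test_two_subjects_two_orthogonal_maps_brute_force(self):
        maps = _orthonormal_maps(2, 8, seed=5)
        s1 = MicrostateSet(maps=maps, labels=["A", "B"])
        s2 = MicrostateSet(maps=maps[::-1].copy(), labels=["A", "B"])
        group, assignments = microstates.group_cluster([s1, s2], 2, seed=0)
        # each subject's maps land in different clusters and the pairing
        # puts identical maps together
        for amap in assignments:
            assert sorted(amap.values()) == [0, 1]
        assert assignments[0][0] == assignments[1][1]

    def test_single_subject_is_identity_clustering(self):
        maps = _orthonormal_maps(3, 10, seed=6)
        s = MicrostateSet(maps=maps, labels=["A", "B", "C"])
        group, assignments = microstates.group_cluster([s], 3, seed=0)
        assert sorted(assignments[0].values()) == [0, 1, 2]

    def test_k_too_small_rejected(self):
        s = self_maps = MicrostateSet(maps=_orthonormal_maps(3, 10, seed=1),
                                      labels=["A", "B", "C"])
        with pytest.raises(ValueError):
            microstates.group_cluster([self_maps], 2, seed=0)


class TestTemporalStats:
    def test_single_state_throughout(self):
        seg = Segmentation(labels=np.zeros(128, dtype=int), gfp=np.ones(128),
                           rate=128.0)
        stats = microstates.temporal_stats(seg)
        assert stats[0]["coverage"] == pytest.approx(1.0)
        assert stats[0]["occurrences_per_s"] == pytest.approx(1.0)
        assert stats[0]["mean_duration_ms"] == pytest.approx(1000.0)

    def test_alternating_runs_hand_value(self):
        labels = np.tile([0] * 10 + [1] * 10, 5)
        seg = Segmentation(labels=labels, gfp=np.ones(labels.size), rate=128.0)
        stats = microstates.temporal_stats(seg)
        # 10-sample runs at 128 Hz: 10/128 s = 78.125 ms
        assert stats[0]["mean_duration_ms"] == pytest.approx(78.125)
        assert stats[1]["mean_duration_ms"] == pytest.approx(78.125)

    def test_coverages_sum_to_labeled_fraction(self, rng):
        labels = rng.integers(0, 3, size=200)
        seg = Segmentation(labels=labels, gfp=np.ones(200), rate=128.0)
        stats = microstates.temporal_stats(seg, n_states=3)
        assert sum(s["coverage"] for s in stats.values()) == pytest.approx(1.0)


class TestHarmonize:
    def test_rounded_mean(self):
        assert microstates.harmonize_k([4, 5, 5, 5]) == 5
        assert microstates.harmonize_k([4, 4, 5, 5]) == 4  # banker's rounding
        assert microstates.harmonize_k([3]) == 3
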