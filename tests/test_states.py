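"""Mark scoring, chromatin-state clustering, expression grouping, profiles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hiclocal.states import (
    MARK_NAMES,
    classify_states,
    expression_groups,
    mark_coverage,
    name_states,
    pca_project,
    profile_around,
    quintile_scores,
    rpkm,
)


class TestMarkCoverage:
    def test_full_half_and_absent(self):
        cov = mark_coverage(
            {"H3K4me2": [(0, 400)], "H3K4me3": [(0, 200)]}, 800, 400
        )
        i2, i3 = MARK_NAMES.index("H3K4me2"), MARK_NAMES.index("H3K4me3")
        assert cov[0, i2] == 1.0
        assert cov[0, i3] == 0.5
        assert cov[1].sum() == 0.0

    def test_overlapping_intervals_union_never_exceed_one(self):
        cov = mark_coverage(
            {"H3K9ac": [(0, 300), (100, 400), (200, 350)]}, 400, 400
        )
        m = MARK_NAMES.index("H3K9ac")
        assert cov[0, m] == 1.0

    def test_union_matches_per_bp_oracle(self):
        rng = np.random.default_rng(8)
        spans = [
            (int(a), int(a + w))
            for a, w in zip(rng.integers(0, 3600, 25), rng.integers(1, 500, 25))
        ]
        cov = mark_coverage({"mCG": spans}, 4000, 400)
        bp = np.zeros(4000, dtype=bool)
        for a, b in spans:
            bp[a:min(b, 4000)] = True
        m = MARK_NAMES.index("mCG")
        for k in range(10):
            assert cov[k, m] == pytest.approx(bp[k * 400:(k + 1) * 400].mean())

    def test_malformed_interval_rejected(self):
        with pytest.raises(ValueError):
            mark_coverage({"mCG": [(500, 500)]}, 4000, 400)


class TestQuintileScores:
    def test_ten_distinct_positive_values(self):
        cov = np.zeros((10, 16))
        cov[:, 0] = np.arange(1, 11)
        sm = quintile_scores(cov)
        assert list(sm.scores[:, 0]) == [0, 0, 1, 1, 2, 2, 3, 3, 4, 4]

    def test_zero_coverage_scores_zero_and_flags_unclear(self):
        cov = np.zeros((5, 16))
        cov[0, 3] = 0.8
        sm = quintile_scores(cov)
        assert not sm.unclear[0]
        assert sm.unclear[1:].all()

    def test_ties_sit_at_the_midrank(self):
        cov = np.zeros((8, 16))
        cov[:, 2] = 0.5  # all equal positives: 50th percentile -> quintile 2
        sm = quintile_scores(cov)
        assert (sm.scores[:, 2] == 2).all()

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        cov = rng.random((40, 16)) * (rng.random((40, 16)) > 0.3)
        s1 = quintile_scores(cov)
        s2 = quintile_scores(np.expm1(3 * cov))  # strictly increasing, 0 -> 0
        assert np.array_equal(s1.scores, s2.scores)
        assert np.array_equal(s1.unclear, s2.unclear)


class TestClassifyStates:
    def _scores(self, labels, rng):
        """Disjoint blocks of marks per planted state."""
        groups = [range(0, 3), range(3, 6), range(6, 9), range(9, 11),
                  range(11, 14), range(14, 16)]
        cov = rng.random((len(labels), 16)) * 0.02
        for i, lab in enumerate(labels):
            for m in groups[lab]:
                cov[i, m] = 0.5 + 0.5 * rng.random()
        return quintile_scores(cov)

    def test_duplicating_every_bin_keeps_the_labelling(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 6, 120)
        sm = self._scores(labels, rng)
        l1, _ = classify_states(sm, seed=1)
        sm2 = type(sm)(
            np.vstack([sm.scores, sm.scores]),
            np.concatenate([sm.unclear, sm.unclear]),
        )
        l2, _ = classify_states(sm2, seed=1)
        n = len(labels)
        assert np.array_equal(l2[:n], l2[n:])

    def test_k1_centroid_is_the_mean(self):
        rng = np.random.default_rng(1)
        sm = self._scores(rng.integers(0, 6, 60), rng)
        labels, centroids = classify_states(sm, k=1, seed=0, restarts=2)
        keep = labels >= 0
        assert (labels[keep] == 0).all()
        assert centroids[0] == pytest.approx(
            sm.scores[~sm.unclear].mean(axis=0)
        )

    def test_too_few_distinct_bins_rejected(self):
        sm = quintile_scores(np.tile([[1.0] + [0.0] * 15], (10, 1)))
        with pytest.raises(ValueError):
            classify_states(sm, k=6)


class TestNameStates:
    def test_polycomb_profile_named_cs2(self):
        centroids = np.zeros((6, 16))
        for s, marks in enumerate([
            ("H3K4me2", "H3K4me3", "H3K9ac"),
            ("H3K27me3", "H3.1", "H3.3"),
            ("H3K9me2", "H3K27me1", "mCG"),
            (),
            ("H3K36me2", "H2Bub", "H3.3"),
            ("H4K20me1", "mCHH"),
        ]):
            for m in marks:
                centroids[s, MARK_NAMES.index(m)] = 3.5
        names = name_states(centroids)
        assert names[1] == "CS2"
        assert names[3] == "CS4"  # featureless centroid
        assert sorted(names) == ["CS1", "CS2", "CS3", "CS4", "CS5", "CS6"]

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        centroids = rng.random((6, 16)) * 4
        names = name_states(centroids)
        perm = rng.permutation(6)
        permuted = name_states(centroids[perm])
        assert [permuted[np.where(perm == i)[0][0]] for i in range(6)] == names


class TestPCA:
    def _matrix(self, scores):
        from hiclocal.states import MarkScoreMatrix
        return MarkScoreMatrix(scores, np.zeros(len(scores), bool))

    def test_rank_one_data_is_fully_explained_by_pc1(self):
        base = np.arange(16)
        scores = np.outer([1, 2, 3, 4], base)
        Y = pca_project(self._matrix(scores))
        assert np.abs(Y[:, 1:]).max() < 1e-9

    def test_orthogonal_clusters_separate_on_pc1(self):
        a = np.zeros(16); a[:8] = 4
        b = np.zeros(16); b[8:] = 4
        scores = np.array([a] * 10 + [b] * 10)
        Y = pca_project(self._matrix(scores))
        assert (Y[:10, 0] > 0).all() != (Y[10:, 0] > 0).all()

    def test_projection_is_centered(self):
        rng = np.random.default_rng(4)
        scores = rng.integers(0, 5, (30, 16))
        Y = pca_project(self._matrix(scores))
        assert Y.mean(axis=0) == pytest.approx(np.zeros(3), abs=1e-9)


class TestExpression:
    def test_rpkm_arithmetic(self):
        assert rpkm([10], [1000], 1e6)[0] == pytest.approx(10.0)
        assert rpkm([0], [1000], 1e6)[0] == 0.0
        assert rpkm([10], [1000], 2e6)[0] == pytest.approx(5.0)

    def test_rpkm_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            rpkm([1], [0], 1e6)
        with pytest.raises(ValueError):
            rpkm([1], [100], 0)

    def test_all_undetected_in_group_one(self):
        assert (expression_groups(np.zeros(20)) == 1).all()

    def test_eight_positives_fill_groups_two_to_nine(self):
        groups = expression_groups(np.array([0.0, 1, 2, 3, 4, 5, 6, 7, 8]))
        assert list(groups) == [1, 2, 3, 4, 5, 6, 7, 8, 9]

    def test_grouping_is_monotone(self):
        rng = np.random.default_rng(5)
        v = np.round(rng.exponential(5, 200), 2)
        g = expression_groups(v)
        order = np.argsort(v)
        assert (np.diff(g[order]) >= 0).all()


class _Region:
    def __init__(self, start_bin):
        self.start_bin = start_bin


class TestProfileAround:
    def test_constant_track_gives_flat_profile(self):
        prof = profile_around([_Region(5), _Region(9)], np.full(20, 2.5), 3)
        assert prof == pytest.approx(np.full(7, 2.5))

    def test_single_region_profile_is_the_slice(self):
        track = np.arange(20.0)
        prof = profile_around([_Region(10)], track, 2)
        assert prof == pytest.approx(track[8:13])

    def test_two_region_means_hand_computed(self):
        track = np.array([1.0, 2.0, 4.0, 8.0, 16.0])
        prof = profile_around([_Region(1), _Region(3)], track, 1)
        # rel -1: (1+4)/2 ; rel 0: (2+8)/2 ; rel +1: (4+16)/2
        assert prof == pytest.approx([2.5, 5.0, 10.0])

    def test_positions_off_the_end_are_skipped(self):
        track = np.array([3.0, 5.0])
        prof = profile_around([_Region(0)], track, 1)
        assert np.isnan(prof[0])
        assert prof[1] == 3.0 and prof[2] == 5.0

    def test_categorical_track_frequencies(self):
        track = np.array(["a", "b", "a", "a"], dtype=object)
        prof = profile_around(
            [_Region(1), _Region(2)], track, 1, categories=("a", "b")
        )
        assert prof[1] == pytest.approx([0.5, 0.5])  # bins 1 and 2

    def test_empty_region_list(self):
        prof = profile_around([], np.ones(5), 2)
        assert np.isnan(prof).all()
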