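"""Contact binning and the Poisson bias regression."""

import warnings

import numpy as np
import pytest
from scipy.optimize import minimize

from hiclocal import (
    ContactMatrix,
    SyntheticTruth,
    bin_contacts,
    contact_strength,
    exclusion_mask,
    gen_contact_map,
    normalize,
)
from hiclocal.genome import BinFeatures
from hiclocal.pairs import PairRecord


class TestBinContacts:
    def test_single_pair_increments_symmetric_cells(self):
        p = PairRecord("c", 1000, "+", 50, "c", 5000, "-", 50)
        mats, inter = bin_contacts([p], 2000, {"c": 10_000})
        m = mats["c"].values
        assert m[0, 2] == 1 and m[2, 0] == 1
        assert m.sum() == 2
        assert inter == {}

    def test_empty_input_zero_matrix(self):
        mats, _ = bin_contacts([], 2000, {"c": 10_000})
        assert mats["c"].values.sum() == 0

    def test_order_independence(self):
        rng = np.random.default_rng(0)
        pairs = [
            PairRecord("c", int(a), "+", 50, "c", int(b), "-", 50)
            for a, b in rng.integers(0, 9999, size=(50, 2))
        ]
        m1, _ = bin_contacts(pairs, 2000, {"c": 10_000})
        m2, _ = bin_contacts(pairs[::-1], 2000, {"c": 10_000})
        assert np.array_equal(m1["c"].values, m2["c"].values)

    def test_interchromosomal_counted_separately(self):
        p = PairRecord("a", 100, "+", 50, "b", 100, "-", 50)
        mats, inter = bin_contacts([p], 2000, {"a": 10_000, "b": 10_000})
        assert inter[("a", "b")] == 1
        assert mats["a"].values.sum() == 0

    def test_position_beyond_chromosome_rejected(self):
        p = PairRecord("c", 50_000, "+", 50, "c", 100, "-", 50)
        with pytest.raises(ValueError):
            bin_contacts([p], 2000, {"c": 10_000})


class TestExclusionMask:
    def test_thresholds_and_centromere_levels(self):
        feats = BinFeatures(
            "c", 2000,
            eff_len=np.array([0.5, 0.05, 0.5, 0.5]),
            gc_ends=np.full(4, 0.4),
            end_count=np.full(4, 5),
            mappability=np.array([0.4, 1.0, 1.0, 1.0]),
        )
        norm_ok, analysis_ok = exclusion_mask(feats, centromere_bins={3})
        # mappability 0.4 < 0.5 and eff_len 0.05 < 0.1 fail normalization
        assert list(norm_ok) == [False, False, True, True]
        # the centromeric bin stays in the regression but not the analysis
        assert list(analysis_ok) == [False, False, True, False]


def _poisson_nll(beta, X, u, offset):
    eta = X @ beta + offset
    return np.sum(np.exp(eta) - u * eta)


class TestNormalize:
    def test_four_bin_coefficients_match_direct_likelihood(self):
        rng = np.random.default_rng(4)
        feats = BinFeatures(
            "c", 2000,
            eff_len=np.array([0.3, 0.5, 0.7, 0.9]),
            gc_ends=np.array([0.30, 0.42, 0.36, 0.48]),
            end_count=np.array([4.0, 8.0, 6.0, 12.0]),
            mappability=np.array([1.0, 0.9, 0.8, 1.0]),
        )
        raw = np.zeros((4, 4))
        i, j = np.triu_indices(4, 1)
        raw[i, j] = raw[j, i] = rng.poisson(40, size=6)
        mat = ContactMatrix("c", 2000, raw, np.ones(4, bool), "raw")
        norm, fit = normalize(mat, feats)

        # oracle: direct minimization of the Poisson negative log-likelihood
        L, G, F, M = feats.eff_len, feats.gc_ends, feats.end_count, feats.mappability
        X = np.column_stack(
            [np.ones(6), np.log(L[i] * L[j]), np.log(G[i] * G[j]),
             np.log(F[i] * F[j])]
        )
        offset = np.log(M[i] * M[j])
        u = raw[i, j]
        res = minimize(
            _poisson_nll, np.zeros(4), args=(X, u, offset),
            jac=lambda b, X, u, o: X.T @ (np.exp(X @ b + o) - u),
            method="BFGS", tol=1e-14,
        )
        assert fit.as_array() == pytest.approx(res.x, abs=1e-6)

    def test_flat_input_gives_zero_residuals(self, uniform_features):
        n = 12
        raw = np.full((n, n), 7.0)
        mat = ContactMatrix("c", 2000, raw, np.ones(n, bool), "raw")
        norm, _ = normalize(mat, uniform_features(n))
        off = ~np.eye(n, dtype=bool)
        assert norm.values[off] == pytest.approx(np.zeros(off.sum()), abs=1e-8)

    def test_residual_matrix_symmetric_with_near_zero_mean(self, varying_features):
        raw, _ = gen_contact_map(80, base_count=20.0, seed=3, strip_boost=2.0)
        norm, _ = normalize(raw, varying_features(80))
        assert np.allclose(norm.values, norm.values.T)
        i, j = np.triu_indices(80, 1)
        assert abs(norm.values[i, j].mean()) < 0.05

    def test_covariate_rescaling_absorbed(self, varying_features):
        raw, _ = gen_contact_map(60, seed=9, strip_boost=2.0)
        feats = varying_features(60)
        norm1, _ = normalize(raw, feats)
        scaled = BinFeatures(
            feats.chrom, feats.bin_size,
            feats.eff_len * 7.0, feats.gc_ends, feats.end_count,
            feats.mappability,
        )
        norm2, _ = normalize(raw, scaled)
        assert norm1.values == pytest.approx(norm2.values, abs=1e-8)

    def test_planted_bias_removed(self, varying_features):
        """Normalized map correlates better with the bias-free expectation
        than the raw map does, across seeds."""
        n = 200
        for seed in range(5):
            feats = varying_features(n, seed=seed)
            bias = feats.end_count / feats.end_count.mean()
            truth = SyntheticTruth(bin_bias=bias)
            raw, _ = gen_contact_map(
                n, base_count=50.0, truth=truth, strip_boost=2.0, seed=seed
            )
            i, j = np.triu_indices(n, 1)
            expect = 50.0 * np.maximum(j - i, 1) ** -1.0
            norm, _ = normalize(raw, feats)
            r_raw = np.corrcoef(raw.values[i, j], expect)[0, 1]
            r_norm = np.corrcoef(norm.values[i, j], expect)[0, 1]
            assert r_norm > r_raw

    def test_unbiased_data_gives_null_end_count_slope(self, varying_features):
        for seed in range(5):
            raw, _ = gen_contact_map(150, base_count=50.0, seed=seed,
                                     strip_boost=2.0)
            _, fit = normalize(raw, varying_features(150, seed=seed + 100))
            assert abs(fit.beta_end) < 0.05

    def test_zero_covariate_bin_automasked(self, uniform_features):
        n = 15
        feats = uniform_features(n)
        feats.end_count = feats.end_count.copy()
        feats.end_count[4] = 0
        raw = np.full((n, n), 5.0)
        mat = ContactMatrix("c", 2000, raw, np.ones(n, bool), "raw")
        with pytest.warns(UserWarning, match="auto-masked"):
            norm, _ = normalize(mat, feats)
        assert not norm.mask[4]
        assert norm.values[4].sum() == 0

    def test_requires_raw_kind(self, uniform_features, normalized_matrix):
        with pytest.raises(ValueError):
            normalize(normalized_matrix(np.ones((12, 12))), uniform_features(12))


class TestContactStrength:
    def test_interior_bin_sums_ten_neighbors(self, normalized_matrix):
        v = np.ones((20, 20)) - np.eye(20)
        s = contact_strength(normalized_matrix(v))
        assert s[10] == 10.0

    def test_chromosome_start_truncates_to_downstream(self, normalized_matrix):
        v = np.ones((20, 20)) - np.eye(20)
        s = contact_strength(normalized_matrix(v))
        assert s[0] == 5.0

    def test_masked_focal_bin_flagged(self, normalized_matrix):
        v = np.ones((20, 20))
        mask = np.ones(20, bool)
        mask[7] = False
        s = contact_strength(normalized_matrix(v, mask))
        assert np.isnan(s[7])
        # masked neighbor is skipped, not zero-filled
        assert s[8] == 9.0
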