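"""Directionality index, HMM state decoding, and region grammars."""

import re

import numpy as np
import pytest

from hiclocal import (
    directionality_index,
    extract_boundaries,
    extract_insulators,
    extract_interiors,
    fit_hmm,
)
from hiclocal.domains import StateTrack


def _track(states: str) -> StateTrack:
    return StateTrack("c", np.zeros(len(states)), states)


class TestDirectionalityIndex:
    def _matrix(self, normalized_matrix, up, down):
        """5-bin matrix with prescribed sums for bin 2 at window 2 bins."""
        v = np.zeros((5, 5))
        v[2, 0], v[2, 1] = up
        v[2, 3], v[2, 4] = down
        v = v + v.T
        return normalized_matrix(v)

    def test_balanced_sums_give_zero(self, normalized_matrix):
        m = self._matrix(normalized_matrix, (4, 6), (6, 4))
        di = directionality_index(m, window_bp=4000)
        assert di[2] == 0.0

    def test_downstream_excess_is_positive(self, normalized_matrix):
        # A=0, B=10 -> E=5 -> DI = +(25/5 + 25/5) = +10
        m = self._matrix(normalized_matrix, (0, 0), (4, 6))
        di = directionality_index(m, window_bp=4000)
        assert di[2] == pytest.approx(10.0)

    def test_upstream_excess_is_negative(self, normalized_matrix):
        m = self._matrix(normalized_matrix, (4, 6), (0, 0))
        di = directionality_index(m, window_bp=4000)
        assert di[2] == pytest.approx(-10.0)

    def test_reversal_negates_di(self, normalized_matrix):
        rng = np.random.default_rng(2)
        v = rng.poisson(8, size=(80, 80)).astype(float)
        v = (v + v.T) / 2
        m = normalized_matrix(v)
        di = directionality_index(m, window_bp=20_000)
        rev = normalized_matrix(v[::-1, ::-1].copy())
        di_rev = directionality_index(rev, window_bp=20_000)
        assert di_rev == pytest.approx(-di[::-1])

    def test_masked_bins_excluded(self, normalized_matrix):
        v = np.ones((70, 70))
        mask = np.ones(70, bool)
        mask[30] = False
        di = directionality_index(normalized_matrix(v, mask))
        assert np.isnan(di[30])

    def test_window_must_align_with_bins(self, normalized_matrix):
        with pytest.raises(ValueError):
            directionality_index(normalized_matrix(np.ones((70, 70))), 61_000)


class TestFitHmm:
    def test_constant_di_decodes_all_neutral(self):
        st = fit_hmm(np.zeros(100))
        assert st.states == "N" * 100

    def test_well_separated_blocks_decode_cleanly(self):
        rng = np.random.default_rng(0)
        di = np.concatenate([
            10 + 0.2 * rng.normal(size=30),
            -10 + 0.2 * rng.normal(size=30),
            0.2 * rng.normal(size=30),
        ])
        st = fit_hmm(di, seed=0)
        assert st.states == "D" * 30 + "U" * 30 + "N" * 30

    def test_naming_by_emission_mean_not_init_order(self):
        rng = np.random.default_rng(1)
        di = np.concatenate([
            -8 + 0.1 * rng.normal(size=40),
            8 + 0.1 * rng.normal(size=40),
            0.1 * rng.normal(size=40),
        ])
        for seed in (0, 1, 2, 3):
            st = fit_hmm(di, seed=seed)
            assert st.states == "U" * 40 + "D" * 40 + "N" * 40

    def test_nan_gaps_split_segments(self):
        di = np.concatenate([np.zeros(40), [np.nan] * 3, np.zeros(40)])
        st = fit_hmm(di)
        assert st.states == "N" * 40 + "..." + "N" * 40


class TestStateBalance:
    def test_unstructured_maps_decode_neutral_with_balanced_tails(
        self, varying_features
    ):
        """Symmetric maps without directional structure: N is the majority
        state and U/D frequencies agree within 0.05, across seeds."""
        from hiclocal import gen_contact_map, normalize

        n = 400
        for seed in range(5):
            raw, _ = gen_contact_map(
                n, base_count=50.0, strip_boost=2.0, seed=seed
            )
            norm, _ = normalize(raw, varying_features(n, seed=seed + 50))
            st = fit_hmm(directionality_index(norm), seed=seed)
            fu = st.states.count("U") / n
            fd = st.states.count("D") / n
            fn = st.states.count("N") / n
            assert fn > max(fu, fd)
            assert abs(fu - fd) < 0.05


class TestPatternExamples:
    def test_type_a_insulator(self):
        calls = extract_insulators(_track("NNUUDDNN"))
        assert [(c.start_bin, c.end_bin, c.type) for c in calls] == [
            (3, 5, "insulatorA")
        ]
        assert calls[0].matched_states == "UD"

    def test_type_b_and_c_insulators(self):
        b = extract_insulators(_track("NNUUNDDNN"))
        assert [(c.start_bin, c.end_bin, c.type) for c in b] == [(3, 6, "insulatorB")]
        c = extract_insulators(_track("NNUUNNDDNN"))
        assert [(r.start_bin, r.end_bin, r.type) for r in c] == [(3, 7, "insulatorC")]

    def test_featureless_string_has_no_calls(self):
        assert extract_insulators(_track("NNNNNNNN")) == []

    def test_core_needs_two_flanking_states(self):
        assert extract_insulators(_track("UUDDNN")) == []   # no left flank
        assert extract_insulators(_track("NNUUDD")) == []   # no right flank

    def test_boundary_at_u_run_end(self):
        calls = extract_boundaries(_track("NUUUUUDDN"))
        assert any(
            c.type == "boundary_UD" and (c.start_bin, c.end_bin) == (5, 7)
            for c in calls
        )

    def test_boundary_overlaps_insulator(self):
        track = _track("NUUUUUDDNN")
        assert extract_boundaries(track)
        assert extract_insulators(track)  # contains ..UUDD.. too

    def test_seven_bins_cannot_hold_an_eight_state_pattern(self):
        assert extract_boundaries(_track("NDDDDDN")) == []

    def test_interior_at_u_run_start(self):
        calls = extract_interiors(_track("NDDUUUUUN"))
        assert any(
            c.type == "interior_DU" and (c.start_bin, c.end_bin) == (2, 4)
            for c in calls
        )

    def test_interior_at_d_run_end(self):
        calls = extract_interiors(_track("DDDDDNUN"))
        assert any(
            c.type == "interior_DUN_end" and (c.start_bin, c.end_bin) == (4, 6)
            for c in calls
        )

    def test_uniform_u_has_no_interiors(self):
        assert extract_interiors(_track("U" * 20)) == []

    def test_patterns_do_not_span_excluded_gaps(self):
        assert extract_insulators(_track("NNUU..DDNN")) == []


# regex oracle: overlapping matches via lookahead, offsets of the called
# region relative to the match start
_ORACLE = {
    "insulatorA": (r"(?=[UDN]{2}(UUDD)[UDN]{2})", 3, 5),
    "insulatorB": (r"(?=[UDN]{2}(UUNDD)[UDN]{2})", 3, 6),
    "insulatorC": (r"(?=[UDN]{2}(UUNNDD)[UDN]{2})", 3, 7),
    "boundary_UD": (r"(?=UUUUU[DN][DN][UDN])", 4, 6),
    "boundary_UND_end": (r"(?=[UDN][UN][UN]DDDDD)", 2, 4),
    "interior_DU": (r"(?=[UDN][DN][DN]UUUUU)", 2, 4),
    "interior_DUN_end": (r"(?=DDDDD[UN][UN][UDN])", 4, 6),
}


def _oracle_regions(states: str, rtype: str) -> set[tuple[int, int]]:
    pattern, a, b = _ORACLE[rtype]
    return {
        (m.start() + a, m.start() + b) for m in re.finditer(pattern, states)
    }


class TestRegexOracle:
    @pytest.mark.parametrize("rtype", sorted(_ORACLE))
    def test_extraction_matches_regex_oracle(self, rtype):
        rng = np.random.default_rng(42)
        states = "".join(
            rng.choice(list("UUDDNNN."), size=10_000)
        )
        track = _track(states)
        if rtype.startswith("insulator"):
            calls = [c for c in extract_insulators(track) if c.type == rtype]
        elif rtype.startswith("boundary"):
            calls = [c for c in extract_boundaries(track) if c.type == rtype]
        else:
            calls = [c for c in extract_interiors(track) if c.type == rtype]
        got = {(c.start_bin, c.end_bin) for c in calls}
        assert got == _oracle_regions(states, rtype)
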