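"""Cross-recurrence plots and line-based CRQA measures."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from facemimic import (
    AUSeries,
    CRQAConfig,
    aggregate_instructed,
    cross_recurrence_matrix,
    crqa_measures,
    diagonal_histogram,
)
from facemimic.crqa import snippet_crqa

from _oracles import brute_crp, brute_crqa, brute_diagonal_histogram


def random_pair(rng, max_len=40, max_dim=4):
    n, m = rng.integers(1, max_len + 1, size=2)
    d = rng.integers(1, max_dim + 1)
    return (rng.integers(0, 6, size=(n, d)).astype(float),
            rng.integers(0, 6, size=(m, d)).astype(float))


class TestMatrix:
    def test_identical_constant_series_fully_recurrent(self):
        a = np.full((20, 3), 2.0)
        crp = cross_recurrence_matrix(a, a, CRQAConfig())
        assert crp.all()

    def test_manhattan_distance_two_strict_vs_inclusive(self):
        f1 = np.array([[0.0, 0.0, 0.0]])
        f2 = np.array([[2.0, 0.0, 0.0]])
        strict = cross_recurrence_matrix(f1, f2, CRQAConfig(theta_convention="strict"))
        inclusive = cross_recurrence_matrix(f1, f2, CRQAConfig(theta_convention="inclusive"))
        assert strict[0, 0] == 0
        assert inclusive[0, 0] == 1

    def test_channel_mismatch_is_an_error(self):
        with pytest.raises(ValueError, match="mismatch"):
            cross_recurrence_matrix(np.zeros((4, 3)), np.zeros((4, 2)))

    def test_matches_brute_force_on_random_pairs(self, rng):
        for _ in range(100):
            a, b = random_pair(rng)
            got = cross_recurrence_matrix(a, b, CRQAConfig())
            np.testing.assert_array_equal(got, brute_crp(a, b, 2.0, True))

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_crr_monotone_in_eps(self, seed):
        rng = np.random.default_rng(seed)
        a, b = random_pair(rng, max_len=20)
        last = -1.0
        for eps in (0.5, 1.0, 2.0, 4.0, 8.0):
            crp = cross_recurrence_matrix(a, b, CRQAConfig(eps=eps))
            crr = crqa_measures(crp, CRQAConfig(eps=eps)).crr
            assert crr >= last
            last = crr


class TestHistogram:
    def test_all_ones_10x10_by_hand(self):
        hist = diagonal_histogram(np.ones((10, 10), dtype=int))
        # main diagonal: one line of 10; offsets +/-k: one line of 10-k each
        expected = {10: 1}
        expected.update({l: 2 for l in range(1, 10)})
        assert hist == expected

    def test_all_zero_matrix_empty(self):
        assert diagonal_histogram(np.zeros((6, 8), dtype=int)) == {}

    def test_identity_matrix(self):
        assert diagonal_histogram(np.eye(5, dtype=int)) == {5: 1}

    def test_matches_brute_force_scan(self, rng):
        for _ in range(50):
            crp = (rng.random((rng.integers(1, 30), rng.integers(1, 30)))
                   < 0.35).astype(int)
            assert diagonal_histogram(crp) == brute_diagonal_histogram(crp)


class TestMeasures:
    def test_identical_constant_150_frames(self):
        a = np.full((150, 3), 1.0)
        crp = cross_recurrence_matrix(a, a, CRQAConfig())
        res = crqa_measures(crp, CRQAConfig())
        assert res.crr == 100.0
        assert res.l_max == 150
        # the fully recurrent plot is deterministic up to its corner
        # diagonals, which are shorter than l_min = 8 and contribute
        # 2 * (1 + ... + 7) = 56 of the 150^2 recurrent points
        assert res.det_normalized == pytest.approx((22500 - 56) / 22500)
        assert round(res.det_normalized) == 1
        assert not res.defined_empty

    def test_empty_recurrence_all_zero_with_flag(self):
        res = crqa_measures(np.zeros((10, 10), dtype=int))
        assert res.defined_empty
        assert res.crr == res.l_avg == res.l_max == res.det == 0

    def test_l_zero_when_no_line_reaches_minimum(self):
        crp = np.eye(5, dtype=int)  # longest line 5 < l_min 8
        res = crqa_measures(crp, CRQAConfig(l_min=8))
        assert not res.has_lines and res.l_avg == 0.0
        assert res.l_max == 5

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(100):
            crp = (rng.random((rng.integers(1, 40), rng.integers(1, 40)))
                   < rng.uniform(0.1, 0.9)).astype(int)
            cfg = CRQAConfig(l_min=int(rng.integers(1, 10)))
            got = crqa_measures(crp, cfg)
            ref = brute_crqa(crp, cfg.l_min)
            assert got.crr == pytest.approx(ref["crr"])
            assert got.l_avg == pytest.approx(ref["l_avg"])
            assert got.l_max == ref["l_max"]
            assert got.det_normalized == pytest.approx(ref["det_normalized"])
            assert got.det_as_printed == pytest.approx(ref["det_as_printed"])

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_conservation_symmetry_and_bounds(self, seed):
        rng = np.random.default_rng(seed)
        crp = (rng.random((rng.integers(2, 30), rng.integers(2, 30)))
               < 0.4).astype(int)
        cfg = CRQAConfig(l_min=4)
        res = crqa_measures(crp, cfg)
        # conservation: sum_l l P(l) equals the recurrent point count
        assert sum(l * c for l, c in res.histogram.items()) == res.n_recurrent
        assert res.n_recurrent == round(res.crr / 100.0 * res.n * res.m)
        # symmetry under transposition
        res_t = crqa_measures(crp.T, cfg)
        assert res_t.crr == pytest.approx(res.crr)
        assert res_t.l_avg == pytest.approx(res.l_avg)
        assert res_t.l_max == res.l_max
        assert res_t.det_normalized == pytest.approx(res.det_normalized)
        # bound chain when qualifying lines exist
        if res.has_lines:
            assert cfg.l_min <= res.l_avg <= res.l_max <= min(res.n, res.m)
        assert 0.0 <= res.det_normalized <= 1.0


class TestSnippetAndAggregation:
    def test_emotion_union_channel_policy(self):
        cfg = CRQAConfig()
        assert cfg.channels_for("fear") == ("AU1", "AU2", "AU4", "AU20")
        assert cfg.channels_for("anger") == ("AU4",)

    def test_perfect_copy_recurs_fully_on_the_main_diagonal(self):
        # an exact copy of a *non-constant* stimulus matches itself at
        # every lag-0 pair (L_max = N) but not across onset vs apex frames,
        # so cRR stays below 100; a constant trajectory is the only case
        # with full recurrence (covered in TestMeasures)
        from facemimic.cohort import default_templates, generate_stimulus_series
        stim = generate_stimulus_series(default_templates()["happiness"])
        res = snippet_crqa(stim, stim, "happiness", CRQAConfig(),
                           smooth_window=10)
        assert res.l_max == 150
        assert 0 < res.crr < 100.0
        assert res.det_normalized > 0.99

    def test_aggregate_single_and_mean(self):
        df = pd.DataFrame({
            "participant_id": ["P01", "P01", "P02"],
            "group": ["morph"] * 3,
            "embodiment": ["virtual"] * 3,
            "emotion": ["anger", "fear", "anger"],
            "trial": [1, 1, 1],
            "cRR": [10.0, 30.0, 50.0],
            "L": [8.0, 10.0, 12.0],
            "Lmax": [20, 40, 60],
            "DET": [0.5, 0.7, 0.9],
        })
        agg = aggregate_instructed(df)
        p1 = agg[agg["participant_id"] == "P01"].iloc[0]
        assert p1["avg_cRR"] == pytest.approx(20.0)
        assert p1["avg_L"] == pytest.approx(9.0)
        assert p1["n_valid"] == 2
        p2 = agg[agg["participant_id"] == "P02"].iloc[0]
        assert p2["avg_cRR"] == pytest.approx(50.0)
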