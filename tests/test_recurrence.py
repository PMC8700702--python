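import numpy as np
import pytest

from conftest import make_symbols, random_symbols
from oracles import (
    brute_continuous_matrix,
    brute_cross_rr,
    brute_rqa,
    brute_symbolic_matrix,
)
from syncmap.embedding import embed
from syncmap.recurrence import (
    cross_recurrence_rate,
    permutation_null_cross_rr,
    radius_for_target_rr,
    rp_continuous,
    rp_cross,
    rp_symbolic,
    rqa_measures,
    windowed_rqa,
)


class TestRpSymbolic:
    def test_ababab_recurrences(self):
        rp = rp_symbolic(embed(make_symbols("ababab"), p=3))
        expected = np.zeros((4, 4), dtype=bool)
        np.fill_diagonal(expected, True)
        for i, j in [(0, 2), (2, 0), (1, 3), (3, 1)]:  # 1-based (1,3),(3,1),(2,4),(4,2)
            expected[i, j] = True
        np.testing.assert_array_equal(rp.matrix, expected)

    def test_all_distinct_is_identity(self):
        rp = rp_symbolic(embed(make_symbols("abcdef"), p=3))
        np.testing.assert_array_equal(rp.matrix, np.eye(4, dtype=bool))

    def test_matches_bruteforce(self, rng):
        s = random_symbols(rng, 200, n_symbols=5)
        e = embed(s, p=3)
        rp = rp_symbolic(e)
        np.testing.assert_array_equal(
            rp.matrix.astype(int), np.array(brute_symbolic_matrix(e.rows))
        )

    def test_symmetric_with_unit_diagonal(self, rng):
        s = random_symbols(rng, 80, n_symbols=4)
        m = rp_symbolic(embed(s, p=3)).matrix
        np.testing.assert_array_equal(m, m.T)
        assert m.diagonal().all()


class TestRpContinuous:
    def test_constant_series_all_ones(self):
        rp = rp_continuous(embed(np.ones(10), p=3), radius=0.5)
        assert rp.matrix.all()

    def test_tiny_radius_identity(self, rng):
        x = rng.permutation(np.arange(20.0))
        rp = rp_continuous(embed(x, p=3), radius=1e-12)
        np.testing.assert_array_equal(rp.matrix, np.eye(18, dtype=bool))

    def test_rr_at_10th_percentile_radius(self, rng):
        x = rng.normal(size=300)
        e = embed(x, p=3)
        r = radius_for_target_rr(e, target_rr=0.10)
        prof = rqa_measures(rp_continuous(e, radius=r))
        assert prof.RR == pytest.approx(0.10, abs=0.02)

    def test_nonfinite_errors(self):
        x = np.array([0.0, 1.0, np.nan, 2.0, 3.0])
        with pytest.raises(ValueError, match="finite"):
            rp_continuous(embed(x, p=3), radius=1.0)

    def test_rr_monotone_in_radius(self, rng):
        e = embed(rng.normal(size=100), p=3)
        rrs = [rqa_measures(rp_continuous(e, radius=r)).RR for r in (0.1, 0.5, 1.0, 2.0)]
        assert rrs == sorted(rrs)


class TestRpCross:
    def test_identical_series_equals_auto(self, rng):
        s = random_symbols(rng, 60, n_symbols=4)
        ea = embed(s, p=3)
        cross = rp_cross(ea, ea)
        auto = rp_symbolic(ea)
        np.testing.assert_array_equal(cross.matrix, auto.matrix)
        assert cross.matrix.diagonal().all()

    def test_disjoint_alphabets_all_zero(self):
        a = make_symbols("aaaa")
        b = make_symbols("bbbb")
        assert not rp_cross(embed(a, p=3), embed(b, p=3)).matrix.any()

    def test_transpose_duality(self, rng):
        a = random_symbols(rng, 50, n_symbols=4)
        b = random_symbols(rng, 70, n_symbols=4)
        mab = rp_cross(embed(a, p=3), embed(b, p=3)).matrix
        mba = rp_cross(embed(b, p=3), embed(a, p=3)).matrix
        np.testing.assert_array_equal(mab, mba.T)

    def test_mismatched_embedding_errors(self, rng):
        a = random_symbols(rng, 50)
        with pytest.raises(ValueError, match="embedding parameters"):
            rp_cross(embed(a, p=3), embed(a, p=2))


class TestRqaMeasures:
    def test_constant_series(self):
        # All cells recur. With the main diagonal Theiler-excluded the two
        # corner cells sit on length-1 diagonals, so strict line accounting
        # gives DET = 10/12 (confirmed by the brute-force oracle below).
        prof = rqa_measures(rp_symbolic(embed(make_symbols("aaaaaa"), p=3)))
        assert prof.RR == 1.0
        assert prof.DET == pytest.approx(10 / 12)
        assert prof.Lmax == 3
        want = brute_rqa(
            brute_symbolic_matrix(embed(make_symbols("aaaaaa"), p=3).rows),
            kind="auto", theiler_w=1,
        )
        assert prof.DET == pytest.approx(want["DET"], abs=1e-15)

    def test_constant_series_no_theiler_rr(self):
        rp = rp_symbolic(embed(make_symbols("aaaaaa"), p=3), theiler_w=0)
        prof = rqa_measures(rp)
        assert prof.RR == 1.0 and not prof.degenerate

    def test_ababab_hand_count(self):
        prof = rqa_measures(rp_symbolic(embed(make_symbols("ababab"), p=3)))
        assert prof.RR == pytest.approx(1 / 3)
        assert prof.DET == 1.0
        assert prof.ENT == 0.0
        assert prof.Lmax == 2

    def test_zero_recurrences_flagged(self):
        prof = rqa_measures(rp_symbolic(embed(make_symbols("abcdefg"), p=3)))
        assert prof.RR == 0.0 and prof.DET == 0.0 and prof.degenerate

    def test_symbolic_oracle_equivalence(self, rng):
        for _ in range(5):
            s = random_symbols(rng, int(rng.integers(30, 150)), n_symbols=4)
            e = embed(s, p=3)
            got = rqa_measures(rp_symbolic(e)).as_dict()
            want = brute_rqa(brute_symbolic_matrix(e.rows), kind="auto", theiler_w=1)
            for key, val in want.items():
                assert got[key] == pytest.approx(val, abs=1e-12), key

    def test_continuous_oracle_equivalence(self, rng):
        x = np.cumsum(rng.normal(size=120))
        e = embed(x, p=3)
        r = radius_for_target_rr(e, 0.1)
        got = rqa_measures(rp_continuous(e, radius=r)).as_dict()
        want = brute_rqa(brute_continuous_matrix(e.rows, r), kind="auto", theiler_w=1)
        for key, val in want.items():
            assert got[key] == pytest.approx(val, abs=1e-12), key

    def test_cross_oracle_equivalence(self, rng):
        a = random_symbols(rng, 90, n_symbols=4)
        b = random_symbols(rng, 110, n_symbols=4)
        rp = rp_cross(embed(a, p=3), embed(b, p=3))
        got = rqa_measures(rp).as_dict()
        want = brute_rqa(
            brute_symbolic_matrix(embed(a, p=3).rows, embed(b, p=3).rows), kind="cross"
        )
        for key, val in want.items():
            assert got[key] == pytest.approx(val, abs=1e-12), key


class TestCrossRecurrenceRate:
    def test_histogram_identity_matches_bruteforce(self, rng):
        a = random_symbols(rng, 150, n_symbols=5)
        b = random_symbols(rng, 180, n_symbols=5)
        fast = cross_recurrence_rate(a, b, p=3)
        slow = brute_cross_rr(list(a.codes), list(b.codes), p=3)
        assert fast == pytest.approx(slow, abs=1e-15)

    def test_permutation_null_contains_uncoupled(self, rng):
        a = random_symbols(rng, 400, n_symbols=6)
        b = random_symbols(rng, 400, n_symbols=6)
        obs, null = permutation_null_cross_rr(a, b, n_shuffles=100, seed=rng)
        lo, hi = np.quantile(null, [0.025, 0.975])
        assert lo <= obs <= hi


class TestWindowedRqa:
    def test_window_arithmetic(self, rng):
        s = random_symbols(rng, 100)
        df = windowed_rqa(s, window=50, step=25, mode="symbolic")
        assert len(df) == 3
        np.testing.assert_allclose(df["t_center"], [24.5, 49.5, 74.5])

    def test_stationary_periodic_identical_profiles(self):
        s = make_symbols("abcabc" * 20)
        df = windowed_rqa(s, window=30, step=30, mode="symbolic")
        assert df["RR"].nunique() == 1
        assert df["DET"].nunique() == 1

    def test_periodic_then_random_halves(self, rng):
        periodic = make_symbols("abcdab" * 50).codes
        noise = rng.integers(0, 27, size=300)
        s = random_symbols(rng, 600)
        s.codes[:300] = periodic
        s.codes[300:] = noise
        df = windowed_rqa(s, window=100, step=100, mode="symbolic")
        first, last = df["DET"].iloc[:3], df["DET"].iloc[3:]
        assert first.min() > last.max()

    def test_zero_windows_errors(self, rng):
        with pytest.raises(ValueError, match="no complete window"):
            windowed_rqa(random_symbols(rng, 10), window=50, step=10)

    def test_continuous_mode_fixed_radius(self, rng):
        x = rng.normal(size=200)
        df = windowed_rqa(x, window=100, step=50, mode="continuous", radius=0.5)
        assert len(df) == 3
        assert (df["RR"] > 0).all()
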