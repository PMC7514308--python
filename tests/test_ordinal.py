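"""Ordinal symbolization: worked examples, tie rule, oracle agreement."""

import math
import warnings
from itertools import permutations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seachorus.ordinal import (
    OrdinalConfig,
    OrdinalWarning,
    index_to_pattern,
    ordinal_distribution,
    pattern_index,
    symbolize_window,
)


def brute_force_pattern(window: np.ndarray) -> tuple[int, ...]:
    """Independent oracle: test every permutation against the descending
    inequality chain v[r0] >= v[r1] >= ... (values indexed by time offset,
    offset 0 = most recent sample) and return the lexicographically largest
    satisfying permutation, which encodes earlier-sample-first tie-breaking."""
    d = len(window)
    by_offset = window[::-1]  # by_offset[r] = value at time offset r
    best = None
    for perm in permutations(range(d)):
        vals = [by_offset[r] for r in perm]
        if all(vals[i] >= vals[i + 1] for i in range(d - 1)):
            if best is None or perm > best:
                best = perm
    return best


class TestSymbolizeWindow:
    @pytest.mark.parametrize(
        "window, expected",
        [
            ((7, 3, 4, 5), (3, 0, 1, 2)),     # worked example, first vector
            ((3, 4, 5, 2), (1, 2, 3, 0)),     # worked example, second vector
            ((1, 2, 3, 4), (0, 1, 2, 3)),     # strictly increasing ramp
            ((5, 5, 5, 5), (3, 2, 1, 0)),     # constant: earlier sample wins ties
        ],
    )
    def test_reference_patterns(self, window, expected):
        pat = symbolize_window(window, OrdinalConfig(d=4))
        assert pat.ranks == expected

    def test_rejects_nonfinite_and_wrong_length(self):
        cfg = OrdinalConfig(d=4)
        with pytest.raises(FloatingPointError):
            symbolize_window((1.0, np.nan, 2.0, 3.0), cfg)
        with pytest.raises(ValueError):
            symbolize_window((1.0, 2.0, 3.0), cfg)

    @pytest.mark.parametrize("d", [3, 4, 5])
    def test_matches_brute_force_oracle(self, d, rng):
        cfg = OrdinalConfig(d=d)
        for i in range(1000):
            if i % 3 == 0:  # force ties regularly
                w = rng.integers(0, d, size=d).astype(float)
            else:
                w = rng.standard_normal(d)
            assert symbolize_window(w, cfg).ranks == brute_force_pattern(w)

    @given(st.lists(st.integers(-10**6, 10**6), min_size=4, max_size=4, unique=True))
    @settings(deadline=None, derandomize=True)
    def test_monotone_transform_invariance(self, window):
        cfg = OrdinalConfig(d=4)
        w = np.asarray(window, dtype=float)
        assert symbolize_window(w, cfg).ranks == symbolize_window(np.exp(w / 1e6), cfg).ranks


class TestPatternIndex:
    def test_lexicographic_endpoints(self):
        assert pattern_index((0, 1, 2, 3)) == 0
        assert pattern_index((3, 2, 1, 0)) == 23

    def test_round_trip_all_d6(self):
        for i in range(math.factorial(6)):
            pat = index_to_pattern(i, 6)
            assert pattern_index(pat) == i

    def test_rejects_non_permutation(self):
        with pytest.raises(ValueError):
            pattern_index((0, 0, 1, 2))
        with pytest.raises(ValueError):
            index_to_pattern(720, 6)


class TestOrdinalDistribution:
    def test_worked_example_series(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", OrdinalWarning)
            dist = ordinal_distribution([7, 3, 4, 5, 2, 9], OrdinalConfig(d=4))
        assert dist.n_vectors == 3
        assert dist.n_patterns == 24  # the d = 4 state space has 4! symbols
        expected = {(3, 0, 1, 2), (1, 2, 3, 0), (0, 2, 3, 1)}  # third: window (4,5,2,9)
        found = {index_to_pattern(i, 4).ranks for i in np.flatnonzero(dist.counts)}
        assert found == expected
        np.testing.assert_allclose(dist.probs[dist.probs > 0], 1 / 3)

    def test_monotone_series_single_pattern(self):
        dist = ordinal_distribution(np.arange(1000.0), OrdinalConfig(d=6))
        assert np.count_nonzero(dist.probs) == 1
        assert dist.probs.max() == 1.0

    def test_iid_noise_is_equidistributed(self, rng):
        n = 100_000
        dist = ordinal_distribution(rng.random(n), OrdinalConfig(d=3))
        se = np.sqrt((1 / 6) * (5 / 6) / dist.n_vectors)
        np.testing.assert_allclose(dist.probs, 1 / 6, atol=3 * se)

    def test_distribution_invariant_under_exp(self, rng):
        x = rng.standard_normal(5000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", OrdinalWarning)
            d1 = ordinal_distribution(x, OrdinalConfig(d=4))
            d2 = ordinal_distribution(np.exp(x), OrdinalConfig(d=4))
        np.testing.assert_array_equal(d1.counts, d2.counts)

    def test_counts_match_oracle_on_short_series(self, rng):
        x = rng.standard_normal(200)
        cfg = OrdinalConfig(d=4, tau=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", OrdinalWarning)
            dist = ordinal_distribution(x, cfg)
        assert dist.n_vectors == 200 - (4 - 1) * 2
        expected = np.zeros(24, dtype=int)
        for s in range(dist.n_vectors):
            window = x[s : s + cfg.span : cfg.tau]
            expected[pattern_index(brute_force_pattern(window))] += 1
        np.testing.assert_array_equal(dist.counts, expected)

    def test_streaming_chunks_agree_with_single_pass(self, rng):
        x = rng.standard_normal(10_000)
        cfg = OrdinalConfig(d=5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", OrdinalWarning)
            whole = ordinal_distribution(x, cfg)
            chunked = ordinal_distribution(x, cfg, chunk_size=777)
        np.testing.assert_array_equal(whole.counts, chunked.counts)

    def test_nan_windows_skipped_not_imputed(self, rng):
        x = rng.standard_normal(500)
        x[100] = np.nan
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", OrdinalWarning)
            dist = ordinal_distribution(x, OrdinalConfig(d=4))
        assert dist.n_skipped == 4  # every vector touching the NaN
        assert dist.n_vectors == 497 - 4
        assert abs(dist.probs.sum() - 1.0) < 1e-12

    def test_short_series_warns_and_shorter_errors(self):
        with pytest.warns(OrdinalWarning, match="d!"):
            ordinal_distribution(np.arange(50.0), OrdinalConfig(d=4))
        with pytest.raises(ValueError):
            ordinal_distribution([1.0, 2.0], OrdinalConfig(d=4))
        with pytest.raises(ValueError):
            ordinal_distribution(np.full(100, np.nan), OrdinalConfig(d=3))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            OrdinalConfig(d=1)
        with pytest.raises(ValueError):
            OrdinalConfig(d=4, tau=0)
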