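"""Entropy, disequilibrium, statistical complexity and the C-H plane."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seachorus.complexity import (
    disequilibrium,
    global_complexity,
    jensen_shannon_divergence,
    limit_curves,
    max_jsd,
    normalized_entropy,
    shannon_entropy,
    statistical_complexity,
)
from seachorus.ordinal import OrdinalConfig, OrdinalWarning


def delta(m: int) -> np.ndarray:
    p = np.zeros(m)
    p[0] = 1.0
    return p


class TestEntropy:
    def test_delta_and_uniform(self):
        assert shannon_entropy(delta(24)) == 0.0
        assert shannon_entropy(np.full(24, 1 / 24)) == pytest.approx(math.log(24))
        assert normalized_entropy(np.full(720, 1 / 720)) == pytest.approx(1.0)
        assert normalized_entropy(delta(720)) == 0.0

    def test_two_atom_entropy(self):
        p = np.zeros(10)
        p[:2] = 0.5
        assert shannon_entropy(p) == pytest.approx(math.log(2))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            shannon_entropy([0.5, 0.6])
        with pytest.raises(ValueError):
            shannon_entropy([1.2, -0.2])
        with pytest.raises(ValueError):
            normalized_entropy([1.0])


class TestJensenShannon:
    def test_identical_distributions(self):
        p = np.full(6, 1 / 6)
        assert jensen_shannon_divergence(p, p) == pytest.approx(0.0, abs=1e-15)

    def test_m2_delta_vs_uniform(self):
        # direct evaluation: S[(0.75, 0.25)] - 0 - ln(2)/2
        expected = -(0.75 * math.log(0.75) + 0.25 * math.log(0.25)) - math.log(2) / 2
        got = jensen_shannon_divergence([1.0, 0.0], [0.5, 0.5])
        assert got == pytest.approx(expected)
        assert got == pytest.approx(0.2158, abs=5e-5)

    @pytest.mark.parametrize("m", [2, 6, 720])
    def test_closed_form_maximum_matches_direct_evaluation(self, m):
        direct = jensen_shannon_divergence(delta(m), np.full(m, 1 / m))
        assert max_jsd(m) == pytest.approx(direct, rel=1e-12)

    def test_symmetry_and_nonnegativity(self, rng):
        for _ in range(200):
            p = rng.dirichlet(np.ones(24))
            q = rng.dirichlet(np.ones(24))
            j_pq = jensen_shannon_divergence(p, q)
            assert j_pq >= -1e-15
            assert j_pq == pytest.approx(jensen_shannon_divergence(q, p), abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            jensen_shannon_divergence([0.5, 0.5], [1 / 3, 1 / 3, 1 / 3])


class TestComplexity:
    def test_extremes_have_zero_complexity(self):
        m = math.factorial(4)
        assert statistical_complexity(np.full(m, 1 / m)) == pytest.approx(0.0, abs=1e-14)
        assert statistical_complexity(delta(m)) == 0.0
        assert disequilibrium(delta(m)) == pytest.approx(1.0, rel=1e-12)
        assert disequilibrium(np.full(m, 1 / m)) == pytest.approx(0.0, abs=1e-14)

    def test_c_is_product_of_h_and_qj(self, rng):
        for _ in range(50):
            p = rng.dirichlet(np.ones(120))
            c = statistical_complexity(p)
            assert c == pytest.approx(normalized_entropy(p) * disequilibrium(p), rel=1e-12)
            assert 0.0 <= disequilibrium(p) <= 1.0

    def test_two_pattern_alternation_closed_form(self):
        # strict alternation visits exactly two ordinal patterns equally often
        x = np.tile([0.0, 1.0], 600)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", OrdinalWarning)
            pt = global_complexity(x, OrdinalConfig(d=3))
        m = 6
        assert pt.H == pytest.approx(math.log(2) / math.log(m), rel=1e-9)
        # independent closed form: mixture of the two-atom P with uniform
        s_mix = -(2 * (1 / 3) * math.log(1 / 3) + 4 * (1 / 12) * math.log(1 / 12))
        j = s_mix - math.log(2) / 2 - math.log(m) / 2
        c_expected = (j / max_jsd(m)) * (math.log(2) / math.log(m))
        assert pt.C == pytest.approx(c_expected, rel=1e-9)

    def test_monotone_ramp_is_fully_ordered(self):
        pt = global_complexity(np.linspace(0, 1, 2000), OrdinalConfig(d=5))
        assert pt.H == 0.0
        assert pt.C == 0.0

    def test_noise_approaches_top_right_corner(self, rng):
        hs, cs = [], []
        for n in (10**3, 10**4, 10**5):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", OrdinalWarning)
                pt = global_complexity(rng.standard_normal(n), OrdinalConfig(d=4))
            hs.append(pt.H)
            cs.append(pt.C)
        assert hs[0] < hs[1] < hs[2]
        assert cs[0] > cs[1] > cs[2]
        assert hs[2] > 0.99

    def test_periodic_pulse_train_lowers_h_raises_c(self, rng):
        noise = 0.1 * rng.standard_normal(40_000)
        pulses = np.zeros_like(noise)
        t = np.arange(noise.size)
        pulses += np.sin(2 * np.pi * t / 7) * (np.sin(2 * np.pi * t / 800) > 0.5)
        base = global_complexity(noise, OrdinalConfig(d=6))
        mixed = global_complexity(noise + pulses, OrdinalConfig(d=6))
        assert mixed.H < base.H
        assert mixed.C > base.C


class TestLimitCurves:
    def test_curves_vanish_at_extremes_and_are_ordered(self):
        ref = limit_curves(4, n_grid=500)
        for curve in (ref.min_curve, ref.max_curve):
            h = curve[:, 0]
            assert curve[np.argmin(h), 1] == pytest.approx(0.0, abs=1e-6)
            assert curve[np.argmax(h), 1] == pytest.approx(0.0, abs=1e-6)
        h_grid = np.linspace(0.0, 1.0, 200)
        assert np.all(ref.c_min(h_grid) <= ref.c_max(h_grid) + 1e-9)

    def test_random_distributions_contained(self, rng):
        ref = limit_curves(4, n_grid=2000)
        pts = []
        for _ in range(2000):
            p = rng.dirichlet(np.ones(24))
            pts.append((normalized_entropy(p), statistical_complexity(p)))
        assert ref.contains(pts, tol=1e-3).all()

    def test_q0_matches_closed_form(self):
        ref = limit_curves(3, n_grid=200)
        assert ref.Q0 == pytest.approx(1.0 / max_jsd(6), rel=1e-12)
        assert ref.S_max == pytest.approx(math.log(6))

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            limit_curves(1)
        with pytest.raises(ValueError):
            limit_curves(4, n_grid=10)
        with pytest.raises(ValueError):
            limit_curves(9)  # 9! families are past the supported envelope size


@given(st.integers(2, 30))
@settings(deadline=None, derandomize=True)
def test_disequilibrium_bounds_any_m(m):
    rng = np.random.default_rng(m)
    p = rng.dirichlet(np.ones(m))
    q = disequilibrium(p)
    assert 0.0 <= q <= 1.0
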