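"""Unit and property tests for the parallel-hyperplane scoring chain."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitscore import (
    ModelError,
    ScorerParams,
    bounded_distance,
    check_constraints,
    hyperplane_positions,
    inverse_bounded_distance,
    piecewise_score,
    round_to_level,
    score,
    signed_distance,
)


def reference_score(x, w, c, p, bl=-0.5, bu=4.5):
    """Independent straight-line re-implementation of the score chain."""
    xhp = float(np.dot(w, x) + c)
    yrd = (bu - bl) / (1.0 + np.exp(-(xhp - (bu + bl) / 2.0))) + bl
    bounds = [bl, p[0], p[1], p[2], p[3], bu]
    for j in range(5):
        if bounds[j] < yrd <= bounds[j + 1] or (j == 4 and yrd > bounds[4]):
            return (yrd - bounds[j]) / (bounds[j + 1] - bounds[j]) + bl + j
    return bl  # yrd at/under bl cannot occur for finite xhp


class TestSignedDistance:
    def test_zero_params_give_zero(self, default_params):
        assert signed_distance([1.0, 2.0, 3.0], default_params) == 0.0

    def test_dot_product(self):
        params = ScorerParams(w=[1.0, 0.0], c=-1.0)
        assert signed_distance([3.0, 99.0], params) == pytest.approx(2.0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(7)
        w, c = rng.normal(size=3), rng.normal()
        params = ScorerParams(w=w, c=c)
        for _ in range(20):
            x = rng.normal(size=3)
            expected = sum(wk * xk for wk, xk in zip(w, x)) + c
            assert signed_distance(x, params) == pytest.approx(expected, abs=1e-12)

    def test_dimension_mismatch(self, default_params):
        with pytest.raises(ModelError):
            signed_distance([1.0, 2.0], default_params)


class TestBoundedDistance:
    def test_midpoint(self):
        assert bounded_distance(2.0) == pytest.approx(2.0)

    def test_limits(self):
        assert bounded_distance(1e3) == pytest.approx(4.5, abs=1e-9)
        assert bounded_distance(-1e3) == pytest.approx(-0.5, abs=1e-9)

    def test_value_at_zero(self):
        assert bounded_distance(0.0) == pytest.approx(5.0 / (1 + np.e**2) - 0.5)
        assert bounded_distance(0.0) == pytest.approx(0.09601, abs=5e-6)

    def test_strictly_increasing_and_inverse(self):
        x = np.linspace(-20, 20, 201)
        y = bounded_distance(x)
        assert np.all(np.diff(y) > 0)
        assert np.allclose(inverse_bounded_distance(y), x, atol=1e-8)


class TestPiecewiseScore:
    def test_demarcation_values(self, default_params):
        for i, p in enumerate(default_params.p):
            assert piecewise_score(p, default_params) == pytest.approx(i + 0.5)

    def test_default_p_is_identity(self, default_params):
        for yrd in np.linspace(-0.49, 4.49, 41):
            assert piecewise_score(yrd, default_params) == pytest.approx(yrd)

    def test_hand_evaluated_segment(self):
        params = ScorerParams(w=np.zeros(1), c=0.0, p=[0.2, 1.5, 2.5, 3.5])
        assert piecewise_score(-0.15, params) == pytest.approx(0.0)

    def test_out_of_range_rejected(self, default_params):
        for yrd in (-0.5, 4.5, -1.0, 5.0):
            with pytest.raises(ModelError):
                piecewise_score(yrd, default_params)

    def test_continuity_at_boundaries(self):
        params = ScorerParams(w=np.zeros(1), c=0.0, p=[0.1, 0.9, 2.7, 4.0])
        eps = 1e-9
        for p in params.p:
            below = piecewise_score(p - eps, params)
            at = piecewise_score(p, params)
            assert at == pytest.approx(below, abs=1e-6)


class TestScoreComposition:
    def test_zero_model_scores_sigmoid_value(self, default_params):
        y = score([5.0, -1.0, 2.0], default_params)
        assert y == pytest.approx(0.09601, abs=5e-6)

    def test_monotone_in_xhp(self):
        params = ScorerParams(w=[1.0], c=0.0, p=[0.2, 1.1, 2.9, 3.9])
        xs = np.linspace(-8, 8, 100)[:, None]
        ys = score(xs, params)
        assert np.all(np.diff(ys) > 0)

    def test_boundary_consistency(self):
        """A point exactly on hyperplane i scores i - 0.5."""
        params = ScorerParams(w=[2.0], c=0.3, p=[0.3, 1.2, 2.5, 4.1])
        for i, xhp in enumerate(hyperplane_positions(params)):
            x = [(xhp - params.c) / 2.0]
            assert score(x, params) == pytest.approx(i + 0.5, abs=1e-9)

    def test_extreme_inputs_stay_in_range(self):
        params = ScorerParams(w=[1.0], c=0.0)
        assert score([1e3], params) == pytest.approx(4.5, abs=1e-6)
        assert score([-1e3], params) == pytest.approx(-0.5, abs=1e-6)

    @settings(deadline=None, max_examples=200)
    @given(st.integers(0, 2**32 - 1))
    def test_matches_independent_reimplementation(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(1, 6))
        w = rng.normal(size=m)
        c = float(rng.normal())
        p = np.sort(rng.uniform(-0.5, 4.5, size=4))
        p += np.arange(4) * 1e-3  # ensure strict gaps
        if p[-1] > 4.5:
            p = np.linspace(p[0], 4.5 - 1e-6, 4)
        params = ScorerParams(w=w, c=c, p=p)
        x = rng.normal(size=m) * 3
        assert score(x, params) == pytest.approx(
            reference_score(x, w, c, p), abs=1e-10
        )


class TestRounding:
    @pytest.mark.parametrize(
        "y,expected",
        [(1.64, 2), (-0.3, 0), (2.5, 3), (0.49, 0), (0.5, 1), (4.49, 4), (-0.49, 0)],
    )
    def test_round_half_up(self, y, expected):
        assert round_to_level(y) == expected

    def test_vectorised(self):
        np.testing.assert_array_equal(
            round_to_level([0.2, 1.5, 3.7]), np.array([0, 2, 4])
        )


class TestConstraints:
    def test_default_ok(self, default_params):
        assert check_constraints(default_params) == []

    def test_p1_below_lower_bound(self):
        params = ScorerParams(w=np.zeros(2), c=0.0, p=[-0.6, 1.5, 2.5, 3.5])
        assert any("p1" in v for v in check_constraints(params))

    def test_p4_above_upper_bound(self):
        params = ScorerParams(w=np.zeros(2), c=0.0, p=[0.5, 1.5, 2.5, 4.6])
        assert any("p4" in v for v in check_constraints(params))

    def test_non_increasing_gap(self):
        params = ScorerParams(w=np.zeros(2), c=0.0, p=[0.5, 0.4, 2.5, 3.5])
        violations = check_constraints(params)
        assert any("p2" in v for v in violations)

    def test_every_violation_reported(self):
        params = ScorerParams(w=np.zeros(2), c=0.0, p=[-0.6, -0.7, 2.5, 4.8])
        assert len(check_constraints(params)) == 3
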