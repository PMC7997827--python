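"""Desirability scoring, ranking/selection and response-surface fitting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, settings, strategies as st

from mdoe.design import Design, DesignSpace, Factor
from mdoe.desirability import (
    DesirabilityConfig,
    combined_desirability,
    desirability_mean,
    desirability_var,
    fit_response_surface,
    rank_and_select,
    response_surface_grid,
    _quadratic_design_matrix,
)
from mdoe.errors import ConfigurationError, InvalidParameterError


class TestRescaling:
    def test_mean_anchors(self):
        d = desirability_mean(np.array([2.0, 5.0, 8.0]))
        assert d[0] == 0.0 and d[2] == 1.0
        assert d[1] == pytest.approx(0.5)

    def test_var_anchors_inverted(self):
        d = desirability_var(np.array([1.0, 3.0, 5.0]))
        assert d[0] == 1.0 and d[2] == 0.0
        assert d[1] == pytest.approx(0.5)

    def test_degenerate_anchors_warn_and_return_ones(self):
        with pytest.warns(UserWarning, match="degenerate"):
            d = desirability_mean(np.array([4.0, 4.0, 4.0]))
        np.testing.assert_array_equal(d, 1.0)

    def test_single_point_rejected(self):
        with pytest.raises(InvalidParameterError):
            desirability_mean(np.array([1.0]))

    @given(
        vals=st.lists(st.floats(-100, 100), min_size=2, max_size=20, unique=True),
        scale=st.floats(0.1, 10.0),
        shift=st.floats(-50, 50),
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_affine_invariance(self, vals, scale, shift):
        assume(max(vals) - min(vals) > 1e-3)  # spread must survive the shift
        base = desirability_mean(np.array(vals))
        transformed = desirability_mean(scale * np.array(vals) + shift)
        np.testing.assert_allclose(transformed, base, atol=1e-9)


class TestCombined:
    def test_weighted_sum_example(self):
        D = combined_desirability(
            np.array([0.5]), np.array([1.0]), DesirabilityConfig(w1=0.8, w2=0.2)
        )
        assert D[0] == pytest.approx(0.6)

    def test_all_ones_stay_one(self):
        D = combined_desirability(np.ones(3), np.ones(3), DesirabilityConfig(0.7, 0.3))
        np.testing.assert_allclose(D, 1.0)

    def test_degenerate_weight_returns_d_r(self):
        d_r = np.array([0.2, 0.9])
        D = combined_desirability(d_r, np.array([0.0, 0.0]), DesirabilityConfig(1.0, 0.0))
        np.testing.assert_array_equal(D, d_r)

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ConfigurationError):
            DesirabilityConfig(w1=0.8, w2=0.3)

    def test_weights_must_be_probabilities(self):
        with pytest.raises(ConfigurationError):
            DesirabilityConfig(w1=1.2, w2=-0.2)

    @given(
        seed=st.integers(0, 500),
        idx=st.integers(0, 7),
        bump=st.floats(0.001, 10.0),
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_monotonicity_in_mean_and_variability(self, seed, idx, bump):
        """Raising one r̄ᵢ never lowers its Dᵢ; raising νᵢ never raises it."""
        rng = np.random.default_rng(seed)
        rbar = rng.uniform(0, 10, 8)
        nu = rng.uniform(0, 5, 8)
        cfg = DesirabilityConfig()

        def score(r, v):
            # fixed anchors from the base vectors, per the invariant's setup
            d_r = (r - rbar.min()) / (rbar.max() - rbar.min())
            d_v = (v - nu.max()) / (nu.min() - nu.max())
            return cfg.w1 * d_r + cfg.w2 * d_v

        base = score(rbar, nu)[idx]
        r_up = rbar.copy()
        r_up[idx] += bump
        assert score(r_up, nu)[idx] >= base - 1e-12
        v_up = nu.copy()
        v_up[idx] += bump
        assert score(rbar, v_up)[idx] <= base + 1e-12


class TestRankAndSelect:
    @staticmethod
    def table(rbar, nu):
        return pd.DataFrame(
            {"exp_id": np.arange(1, len(rbar) + 1), "r_mean": rbar, "nu": nu}
        )

    def test_selects_top_n_by_D(self):
        t = self.table([1.0, 5.0, 3.0, 4.0, 2.0], [1.0, 1.0, 1.0, 1.0, 1.0])
        with pytest.warns(UserWarning):
            ranking = rank_and_select(t, DesirabilityConfig(n_select=2))
        assert set(ranking.selected["exp_id"]) == {2, 4}
        assert int(ranking.best["exp_id"]) == 2

    def test_tie_break_by_exp_id(self):
        t = self.table([1.0, 1.0, 1.0, 1.0], [2.0, 2.0, 2.0, 2.0])
        with pytest.warns(UserWarning):
            ranking = rank_and_select(t, DesirabilityConfig(n_select=2))
        assert list(ranking.selected["exp_id"]) == [1, 2]

    def test_dominant_point_ranks_first(self):
        t = self.table([1.0, 9.0, 2.0], [3.0, 0.5, 2.0])
        ranking = rank_and_select(t, DesirabilityConfig(n_select=1))
        assert int(ranking.best["exp_id"]) == 2
        assert ranking.best["D"] == pytest.approx(1.0)

    def test_desirabilities_in_unit_interval_with_anchors(self):
        rng = np.random.default_rng(1)
        t = self.table(rng.uniform(0, 50, 29), rng.uniform(0, 10, 29))
        ranking = rank_and_select(t, DesirabilityConfig(n_select=4))
        tbl = ranking.table
        for col in ("d_r", "d_v", "D"):
            assert tbl[col].between(0, 1).all()
        assert tbl["d_r"].max() == 1.0 and tbl["d_r"].min() == 0.0
        assert len(ranking.selected) == 4

    def test_cannot_select_more_than_available(self):
        t = self.table([1.0, 2.0], [0.1, 0.2])
        with pytest.raises(InvalidParameterError):
            rank_and_select(t, DesirabilityConfig(n_select=3))


@pytest.fixture
def space_2f():
    return DesignSpace(factors=(Factor("x1", 0, 1), Factor("x2", 0, 2)))


def design_from_points(space, pts):
    return Design(space=space, points=np.asarray(pts, dtype=float), n_random=0, seed=0)


class TestResponseSurface:
    def test_exact_quadratic_recovered(self, space_2f):
        rng = np.random.default_rng(0)
        pts = rng.uniform([0, 0], [1, 2], size=(15, 2))
        design = design_from_points(space_2f, pts)
        truth = np.array([0.3, 1.2, -0.7, 0.5, -0.4, 0.9])  # 1, x1, x2, x1x2, x1^2, x2^2
        D = _quadratic_design_matrix(pts) @ truth
        rs = fit_response_surface(design, D)
        np.testing.assert_allclose(rs.coefficients, truth, atol=1e-8)
        assert rs.r2 == pytest.approx(1.0)

    def test_constant_response_gives_intercept_only(self, space_2f):
        rng = np.random.default_rng(1)
        pts = rng.uniform([0, 0], [1, 2], size=(12, 2))
        design = design_from_points(space_2f, pts)
        rs = fit_response_surface(design, np.full(12, 0.42))
        assert rs.coefficients[0] == pytest.approx(0.42, abs=1e-10)
        np.testing.assert_allclose(rs.coefficients[1:], 0.0, atol=1e-10)

    def test_pure_linear_response(self, space_2f):
        rng = np.random.default_rng(2)
        pts = rng.uniform([0, 0], [1, 2], size=(12, 2))
        design = design_from_points(space_2f, pts)
        rs = fit_response_surface(design, 2.0 * pts[:, 0] + 0.1)
        named = dict(zip(rs.terms, rs.coefficients))
        assert named["x1"] == pytest.approx(2.0, abs=1e-8)
        for term in ("x1:x2", "x1^2", "x2^2"):
            assert named[term] == pytest.approx(0.0, abs=1e-8)

    def test_coefficient_count(self, space_2f):
        rng = np.random.default_rng(3)
        pts = rng.uniform([0, 0], [1, 2], size=(10, 2))
        rs = fit_response_surface(design_from_points(space_2f, pts), rng.uniform(size=10))
        f = 2
        assert len(rs.coefficients) == 1 + f + f * (f - 1) // 2 + f

    def test_rank_deficient_design_names_terms(self, space_2f):
        pts = np.column_stack([np.linspace(0, 1, 10), np.linspace(0, 2, 10)])  # x2 = 2*x1
        with pytest.raises(InvalidParameterError, match="confounded"):
            fit_response_surface(design_from_points(space_2f, pts), np.ones(10))

    def test_too_few_points_rejected(self, space_2f):
        pts = np.array([[0.1, 0.2], [0.5, 1.0], [0.9, 1.8]])
        with pytest.raises(InvalidParameterError):
            fit_response_surface(design_from_points(space_2f, pts), np.ones(3))

    def test_grid_export_shape_and_columns(self, space_2f):
        rng = np.random.default_rng(4)
        pts = rng.uniform([0, 0], [1, 2], size=(15, 2))
        design = design_from_points(space_2f, pts)
        rs = fit_response_surface(design, rng.uniform(size=15))
        grid = response_surface_grid(rs, design, "x1", "x2", fixed={}, n_grid=21)
        assert list(grid.columns) == ["x1", "x2", "D_fit"]
        assert len(grid) == 21 * 21
        assert grid["x1"].min() == 0.0 and grid["x2"].max() == 2.0
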