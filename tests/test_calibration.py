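"""Noise perturbation, goodness-of-fit metrics, quantiles and fitting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mdoe.calibration import (
    CalibrationConfig,
    MeasurementDataset,
    NoiseSpec,
    ParameterEnsemble,
    build_ensemble,
    dcw_weight_rule,
    fit_parameters,
    perturb_dataset,
    quantile_r7,
    r_squared,
    rmsd,
)
from mdoe.errors import InvalidParameterError
from mdoe.toy import generate_toy_dataset, toy_scenario


def make_dataset(obs_rows, initial=None, setpoints=None):
    return MeasurementDataset(
        observations=pd.DataFrame(obs_rows, columns=["observable", "time_h", "value", "sd"]),
        initial=initial or {},
        setpoints=setpoints or {},
    )


@pytest.fixture
def simple_dataset():
    rows = [("c_Glc", float(t), 10.0 - t, 0.2) for t in range(5)]
    rows += [("c_DCW", float(t), 2.0 + t, 0.1) for t in range(5)]
    return make_dataset(rows, initial={"c_Glc": (10.0, float("nan"))}, setpoints={"env.pH": (5.0, float("nan"))})


class TestPerturbDataset:
    def test_zero_sd_returns_identical_values(self):
        rows = [("c_Glc", float(t), 5.0, 0.0) for t in range(3)]
        d = make_dataset(rows)
        out = perturb_dataset(d, NoiseSpec(), seed=0)
        np.testing.assert_array_equal(out.observations["value"], d.observations["value"])

    def test_same_seed_is_deterministic(self, simple_dataset):
        a = perturb_dataset(simple_dataset, NoiseSpec(), seed=42)
        b = perturb_dataset(simple_dataset, NoiseSpec(), seed=42)
        pd.testing.assert_frame_equal(a.observations, b.observations)
        assert a.initial == b.initial and a.setpoints == b.setpoints

    def test_relative_noise_magnitude(self):
        """1e5 draws of one value at 5% relative sd: empirical cv = 0.05 +- 0.002."""
        rows = [("y", float(t), 10.0, float("nan")) for t in range(2)]
        d = make_dataset(rows)
        noise = NoiseSpec(measurement_rel=0.05)
        rng = np.random.default_rng(7)
        draws = np.array(
            [perturb_dataset(d, noise, rng).observations["value"].iloc[0] for _ in range(50_000)]
        )
        assert draws.std() / draws.mean() == pytest.approx(0.05, abs=0.002)

    def test_draws_never_negative(self):
        rows = [("y", 0.0, 0.05, 0.5), ("y", 1.0, 0.05, 0.5)]  # sd >> mean
        d = make_dataset(rows)
        rng = np.random.default_rng(1)
        for _ in range(200):
            out = perturb_dataset(d, NoiseSpec(), rng)
            assert (out.observations["value"] >= 0).all()

    def test_compartment_split_uses_10_percent(self):
        d = make_dataset(
            [("y", 0.0, 1.0, 0.0), ("y", 1.0, 1.0, 0.0)],
            initial={"X_pri": (10.0, float("nan")), "c_Glc": (10.0, float("nan"))},
        )
        rng = np.random.default_rng(3)
        xs, gs = [], []
        for _ in range(4000):
            out = perturb_dataset(d, NoiseSpec(), rng)
            xs.append(out.initial["X_pri"][0])
            gs.append(out.initial["c_Glc"][0])
        assert np.std(xs) / np.mean(xs) == pytest.approx(0.10, abs=0.01)
        assert np.std(gs) / np.mean(gs) == pytest.approx(0.05, abs=0.005)


class TestRmsd:
    def test_perfect_fit_is_zero(self, simple_dataset):
        sim = {o: simple_dataset.values(o) for o in simple_dataset.observables}
        assert rmsd(sim, simple_dataset) == 0.0

    def test_four_unit_residuals(self):
        d = make_dataset([("y", float(t), 1.0, 0.0) for t in range(4)])
        sim = {"y": np.zeros(4)}
        assert rmsd(sim, d) == pytest.approx(1.0, rel=1e-12)

    def test_dense_culture_rule_halves_weight(self):
        d = make_dataset([("c_DCW", 0.0, 120.0, 0.0), ("c_DCW", 1.0, 120.0, 0.0)])
        sim = {"c_DCW": np.array([122.0, 120.0])}
        # one residual of 2, weight 0.5, pooled over 2 points: sqrt(4*0.5/2)
        assert rmsd(sim, d) == pytest.approx(np.sqrt(4 * 0.5 / 2), rel=1e-12)

    def test_weight_rule_thresholds(self):
        assert dcw_weight_rule("c_DCW", 120.0) == 0.5
        assert dcw_weight_rule("c_DCW", 80.0) == 1.0
        assert dcw_weight_rule("c_Glc", 500.0) == 1.0

    @given(st.data())
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_matches_brute_force_oracle(self, data):
        """Pooled weighted RMSD equals a plain-Python recomputation."""
        n_obs = data.draw(st.integers(1, 3))
        rows, sims = [], {}
        for j in range(n_obs):
            n = data.draw(st.integers(2, 6))
            name = f"obs{j}"
            vals = [data.draw(st.floats(0.0, 200.0)) for _ in range(n)]
            sim = [data.draw(st.floats(0.0, 200.0)) for _ in range(n)]
            rows += [(name, float(t), v, 0.0) for t, v in enumerate(vals)]
            sims[name] = np.array(sim)
        d = make_dataset(rows)
        # oracle: explicit loop following the weighted-RMSD definition
        sq, count = 0.0, 0
        for name in sorted(sims):
            for y_m, y_s in zip(d.values(name), sims[name]):
                w = 0.5 if name == "c_DCW" and y_m > 100 else 1.0
                sq += w * (y_s - y_m) ** 2
                count += 1
        expected = np.sqrt(sq / count)
        assert rmsd(sims, d) == pytest.approx(expected, abs=1e-12, rel=1e-12)

    def test_empty_dataset_rejected(self):
        empty = MeasurementDataset(
            observations=pd.DataFrame(columns=["observable", "time_h", "value", "sd"])
        )
        with pytest.raises(InvalidParameterError):
            rmsd({}, empty)


class TestRSquared:
    def test_perfect_fit(self):
        y = np.array([1.0, 2.0, 3.0])
        assert r_squared(y, y) == pytest.approx(1.0)

    def test_mean_prediction_scores_zero(self):
        y = np.array([1.0, 2.0, 3.0])
        assert r_squared(np.full(3, 2.0), y) == pytest.approx(0.0, abs=1e-12)

    def test_worse_than_mean_is_negative(self):
        y = np.array([1.0, 2.0, 3.0])
        assert r_squared(np.array([3.0, 1.0, -1.0]), y) < 0

    def test_zero_variance_undefined(self):
        assert np.isnan(r_squared(np.array([1.0, 2.0]), np.array([5.0, 5.0])))

    @given(
        scale=st.floats(0.1, 50.0), shift=st.floats(-100, 100),
        seed=st.integers(0, 1000),
    )
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_affine_invariance(self, scale, shift, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(size=8)
        s = y + rng.normal(scale=0.3, size=8)
        base = r_squared(s, y)
        transformed = r_squared(scale * s + shift, scale * y + shift)
        assert transformed == pytest.approx(base, rel=1e-9, abs=1e-9)


class TestQuantileR7:
    def test_one_to_ten_at_p01(self):
        assert quantile_r7(range(1, 11), 0.1) == pytest.approx(1.9, abs=1e-12)

    def test_p0_is_min_and_p1_is_max(self):
        x = [3.2, -1.0, 7.5, 0.0]
        assert quantile_r7(x, 0.0) == -1.0
        assert quantile_r7(x, 1.0) == 7.5

    @given(
        vals=st.lists(st.floats(-1e3, 1e3), min_size=1, max_size=40),
        p=st.floats(0.0, 1.0),
    )
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_matches_linear_interpolation_oracle(self, vals, p):
        """R-7 equals explicit interpolation at h = (n-1)p + 1 on sorted data."""
        x = sorted(vals)
        h = (len(x) - 1) * p + 1  # one-based h of the R definition
        lo = int(np.floor(h))
        frac = h - lo
        expected = x[lo - 1] + frac * (x[min(lo, len(x) - 1)] - x[lo - 1])
        assert quantile_r7(vals, p) == pytest.approx(expected, rel=1e-12, abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(InvalidParameterError):
            quantile_r7([], 0.5)


class TestFitParameters:
    def test_zero_iteration_budget_returns_start_point(self):
        sc = toy_scenario()
        d = generate_toy_dataset(seed=0)
        cfg = CalibrationConfig(free_params=("q_max", "Y_XS"), maxiter=0)
        values, score, ok = fit_parameters(sc, d, cfg, seed=0)
        assert values["q_max"] == sc.params["q_max"]
        assert values["Y_XS"] == sc.params["Y_XS"]
        assert score > 0 and ok

    def test_noise_free_self_consistency(self):
        """Fitting noise-free data from known parameters recovers them within 1%."""
        sc = toy_scenario()
        d = generate_toy_dataset(seed=0, rel_sd=0.0)
        cfg = CalibrationConfig(free_params=("q_max", "Y_XS"), n_starts=2, maxiter=200)
        values, score, _ = fit_parameters(sc, d, cfg, seed=1)
        assert values["q_max"] == pytest.approx(sc.params["q_max"], rel=0.01)
        assert values["Y_XS"] == pytest.approx(sc.params["Y_XS"], rel=0.01)

    def test_result_respects_bounds(self):
        sc = toy_scenario()
        d = generate_toy_dataset(seed=2)
        cfg = CalibrationConfig(free_params=("q_max",), n_starts=1, maxiter=50)
        values, _, _ = fit_parameters(sc, d, cfg, seed=0)
        lo, hi = sc.params.bounds["q_max"]
        assert lo <= values["q_max"] <= hi


@pytest.fixture(scope="module")
def toy_ensemble():
    sc = toy_scenario()
    d = generate_toy_dataset(seed=5)
    cfg = CalibrationConfig(
        free_params=("q_max", "Y_XS"), n_fits=8, n_starts=1, maxiter=60, seed=9
    )
    return build_ensemble(sc, d, NoiseSpec(), cfg), sc


class TestBuildEnsemble:
    def test_ensemble_size_equals_n_fits(self, toy_ensemble):
        ens, _ = toy_ensemble
        assert len(ens.members) == 8

    def test_quantile_ordering_and_bound_containment(self, toy_ensemble):
        ens, sc = toy_ensemble
        q = ens.quantiles()
        assert (q["q10"] <= q["median"]).all() and (q["median"] <= q["q90"]).all()
        for name in ens.parameter_names:
            lo, hi = sc.params.bounds[name]
            assert ((ens.members[name] >= lo) & (ens.members[name] <= hi)).all()

    def test_seed_determinism(self, toy_ensemble):
        ens, sc = toy_ensemble
        d = generate_toy_dataset(seed=5)
        cfg = CalibrationConfig(
            free_params=("q_max", "Y_XS"), n_fits=8, n_starts=1, maxiter=60, seed=9
        )
        again = build_ensemble(sc, d, NoiseSpec(), cfg)
        pd.testing.assert_frame_equal(ens.members, again.members)

    def test_zero_noise_collapses_ensemble(self):
        sc = toy_scenario()
        d = generate_toy_dataset(seed=0, rel_sd=0.0)
        zero = NoiseSpec(measurement_rel=0.0, initial_rel=0.0, compartment_rel=0.0, setpoint_rel=0.0)
        cfg = CalibrationConfig(free_params=("q_max",), n_fits=3, n_starts=1, maxiter=120, seed=4)
        ens = build_ensemble(sc, d, zero, cfg)
        q = ens.quantiles()
        assert q.loc["q_max", "q90"] - q.loc["q_max", "q10"] == pytest.approx(0.0, abs=1e-3)
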