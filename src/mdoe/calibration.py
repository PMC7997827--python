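"""Monte-Carlo parameter-uncertainty quantification.

The measured data, the initial values and the setpoints are repeatedly
perturbed according to their experimental uncertainty (independent normal
noise; 5% relative on measurements/initial values/setpoints by default, 10%
on the unobservable biomass-compartment split), and the model parameters
are re-fitted to every perturbed replicate by minimizing a weighted
root-mean-square deviation

    RMSD = sqrt( sum_i (y_s,i − y_m,i)^2 * k_weighting / n ),

where ``k_weighting`` down-weights (0.5) dry-cell-weight points above
100 g/l and is 1 otherwise.  The resulting ensemble of parameter vectors is
summarized by its median and the 10%/90% quantiles (type R-7), which later
bound the Latin-Hypercube draws of the design-evaluation stage.  Fit quality
is scored by the coefficient of determination R².
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from mdoe.errors import CalibrationError, EnsembleError, InvalidParameterError, MdoeError
from mdoe.scenario import Scenario


@dataclass
class MeasurementDataset:
    """Time-series measurements plus uncertain initial values and setpoints.

    ``observations`` has columns ``observable, time_h, value, sd`` (native
    units).  ``initial`` maps state names to ``(value, sd)``; ``setpoints``
    maps dotted scenario paths (see :class:`mdoe.scenario.Scenario`) to
    ``(value, sd)``.  An ``sd`` of NaN means "use the relative default from
    the noise specification".
    """

    observations: pd.DataFrame
    initial: dict[str, tuple[float, float]] = field(default_factory=dict)
    setpoints: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        required = {"observable", "time_h", "value", "sd"}
        missing = required - set(self.observations.columns)
        if missing:
            raise InvalidParameterError(f"observations missing columns {sorted(missing)}")
        sds = pd.to_numeric(self.observations["sd"], errors="coerce").to_numpy(dtype=float)
        if np.any(sds[~np.isnan(sds)] < 0):
            raise InvalidParameterError("negative measurement sd")
        counts = self.observations.groupby("observable").size()
        if (counts < 2).any():
            bad = counts[counts < 2].index.tolist()
            raise InvalidParameterError(f"observables with < 2 points: {bad}")

    @property
    def observables(self) -> list[str]:
        return sorted(self.observations["observable"].unique())

    def times(self, observable: str) -> np.ndarray:
        mask = self.observations["observable"] == observable
        return self.observations.loc[mask, "time_h"].to_numpy()

    def values(self, observable: str) -> np.ndarray:
        mask = self.observations["observable"] == observable
        return self.observations.loc[mask, "value"].to_numpy()


@dataclass(frozen=True)
class NoiseSpec:
    """Relative standard deviations of the experimental uncertainty model."""

    measurement_rel: float | None = None  # None: use per-point sd column
    initial_rel: float = 0.05
    compartment_rel: float = 0.10
    setpoint_rel: float = 0.05

    def __post_init__(self):
        for v in (self.measurement_rel or 0.0, self.initial_rel, self.compartment_rel, self.setpoint_rel):
            if v < 0:
                raise InvalidParameterError("relative sd must be >= 0")


def _draw_nonnegative(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Normal draw re-drawn until non-negative (truncated, not clipped)."""
    if sd == 0:
        return mean
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if v >= 0:
            return float(v)
    return max(mean, 0.0)


def perturb_dataset(
    d: MeasurementDataset, noise: NoiseSpec, seed: int | np.random.Generator
) -> MeasurementDataset:
    """One noisy replicate of a dataset, deterministic under the seed.

    Measured values, initial values (5% default; 10% for biomass
    compartments, whose split cannot be measured) and setpoints (5%) are
    each replaced by an independent normal draw centered on the original.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    obs = d.observations.copy()
    new_vals = []
    for v, sd in zip(obs["value"], obs["sd"]):
        if noise.measurement_rel is not None:
            sd = noise.measurement_rel * abs(v)
        elif np.isnan(sd):
            sd = 0.0
        new_vals.append(_draw_nonnegative(rng, v, sd))
    obs["value"] = new_vals

    initial = {}
    for name, (v, sd) in d.initial.items():
        rel = noise.compartment_rel if name.startswith("X_") else noise.initial_rel
        eff_sd = rel * abs(v) if np.isnan(sd) else sd
        initial[name] = (_draw_nonnegative(rng, v, eff_sd), sd)
    setpoints = {}
    for path, (v, sd) in d.setpoints.items():
        eff_sd = noise.setpoint_rel * abs(v) if np.isnan(sd) else sd
        setpoints[path] = (_draw_nonnegative(rng, v, eff_sd), sd)
    return MeasurementDataset(observations=obs, initial=initial, setpoints=setpoints)


# --------------------------------------------------------------------------
# goodness of fit
# --------------------------------------------------------------------------

WeightRule = Callable[[str, float], float]


def dcw_weight_rule(observable: str, measured: float) -> float:
    """Down-weight very dense culture points: 0.5 for c_DCW > 100 g/l, else 1."""
    return 0.5 if observable == "c_DCW" and measured > 100.0 else 1.0


def rmsd(
    sim: Mapping[str, np.ndarray],
    meas: MeasurementDataset,
    weight_rule: WeightRule = dcw_weight_rule,
    normalize: bool = False,
) -> float:
    """Weighted root-mean-square deviation pooled over all observables.

    ``sim`` maps observable name to simulated values aligned with that
    observable's measurement times.  With ``normalize=True`` residuals of
    each observable are divided by the mean measured magnitude first, which
    makes the pooled sum unit-consistent across observables of very
    different scales.
    """
    if len(meas.observations) == 0:
        raise InvalidParameterError("empty dataset")
    sq = 0.0
    n = 0
    for obs_name in meas.observables:
        y_m = meas.values(obs_name)
        y_s = np.asarray(sim[obs_name], dtype=float)
        if y_s.shape != y_m.shape:
            raise InvalidParameterError(
                f"simulated series for {obs_name!r} has shape {y_s.shape}, expected {y_m.shape}"
            )
        scale = np.mean(np.abs(y_m)) if normalize else 1.0
        scale = scale if scale > 0 else 1.0
        w = np.array([weight_rule(obs_name, v) for v in y_m])
        sq += float(np.sum(w * ((y_s - y_m) / scale) ** 2))
        n += len(y_m)
    return float(np.sqrt(sq / n))


def r_squared(sim: np.ndarray, meas: np.ndarray) -> float:
    """Coefficient of determination, 1 − SS_res/SS_tot (NaN if var(meas)=0)."""
    sim = np.asarray(sim, dtype=float)
    meas = np.asarray(meas, dtype=float)
    if len(meas) < 2:
        raise InvalidParameterError("need >= 2 measurements")
    ss_tot = float(np.sum((meas - meas.mean()) ** 2))
    if ss_tot == 0:
        return float("nan")
    ss_res = float(np.sum((meas - sim) ** 2))
    return 1.0 - ss_res / ss_tot


def quantile_r7(sample: Sequence[float] | np.ndarray, p: float) -> float:
    """Type R-7 quantile: linear interpolation at h = (n−1)p + 1.

    This is the default of R's ``quantile`` and matches numpy's ``linear``
    method; it is implemented directly because the 10/90% interval bounds of
    the parameter ensemble are defined through it.
    """
    x = np.sort(np.asarray(sample, dtype=float))
    if x.size == 0:
        raise InvalidParameterError("empty sample")
    if not 0.0 <= p <= 1.0:
        raise InvalidParameterError(f"p = {p} outside [0, 1]")
    h = (x.size - 1) * p  # zero-based position of the R definition h-1
    lo = int(np.floor(h))
    hi = min(lo + 1, x.size - 1)
    return float(x[lo] + (h - lo) * (x[hi] - x[lo]))


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------


@dataclass
class CalibrationConfig:
    """Settings of the Monte-Carlo parameter adaptation."""

    free_params: tuple[str, ...]
    n_fits: int = 116  # adaptation count of the cultivation case study
    n_starts: int = 3
    start_jitter: float = 0.10  # relative jitter of multi-start points
    maxiter: int = 200
    seed: int = 0
    # pool residuals across observables after scaling by each observable's
    # mean measured magnitude (unit consistency); switch off for raw pooling
    normalize: bool = True
    weight_rule: WeightRule = dcw_weight_rule
    fail_fraction_limit: float = 0.5

    def __post_init__(self):
        if self.n_fits < 1:
            raise InvalidParameterError("n_fits must be >= 1")
        if len(self.free_params) == 0:
            raise InvalidParameterError("no free parameters")


@dataclass
class ParameterEnsemble:
    """Fitted parameter vectors with medians and R-7 10/90% quantiles."""

    members: pd.DataFrame  # n_fits x free parameters
    rmsd: np.ndarray
    converged: np.ndarray
    bounds: dict[str, tuple[float, float]]

    @property
    def parameter_names(self) -> list[str]:
        return list(self.members.columns)

    def quantiles(self) -> pd.DataFrame:
        """Frame indexed by parameter with columns q10, median, q90."""
        rows = {}
        for name in self.members.columns:
            col = self.members[name].to_numpy()
            rows[name] = {
                "q10": quantile_r7(col, 0.10),
                "median": quantile_r7(col, 0.50),
                "q90": quantile_r7(col, 0.90),
            }
        return pd.DataFrame(rows).T[["q10", "median", "q90"]]

    def median_values(self) -> dict[str, float]:
        return {n: quantile_r7(self.members[n].to_numpy(), 0.5) for n in self.members.columns}


def _scenario_with_dataset(scenario: Scenario, d: MeasurementDataset) -> Scenario:
    """Push a dataset's (possibly perturbed) initial values and setpoints in."""
    assignments = {path: v for path, (v, _sd) in d.setpoints.items()}
    sc = scenario.apply(assignments) if assignments else scenario
    if d.initial:
        init = dict(sc.initial)
        init.update({k: v for k, (v, _sd) in d.initial.items()})
        sc = Scenario(sc.model, sc.params, init, sc.feeds, sc.env, sc.t_grid)
    return sc


def _objective_factory(scenario: Scenario, d: MeasurementDataset, cfg: CalibrationConfig):
    sc = _scenario_with_dataset(scenario, d)
    all_times = np.unique(d.observations["time_h"].to_numpy())
    t0 = min(0.0, all_times.min())
    t_grid = np.unique(np.concatenate([[t0], all_times, [sc.t_grid[-1]]]))
    sc = Scenario(sc.model, sc.params, sc.initial, sc.feeds, sc.env, t_grid)
    names = list(cfg.free_params)

    def objective(theta: np.ndarray) -> float:
        try:
            params = sc.params.replace(**dict(zip(names, theta)))
        except InvalidParameterError:
            return 1e9
        try:
            traj = sc.simulate(params)
        except MdoeError:
            return 1e9
        sim = {
            obs_name: np.array([traj.at_time(obs_name, t) for t in d.times(obs_name)])
            for obs_name in d.observables
        }
        return rmsd(sim, d, weight_rule=cfg.weight_rule, normalize=cfg.normalize)

    return objective


def fit_parameters(
    scenario: Scenario,
    d: MeasurementDataset,
    cfg: CalibrationConfig,
    seed: int | np.random.Generator = 0,
) -> tuple[dict[str, float], float, bool]:
    """Fit the free parameters to one dataset by bounded RMSD minimization.

    A derivative-free simplex search (Nelder–Mead with box bounds) is run
    from ``cfg.n_starts`` start points — the nominal values plus jittered
    copies — and the best result is returned as
    ``(values, rmsd, converged)``.  A zero iteration budget returns the
    nominal start point with its RMSD (optimizer contract).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    names = list(cfg.free_params)
    bounds = scenario.params.subset_bounds(names)
    x0 = scenario.params.subset_vector(names)
    objective = _objective_factory(scenario, d, cfg)

    if cfg.maxiter == 0:
        return dict(zip(names, x0)), float(objective(x0)), True

    best = None
    for start in range(cfg.n_starts):
        if start == 0:
            xs = x0.copy()
        else:
            xs = x0 * (1.0 + cfg.start_jitter * rng.standard_normal(len(x0)))
        xs = np.clip(xs, [b[0] for b in bounds], [b[1] for b in bounds])
        try:
            res = minimize(
                objective,
                xs,
                method="Nelder-Mead",
                bounds=bounds,
                options={"maxiter": cfg.maxiter, "xatol": 1e-6, "fatol": 1e-8},
            )
        except MdoeError:
            continue
        if res.fun >= 1e9:
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise CalibrationError("all optimizer starts failed")
    theta = np.clip(best.x, [b[0] for b in bounds], [b[1] for b in bounds])
    return dict(zip(names, theta)), float(best.fun), bool(best.success)


def build_ensemble(
    scenario: Scenario,
    d: MeasurementDataset,
    noise: NoiseSpec,
    cfg: CalibrationConfig,
) -> ParameterEnsemble:
    """Perturb→fit ``cfg.n_fits`` times and summarize the parameter ensemble.

    Each cycle derives its own random stream from ``cfg.seed``, perturbs the
    dataset (measurements, initial values, setpoints and biomass-compartment
    split) and refits the free parameters to the replicate.  More than
    ``fail_fraction_limit`` failed fits abort with an error.
    """
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_fits)
    rows = []
    rmsds = []
    flags = []
    failures = 0
    for i in range(cfg.n_fits):
        rng = np.random.default_rng(seeds[i])
        replicate = perturb_dataset(d, noise, rng)
        try:
            values, score, ok = fit_parameters(scenario, replicate, cfg, rng)
        except CalibrationError:
            failures += 1
            continue
        rows.append(values)
        rmsds.append(score)
        flags.append(ok)
    if failures > cfg.fail_fraction_limit * cfg.n_fits:
        raise EnsembleError(f"{failures}/{cfg.n_fits} Monte-Carlo fits failed")
    members = pd.DataFrame(rows, columns=list(cfg.free_params))
    bounds = {n: scenario.params.bounds[n] for n in cfg.free_params}
    return ParameterEnsemble(
        members=members,
        rmsd=np.array(rmsds),
        converged=np.array(flags, dtype=bool),
        bounds=bounds,
    )
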