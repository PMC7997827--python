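"""Mechanistic fed-batch process model and trajectory simulation.

The framework is model-agnostic: any object satisfying the
:class:`ProcessModel` contract (state names, default parameters with bounds,
a right-hand side) can be simulated, calibrated and used for design
evaluation.  The bundled :class:`ReferenceYeastModel` is a structured
six-compartment description of *Saccharomyces cerevisiae* fed-batch
cultivation and whole-cell biocatalysis:

* biomass is segregated into six compartments — autocatalytically active
  (Xpri), product-forming (Xp), biocatalytically inactive (Xi), structurally
  active (Xs) and inactive (Xsi), and dead (Xd);
* substrate uptake follows Monod kinetics multiplied by double-sigmoid
  switches of stress variables (ethanol, biocatalysis educt, glucose,
  nitrogen, pH);
* each metabolic pathway (oxidative growth, overflow fermentation, ethanol
  oxidation, educt reduction) is a single elemental-balanced stoichiometric
  equation, so mass yields and off-gas (O2, CO2) follow from the balanced
  coefficients;
* general mass balances dc_i/dt = rc+·Xv − rc−·Xv + c_feed·F/V − c_i·F/V
  couple the kinetics to the fed-batch dilution terms.

Compartment transfers (activation, inactivation, mortality) are first-order
with rate constants gated by double sigmoids of the stress variables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Protocol, Sequence, runtime_checkable

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from mdoe.errors import InvalidParameterError, ModelEvaluationError, SimulationError
from mdoe.feeds import FeedSchedule, feed_rate, feed_rate_l_h, total_fed_volume
from mdoe.kinetics import SigmoidParams, dsig
from mdoe.stoichiometry import (
    AMMONIA,
    BIOMASS,
    CO2,
    E3HB,
    EAA,
    ETHANOL,
    GLUCOSE,
    OXYGEN,
    WATER,
    ElementalSpecies,
    PathwayStoichiometry,
    balance_pathway,
)


@dataclass(frozen=True)
class Environment:
    """Exogenous, time-constant setpoints of the cultivation."""

    pH: float = 5.0
    temperature: float = 30.0  # degC
    DO: float = 30.0  # % saturation

    def __post_init__(self):
        if not 0 < self.pH < 14:
            raise InvalidParameterError(f"pH {self.pH} outside (0, 14)")
        if not 0 <= self.DO <= 100:
            raise InvalidParameterError(f"DO {self.DO} outside [0, 100]")


@dataclass
class ModelParameters:
    """Named flat parameter vector with per-parameter [lower, upper] bounds."""

    values: dict[str, float]
    bounds: dict[str, tuple[float, float]]
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for name, v in self.values.items():
            lo, hi = self.bounds.get(name, (-np.inf, np.inf))
            if not lo <= v <= hi:
                raise InvalidParameterError(
                    f"parameter {name!r} = {v} outside bounds [{lo}, {hi}]"
                )

    def replace(self, **updates: float) -> "ModelParameters":
        unknown = set(updates) - set(self.values)
        if unknown:
            raise InvalidParameterError(f"unknown parameters {sorted(unknown)}")
        values = {**self.values, **updates}
        return ModelParameters(values, dict(self.bounds), dict(self.units))

    def subset_vector(self, names: Sequence[str]) -> np.ndarray:
        return np.array([self.values[n] for n in names], dtype=float)

    def subset_bounds(self, names: Sequence[str]) -> list[tuple[float, float]]:
        return [self.bounds[n] for n in names]

    def __getitem__(self, name: str) -> float:
        return self.values[name]


@dataclass
class ProcessState:
    """Reactor state at one time point (reference-model layout).

    Dissolved components in g/l, the six biomass compartments in g/l,
    volume in l, cumulative O2 consumed and CO2 produced in mol.
    """

    concentrations: dict[str, float]
    compartments: dict[str, float]
    V: float
    nO2: float = 0.0
    nCO2: float = 0.0

    COMPARTMENT_NAMES = ("X_pri", "X_p", "X_i", "X_s", "X_si", "X_d")

    def __post_init__(self):
        if self.V <= 0:
            raise InvalidParameterError(f"volume {self.V} must be > 0")
        for k, v in {**self.concentrations, **self.compartments}.items():
            if v < 0:
                raise InvalidParameterError(f"negative concentration {k} = {v}")

    @property
    def c_DCW(self) -> float:
        """Total dry cell weight: sum of all six compartments, g/l."""
        return float(sum(self.compartments.values()))

    def as_dict(self) -> dict[str, float]:
        return {
            **{f"c_{k}": v for k, v in self.concentrations.items()},
            **self.compartments,
            "V_l": self.V,
            "nO2_mol": self.nO2,
            "nCO2_mol": self.nCO2,
        }


@runtime_checkable
class ProcessModel(Protocol):
    """Plug-in contract: anything with state names, parameters and a RHS.

    ``rhs`` receives the raw state vector (ordered as ``state_names``), the
    parameter value mapping, the active feed schedules and the environment,
    and returns d(state)/dt.  ``derived_observables`` may add computed
    columns (e.g. total dry cell weight) to a trajectory frame.
    """

    name: str
    state_names: tuple[str, ...]

    def default_parameters(self) -> ModelParameters: ...

    def rhs(
        self,
        t: float,
        y: np.ndarray,
        params: Mapping[str, float],
        feeds: Sequence[FeedSchedule],
        env: Environment,
    ) -> np.ndarray: ...

    def derived_observables(self, frame: pd.DataFrame) -> pd.DataFrame: ...


@dataclass
class Trajectory:
    """Simulated time courses on a fixed grid.

    ``data`` columns: ``time_h``, every model state, and one
    ``F_<feed>_ml_min`` column per feed.  Gas totals (``nO2_mol``,
    ``nCO2_mol``) are cumulative since t0.
    """

    data: pd.DataFrame
    feeds: tuple[FeedSchedule, ...] = ()

    @property
    def time(self) -> np.ndarray:
        return self.data["time_h"].to_numpy()

    def series(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy()

    def at_time(self, name: str, t: float) -> float:
        """Linear interpolation of a column at time t."""
        return float(np.interp(t, self.time, self.series(name)))


def simulate(
    model: ProcessModel,
    params: ModelParameters | Mapping[str, float],
    initial: Mapping[str, float] | ProcessState,
    feeds: Sequence[FeedSchedule] = (),
    env: Environment = Environment(),
    t_grid: np.ndarray | Sequence[float] | None = None,
    rtol: float = 1e-6,
    atol: float = 1e-8,
) -> Trajectory:
    """Integrate a process model on ``t_grid`` (hours, strictly increasing).

    Feed ramp starts/ends and pulses are treated as integration breakpoints;
    pulse feeds apply an instantaneous volume/concentration jump.  The volume
    balance |V(t_end) − V(0) − ∫ΣF dt| closes within solver tolerance.
    """
    if t_grid is None:
        t_grid = np.linspace(0.0, 48.0, 97)
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 2 or np.any(np.diff(t_grid) <= 0):
        raise InvalidParameterError("t_grid must be strictly increasing with >= 2 points")

    pvals = params.values if isinstance(params, ModelParameters) else dict(params)
    if isinstance(initial, ProcessState):
        init_map = initial.as_dict()
    else:
        init_map = dict(initial)
    names = model.state_names
    missing = set(names) - set(init_map)
    if missing:
        raise InvalidParameterError(f"initial state missing {sorted(missing)}")
    y0 = np.array([init_map[n] for n in names], dtype=float)

    t0, t_end = float(t_grid[0]), float(t_grid[-1])

    # breakpoints: feed discontinuities and pulse events inside the horizon
    breaks: set[float] = set()
    pulse_events: list[tuple[float, FeedSchedule]] = []
    for f in feeds:
        if f.kind == "pulses":
            for tp, _vol in f.pulses:
                if t0 < tp < t_end:
                    breaks.add(tp)
                    pulse_events.append((tp, f))
        else:
            for tb in (f.t_start, f.t_end):
                if t0 < tb < t_end:
                    breaks.add(tb)
    pulse_events.sort(key=lambda e: e[0])
    segment_edges = np.unique(np.concatenate([[t0, t_end], sorted(breaks)]))

    def wrapped_rhs(t, y):
        dy = np.asarray(model.rhs(t, y, pvals, feeds, env), dtype=float)
        if not np.all(np.isfinite(dy)):
            bad = [names[i] for i in np.flatnonzero(~np.isfinite(dy))]
            raise ModelEvaluationError(f"non-finite derivative for {bad} at t={t:.4g}")
        return dy

    i_v = names.index("V_l") if "V_l" in names else None

    rows: list[np.ndarray] = []
    times: list[float] = []
    y = y0.copy()
    for a, b in zip(segment_edges[:-1], segment_edges[1:]):
        inner = t_grid[(t_grid >= a) & (t_grid <= b)]
        t_eval = np.unique(np.concatenate([[a], inner, [b]]))
        sol = solve_ivp(
            wrapped_rhs,
            (a, b),
            y,
            method="LSODA",
            t_eval=t_eval,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            last = float(sol.t[-1]) if len(sol.t) else a
            raise SimulationError(
                f"integration failed at t={last:.4g} h: {sol.message}", last_valid_time=last
            )
        for tt, yy in zip(sol.t, sol.y.T):
            if np.any((tt == t_grid)):
                times.append(float(tt))
                rows.append(yy.copy())
        y = sol.y[:, -1].copy()
        # apply any pulse scheduled exactly at this segment boundary
        for tp, f in pulse_events:
            if np.isclose(tp, b):
                vol = sum(v for tpp, v in f.pulses if np.isclose(tpp, tp))
                y = _apply_pulse(y, names, f, vol, i_v)

    frame = pd.DataFrame(rows, columns=list(names))
    frame.insert(0, "time_h", times)
    frame = frame.drop_duplicates(subset="time_h").reset_index(drop=True)
    # tiny negative undershoots from the integrator are floored
    state_cols = [c for c in frame.columns if c != "time_h"]
    vals = frame[state_cols].to_numpy()
    if np.any(vals < -1e-9):
        worst = vals.min()
        raise SimulationError(f"state went negative beyond tolerance ({worst:.3e})")
    frame[state_cols] = np.clip(vals, 0.0, None)
    for f in feeds:
        frame[f"F_{f.feed_id}_ml_min"] = [feed_rate(f, t) for t in frame["time_h"]]
    frame = model.derived_observables(frame)
    return Trajectory(data=frame, feeds=tuple(feeds))


def _apply_pulse(
    y: np.ndarray,
    names: tuple[str, ...],
    f: FeedSchedule,
    vol: float,
    i_v: int | None,
) -> np.ndarray:
    """Instantaneous, conservative mixing of a feed pulse into the reactor."""
    if i_v is None:
        return y
    y = y.copy()
    v_old = y[i_v]
    v_new = v_old + vol
    for i, n in enumerate(names):
        if n == "V_l" or n.startswith("n"):
            continue
        comp = n[2:] if n.startswith("c_") else n
        c_feed = f.composition.get(comp, f.composition.get(n, 0.0))
        y[i] = (y[i] * v_old + c_feed * vol) / v_new
    y[i_v] = v_new
    return y


def volume_balance_error(traj: Trajectory) -> float:
    """|V(t_end) − V(0) − fed volume|, the simulator's volume-closure check."""
    v = traj.series("V_l")
    t = traj.time
    fed = total_fed_volume(traj.feeds, t[0], t[-1])
    return abs(v[-1] - v[0] - fed)


def respiratory_quotient(
    traj: Trajectory, window: float = 1.0, cumulative: bool = False
) -> pd.DataFrame:
    """RQ = CO2 produced / O2 consumed (mol/mol) per trailing window.

    Returns a frame with columns ``time_h`` and ``RQ``; windows in which no
    oxygen was consumed yield NaN (undefined, not an error).  With
    ``cumulative=True`` the ratio of the running totals is returned instead.
    """
    t = traj.time
    o2 = traj.series("nO2_mol")
    co2 = traj.series("nCO2_mol")
    if cumulative:
        with np.errstate(divide="ignore", invalid="ignore"):
            rq = np.where(o2 > 1e-12, co2 / np.where(o2 > 1e-12, o2, 1.0), np.nan)
        return pd.DataFrame({"time_h": t, "RQ": rq})
    t_prev = t - window
    o2_prev = np.interp(t_prev, t, o2)
    co2_prev = np.interp(t_prev, t, co2)
    d_o2 = o2 - o2_prev
    d_co2 = co2 - co2_prev
    rq = np.where(d_o2 > 1e-12, d_co2 / np.where(d_o2 > 1e-12, d_o2, 1.0), np.nan)
    rq[t < t[0] + window] = np.nan
    return pd.DataFrame({"time_h": t, "RQ": rq})


# --------------------------------------------------------------------------
# Reference six-compartment yeast model
# --------------------------------------------------------------------------

_REF_STATES = (
    "c_Glc",
    "c_EtOH",
    "c_N",
    "c_EAA",
    "c_E3HB",
    "X_pri",
    "X_p",
    "X_i",
    "X_s",
    "X_si",
    "X_d",
    "V_l",
    "nO2_mol",
    "nCO2_mol",
)

_REF_DEFAULTS: dict[str, tuple[float, float, float, str]] = {
    # name: (default, lower, upper, unit)
    "qGlc_ox_max": (0.60, 0.10, 2.0, "g/(g h)"),
    "Ks_Glc": (0.10, 0.01, 1.0, "g/l"),
    "qGlc_ferm_max": (1.50, 0.10, 4.0, "g/(g h)"),
    "Ks_ferm": (1.00, 0.10, 5.0, "g/l"),
    "Glc_crab": (0.80, 0.10, 5.0, "g/l"),
    "K_crab": (6.0, 1.0, 20.0, "l/g"),
    "qEtOH_max": (0.25, 0.01, 1.0, "g/(g h)"),
    "Ks_EtOH": (0.50, 0.05, 5.0, "g/l"),
    "Y_XS_ox": (0.50, 0.30, 0.65, "g/g"),
    "Y_XS_et": (0.55, 0.30, 0.70, "g/g"),
    "qEAA_max": (0.12, 0.005, 0.50, "g/(g h)"),
    "Ks_EAA": (0.10, 0.01, 1.0, "g/l"),
    "EAA_inhib_50": (1.0, 0.30, 4.0, "g/l"),
    "K_EAA_inhib": (3.0, 0.50, 10.0, "l/g"),
    "EtOH_inhib_50": (40.0, 20.0, 80.0, "g/l"),
    "K_EtOH_inhib": (0.15, 0.05, 1.0, "l/g"),
    "f_EtOH_inhib": (0.10, 0.0, 0.50, "-"),
    "pH_50l": (4.0, 3.0, 5.0, "-"),
    "pH_50h": (6.5, 5.5, 8.0, "-"),
    "K_pH": (2.5, 0.5, 6.0, "1/pH"),
    "f_pH_low": (0.20, 0.0, 1.0, "-"),
    "f_pH_high": (0.30, 0.0, 1.0, "-"),
    "N_50": (0.05, 0.005, 0.50, "g/l"),
    "K_N": (60.0, 10.0, 200.0, "l/g"),
    "f_N_lim": (0.05, 0.0, 0.50, "-"),
    "k_act": (0.02, 0.0, 0.20, "1/h"),
    "k_pp": (0.05, 0.0, 0.50, "1/h"),
    "k_inact": (0.010, 0.0, 0.10, "1/h"),
    "EtOH_stress_50": (45.0, 30.0, 90.0, "g/l"),
    "K_stress": (0.20, 0.05, 1.0, "l/g"),
    "k_d": (0.002, 0.0, 0.05, "1/h"),
    "f_stress_mort": (20.0, 1.0, 50.0, "-"),
    "EAA_mort_50": (2.5, 0.5, 6.0, "g/l"),
    "K_EAA_mort": (2.0, 0.5, 6.0, "l/g"),
    "phi_struct": (0.15, 0.0, 0.50, "-"),
}


class ReferenceYeastModel:
    """Six-compartment fed-batch model of yeast growth and biocatalysis.

    Pathways (all elemental-balanced at construction):

    * oxidative growth on glucose (yield ``Y_XS_ox`` as the stoichiometric
      degree of freedom),
    * overflow fermentation of glucose to ethanol (Crabtree effect, switched
      on by a double sigmoid of the glucose concentration),
    * oxidative growth on ethanol after glucose depletion (diauxie; glucose
      represses ethanol uptake through a double sigmoid),
    * whole-cell reduction of ethyl acetoacetate (EAA) to ethyl
      3-hydroxybutyrate (E3HB), glucose-coupled for redox, carried by the
      product-forming compartment and inhibited by EAA itself above
      ~0.5–1 g/l.

    The nitrogen source is lumped into one assimilable species with a
    configurable elemental formula (ammonia-equivalent by default).
    """

    name = "reference_yeast_six_compartment"
    state_names = _REF_STATES

    def __init__(self, n_source: ElementalSpecies = AMMONIA):
        self.n_source = n_source
        self.species = {
            "Glc": GLUCOSE,
            "EtOH": ETHANOL,
            "N": n_source,
            "EAA": EAA,
            "E3HB": E3HB,
            "X": BIOMASS,
        }
        self._idx = {n: i for i, n in enumerate(self.state_names)}
        self._pathway_cache: dict[tuple[float, float], dict] = {}
        self._modifier_cache: dict[tuple, dict[str, SigmoidParams]] = {}
        self._table_cache: dict[tuple[float, float], list] = {}

    def _rate_table(self, p: Mapping[str, float]) -> list:
        """Flattened pathway data for the RHS hot loop (cached).

        Per pathway: substrate name, [(component, signed mass yield)],
        mol O2 consumed and mol CO2 produced per gram substrate.
        """
        key = (p["Y_XS_ox"], p["Y_XS_et"])
        cached = self._table_cache.get(key)
        if cached is not None:
            return cached
        paths = self.pathways(p)
        table = []
        for pname in ("ox", "ferm", "et_ox", "biocat"):
            pw = paths[pname]
            mw_s = pw.substrate.molecular_weight
            contribs = []
            o2 = co2 = 0.0
            for sp, _role in pw.species:
                nu_signed = pw.signed_coefficient(sp.name)
                if sp.name == "H2O":
                    continue
                if sp.name == "O2":
                    o2 = -nu_signed / mw_s
                elif sp.name == "CO2":
                    co2 = nu_signed / mw_s
                else:
                    contribs.append((sp.name, nu_signed * sp.molecular_weight / mw_s))
            table.append((pw.substrate.name, contribs, o2, co2))
        if len(self._table_cache) > 64:
            self._table_cache.clear()
        self._table_cache[key] = table
        return table

    def default_parameters(self) -> ModelParameters:
        return ModelParameters(
            values={k: v[0] for k, v in _REF_DEFAULTS.items()},
            bounds={k: (v[1], v[2]) for k, v in _REF_DEFAULTS.items()},
            units={k: v[3] for k, v in _REF_DEFAULTS.items()},
        )

    # -- stoichiometry ----------------------------------------------------

    def pathways(self, p: Mapping[str, float]) -> dict[str, PathwayStoichiometry]:
        """Build and balance the four pathways for a parameter set (cached)."""
        key = (p["Y_XS_ox"], p["Y_XS_et"])
        cached = self._pathway_cache.get(key)
        if cached is not None:
            return cached
        x = self.species["X"]
        nu_x_ox = p["Y_XS_ox"] * GLUCOSE.molecular_weight / x.molecular_weight
        ox = balance_pathway(
            PathwayStoichiometry(
                name="glc_oxidative_growth",
                substrate=GLUCOSE,
                species=(
                    (OXYGEN, "O2"),
                    (self.n_source, "N-source"),
                    (x, "biomass"),
                    (CO2, "CO2"),
                    (WATER, "H2O"),
                ),
                nu={"O2": None, self.n_source.name: None, "X": nu_x_ox, "CO2": None, "H2O": None},
            )
        )
        ferm = balance_pathway(
            PathwayStoichiometry(
                name="glc_fermentation",
                substrate=GLUCOSE,
                species=((ETHANOL, "product"), (CO2, "CO2")),
                nu={"EtOH": None, "CO2": None},
            )
        )
        nu_x_et = p["Y_XS_et"] * ETHANOL.molecular_weight / x.molecular_weight
        et_ox = balance_pathway(
            PathwayStoichiometry(
                name="etoh_oxidative_growth",
                substrate=ETHANOL,
                species=(
                    (OXYGEN, "O2"),
                    (self.n_source, "N-source"),
                    (x, "biomass"),
                    (CO2, "CO2"),
                    (WATER, "H2O"),
                ),
                nu={"O2": None, self.n_source.name: None, "X": nu_x_et, "CO2": None, "H2O": None},
            )
        )
        biocat = balance_pathway(
            PathwayStoichiometry(
                name="eaa_reduction",
                substrate=EAA,
                species=(
                    (GLUCOSE, "cosubstrate"),
                    (E3HB, "product"),
                    (CO2, "CO2"),
                    (WATER, "H2O"),
                ),
                nu={"Glc": None, "E3HB": 1.0, "CO2": None, "H2O": None},
            )
        )
        result = {"ox": ox, "ferm": ferm, "et_ox": et_ox, "biocat": biocat}
        if len(self._pathway_cache) > 64:
            self._pathway_cache.clear()
        self._pathway_cache[key] = result
        return result

    # -- kinetics ---------------------------------------------------------

    @staticmethod
    def _sig(Y_l, Y_mid, Y_h, K, x50l, x50h=None) -> SigmoidParams:
        return SigmoidParams(Y_l, Y_mid, Y_h, K, x50l, x50h if x50h is not None else x50l)

    _MODIFIER_PARAMS = (
        "f_EtOH_inhib",
        "K_EtOH_inhib",
        "EtOH_inhib_50",
        "f_pH_low",
        "f_pH_high",
        "K_pH",
        "pH_50l",
        "pH_50h",
        "f_N_lim",
        "K_N",
        "N_50",
        "K_crab",
        "Glc_crab",
        "K_EAA_inhib",
        "EAA_inhib_50",
        "K_stress",
        "EtOH_stress_50",
        "f_stress_mort",
        "K_EAA_mort",
        "EAA_mort_50",
    )

    def _modifiers(self, p: Mapping[str, float]) -> dict[str, SigmoidParams]:
        key = tuple(p[k] for k in self._MODIFIER_PARAMS)
        cached = self._modifier_cache.get(key)
        if cached is not None:
            return cached
        s = self._sig
        out = {
            # ethanol inhibition of uptake: 1 -> f_EtOH_inhib at high EtOH
            "etoh_inhib": s(1.0, 1.0, p["f_EtOH_inhib"], p["K_EtOH_inhib"], p["EtOH_inhib_50"]),
            # pH window: f_pH_low below pH_50l, 1 in the optimum, f_pH_high above pH_50h
            "ph": s(p["f_pH_low"], 1.0, p["f_pH_high"], p["K_pH"], p["pH_50l"], p["pH_50h"]),
            # nitrogen limitation of growth: f_N_lim -> 1 above N_50
            "n_lim": s(p["f_N_lim"], 1.0, 1.0, p["K_N"], p["N_50"]),
            # Crabtree switch: overflow fermentation activates above Glc_crab
            "crabtree": s(0.01, 1.0, 1.0, p["K_crab"], p["Glc_crab"]),
            # glucose repression of ethanol uptake: 1 -> 0.02 above ~0.5 g/l
            "glc_repress": s(1.0, 1.0, 0.02, 10.0, 0.5),
            # educt (EAA) inhibition of biocatalysis
            "eaa_inhib": s(1.0, 1.0, 0.05, p["K_EAA_inhib"], p["EAA_inhib_50"]),
            # stress gates for inactivation and mortality
            "etoh_stress": s(0.05, 0.05, 1.0, p["K_stress"], p["EtOH_stress_50"]),
            "etoh_mort": s(1.0, 1.0, p["f_stress_mort"], p["K_stress"], p["EtOH_stress_50"]),
            "eaa_mort": s(1.0, 1.0, p["f_stress_mort"], p["K_EAA_mort"], p["EAA_mort_50"]),
            # EAA induces conversion of primary to product-forming biomass
            "eaa_induce": s(0.02, 1.0, 1.0, 30.0, 0.1),
        }
        if len(self._modifier_cache) > 64:
            self._modifier_cache.clear()
        self._modifier_cache[key] = out
        return out

    def rhs(
        self,
        t: float,
        y: np.ndarray,
        params: Mapping[str, float],
        feeds: Sequence[FeedSchedule],
        env: Environment,
    ) -> np.ndarray:
        p = params
        idx = self._idx
        # clip only inside the rate evaluation; the solver state is untouched
        glc = max(y[idx["c_Glc"]], 0.0)
        etoh = max(y[idx["c_EtOH"]], 0.0)
        n_src = max(y[idx["c_N"]], 0.0)
        eaa = max(y[idx["c_EAA"]], 0.0)
        x_pri = max(y[idx["X_pri"]], 0.0)
        x_p = max(y[idx["X_p"]], 0.0)
        x_s = max(y[idx["X_s"]], 0.0)
        v = y[idx["V_l"]]

        m = self._modifiers(p)
        f_etoh = dsig(etoh, m["etoh_inhib"])
        f_ph = dsig(env.pH, m["ph"])
        f_n = dsig(n_src, m["n_lim"])

        # specific pathway rates, g substrate/(g catalyst h)
        q_ox = p["qGlc_ox_max"] * glc / (p["Ks_Glc"] + glc) * f_etoh * f_ph * f_n
        q_ferm = (
            p["qGlc_ferm_max"]
            * glc
            / (p["Ks_ferm"] + glc)
            * dsig(glc, m["crabtree"])
            * f_etoh
            * f_ph
        )
        q_et = (
            p["qEtOH_max"]
            * etoh
            / (p["Ks_EtOH"] + etoh)
            * dsig(glc, m["glc_repress"])
            * f_ph
            * f_n
        )
        q_eaa = (
            p["qEAA_max"] * eaa / (p["Ks_EAA"] + eaa) * dsig(eaa, m["eaa_inhib"]) * f_etoh
        )

        table = self._rate_table(p)
        fluxes = (q_ox * x_pri, q_ferm * x_pri, q_et * x_pri, q_eaa * x_p)

        # volumetric conversion rates rc_i (g/(l h)), summed over pathways
        rc: dict[str, float] = {k: 0.0 for k in ("Glc", "EtOH", "N", "EAA", "E3HB", "X")}
        d_o2 = 0.0  # mol/h consumed
        d_co2 = 0.0  # mol/h produced
        for (substrate, contribs, o2_per_g, co2_per_g), flux in zip(table, fluxes):
            if flux == 0.0:
                continue
            rc[substrate] -= flux
            for name, y_signed in contribs:
                rc[name] += y_signed * flux
            d_o2 += o2_per_g * flux * v
            d_co2 += co2_per_g * flux * v

        # compartment transfers, 1/h
        r_act = p["k_act"]
        r_pp = p["k_pp"] * dsig(eaa, m["eaa_induce"])
        r_inact = p["k_inact"] * dsig(etoh, m["etoh_stress"])
        r_mort = p["k_d"] * dsig(etoh, m["etoh_mort"]) * dsig(eaa, m["eaa_mort"])

        growth = rc["X"]  # g/(l h) new biomass, from the balanced pathways
        phi = p["phi_struct"]

        # feeds: total flow and per-component inputs
        f_tot = 0.0  # l/h
        inputs: dict[str, float] = {}
        for f in feeds:
            flow = feed_rate_l_h(f, t)
            f_tot += flow
            for comp, c_f in f.composition.items():
                inputs[comp] = inputs.get(comp, 0.0) + c_f * flow
        dil = f_tot / v

        dy = np.zeros_like(y)

        def comp_name(state: str) -> str:
            return state[2:] if state.startswith("c_") else state

        for state in ("c_Glc", "c_EtOH", "c_N", "c_EAA", "c_E3HB"):
            comp = comp_name(state)
            dy[idx[state]] = (
                rc[comp] + inputs.get(comp, 0.0) / v - max(y[idx[state]], 0.0) * dil
            )

        dy[idx["X_pri"]] = (
            (1 - phi) * growth
            + r_act * x_s
            - (r_pp + r_inact + r_mort) * x_pri
            - x_pri * dil
        )
        dy[idx["X_p"]] = r_pp * x_pri - (r_inact + r_mort) * x_p - x_p * dil
        dy[idx["X_i"]] = r_inact * (x_pri + x_p) - max(y[idx["X_i"]], 0.0) * dil
        dy[idx["X_s"]] = phi * growth - (r_act + r_inact + r_mort) * x_s - x_s * dil
        dy[idx["X_si"]] = r_inact * x_s - max(y[idx["X_si"]], 0.0) * dil
        dy[idx["X_d"]] = r_mort * (x_pri + x_p + x_s) - max(y[idx["X_d"]], 0.0) * dil
        # biomass entering through a feed (unusual, but the balance allows it)
        for state in ProcessState.COMPARTMENT_NAMES:
            if state in inputs:
                dy[idx[state]] += inputs[state] / v

        dy[idx["V_l"]] = f_tot
        dy[idx["nO2_mol"]] = d_o2
        dy[idx["nCO2_mol"]] = d_co2
        return dy

    def derived_observables(self, frame: pd.DataFrame) -> pd.DataFrame:
        frame = frame.copy()
        frame["c_DCW"] = frame[list(ProcessState.COMPARTMENT_NAMES)].sum(axis=1)
        return frame

    # -- conservation check ------------------------------------------------

    def carbon_fraction(self, name: str) -> float:
        sp = self.species[name]
        return sp.atoms("C") * 12.011 / sp.molecular_weight

    def carbon_inventory(self, traj: Trajectory, row: int) -> float:
        """Grams of carbon in all pools plus cumulative CO2 at grid index ``row``."""
        r = traj.data.iloc[row]
        v = r["V_l"]
        total = 0.0
        for state, comp in (
            ("c_Glc", "Glc"),
            ("c_EtOH", "EtOH"),
            ("c_EAA", "EAA"),
            ("c_E3HB", "E3HB"),
        ):
            total += r[state] * v * self.carbon_fraction(comp)
        for comp in ProcessState.COMPARTMENT_NAMES:
            total += r[comp] * v * self.carbon_fraction("X")
        total += r["nCO2_mol"] * 12.011
        return float(total)

    def carbon_fed(self, traj: Trajectory, t0: float, t1: float) -> float:
        """Grams of carbon delivered by all feeds on [t0, t1]."""
        total = 0.0
        for f in traj.feeds:
            vol = total_fed_volume([f], t0, t1)
            for comp, c_f in f.composition.items():
                if comp in self.species:
                    total += vol * c_f * self.carbon_fraction(comp)
                elif comp in ProcessState.COMPARTMENT_NAMES:
                    total += vol * c_f * self.carbon_fraction("X")
        return total

    def carbon_balance_error(self, traj: Trajectory) -> float:
        """Relative carbon-closure error over the whole trajectory."""
        c0 = self.carbon_inventory(traj, 0)
        c1 = self.carbon_inventory(traj, len(traj.data) - 1)
        fed = self.carbon_fed(traj, traj.time[0], traj.time[-1])
        return abs(c1 - (c0 + fed)) / max(c0 + fed, 1e-12)
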