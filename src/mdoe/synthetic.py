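"""Synthetic fed-batch study generation with a known ground truth.

Two study shapes are emulated, mirroring the optimization case studies the
toolbox is built for:

* **S1** — yeast growth: pH setpoint plus linearly rising glucose and
  nitrogen feed ramps, biomass (dry cell weight) as the response;
* **S2** — whole-cell biocatalysis: constant EAA/glucose/nitrogen feeds,
  product (E3HB) as the response, with EAA substrate inhibition.

The generator simulates the reference model at a chosen ground truth,
samples observables on a realistic schedule (every 3 h), applies the
experimental noise model (5% relative on measurements, initial values and
setpoints; 10% on the unobservable biomass-compartment split) and returns
both the noisy dataset and the truth, enabling parameter-recovery tests
without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from mdoe.calibration import MeasurementDataset, NoiseSpec, perturb_dataset
from mdoe.design import DesignSpace, Factor
from mdoe.errors import InvalidParameterError
from mdoe.feeds import FeedSchedule
from mdoe.mc import ResponseSpec
from mdoe.model import Environment, ModelParameters, ReferenceYeastModel
from mdoe.scenario import Scenario

StudyKind = Literal["S1", "S2"]

#: Observation schedule: every 3 h over the 48 h horizon.
DEFAULT_SAMPLE_TIMES = np.arange(0.0, 48.1, 3.0)

#: Initial biomass split over the six compartments (fractions of total DCW).
S1_COMPARTMENT_SPLIT = {"X_pri": 0.60, "X_p": 0.0, "X_i": 0.05, "X_s": 0.25, "X_si": 0.05, "X_d": 0.05}
S2_COMPARTMENT_SPLIT = {"X_pri": 0.30, "X_p": 0.35, "X_i": 0.10, "X_s": 0.15, "X_si": 0.05, "X_d": 0.05}


def s1_scenario(params: ModelParameters | None = None) -> Scenario:
    """Growth study: 2 g/l initial DCW, glucose+nitrogen ramps, pH 5."""
    model = ReferenceYeastModel()
    if params is None:
        params = model.default_parameters()
    dcw0 = 2.0
    initial = {
        "c_Glc": 10.0,
        "c_EtOH": 0.0,
        "c_N": 2.0,
        "c_EAA": 0.0,
        "c_E3HB": 0.0,
        **{k: f * dcw0 for k, f in S1_COMPARTMENT_SPLIT.items()},
        "V_l": 1.5,
        "nO2_mol": 0.0,
        "nCO2_mol": 0.0,
    }
    feeds = (
        FeedSchedule(
            "glc", "linear_ramp", composition={"Glc": 400.0}, t_start=1.0, t_end=48.0, F_end=0.42
        ),
        FeedSchedule(
            "n", "linear_ramp", composition={"N": 120.0}, t_start=1.0, t_end=48.0, F_end=0.20
        ),
    )
    return Scenario(
        model=model,
        params=params,
        initial=initial,
        feeds=feeds,
        env=Environment(pH=5.0),
        t_grid=np.linspace(0.0, 48.0, 97),
    )


def s2_scenario(params: ModelParameters | None = None) -> Scenario:
    """Biocatalysis study: 45 g/l initial DCW, constant EAA/Glc/N feeds."""
    model = ReferenceYeastModel()
    if params is None:
        params = model.default_parameters()
    dcw0 = 45.0
    initial = {
        "c_Glc": 0.5,
        "c_EtOH": 0.0,
        "c_N": 1.0,
        "c_EAA": 0.2,
        "c_E3HB": 0.0,
        **{k: f * dcw0 for k, f in S2_COMPARTMENT_SPLIT.items()},
        "V_l": 1.5,
        "nO2_mol": 0.0,
        "nCO2_mol": 0.0,
    }
    feeds = (
        FeedSchedule("eaa", "constant", composition={"EAA": 800.0}, t_start=0.0, t_end=48.0, F=0.04),
        FeedSchedule("glc", "constant", composition={"Glc": 400.0}, t_start=0.0, t_end=48.0, F=0.30),
        FeedSchedule("n", "constant", composition={"N": 120.0}, t_start=0.0, t_end=48.0, F=0.03),
    )
    return Scenario(
        model=model,
        params=params,
        initial=initial,
        feeds=feeds,
        env=Environment(pH=5.0),
        t_grid=np.linspace(0.0, 48.0, 97),
    )


def study_design_space(kind: StudyKind) -> tuple[DesignSpace, list[str]]:
    """Factor bounds and their scenario paths for each study shape."""
    if kind == "S1":
        space = DesignSpace(
            factors=(
                Factor("pH", 3.0, 7.0, "-"),
                Factor("F_Glc", 0.1, 1.0, "ml/min"),
                Factor("F_N", 0.05, 0.6, "ml/min"),
            )
        )
        paths = ["env.pH", "feeds.glc.F_end", "feeds.n.F_end"]
    elif kind == "S2":
        space = DesignSpace(
            factors=(
                Factor("F_EAA", 0.005, 0.10, "ml/min"),
                Factor("F_Glc", 0.05, 1.0, "ml/min"),
                Factor("F_N", 0.005, 0.10, "ml/min"),
            )
        )
        paths = ["feeds.eaa.F", "feeds.glc.F", "feeds.n.F"]
    else:
        raise InvalidParameterError(f"unknown study kind {kind!r}")
    return space, paths


def study_response(kind: StudyKind) -> ResponseSpec:
    if kind == "S1":
        return ResponseSpec(observable="c_DCW", reduction="value_at_time", at_time=48.0)
    return ResponseSpec(observable="c_E3HB", reduction="max_over_time")


_S1_OBSERVABLES = ("c_DCW", "c_Glc", "c_EtOH")
_S2_OBSERVABLES = ("c_DCW", "c_Glc", "c_EtOH", "c_EAA", "c_E3HB")


@dataclass
class SyntheticStudy:
    """A generated study: truth scenario, noisy dataset and provenance."""

    kind: StudyKind
    scenario: Scenario  # at the ground-truth parameters
    truth: ModelParameters
    noise: NoiseSpec
    dataset: MeasurementDataset
    seed: int


def generate_synthetic_study(
    kind: StudyKind = "S1",
    truth: ModelParameters | None = None,
    noise: NoiseSpec = NoiseSpec(measurement_rel=0.05),
    seed: int = 0,
    sample_times: np.ndarray | None = None,
) -> SyntheticStudy:
    """Simulate a ground-truth study and return its noisy dataset.

    The dataset records the nominal per-point standard deviation (the
    relative measurement noise times the noise-free value); initial values
    and setpoints are listed with NaN sd so the calibration stage applies
    the default 5%/10% rules.  Regenerating with the same seed reproduces
    the dataset bit-exactly.
    """
    scenario = s1_scenario(truth) if kind == "S1" else s2_scenario(truth)
    truth_params = scenario.params
    if sample_times is None:
        sample_times = DEFAULT_SAMPLE_TIMES
    grid = np.unique(np.concatenate([scenario.t_grid, sample_times]))
    scenario = Scenario(
        scenario.model, truth_params, scenario.initial, scenario.feeds, scenario.env, grid
    )
    traj = scenario.simulate()

    observables = _S1_OBSERVABLES if kind == "S1" else _S2_OBSERVABLES
    rel = noise.measurement_rel if noise.measurement_rel is not None else 0.05
    rows = []
    for obs_name in observables:
        for t in sample_times:
            v = traj.at_time(obs_name, float(t))
            rows.append(
                {"observable": obs_name, "time_h": float(t), "value": v, "sd": rel * abs(v)}
            )
    clean = pd.DataFrame(rows)

    initial = {k: (float(v), float("nan")) for k, v in scenario.initial.items() if v > 0}
    setpoints: dict[str, tuple[float, float]] = {"env.pH": (scenario.env.pH, float("nan"))}
    for f in scenario.feeds:
        field_name = "F_end" if f.kind == "linear_ramp" else "F"
        setpoints[f"feeds.{f.feed_id}.{field_name}"] = (getattr(f, field_name), float("nan"))
        for comp, c in f.composition.items():
            setpoints[f"feeds.{f.feed_id}.composition.{comp}"] = (c, float("nan"))

    clean_ds = MeasurementDataset(observations=clean, initial=initial, setpoints=setpoints)
    # measurement noise only here; initial/setpoint perturbation is the
    # calibration stage's job (it re-perturbs per Monte-Carlo fit)
    rng = np.random.default_rng(seed)
    obs = clean_ds.observations.copy()
    obs["value"] = [
        v if sd == 0 else _nonneg_normal(rng, v, sd) for v, sd in zip(obs["value"], obs["sd"])
    ]
    noisy_ds = MeasurementDataset(observations=obs, initial=initial, setpoints=setpoints)
    return SyntheticStudy(
        kind=kind,
        scenario=scenario,
        truth=truth_params,
        noise=noise,
        dataset=noisy_ds,
        seed=seed,
    )


def _nonneg_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if v >= 0:
            return float(v)
    return max(mean, 0.0)
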