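"""A minimal fed-batch plug-in model with substrate-inhibited growth.

Three states (substrate, biomass, volume) and four parameters.  Growth is
Monod in the substrate with a Haldane-type inhibition term, so the biomass
reached at the end of a run is unimodal in the feed rate: feeding too little
starves the culture, feeding too much accumulates inhibitory substrate.
The model exists to exercise the full pipeline (calibration, design
planning, Monte-Carlo evaluation, desirability ranking) at negligible cost
and with a known optimum; it is a demonstration of the plug-in contract,
not a description of any real organism.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from mdoe.feeds import FeedSchedule, feed_rate_l_h
from mdoe.model import Environment, ModelParameters

_TOY_DEFAULTS = {
    "q_max": (0.9, 0.1, 3.0, "g/(g h)"),
    "K_s": (0.2, 0.01, 2.0, "g/l"),
    "K_i": (8.0, 0.5, 30.0, "g/l"),
    "Y_XS": (0.5, 0.2, 0.8, "g/g"),
}


class ToyFedBatchModel:
    """Single-substrate, single-biomass fed-batch model (plug-in contract)."""

    name = "toy_fed_batch"
    state_names = ("c_S", "X", "V_l")

    def default_parameters(self) -> ModelParameters:
        return ModelParameters(
            values={k: v[0] for k, v in _TOY_DEFAULTS.items()},
            bounds={k: (v[1], v[2]) for k, v in _TOY_DEFAULTS.items()},
            units={k: v[3] for k, v in _TOY_DEFAULTS.items()},
        )

    def rhs(
        self,
        t: float,
        y: np.ndarray,
        params: Mapping[str, float],
        feeds: Sequence[FeedSchedule],
        env: Environment,
    ) -> np.ndarray:
        s = max(y[0], 0.0)
        x = max(y[1], 0.0)
        v = y[2]
        q = params["q_max"] * s / (params["K_s"] + s + s * s / params["K_i"])
        f_tot = 0.0
        s_in = 0.0
        for f in feeds:
            flow = feed_rate_l_h(f, t)
            f_tot += flow
            s_in += f.composition.get("S", 0.0) * flow
        dil = f_tot / v
        return np.array(
            [
                -q * x + s_in / v - s * dil,
                params["Y_XS"] * q * x - x * dil,
                f_tot,
            ]
        )

    def derived_observables(self, frame: pd.DataFrame) -> pd.DataFrame:
        return frame


def toy_scenario(params: ModelParameters | None = None):
    """24 h toy run: dilute inoculum, one constant feed carrying substrate."""
    from mdoe.scenario import Scenario

    model = ToyFedBatchModel()
    if params is None:
        params = model.default_parameters()
    initial = {"c_S": 0.5, "X": 0.1, "V_l": 1.0}
    feeds = (
        FeedSchedule("f", "constant", composition={"S": 100.0}, t_start=0.0, t_end=24.0, F=0.2),
    )
    return Scenario(
        model=model,
        params=params,
        initial=initial,
        feeds=feeds,
        env=Environment(),
        t_grid=np.linspace(0.0, 24.0, 49),
    )


def toy_design_space():
    """Single factor: the feed rate, spanning starvation to inhibition."""
    from mdoe.design import DesignSpace, Factor

    return DesignSpace(factors=(Factor("F", 0.05, 0.45, "ml/min"),)), ["feeds.f.F"]


def toy_response():
    from mdoe.mc import ResponseSpec

    return ResponseSpec(observable="X", reduction="value_at_time", at_time=24.0)


def generate_toy_dataset(seed: int = 0, rel_sd: float = 0.05):
    """Noisy substrate/biomass series from the toy truth, for calibration."""
    from mdoe.calibration import MeasurementDataset

    sc = toy_scenario()
    traj = sc.simulate()
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, 24.1, 2.0)
    rows = []
    for obs in ("c_S", "X"):
        for t in times:
            v = traj.at_time(obs, float(t))
            sd = rel_sd * abs(v)
            noisy = v if sd == 0 else abs(rng.normal(v, sd))
            rows.append({"observable": obs, "time_h": float(t), "value": noisy, "sd": sd})
    initial = {k: (float(v), float("nan")) for k, v in sc.initial.items() if v > 0}
    setpoints = {"feeds.f.F": (0.2, float("nan"))}
    return MeasurementDataset(
        observations=pd.DataFrame(rows), initial=initial, setpoints=setpoints
    )
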