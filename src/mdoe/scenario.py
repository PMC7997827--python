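"""Simulation scenarios and declarative factor mapping.

A :class:`Scenario` bundles everything one simulation needs — model,
parameters, initial state, feed schedules, environment and time grid.
Design factors and perturbed setpoints address scenario fields through
dotted paths (``env.pH``, ``feeds.glc.F_end``, ``initial.c_Glc``), which is
how a planned factor combination is turned into a concrete virtual
experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace
from typing import Mapping

import numpy as np

from mdoe.errors import ConfigurationError
from mdoe.feeds import FeedSchedule
from mdoe.model import Environment, ModelParameters, ProcessModel, Trajectory, simulate


@dataclass
class Scenario:
    """One fully specified virtual experiment."""

    model: ProcessModel
    params: ModelParameters
    initial: dict[str, float]
    feeds: tuple[FeedSchedule, ...]
    env: Environment
    t_grid: np.ndarray

    def simulate(self, params: ModelParameters | Mapping[str, float] | None = None) -> Trajectory:
        return simulate(
            self.model,
            self.params if params is None else params,
            self.initial,
            self.feeds,
            self.env,
            self.t_grid,
        )

    def apply(self, assignments: Mapping[str, float]) -> "Scenario":
        """Return a copy with dotted-path assignments applied.

        Supported paths: ``env.<field>``, ``initial.<state>``,
        ``feeds.<feed_id>.<field>`` (numeric fields such as ``F``, ``F_end``,
        ``t_start``, ``t_end``) and ``feeds.<feed_id>.composition.<component>``.
        """
        env_updates: dict[str, float] = {}
        init = dict(self.initial)
        feeds = {f.feed_id: f for f in self.feeds}
        for path, value in assignments.items():
            parts = path.split(".")
            if parts[0] == "env" and len(parts) == 2:
                env_updates[parts[1]] = value
            elif parts[0] == "initial" and len(parts) == 2:
                init[parts[1]] = value
            elif parts[0] == "feeds" and len(parts) >= 3:
                fid = parts[1]
                if fid not in feeds:
                    raise ConfigurationError(f"unknown feed {fid!r} in path {path!r}")
                f = feeds[fid]
                if parts[2] == "composition" and len(parts) == 4:
                    comp = dict(f.composition)
                    comp[parts[3]] = value
                    feeds[fid] = dc_replace(f, composition=comp)
                elif len(parts) == 3 and parts[2] in ("F", "F_end", "t_start", "t_end"):
                    feeds[fid] = dc_replace(f, **{parts[2]: value})
                else:
                    raise ConfigurationError(f"unsupported factor path {path!r}")
            else:
                raise ConfigurationError(f"unsupported factor path {path!r}")
        env = dc_replace(self.env, **env_updates) if env_updates else self.env
        return Scenario(
            model=self.model,
            params=self.params,
            initial=init,
            feeds=tuple(feeds[f.feed_id] for f in self.feeds),
            env=env,
            t_grid=self.t_grid,
        )

    def read(self, path: str) -> float:
        """Read the current value at a dotted path (inverse of :meth:`apply`)."""
        parts = path.split(".")
        if parts[0] == "env":
            return float(getattr(self.env, parts[1]))
        if parts[0] == "initial":
            return float(self.initial[parts[1]])
        if parts[0] == "feeds":
            f = {f.feed_id: f for f in self.feeds}[parts[1]]
            if parts[2] == "composition":
                return float(f.composition.get(parts[3], 0.0))
            return float(getattr(f, parts[2]))
        raise ConfigurationError(f"unsupported path {path!r}")
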