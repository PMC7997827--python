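"""Feed schedules for fed-batch operation.

Three profile kinds are supported: a constant flow on a time window, the
linearly rising ramp used in the cultivation case study,

    F_k(t) = F_k,end / t_end * (t - t_start)   for t >= t_start, else 0,

and instantaneous volume pulses handled as discrete events by the simulator.
Flows are specified in ml/min (the bench convention) and converted to l/h
internally (x 0.06).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

from mdoe.errors import InvalidParameterError

ML_MIN_TO_L_H = 0.06

ProfileKind = Literal["constant", "linear_ramp", "pulses"]

#: How the ramp end-flow is interpreted.  ``as_printed`` evaluates
#: F_end/t_end*(t-t_start), so the flow at t_end is F_end*(t_end-t_start)/t_end;
#: ``reach_Fend_at_tend`` rescales the slope so the flow reaches F_end exactly
#: at t_end.
RampConvention = Literal["as_printed", "reach_Fend_at_tend"]


@dataclass(frozen=True)
class FeedSchedule:
    """One feed line: profile, timing and composition.

    ``composition`` maps model component names to concentrations (g/l) in
    the feed solution.  ``F_end`` (ramp) and ``F`` (constant) are in ml/min;
    ``pulses`` is a sequence of ``(time_h, volume_l)`` events.
    """

    feed_id: str
    kind: ProfileKind
    composition: Mapping[str, float] = field(default_factory=dict)
    t_start: float = 0.0
    t_end: float = 48.0
    F: float = 0.0  # ml/min, constant profiles
    F_end: float = 0.0  # ml/min, ramp profiles
    pulses: tuple[tuple[float, float], ...] = ()
    ramp_convention: RampConvention = "as_printed"

    def __post_init__(self):
        if self.t_start >= self.t_end:
            raise InvalidParameterError(
                f"feed {self.feed_id!r}: t_start ({self.t_start}) must precede t_end ({self.t_end})"
            )
        if self.F < 0 or self.F_end < 0:
            raise InvalidParameterError(f"feed {self.feed_id!r}: flows must be >= 0")
        if any(c < 0 for c in self.composition.values()):
            raise InvalidParameterError(f"feed {self.feed_id!r}: negative feed concentration")
        if any(v < 0 for _, v in self.pulses):
            raise InvalidParameterError(f"feed {self.feed_id!r}: negative pulse volume")


def feed_rate(schedule: FeedSchedule, t: float) -> float:
    """Feed flow in ml/min at time ``t`` (hours).

    Pulses contribute no continuous flow; they are applied as state jumps by
    the simulator (see :func:`mdoe.model.simulate`).
    """
    if t < 0:
        raise InvalidParameterError(f"time {t} < 0")
    if schedule.kind == "pulses":
        return 0.0
    if t < schedule.t_start or t > schedule.t_end:
        return 0.0
    if schedule.kind == "constant":
        return schedule.F
    if schedule.kind == "linear_ramp":
        if schedule.ramp_convention == "reach_Fend_at_tend":
            slope = schedule.F_end / (schedule.t_end - schedule.t_start)
        else:
            slope = schedule.F_end / schedule.t_end
        flow = slope * (t - schedule.t_start)
        if flow < 0:
            raise InvalidParameterError(f"feed {schedule.feed_id!r}: computed flow {flow} < 0")
        return flow
    raise InvalidParameterError(f"unknown profile kind {schedule.kind!r}")


def feed_rate_l_h(schedule: FeedSchedule, t: float) -> float:
    """Feed flow converted to l/h for the mass balances."""
    return feed_rate(schedule, t) * ML_MIN_TO_L_H


def total_fed_volume(feeds: Sequence[FeedSchedule], t0: float, t1: float) -> float:
    """Volume (l) delivered by all feeds on [t0, t1], pulses included.

    Continuous profiles are integrated in closed form (they are piecewise
    linear), so this serves as the independent check of the simulator's
    volume balance.
    """
    total = 0.0
    for f in feeds:
        if f.kind == "pulses":
            total += sum(v for tp, v in f.pulses if t0 < tp <= t1)
            continue
        a, b = max(t0, f.t_start), min(t1, f.t_end)
        if a >= b:
            continue
        # trapezoid on [a, b]; flow is linear there for both kinds
        total += 0.5 * (feed_rate_l_h(f, a) + feed_rate_l_h(f, b)) * (b - a)
    return total
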