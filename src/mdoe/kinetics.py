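"""Uptake kinetics: Monod saturation modulated by double-sigmoid switches.

Substrate uptake is rate-limiting and follows Monod kinetics,

    rS = rS_max * S / (K_s + S) * prod_i f_Dsig(x_i),

where each ``f_Dsig`` is a product of two logistic transitions giving three
plateaus (low / mid / high).  The double sigmoid is the workhorse used to
encode substrate or product inhibition, overflow metabolism thresholds and
the influence of pH, temperature or dissolved oxygen on a rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.special import expit


def _expit_scalar(z: float) -> float:
    if z >= 0:
        return 1.0 / (1.0 + math.exp(-z))
    e = math.exp(z)
    return e / (1.0 + e)

from mdoe.errors import InvalidParameterError


@dataclass(frozen=True)
class SigmoidParams:
    """Parameters of the double sigmoidal function.

    ``Y_l`` is the plateau at low x, ``Y_mid`` between the two transition
    midpoints ``X_50l`` and ``X_50h``, and ``Y_h`` at high x.  ``K_sl`` sets
    the slope of both flanks; an optional ``K_sl_h`` gives the upper flank
    its own slope.
    """

    Y_l: float
    Y_mid: float
    Y_h: float
    K_sl: float
    X_50l: float
    X_50h: float
    K_sl_h: float | None = None

    def __post_init__(self):
        if self.Y_mid == 0:
            raise InvalidParameterError("Y_mid must be nonzero (it divides Y_h)")
        if not np.isfinite(self.K_sl):
            raise InvalidParameterError("K_sl must be finite")
        if self.X_50l > self.X_50h:
            raise InvalidParameterError(
                f"X_50l ({self.X_50l}) must not exceed X_50h ({self.X_50h})"
            )

    @property
    def slope_high(self) -> float:
        return self.K_sl if self.K_sl_h is None else self.K_sl_h


def dsig(x, p: SigmoidParams):
    """Evaluate the double sigmoidal function at x (scalar or array).

    Limits: ``dsig -> Y_l`` for x far below ``X_50l``, ``Y_mid`` between the
    midpoints (for well-separated flanks), ``Y_h`` far above ``X_50h``.
    Constant when all three plateaus coincide.
    """
    if isinstance(x, (int, float)):
        low = p.Y_l + (p.Y_mid - p.Y_l) * _expit_scalar(p.K_sl * (x - p.X_50l))
        high = 1.0 + (p.Y_h / p.Y_mid - 1.0) * _expit_scalar(p.slope_high * (x - p.X_50h))
        return low * high
    x = np.asarray(x, dtype=float)
    low = p.Y_l + (p.Y_mid - p.Y_l) * expit(p.K_sl * (x - p.X_50l))
    high = 1.0 + (p.Y_h / p.Y_mid - 1.0) * expit(p.slope_high * (x - p.X_50h))
    out = low * high
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class UptakeKinetics:
    """Monod uptake with multiplicative double-sigmoid modifiers.

    ``modifiers`` maps state-variable names (e.g. ``"c_EtOH"``, ``"pH"``)
    to sigmoid parameter sets; the referenced values are looked up in the
    state/environment mapping passed to :func:`uptake_rate`.
    """

    rS_max: float  # g substrate / (g catalyst biomass * h)
    K_s: float  # g/l
    modifiers: tuple[tuple[str, SigmoidParams], ...] = ()

    def __post_init__(self):
        if self.rS_max < 0:
            raise InvalidParameterError("rS_max must be >= 0")
        if self.K_s <= 0:
            raise InvalidParameterError("K_s must be > 0")


def uptake_rate(S: float, k: UptakeKinetics, variables: Mapping[str, float]) -> float:
    """Specific uptake rate in g/(g h) at substrate concentration ``S``.

    ``variables`` holds every state variable and environment setpoint a
    modifier may reference.  Missing references raise ``KeyError`` so that a
    misconfigured model fails loudly.
    """
    if S < 0:
        raise InvalidParameterError(f"substrate concentration {S} < 0")
    rate = k.rS_max * S / (k.K_s + S)
    for var, p in k.modifiers:
        rate *= dsig(variables[var], p)
    return rate


def sigmoid_bounds(p: SigmoidParams) -> tuple[float, float]:
    """Conservative [min, max] envelope of dsig over all finite x.

    For positive plateaus the function stays within the envelope spanned by
    the three plateau values and their pairwise products of the two factor
    extrema; this is used by property tests and by rate-cap sanity checks.
    """
    f1 = np.array([p.Y_l, p.Y_mid])
    f2 = np.array([1.0, p.Y_h / p.Y_mid])
    prods = np.outer(f1, f2).ravel()
    return float(prods.min()), float(prods.max())
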