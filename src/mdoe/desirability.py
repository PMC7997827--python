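"""Desirability-based ranking of planned experiments.

Each planned experiment i carries a mean expected response r̄ᵢ (to be
maximized) and a variability νᵢ = q90 − q10 (to be minimized).  Both are
min–max rescaled to [0, 1] desirabilities,

    d(r̄ᵢ) = (r̄ᵢ − L(r̄)) / (U(r̄) − L(r̄)),
    d(νᵢ) = (νᵢ − U(ν)) / (L(ν) − U(ν)),

and combined with weights w1 + w2 = 1 (defaults 0.8/0.2) into

    Dᵢ = w1·d(r̄ᵢ) + w2·d(νᵢ).

The experiments with the highest Dᵢ (typically 2–4) are recommended for
the bench.  A quadratic response surface of Dᵢ over the factors is fitted
by ordinary least squares for visualization only — selection always uses
the raw Dᵢ values.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mdoe.design import Design
from mdoe.errors import ConfigurationError, InvalidParameterError


@dataclass(frozen=True)
class DesirabilityConfig:
    """Weights on mean desirability (w1) and variability desirability (w2)."""

    w1: float = 0.8
    w2: float = 0.2
    n_select: int = 4

    def __post_init__(self):
        if not (0 <= self.w1 <= 1 and 0 <= self.w2 <= 1):
            raise ConfigurationError("weights must lie in [0, 1]")
        if abs(self.w1 + self.w2 - 1.0) > 1e-12:
            raise ConfigurationError(f"w1 + w2 must equal 1, got {self.w1 + self.w2}")
        if self.n_select < 1:
            raise ConfigurationError("n_select must be >= 1")


def _rescale(values: np.ndarray, invert: bool) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise InvalidParameterError("need >= 2 design points to rescale")
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:
        warnings.warn("degenerate desirability anchors (all values equal); returning 1s")
        return np.ones_like(values)
    if invert:
        return (values - hi) / (lo - hi)
    return (values - lo) / (hi - lo)


def desirability_mean(rbar: np.ndarray) -> np.ndarray:
    """d(r̄ᵢ): min–max rescaling, larger mean response → larger desirability."""
    return _rescale(rbar, invert=False)


def desirability_var(nu: np.ndarray) -> np.ndarray:
    """d(νᵢ): inverse rescaling, larger variability → smaller desirability."""
    return _rescale(nu, invert=True)


def combined_desirability(
    d_r: np.ndarray, d_v: np.ndarray, cfg: DesirabilityConfig = DesirabilityConfig()
) -> np.ndarray:
    """Dᵢ = w1·d(r̄ᵢ) + w2·d(νᵢ) (convex combination, stays in [0, 1])."""
    d_r = np.asarray(d_r, dtype=float)
    d_v = np.asarray(d_v, dtype=float)
    if d_r.shape != d_v.shape:
        raise InvalidParameterError("d_r and d_v must have equal length")
    return cfg.w1 * d_r + cfg.w2 * d_v


@dataclass
class DesirabilityRanking:
    """Scored, ranked and selected experiments plus the rescaling anchors."""

    table: pd.DataFrame  # exp_id, factors, r_mean, nu, d_r, d_v, D, rank, selected
    anchors: dict[str, float]
    config: DesirabilityConfig

    @property
    def selected(self) -> pd.DataFrame:
        return self.table[self.table["selected"]]

    @property
    def best(self) -> pd.Series:
        return self.table[self.table["rank"] == 1].iloc[0]


def rank_and_select(
    summaries: pd.DataFrame, cfg: DesirabilityConfig = DesirabilityConfig()
) -> DesirabilityRanking:
    """Compute desirabilities, rank descending by D and select the top experiments.

    ``summaries`` needs columns ``exp_id``, ``r_mean`` and ``nu`` (factor
    columns are carried through).  Ties in D are broken by lower exp_id for
    reproducibility.
    """
    if len(summaries) < cfg.n_select:
        raise InvalidParameterError(
            f"cannot select {cfg.n_select} of {len(summaries)} experiments"
        )
    table = summaries.copy().reset_index(drop=True)
    rbar = table["r_mean"].to_numpy()
    nu = table["nu"].to_numpy()
    d_r = desirability_mean(rbar)
    d_v = desirability_var(nu)
    D = combined_desirability(d_r, d_v, cfg)
    table["d_r"] = d_r
    table["d_v"] = d_v
    table["D"] = D
    order = np.lexsort((table["exp_id"].to_numpy(), -D))
    rank = np.empty(len(table), dtype=int)
    rank[order] = np.arange(1, len(table) + 1)
    table["rank"] = rank
    table["selected"] = table["rank"] <= cfg.n_select
    anchors = {
        "L_rbar": float(rbar.min()),
        "U_rbar": float(rbar.max()),
        "L_nu": float(nu.min()),
        "U_nu": float(nu.max()),
    }
    return DesirabilityRanking(table=table, anchors=anchors, config=cfg)


@dataclass
class RSModel:
    """Quadratic response surface of D over the factors (visualization aid)."""

    factor_names: list[str]
    terms: list[str]  # "1", names, pairwise interactions, squares
    coefficients: np.ndarray
    r2: float

    def predict(self, points: np.ndarray) -> np.ndarray:
        return _quadratic_design_matrix(np.atleast_2d(points)) @ self.coefficients


def _quadratic_design_matrix(x: np.ndarray) -> np.ndarray:
    n, f = x.shape
    cols = [np.ones(n)]
    for i in range(f):
        cols.append(x[:, i])
    for i, j in itertools.combinations(range(f), 2):
        cols.append(x[:, i] * x[:, j])
    for i in range(f):
        cols.append(x[:, i] ** 2)
    return np.column_stack(cols)


def _term_names(names: list[str]) -> list[str]:
    terms = ["1"] + list(names)
    terms += [f"{a}:{b}" for a, b in itertools.combinations(names, 2)]
    terms += [f"{n}^2" for n in names]
    return terms


def fit_response_surface(design: Design, D: np.ndarray) -> RSModel:
    """Ordinary least-squares quadratic fit of D over the design factors.

    The model has 1 + f + f(f−1)/2 + f coefficients for f factors; a
    rank-deficient design matrix (confounded terms) raises an error naming
    the deficiency.
    """
    x = np.asarray(design.points, dtype=float)
    D = np.asarray(D, dtype=float)
    mat = _quadratic_design_matrix(x)
    names = _term_names(design.space.names)
    if len(D) < mat.shape[1]:
        raise InvalidParameterError(
            f"need >= {mat.shape[1]} points for {len(names)} quadratic terms, got {len(D)}"
        )
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        # identify confounded columns via QR pivoting on the gram matrix
        _, r = np.linalg.qr(mat)
        diag = np.abs(np.diag(r))
        bad = [names[i] for i in np.flatnonzero(diag < 1e-10 * diag.max())]
        raise InvalidParameterError(f"rank-deficient design; confounded terms: {bad}")
    coef, *_ = np.linalg.lstsq(mat, D, rcond=None)
    fitted = mat @ coef
    ss_tot = float(np.sum((D - D.mean()) ** 2))
    r2 = 1.0 - float(np.sum((D - fitted) ** 2)) / ss_tot if ss_tot > 0 else 1.0
    return RSModel(factor_names=design.space.names, terms=names, coefficients=coef, r2=r2)


def response_surface_grid(
    model: RSModel,
    design: Design,
    factor_x: str,
    factor_y: str,
    fixed: dict[str, float],
    n_grid: int = 41,
) -> pd.DataFrame:
    """Contour grid of fitted D over two factors at fixed values of the rest."""
    names = design.space.names
    ix, iy = names.index(factor_x), names.index(factor_y)
    lo, hi = design.space.lowers, design.space.uppers
    gx = np.linspace(lo[ix], hi[ix], n_grid)
    gy = np.linspace(lo[iy], hi[iy], n_grid)
    xx, yy = np.meshgrid(gx, gy)
    pts = np.empty((xx.size, len(names)))
    for j, n in enumerate(names):
        if n == factor_x:
            pts[:, j] = xx.ravel()
        elif n == factor_y:
            pts[:, j] = yy.ravel()
        else:
            if n not in fixed:
                raise InvalidParameterError(f"no fixed value for factor {n!r}")
            pts[:, j] = fixed[n]
    return pd.DataFrame(
        {factor_x: xx.ravel(), factor_y: yy.ravel(), "D_fit": model.predict(pts)}
    )
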