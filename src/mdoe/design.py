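"""Space-filling design planning by k-means clustering.

A large uniform random sample (default one million points) is drawn inside
the factor bounds, optionally rejection-filtered by a feasibility
predicate, and partitioned by k-means; the k cluster centers are the
planned factor combinations.  Unlike classical optimal designs this works
for any number of factors and any feasible-region shape.  Factors are
min–max scaled to [0, 1] before clustering so that units do not dominate
the Euclidean distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from mdoe.errors import DesignError, InvalidParameterError


@dataclass(frozen=True)
class Factor:
    name: str
    lower: float
    upper: float
    unit: str = ""

    def __post_init__(self):
        if not self.lower < self.upper:
            raise InvalidParameterError(
                f"factor {self.name!r}: lower ({self.lower}) must be < upper ({self.upper})"
            )


@dataclass
class DesignSpace:
    """Bounded (optionally constrained) factor space."""

    factors: tuple[Factor, ...]
    feasible: Callable[[np.ndarray], np.ndarray] | None = None  # vectorized predicate

    def __post_init__(self):
        if len(self.factors) == 0:
            raise InvalidParameterError("need at least one factor")
        names = [f.name for f in self.factors]
        if len(names) != len(set(names)):
            raise InvalidParameterError("factor names must be unique")

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.factors]

    @property
    def lowers(self) -> np.ndarray:
        return np.array([f.lower for f in self.factors])

    @property
    def uppers(self) -> np.ndarray:
        return np.array([f.upper for f in self.factors])

    def scale(self, points: np.ndarray) -> np.ndarray:
        """Min–max map to the unit cube (exact inverse of :meth:`unscale`)."""
        return (points - self.lowers) / (self.uppers - self.lowers)

    def unscale(self, unit_points: np.ndarray) -> np.ndarray:
        return unit_points * (self.uppers - self.lowers) + self.lowers

    def contains(self, points: np.ndarray) -> np.ndarray:
        inside = np.all((points >= self.lowers) & (points <= self.uppers), axis=1)
        if self.feasible is not None:
            inside &= np.asarray(self.feasible(points), dtype=bool)
        return inside


@dataclass
class Design:
    """k planned factor combinations with generation metadata."""

    space: DesignSpace
    points: np.ndarray  # k x n_factors, factor units
    n_random: int
    seed: int

    def __post_init__(self):
        if not np.all(self.space.contains(self.points)):
            raise DesignError("design contains out-of-bounds or infeasible points")

    @property
    def k(self) -> int:
        return len(self.points)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.points, columns=self.space.names)
        frame.insert(0, "exp_id", np.arange(1, self.k + 1))
        return frame


def sample_space(
    space: DesignSpace, n_random: int = 1_000_000, seed: int = 0
) -> np.ndarray:
    """Uniform i.i.d. points within bounds, rejection-filtered for feasibility.

    Raises :class:`DesignError` if fewer than 0.1% of the raw draws are
    feasible, which usually means the bounds should be revised.
    """
    rng = np.random.default_rng(seed)
    raw = rng.uniform(space.lowers, space.uppers, size=(n_random, len(space.factors)))
    if space.feasible is None:
        return raw
    mask = np.asarray(space.feasible(raw), dtype=bool)
    if mask.mean() < 1e-3:
        raise DesignError(
            f"only {mask.mean():.2%} of sampled points are feasible; revise the bounds"
        )
    return raw[mask]


def plan_design(
    space: DesignSpace,
    k: int = 29,
    n_random: int = 1_000_000,
    seed: int = 0,
    n_restarts: int = 10,
) -> Design:
    """k-means design: cluster the random cloud, return the k centers.

    Clustering happens in min–max scaled coordinates with greedy (k-means++)
    seeding and ``n_restarts`` restarts, keeping the best inertia.  Centers
    are mapped back to factor units; as convex combinations of in-bounds
    points they are guaranteed in-bounds themselves.
    """
    if k < 1:
        raise InvalidParameterError("k must be >= 1")
    if n_random < k:
        raise InvalidParameterError(f"n_random ({n_random}) must be >= k ({k})")
    cloud = sample_space(space, n_random, seed)
    if len(cloud) < k:
        raise DesignError(f"only {len(cloud)} feasible points for k={k}")
    scaled = space.scale(cloud)
    if k == len(cloud):
        centers = scaled
    else:
        km = KMeans(
            n_clusters=k,
            init="k-means++",
            n_init=n_restarts,
            random_state=np.random.SeedSequence(seed).spawn(1)[0].generate_state(1)[0] % (2**31),
        )
        km.fit(scaled)
        centers = km.cluster_centers_
    points = space.unscale(np.clip(centers, 0.0, 1.0))
    # sort by first factor for a stable, reader-friendly ordering
    order = np.lexsort(points.T[::-1])
    return Design(space=space, points=points[order], n_random=n_random, seed=seed)


def max_nearest_distance(design_points: np.ndarray, test_points: np.ndarray) -> float:
    """Fill distance: max over test points of the distance to the nearest design point."""
    d2 = (
        np.sum(test_points**2, axis=1)[:, None]
        - 2 * test_points @ design_points.T
        + np.sum(design_points**2, axis=1)[None, :]
    )
    return float(np.sqrt(np.maximum(d2.min(axis=1), 0.0).max()))
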