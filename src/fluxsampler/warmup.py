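"""LP-generated warm-up points for the hit-and-run family of samplers.

The artificial-centering samplers need an initial set of points whose
pairwise directions span the flux polytope. Following the COBRA-style
warm-up procedure these are LP optima: part (1) minimises and maximises
each reaction's flux in turn (2n points); part (2) optimises random weight
vectors (used only when emulating gpSampler, which needs one warm-up point
per chain). LP optima sit on the polytope boundary, where the feasible
segment through a point degenerates, so the whole set is optionally pulled
toward its centroid by a convex blend before sampling starts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._lp import solve_flux_lp
from .polytope import SolutionSpace

__all__ = ["WarmupSet", "minmax_warmup", "random_weight_warmup", "pull_to_interior"]


@dataclass
class WarmupSet:
    """A matrix of warm-up points (one per row) with their provenance.

    ``origin[i]`` is ``"minmax"`` or ``"random_weight"``; ``pulled`` records
    whether the interior-pulling blend has been applied.
    """

    points: np.ndarray
    origin: list[str]
    pulled: bool = False

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[0] != len(self.origin):
            raise ValueError("one origin tag per warm-up point required")
        if self.points.shape[0] < 1:
            raise ValueError("a warm-up set needs at least one point")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)


def minmax_warmup(space: SolutionSpace) -> WarmupSet:
    """2n warm-up points: min and max flux of each reaction (model order).

    Point order is deterministic: reaction 0 min, reaction 0 max, reaction 1
    min, ... Duplicate optima are kept. Raises on infeasible or unbounded
    LPs (the polytope must be non-empty and bounded).
    """
    n = space.n
    pts = np.empty((2 * n, n))
    for i in range(n):
        c = np.zeros(n)
        c[i] = 1.0
        rid = space.model.reaction_ids[i]
        pts[2 * i] = solve_flux_lp(space.S, space.lb, space.ub, c, context=f"min {rid}")
        pts[2 * i + 1] = solve_flux_lp(
            space.S, space.lb, space.ub, c, maximize=True, context=f"max {rid}"
        )
    return WarmupSet(pts, ["minmax"] * (2 * n))


def random_weight_warmup(
    space: SolutionSpace, count: int, rng: np.random.Generator
) -> WarmupSet:
    """Warm-up points maximising random objectives c ~ Uniform[-1, 1]^n."""
    if count < 1:
        raise ValueError("count must be >= 1")
    n = space.n
    pts = np.empty((count, n))
    for j in range(count):
        c = rng.uniform(-1.0, 1.0, size=n)
        pts[j] = solve_flux_lp(
            space.S, space.lb, space.ub, c, maximize=True, context=f"random weight {j}"
        )
    return WarmupSet(pts, ["random_weight"] * count)


def pull_to_interior(wset: WarmupSet, tau: float = 0.5) -> WarmupSet:
    """Blend every point toward the set centroid: x -> c + tau * (x - c).

    tau = 1 is the identity; tau -> 0 collapses the set onto its centroid.
    Convexity of the polytope preserves feasibility for any tau in (0, 1].
    """
    if not (0.0 < tau <= 1.0):
        raise ValueError("tau must be in (0, 1]")
    if wset.n_points < 2:
        raise ValueError("interior pulling needs at least two points")
    c = wset.centroid
    pts = c + tau * (wset.points - c)
    return WarmupSet(pts, list(wset.origin), pulled=True)
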