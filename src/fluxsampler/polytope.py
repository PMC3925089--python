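"""Geometry of the steady-state flux polytope.

The solution space of a constraint-based model,

    P = {v : S v = 0, lb <= v <= ub},

is a bounded convex polytope inside the nullspace of S. Samplers need three
geometric primitives: a feasibility check with explicit tolerances, the
extent of the feasible segment through a point along a direction, and a
projection that pulls a point drifted off {S v = 0} by accumulated
floating-point error back onto it.

Because {S v = 0} is a linear subspace, the difference of two feasible
points is again in the nullspace; hit-and-run style moves along such
difference directions therefore preserve mass balance exactly up to
round-off, and the drift correction only has to absorb round-off.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import scipy.linalg

from .model_io import MetabolicModel

__all__ = [
    "SolutionSpace",
    "FeasibilityReport",
    "GeometryError",
    "DegenerateDirectionError",
    "OffNullspaceError",
    "DriftError",
]

logger = logging.getLogger(__name__)

#: Cap applied to a segment end when no bound is hit in that direction.
_UNBOUNDED_CAP = 1e6


class GeometryError(RuntimeError):
    pass


class DegenerateDirectionError(GeometryError):
    """Direction vector is (numerically) zero."""


class OffNullspaceError(GeometryError):
    """Direction does not preserve the mass-balance constraints."""


class DriftError(GeometryError):
    """Point has drifted too far off {S v = 0} to be safely corrected."""


class FeasibilityReport(NamedTuple):
    feasible: bool
    max_equality_residual: float
    worst_bound_violation: float


@dataclass
class SolutionSpace:
    """The flux polytope of a model with cached numerical structure.

    Parameters
    ----------
    model : MetabolicModel
        The generating model; must admit at least one feasible point.
    feas_tol : float
        Tolerance on the mass-balance residual ``max|S v|``.
    bound_tol : float
        Tolerance on bound violations.
    fixed_tol : float
        Reactions with ``ub - lb <= fixed_tol`` are treated as fixed; the
        samplers never move along these coordinates.
    dir_tol : float
        Direction components below this magnitude are ignored when
        intersecting a line with the bounds (prevents division blow-ups).
    drift_limit : float
        Maximum mass-balance residual :meth:`correct_drift` will repair.
    """

    model: MetabolicModel
    feas_tol: float = 1e-6
    bound_tol: float = 1e-6
    fixed_tol: float = 1e-9
    dir_tol: float = 1e-9
    drift_limit: float = 1e-3

    fixed_mask: np.ndarray = field(init=False, repr=False)
    _projector: np.ndarray | None = field(init=False, repr=False, default=None)
    _free_basis: np.ndarray | None = field(init=False, repr=False, default=None)

    def __post_init__(self) -> None:
        self.fixed_mask = (self.model.ub - self.model.lb) <= self.fixed_tol
        if np.all(self.fixed_mask) and self.model.n_reactions > 0:
            # A fully fixed polytope is a single point; nothing to sample.
            raise GeometryError("all reactions are fixed; the polytope is a point")

    # -- cached linear algebra ------------------------------------------------

    @property
    def S(self) -> np.ndarray:
        return self.model.S

    @property
    def lb(self) -> np.ndarray:
        return self.model.lb

    @property
    def ub(self) -> np.ndarray:
        return self.model.ub

    @property
    def n(self) -> int:
        return self.model.n_reactions

    @property
    def nullspace_projector(self) -> np.ndarray:
        """Orthogonal projector onto the nullspace of S (n x n)."""
        if self._projector is None:
            if self.S.shape[0] == 0:
                self._projector = np.eye(self.n)
            else:
                N = scipy.linalg.null_space(self.S)
                self._projector = N @ N.T
        return self._projector

    @property
    def free_nullspace_basis(self) -> np.ndarray:
        """Orthonormal basis (n x k) of {S v = 0} restricted to non-fixed coords.

        Directions in this basis move only the free reactions while keeping
        mass balance; used by plain hit-and-run and by rejection sampling.
        """
        if self._free_basis is None:
            rows = [self.S] if self.S.shape[0] else []
            if self.fixed_mask.any():
                eye = np.eye(self.n)[self.fixed_mask]
                rows.append(eye)
            if rows:
                A = np.vstack(rows)
                basis = scipy.linalg.null_space(A)
            else:
                basis = np.eye(self.n)
            if basis.shape[1] == 0:
                raise GeometryError("polytope has no free dimensions")
            self._free_basis = basis
        return self._free_basis

    # -- operations -----------------------------------------------------------

    def is_feasible(self, point: np.ndarray) -> FeasibilityReport:
        """Check S v = 0 and lb <= v <= ub within the space's tolerances."""
        v = np.asarray(point, dtype=float).ravel()
        if v.shape != (self.n,):
            raise ValueError(f"point has length {v.size}, expected {self.n}")
        eq = float(np.max(np.abs(self.S @ v))) if self.S.shape[0] else 0.0
        bound = float(np.max(np.maximum(self.lb - v, v - self.ub), initial=0.0))
        ok = eq <= self.feas_tol and bound <= self.bound_tol
        return FeasibilityReport(ok, eq, bound)

    def line_limits(self, point: np.ndarray, direction: np.ndarray) -> tuple[float, float]:
        """Feasible step range (alpha_min, alpha_max) along ``direction``.

        ``point + alpha * direction`` respects all bounds for every alpha in
        the returned interval, which always contains 0. The direction must be
        nonzero and (numerically) inside the nullspace of S so the move
        preserves mass balance.
        """
        v = np.asarray(point, dtype=float).ravel()
        d = np.asarray(direction, dtype=float).ravel()
        if v.shape != (self.n,) or d.shape != (self.n,):
            raise ValueError("point/direction length mismatch")
        nrm = float(np.linalg.norm(d))
        if nrm <= self.dir_tol:
            raise DegenerateDirectionError("direction is numerically zero")
        if self.S.shape[0]:
            resid = float(np.max(np.abs(self.S @ d)))
            if resid > self.feas_tol * (1.0 + nrm):
                raise OffNullspaceError(
                    f"direction leaves the nullspace (residual {resid:.3g})"
                )
        return self._line_limits_fast(v, d)

    def _line_limits_fast(self, v: np.ndarray, d: np.ndarray) -> tuple[float, float]:
        # Hot path shared with the samplers: no validation, bounds only.
        tol = self.dir_tol
        with np.errstate(divide="ignore", invalid="ignore"):
            to_ub = (self.ub - v) / d
            to_lb = (self.lb - v) / d
        pos = d > tol
        neg = d < -tol
        amax = np.inf
        amin = -np.inf
        if pos.any():
            amax = min(amax, float(np.min(to_ub[pos])))
            amin = max(amin, float(np.max(to_lb[pos])))
        if neg.any():
            amax = min(amax, float(np.min(to_lb[neg])))
            amin = max(amin, float(np.max(to_ub[neg])))
        cap = _UNBOUNDED_CAP * (1.0 + float(np.linalg.norm(v)))
        if amax > cap:
            logger.warning("unbounded segment capped at %g", cap)
            amax = cap
        if amin < -cap:
            logger.warning("unbounded segment capped at %g", -cap)
            amin = -cap
        # A feasible point may sit on a bound to round-off; keep 0 inside.
        return min(amin, 0.0), max(amax, 0.0)

    def correct_drift(self, point: np.ndarray) -> np.ndarray:
        """Project ``point`` back onto {S v = 0} and clamp tiny bound overshoots.

        Least-squares (orthogonal) projection; raises :class:`DriftError` if
        the mass-balance residual exceeds ``drift_limit``, which indicates a
        corrupted chain rather than accumulated round-off.
        """
        v = np.asarray(point, dtype=float).ravel()
        if self.S.shape[0] == 0:
            return np.clip(v, self.lb, self.ub)
        resid = float(np.max(np.abs(self.S @ v)))
        scale = max(1.0, float(np.max(np.abs(v))))
        if resid > self.drift_limit * scale:
            raise DriftError(f"residual {resid:.3g} exceeds drift limit")
        out = self.nullspace_projector @ v
        # Clamp violations no larger than bound_tol back onto the bound.
        low = (out < self.lb) & (out >= self.lb - self.bound_tol)
        high = (out > self.ub) & (out <= self.ub + self.bound_tol)
        out[low] = self.lb[low]
        out[high] = self.ub[high]
        return out
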