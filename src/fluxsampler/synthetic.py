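"""Synthetic metabolic models with known polytope geometry, plus a
rejection-sampling oracle.

These fixtures make every sampler and diagnostic testable without external
model downloads: hyper-rectangles have closed-form uniform moments, the
triangle has a known centroid and area, and random networks are built
around a planted strictly-interior flux vector so feasibility and
boundedness hold by construction. Mixed tight/loose bounds give the random
networks the anisotropic, elongated shape characteristic of real flux
spaces (loosely constrained reactions stretch the polytope, tightly
constrained ones flatten it).

Rejection sampling draws exactly-uniform points by proposing uniformly in
an axis-aligned bounding box of the polytope expressed in an orthonormal
nullspace parameterisation. The acceptance rate collapses with dimension,
so it is restricted to <= 4 effective dimensions and serves purely as a
ground-truth oracle for the chain samplers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from ._lp import solve_flux_lp
from .model_io import MetabolicModel, SampleMatrix
from .polytope import SolutionSpace
from .warmup import minmax_warmup

__all__ = [
    "FixtureSpec",
    "make_box",
    "make_triangle",
    "make_simplex",
    "make_anisotropic_slab",
    "make_random_network",
    "make_fixture",
    "rejection_sample",
    "GenerationError",
]


class GenerationError(RuntimeError):
    """Random-network construction failed after the retry budget."""


@dataclass
class FixtureSpec:
    """Declarative description of a synthetic fixture (for CLI emission)."""

    kind: str  # box | triangle | anisotropic_slab | random_network
    n: int = 3
    seed: int = 0
    params: dict[str, Any] = field(default_factory=dict)


def make_box(n: int, lb_vec, ub_vec) -> MetabolicModel:
    """Hyper-rectangle: no mass-balance rows, bounds only.

    Uniform moments are closed-form (mean (lb+ub)/2, variance width^2/12
    per coordinate), which anchors the sampler moment tests.
    """
    lb = np.broadcast_to(np.asarray(lb_vec, dtype=float), (n,)).copy()
    ub = np.broadcast_to(np.asarray(ub_vec, dtype=float), (n,)).copy()
    if np.any(lb >= ub):
        fixed = lb == ub
        if np.any(lb > ub):
            raise ValueError("lb must be < ub (or == for a fixed coordinate)")
        if fixed.all():
            raise ValueError("at least one coordinate must be free")
    return MetabolicModel(
        [f"R{j + 1}" for j in range(n)], [], np.empty((0, n)), lb, ub
    )


def make_triangle() -> MetabolicModel:
    """Three reactions x, y, s with x + y + s = 0, projecting onto the
    triangle {x, y >= 0, x + y <= 1}.

    Known geometry: FVA ranges x, y in [0, 1]; uniform centroid
    (1/3, 1/3, -2/3); uniform covariance diag(1/18, 1/18) in (x, y).
    """
    S = np.array([[1.0, 1.0, 1.0]])
    return MetabolicModel(
        ["x", "y", "s"], ["A"], S, np.array([0.0, 0.0, -1.0]), np.array([1.0, 1.0, 0.0])
    )


def make_simplex(d: int) -> MetabolicModel:
    """d+1 reactions x_1..x_d, s with sum x_i + s = 0, projecting onto the
    standard simplex {x >= 0, sum x <= 1}.

    The uniform distribution on the d-simplex has Beta(1, d) marginals
    (mean 1/(d+1)), concentrated near the coordinate faces; for larger d
    this is the slowest-mixing convex shape available at a given dimension,
    which makes it the fixture of choice for convergence-rate comparisons.
    """
    if d < 2:
        raise ValueError("need d >= 2")
    n = d + 1
    S = np.ones((1, n))
    lb = np.append(np.zeros(d), -1.0)
    ub = np.append(np.ones(d), 0.0)
    return MetabolicModel(
        [f"x{j + 1}" for j in range(d)] + ["s"], ["A"], S, lb, ub
    )


def make_anisotropic_slab(n: int = 4, aspect: float = 100.0) -> MetabolicModel:
    """Box with geometrically graded widths from 1 up to ``aspect``.

    Emulates the elongated/narrow axis mix of real flux polytopes without
    any stoichiometric coupling; used for mixing-rate comparisons.
    """
    if n < 2 or aspect <= 1.0:
        raise ValueError("need n >= 2 and aspect > 1")
    widths = aspect ** (np.arange(n) / (n - 1))
    return make_box(n, np.zeros(n), widths)


def make_random_network(
    m: int, n: int, seed: int = 0, density: float = 0.4
) -> MetabolicModel:
    """Sparse random stoichiometry with a planted interior flux vector.

    Entries of S are integers in {-2, -1, 1, 2}, each metabolite touching
    at least two reactions. A planted vector v0 in the nullspace (with all
    |v0_i| bounded away from zero, so no reaction is FVA-blocked) anchors
    asymmetric bounds: roughly half the reactions get loose bounds, half
    tight ones, producing an anisotropic polytope. Deterministic in
    ``seed``; raises :class:`GenerationError` if no valid construction is
    found within the retry budget.
    """
    if not (n > m >= 1):
        raise ValueError("need n > m >= 1")
    if density <= 0.0 or density > 1.0:
        raise ValueError("density must be in (0, 1]")
    rng = np.random.default_rng(seed)
    import scipy.linalg

    for _ in range(60):
        S = np.zeros((m, n))
        for i in range(m):
            nnz = max(2, rng.binomial(n, density))
            cols = rng.choice(n, size=min(nnz, n), replace=False)
            S[i, cols] = rng.choice([-2.0, -1.0, 1.0, 2.0], size=cols.size)
        basis = scipy.linalg.null_space(S)
        if basis.shape[1] == 0:
            continue
        # Pick the planted vector maximising its smallest |component|.
        best, best_min = None, 0.0
        for _ in range(60):
            v0 = basis @ rng.standard_normal(basis.shape[1])
            peak = np.max(np.abs(v0))
            if peak <= 0.0:
                continue
            v0 = v0 * (2.0 / peak)
            lo = float(np.min(np.abs(v0)))
            if lo > best_min:
                best, best_min = v0, lo
        if best is None or best_min < 0.05:
            continue
        v0 = best
        loose = rng.random(n) < 0.5
        width = np.where(loose, rng.uniform(5.0, 20.0, n), rng.uniform(0.2, 1.0, n))
        split = rng.uniform(0.25, 0.75, n)
        lb = v0 - width * split
        ub = v0 + width * (1.0 - split)
        return MetabolicModel(
            [f"R{j + 1}" for j in range(n)],
            [f"M{i + 1}" for i in range(m)],
            S,
            lb,
            ub,
        )
    raise GenerationError(f"no feasible random network for seed {seed}; reseed")


def make_fixture(spec: FixtureSpec) -> MetabolicModel:
    """Build the model described by a :class:`FixtureSpec`."""
    if spec.kind == "box":
        lb = spec.params.get("lb", 0.0)
        ub = spec.params.get("ub", 1.0)
        return make_box(spec.n, lb, ub)
    if spec.kind == "triangle":
        return make_triangle()
    if spec.kind == "simplex":
        return make_simplex(spec.n - 1)
    if spec.kind == "anisotropic_slab":
        return make_anisotropic_slab(spec.n, spec.params.get("aspect", 100.0))
    if spec.kind == "random_network":
        return make_random_network(
            spec.params.get("m", max(1, spec.n // 2)),
            spec.n,
            spec.seed,
            spec.params.get("density", 0.4),
        )
    raise ValueError(f"unknown fixture kind {spec.kind!r}")


def nullspace_bounding_box(space: SolutionSpace) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Particular point p, basis N and per-direction z-ranges of the polytope.

    Every feasible v equals p + N z with z in the returned box (the box is
    the axis-aligned hull in the nullspace frame, computed by two LPs per
    basis direction).
    """
    basis = space.free_nullspace_basis
    p = minmax_warmup(space).centroid
    k = basis.shape[1]
    z_lo = np.empty(k)
    z_hi = np.empty(k)
    for j in range(k):
        c = basis[:, j]
        vmin = solve_flux_lp(space.S, space.lb, space.ub, c, context=f"z{j} min")
        vmax = solve_flux_lp(space.S, space.lb, space.ub, c, maximize=True, context=f"z{j} max")
        z_lo[j] = c @ (vmin - p)
        z_hi[j] = c @ (vmax - p)
    return p, basis, np.column_stack([z_lo, z_hi])


def rejection_sample(
    space: SolutionSpace, count: int, rng: np.random.Generator
) -> SampleMatrix:
    """Exactly-uniform samples over the polytope (test oracle only).

    Proposes uniformly in the nullspace bounding box and keeps proposals
    respecting the bounds. Refuses spaces with more than 4 effective
    dimensions or a pilot acceptance rate below 1e-4, where rejection
    sampling stops being practical.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    p, basis, zbox = nullspace_bounding_box(space)
    k = basis.shape[1]
    if k > 4:
        raise ValueError(f"rejection sampling restricted to <= 4 effective dims, got {k}")
    lo, hi = zbox[:, 0], zbox[:, 1]

    def propose(size: int) -> np.ndarray:
        z = rng.uniform(lo, hi, size=(size, k))
        v = p + z @ basis.T
        ok = np.all(v >= space.lb - 1e-12, axis=1) & np.all(v <= space.ub + 1e-12, axis=1)
        return v[ok]

    pilot = propose(1000)
    rate = pilot.shape[0] / 1000.0
    if rate < 1e-4:
        raise RuntimeError(f"pilot acceptance rate {rate:.2e} too low for rejection sampling")
    chunks = [pilot]
    have = pilot.shape[0]
    while have < count:
        batch = propose(max(1000, int((count - have) / max(rate, 1e-3) * 1.2)))
        chunks.append(batch)
        have += batch.shape[0]
    samples = np.vstack(chunks)[:count]
    meta = {"sampler": "rejection", "n_samples": count, "acceptance_rate_pilot": rate}
    return SampleMatrix(samples, list(space.model.reaction_ids), meta)
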