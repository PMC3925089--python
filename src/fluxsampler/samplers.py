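"""Hit-and-run family samplers for the steady-state flux polytope.

Three chain-orchestration policies share one primitive, the artificial-
centering hit-and-run (ACHR) iterate:

* ``sample_hr`` — plain hit-and-run: isotropic directions drawn in the
  nullspace of S, a uniform step on the feasible segment, optional thinning.
* ``sample_gp`` — gpSampler emulation: one warm-up point per requested
  sample; each short chain runs ``step_count`` ACHR iterates from its
  warm-up point and returns only its end point.
* ``sample_optgp`` — optGpSampler: a few long chains started at randomly
  chosen warm-up points; each chain runs continuously and every
  ``step_count``-th iterate is stored, so the s-th stored sample has
  travelled s * step_count iterates from the chain start. Compared to the
  gp scheme this uses far fewer but much longer chains, which helps the
  sampler escape the neighbourhood of the boundary warm-up points.

An ACHR iterate draws a previous point p from a direction pool, moves along
(p - center) / ||p - center|| where ``center`` is the running mean of all
absorbed points, and takes a uniform step on the feasible segment.
Difference directions between feasible points stay in the nullspace of S,
so mass balance is preserved exactly up to round-off; round-off is removed
by a periodic least-squares projection and before any sample is stored.

ACHR iterates are not a Markov chain (directions depend on the past), so
none of these samplers carries an asymptotic uniformity guarantee;
empirical convergence is assessed with :mod:`fluxsampler.diagnostics` and
:mod:`fluxsampler.deviation`.

Chains are logical: each owns an RNG stream spawned from (master seed,
chain index), so results depend only on the configuration, never on how
many worker processes execute the chains. The chain loops run in compiled
kernels (:mod:`fluxsampler._kernels`) that consume the random stream
exactly like the pure-Python :func:`achr_step` reference.
"""

from __future__ import annotations

import math
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .model_io import SampleMatrix
from .polytope import SolutionSpace
from .warmup import WarmupSet, minmax_warmup, pull_to_interior, random_weight_warmup

__all__ = [
    "SamplerConfig",
    "ChainState",
    "ConfigurationError",
    "DegeneratePoolError",
    "achr_step",
    "sample_optgp",
    "sample_gp",
    "sample_hr",
]

#: Interval (in iterates) between nullspace re-projections of the chain point.
DRIFT_CORRECT_EVERY = 100
#: Minimum usable segment length; shorter segments trigger a direction redraw.
_MIN_SEGMENT = 1e-12
#: Attempts at drawing a usable direction before the deterministic fallback.
_MAX_REDRAWS = 10


class ConfigurationError(ValueError):
    pass


class DegeneratePoolError(RuntimeError):
    """The direction pool has collapsed onto the chain center."""


@dataclass
class SamplerConfig:
    """Configuration shared by the chain-based samplers.

    n_samples
        Total number of stored samples (nS).
    step_count
        ACHR iterates between stored samples (optgp thinning) or the length
        of each short chain (gp). st = 0 is allowed in gp mode only and
        returns the pulled warm-up points themselves.
    n_chains
        Logical chain count (nP). Ignored in gp mode, where the chain count
        equals ``n_samples`` by construction.
    seed
        Master seed; every chain derives an independent stream from it.
    mode
        One of ``"hr"``, ``"gp"``, ``"optgp"``.
    """

    n_samples: int
    step_count: int
    n_chains: int = 1
    seed: int = 0
    mode: str = "optgp"

    def __post_init__(self) -> None:
        if self.mode not in ("hr", "gp", "optgp"):
            raise ConfigurationError(f"unknown sampler mode {self.mode!r}")
        if self.n_samples < 1:
            raise ConfigurationError("n_samples must be >= 1")
        if self.step_count < 0 or (self.step_count == 0 and self.mode != "gp"):
            raise ConfigurationError("step_count must be >= 1 (0 allowed in gp mode)")
        if self.n_chains < 1:
            raise ConfigurationError("n_chains must be >= 1")
        if self.mode == "optgp" and self.n_samples < self.n_chains:
            raise ConfigurationError(
                f"optgp mode needs n_samples >= n_chains "
                f"({self.n_samples} < {self.n_chains})"
            )


@dataclass
class ChainState:
    """Mutable state of one ACHR chain.

    ``center`` is the running mean of the ``iterate_count`` points absorbed
    so far (the pool-initialising warm-up points plus every accepted
    iterate). ``pool[:pool_count]`` is the direction pool: warm-up points
    plus, in optgp mode, this chain's stored samples.
    """

    current: np.ndarray
    center: np.ndarray
    iterate_count: int
    pool: np.ndarray
    pool_count: int
    rng: np.random.Generator


def achr_step(space: SolutionSpace, state: ChainState) -> ChainState:
    """Advance ``state`` by one ACHR iterate (in place; returns ``state``).

    Draws a pool point p uniformly, moves along the unit vector from the
    running center toward p by a step uniform on the feasible segment, then
    absorbs the new point into the running center. Degenerate draws (pool
    point at the center, or a segment shorter than 1e-12) are redrawn up to
    10 times, after which the pool point farthest from the center is used;
    a pool that offers no usable direction at all raises
    :class:`DegeneratePoolError`.

    This is the reference implementation of the iterate; the sampling
    drivers run the bit-identical compiled version in
    :mod:`fluxsampler._kernels`.
    """
    rng = state.rng
    fixed = space.fixed_mask
    any_fixed = bool(fixed.any())
    d = None
    for _ in range(_MAX_REDRAWS):
        idx = int(rng.random() * state.pool_count)
        idx = min(idx, state.pool_count - 1)
        diff = state.pool[idx] - state.center
        if any_fixed:
            diff[fixed] = 0.0
        nrm = math.sqrt(float(diff @ diff))
        if nrm <= space.dir_tol:
            continue
        cand = diff / nrm
        amin, amax = space._line_limits_fast(state.current, cand)
        if amax - amin >= _MIN_SEGMENT:
            d = cand
            break
    if d is None:
        # Deterministic fallback: the pool point farthest from the center.
        diffs = state.pool[: state.pool_count] - state.center
        if any_fixed:
            diffs[:, fixed] = 0.0
        norms = np.linalg.norm(diffs, axis=1)
        far = int(np.argmax(norms))
        if norms[far] <= space.dir_tol:
            raise DegeneratePoolError("direction pool collapsed onto the center")
        d = diffs[far] / norms[far]
        amin, amax = space._line_limits_fast(state.current, d)
        if amax - amin < _MIN_SEGMENT:
            raise DegeneratePoolError("no usable direction in the pool")
    alpha = amin + rng.random() * (amax - amin)
    state.current = state.current + alpha * d
    k = state.iterate_count
    state.center = state.center + (state.current - state.center) / (k + 1)
    state.iterate_count = k + 1
    return state


def _kernel_geometry(space: SolutionSpace):
    """Arrays handed to the compiled kernels."""
    has_proj = space.S.shape[0] > 0
    proj = space.nullspace_projector if has_proj else np.empty((0, 0))
    return (
        np.ascontiguousarray(space.lb),
        np.ascontiguousarray(space.ub),
        np.ascontiguousarray(space.fixed_mask),
        space.dir_tol,
        np.ascontiguousarray(proj),
        has_proj,
        space.bound_tol,
    )


# ---------------------------------------------------------------------------
# optGp mode


def _chain_sample_counts(n_samples: int, n_chains: int) -> list[int]:
    """Allocate nS samples over nP chains; earlier chains take the remainder."""
    q, r = divmod(n_samples, n_chains)
    return [q + 1 if j < r else q for j in range(n_chains)]


def _run_optgp_chain(
    space: SolutionSpace,
    warm_points: np.ndarray,
    n_store: int,
    step_count: int,
    seed_seq: np.random.SeedSequence,
) -> np.ndarray:
    rng = np.random.default_rng(seed_seq)
    w, n = warm_points.shape
    pool = np.empty((w + n_store, n))
    pool[:w] = warm_points
    lb, ub, fixed, dir_tol, proj, has_proj, bound_tol = _kernel_geometry(space)
    try:
        return _kernels.optgp_chain(
            lb, ub, fixed, dir_tol, proj, has_proj, bound_tol,
            pool, w, step_count, n_store, DRIFT_CORRECT_EVERY, rng,
        )
    except RuntimeError as exc:
        raise DegeneratePoolError(str(exc)) from exc


def _run_optgp_chain_star(job) -> np.ndarray:
    return _run_optgp_chain(*job)


def sample_optgp(
    space: SolutionSpace,
    cfg: SamplerConfig,
    *,
    tau: float = 0.5,
    workers: int = 1,
) -> SampleMatrix:
    """optGpSampler: few long thinned ACHR chains from LP warm-up points.

    Warm-up is min/max LPs only (2n points), pulled toward the interior by
    ``tau``. Each of ``cfg.n_chains`` chains starts at a warm-up point
    chosen uniformly by its own RNG stream and stores every
    ``cfg.step_count``-th iterate until its share of ``cfg.n_samples`` is
    collected (earlier chains take the remainder). Output rows are
    chain-major and deterministic given the seed, independent of
    ``workers``.
    """
    if cfg.mode != "optgp":
        raise ConfigurationError(f"config mode is {cfg.mode!r}, expected 'optgp'")
    warm = pull_to_interior(minmax_warmup(space), tau)
    counts = _chain_sample_counts(cfg.n_samples, cfg.n_chains)
    children = np.random.SeedSequence(cfg.seed).spawn(cfg.n_chains)
    jobs = [
        (space, warm.points, counts[j], cfg.step_count, children[j])
        for j in range(cfg.n_chains)
    ]
    if workers > 1 and cfg.n_chains > 1:
        with ProcessPoolExecutor(max_workers=workers) as pool:
            blocks = list(pool.map(_run_optgp_chain_star, jobs))
    else:
        blocks = [_run_optgp_chain(*job) for job in jobs]
    samples = np.vstack(blocks)
    meta = {
        "sampler": "optgp",
        "n_samples": cfg.n_samples,
        "step_count": cfg.step_count,
        "n_chains": cfg.n_chains,
        "seed": cfg.seed,
        "tau": tau,
        "chain_sample_counts": counts,
        "pool_policy": "warmup+stored",
    }
    return SampleMatrix(samples, list(space.model.reaction_ids), meta)


# ---------------------------------------------------------------------------
# gp mode


def _gp_warmup(space: SolutionSpace, n_samples: int, rng: np.random.Generator) -> WarmupSet:
    base = minmax_warmup(space)
    w = base.n_points
    if n_samples > w:
        extra = random_weight_warmup(space, n_samples - w, rng)
        return WarmupSet(
            np.vstack([base.points, extra.points]), base.origin + extra.origin
        )
    if n_samples < w:
        return WarmupSet(base.points[:n_samples], base.origin[:n_samples])
    return base


def sample_gp(space: SolutionSpace, cfg: SamplerConfig, *, tau: float = 0.5) -> SampleMatrix:
    """gpSampler emulation: one short ACHR chain per sample.

    Warm-up: 2n min/max points, extended with random-weight LP optima when
    ``cfg.n_samples`` exceeds 2n (truncated when below). After interior
    pulling, chain i starts at warm-up point i, runs exactly
    ``cfg.step_count`` iterates with the full warm-up set as its direction
    pool and the warm-up centroid as initial center, and returns its end
    point. ``step_count = 0`` returns the pulled warm-up points themselves.
    """
    if cfg.mode != "gp":
        raise ConfigurationError(f"config mode is {cfg.mode!r}, expected 'gp'")
    n_s = cfg.n_samples
    master = np.random.SeedSequence(cfg.seed)
    weight_seed, *chain_seeds = master.spawn(n_s + 1)
    warm = _gp_warmup(space, n_s, np.random.default_rng(weight_seed))
    warm = pull_to_interior(warm, tau) if warm.n_points >= 2 else warm
    out = np.empty((n_s, space.n))
    if cfg.step_count == 0:
        out[:] = warm.points
    else:
        lb, ub, fixed, dir_tol, proj, has_proj, bound_tol = _kernel_geometry(space)
        warm_pts = np.ascontiguousarray(warm.points)
        centroid = warm.centroid
        for i in range(n_s):
            rng = np.random.default_rng(chain_seeds[i])
            try:
                out[i] = _kernels.gp_chain(
                    lb, ub, fixed, dir_tol, proj, has_proj, bound_tol,
                    warm_pts, centroid, i, cfg.step_count, DRIFT_CORRECT_EVERY, rng,
                )
            except RuntimeError as exc:
                raise DegeneratePoolError(str(exc)) from exc
    meta = {
        "sampler": "gp",
        "n_samples": n_s,
        "step_count": cfg.step_count,
        "n_chains": n_s,
        "seed": cfg.seed,
        "tau": tau,
        "chain_sample_counts": [1] * n_s,
        "pool_policy": "warmup-only",
    }
    return SampleMatrix(out, list(space.model.reaction_ids), meta)


# ---------------------------------------------------------------------------
# plain hit-and-run


def sample_hr(
    space: SolutionSpace, n_samples: int, thin: int = 1, seed: int = 0
) -> SampleMatrix:
    """Plain hit-and-run with isotropic nullspace directions.

    Directions are uniform on the unit sphere of the nullspace of S
    restricted to non-fixed reactions (standard normal in an orthonormal
    nullspace basis, normalised); the step is uniform on the feasible
    segment. The chain starts at the centroid of the min/max warm-up set
    and every ``thin``-th point is stored.
    """
    if n_samples < 1:
        raise ConfigurationError("n_samples must be >= 1")
    if thin < 1:
        raise ConfigurationError("thin must be >= 1")
    basis = np.ascontiguousarray(space.free_nullspace_basis)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    start = minmax_warmup(space).centroid
    lb, ub, fixed, dir_tol, proj, has_proj, bound_tol = _kernel_geometry(space)
    try:
        samples = _kernels.hr_chain(
            lb, ub, dir_tol, basis, proj, has_proj, bound_tol,
            start, n_samples, thin, DRIFT_CORRECT_EVERY, rng,
        )
    except RuntimeError as exc:
        raise DegeneratePoolError(str(exc)) from exc
    meta = {
        "sampler": "hr",
        "n_samples": n_samples,
        "step_count": thin,
        "n_chains": 1,
        "seed": seed,
        "chain_sample_counts": [n_samples],
    }
    return SampleMatrix(samples, list(space.model.reaction_ids), meta)
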