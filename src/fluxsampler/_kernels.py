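"""Compiled chain kernels.

The samplers spend essentially all their time in the ACHR iterate, a few
dozen scalar operations on short vectors, where the interpreter overhead of
vectorised numpy dominates. These numba kernels implement the identical
iterate (same random-stream consumption as the pure-Python
:func:`fluxsampler.samplers.achr_step`, which remains the readable
reference; agreement between the two paths is pinned by a test) and run the
whole chain loop compiled.

All random draws go through ``Generator.random`` / ``standard_normal`` so
the bit stream matches numpy's exactly for a given seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["optgp_chain", "gp_chain", "hr_chain"]

_MIN_SEGMENT = 1e-12
_MAX_REDRAWS = 10
_UNBOUNDED_CAP = 1e6


@njit(cache=True)
def _limits(lb, ub, dir_tol, v, d):
    """Feasible alpha range along d from v (bounds only)."""
    amin = -np.inf
    amax = np.inf
    n = v.shape[0]
    for j in range(n):
        dj = d[j]
        if dj > dir_tol:
            hi = (ub[j] - v[j]) / dj
            lo = (lb[j] - v[j]) / dj
        elif dj < -dir_tol:
            hi = (lb[j] - v[j]) / dj
            lo = (ub[j] - v[j]) / dj
        else:
            continue
        if hi < amax:
            amax = hi
        if lo > amin:
            amin = lo
    nrm2 = 0.0
    for j in range(n):
        nrm2 += v[j] * v[j]
    cap = _UNBOUNDED_CAP * (1.0 + np.sqrt(nrm2))
    if amax > cap:
        amax = cap
    if amin < -cap:
        amin = -cap
    if amin > 0.0:
        amin = 0.0
    if amax < 0.0:
        amax = 0.0
    return amin, amax


@njit(cache=True)
def _project_clamp(proj, has_proj, lb, ub, bound_tol, v):
    """Nullspace projection followed by clamping of tiny bound overshoots."""
    n = v.shape[0]
    if has_proj:
        out = proj @ v
        for j in range(n):
            if out[j] < lb[j] and out[j] >= lb[j] - bound_tol:
                out[j] = lb[j]
            elif out[j] > ub[j] and out[j] <= ub[j] + bound_tol:
                out[j] = ub[j]
    else:
        out = v.copy()
        for j in range(n):
            if out[j] < lb[j]:
                out[j] = lb[j]
            elif out[j] > ub[j]:
                out[j] = ub[j]
    return out


@njit(cache=True)
def _achr_iterate(lb, ub, fixed, dir_tol, pool, pool_count, center, current, k, rng, d):
    """One ACHR iterate; mutates current/center in place, returns k + 1."""
    n = lb.shape[0]
    found = False
    amin = 0.0
    amax = 0.0
    for _ in range(_MAX_REDRAWS):
        idx = int(rng.random() * pool_count)
        if idx == pool_count:
            idx = pool_count - 1
        nrm2 = 0.0
        for j in range(n):
            dj = 0.0 if fixed[j] else pool[idx, j] - center[j]
            d[j] = dj
            nrm2 += dj * dj
        nrm = np.sqrt(nrm2)
        if nrm <= dir_tol:
            continue
        inv = 1.0 / nrm
        for j in range(n):
            d[j] *= inv
        amin, amax = _limits(lb, ub, dir_tol, current, d)
        if amax - amin >= _MIN_SEGMENT:
            found = True
            break
    if not found:
        # Deterministic fallback: farthest pool point from the center.
        best = -1
        best2 = 0.0
        for i in range(pool_count):
            nrm2 = 0.0
            for j in range(n):
                dj = 0.0 if fixed[j] else pool[i, j] - center[j]
                nrm2 += dj * dj
            if nrm2 > best2:
                best2 = nrm2
                best = i
        if best < 0 or np.sqrt(best2) <= dir_tol:
            raise RuntimeError("direction pool collapsed onto the center")
        inv = 1.0 / np.sqrt(best2)
        for j in range(n):
            d[j] = 0.0 if fixed[j] else (pool[best, j] - center[j]) * inv
        amin, amax = _limits(lb, ub, dir_tol, current, d)
        if amax - amin < _MIN_SEGMENT:
            raise RuntimeError("no usable direction in the pool")
    alpha = amin + rng.random() * (amax - amin)
    kk = k + 1
    for j in range(n):
        cur = current[j] + alpha * d[j]
        current[j] = cur
        center[j] += (cur - center[j]) / kk
    return kk


@njit(cache=True)
def optgp_chain(
    lb, ub, fixed, dir_tol, proj, has_proj, bound_tol,
    pool, n_warm, step_count, n_store, drift_every, rng,
):
    """Run one optGp chain: store every step_count-th iterate, append stored
    samples to the direction pool. ``pool`` must have n_warm + n_store rows
    with the warm-up points in the first n_warm."""
    n = lb.shape[0]
    center = np.zeros(n)
    for i in range(n_warm):
        for j in range(n):
            center[j] += pool[i, j]
    for j in range(n):
        center[j] /= n_warm
    idx0 = int(rng.random() * n_warm)
    if idx0 == n_warm:
        idx0 = n_warm - 1
    current = pool[idx0].copy()
    d = np.empty(n)
    out = np.empty((n_store, n))
    k = n_warm
    pool_count = n_warm
    iterates = 0
    for s in range(n_store):
        for _ in range(step_count):
            k = _achr_iterate(lb, ub, fixed, dir_tol, pool, pool_count, center, current, k, rng, d)
            iterates += 1
            if iterates % drift_every == 0:
                current = _project_clamp(proj, has_proj, lb, ub, bound_tol, current)
        current = _project_clamp(proj, has_proj, lb, ub, bound_tol, current)
        out[s] = current
        pool[pool_count] = current
        pool_count += 1
    return out


@njit(cache=True)
def gp_chain(
    lb, ub, fixed, dir_tol, proj, has_proj, bound_tol,
    warm, centroid, start_index, step_count, drift_every, rng,
):
    """Run one gp chain: step_count iterates from warm[start_index] with the
    fixed warm-up pool; returns the end point."""
    n = lb.shape[0]
    center = centroid.copy()
    current = warm[start_index].copy()
    d = np.empty(n)
    k = warm.shape[0]
    for t in range(1, step_count + 1):
        k = _achr_iterate(lb, ub, fixed, dir_tol, warm, warm.shape[0], center, current, k, rng, d)
        if t % drift_every == 0:
            current = _project_clamp(proj, has_proj, lb, ub, bound_tol, current)
    return _project_clamp(proj, has_proj, lb, ub, bound_tol, current)


@njit(cache=True)
def hr_chain(
    lb, ub, dir_tol, basis, proj, has_proj, bound_tol,
    start, n_store, thin, drift_every, rng,
):
    """Plain hit-and-run: isotropic directions in the nullspace basis,
    storing every thin-th point."""
    n = lb.shape[0]
    kdim = basis.shape[1]
    current = start.copy()
    z = np.empty(kdim)
    d = np.empty(n)
    out = np.empty((n_store, n))
    iterates = 0
    for s in range(n_store):
        for _ in range(thin):
            ok = False
            for _try in range(_MAX_REDRAWS):
                for i in range(kdim):
                    z[i] = rng.standard_normal()
                nrm2 = 0.0
                for j in range(n):
                    acc = 0.0
                    for i in range(kdim):
                        acc += basis[j, i] * z[i]
                    d[j] = acc
                    nrm2 += acc * acc
                nrm = np.sqrt(nrm2)
                if nrm <= dir_tol:
                    continue
                inv = 1.0 / nrm
                for j in range(n):
                    d[j] *= inv
                amin, amax = _limits(lb, ub, dir_tol, current, d)
                if amax - amin >= _MIN_SEGMENT:
                    ok = True
                    break
            if not ok:
                raise RuntimeError("could not draw a usable hit-and-run direction")
            alpha = amin + rng.random() * (amax - amin)
            for j in range(n):
                current[j] += alpha * d[j]
            iterates += 1
            if iterates % drift_every == 0:
                current = _project_clamp(proj, has_proj, lb, ub, bound_tol, current)
        current = _project_clamp(proj, has_proj, lb, ub, bound_tol, current)
        out[s] = current
    return out
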