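"""Thin linear-programming layer used by FVA and warm-up generation.

All LPs in the package have the same feasible region -- the flux polytope
{v : S v = 0, lb <= v <= ub} -- and differ only in the objective. They are
solved with scipy's HiGHS interface, which is deterministic for a fixed
problem, so warm-up point sets are reproducible across runs.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog

__all__ = ["LPError", "InfeasibleError", "UnboundedError", "solve_flux_lp"]


class LPError(RuntimeError):
    """Generic LP solver failure."""


class InfeasibleError(LPError):
    """The flux polytope is empty."""


class UnboundedError(LPError):
    """The LP is unbounded (polytope not bounded in the objective direction)."""


def solve_flux_lp(
    S: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    c: np.ndarray,
    *,
    maximize: bool = False,
    context: str = "",
) -> np.ndarray:
    """Solve min (or max) c.v subject to S v = 0 and lb <= v <= ub.

    Returns the optimal flux vector. Raises :class:`InfeasibleError` /
    :class:`UnboundedError` with *context* (e.g. a reaction id) in the message.
    """
    obj = -np.asarray(c, dtype=float) if maximize else np.asarray(c, dtype=float)
    m = S.shape[0] if S.size else 0
    res = linprog(
        obj,
        A_eq=S if m else None,
        b_eq=np.zeros(m) if m else None,
        bounds=np.column_stack([lb, ub]),
        method="highs",
    )
    if res.status == 2:
        raise InfeasibleError(f"flux polytope infeasible ({context})" if context else "flux polytope infeasible")
    if res.status == 3:
        raise UnboundedError(f"LP unbounded ({context})" if context else "LP unbounded")
    if res.status != 0:
        raise LPError(f"LP solver failure status={res.status} ({context}): {res.message}")
    return np.asarray(res.x, dtype=float)
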