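"""The xy-deviation measure for comparing sampler outputs.

Given r runs of sampler x at step count x1 and r runs of sampler y at a
much larger step count x2, the measure compares, reaction by reaction, the
sorted and bound-normalised flux chains of x against the element-wise mean
of y's sorted chains. The per-reaction deviation

    D_j = (1 / (r N)) * sum over runs and sorted positions |x_hat - y_bar|

lies in [0, 1] because every normalised flux lies in a unit-width interval,
and the xy-deviation is the average of D_j over reactions (expressible as a
percentage). A small xy-deviation indicates that sampler x has converged
empirically to the sample distribution of sampler y; self-deviation
(x = y) measures run-to-run stability. The measure is asymmetric: y's runs
are reduced to their mean chain. Mean absolute deviation is used rather
than the standard deviation for robustness to erroneous measurements.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model_io import SampleMatrix

__all__ = [
    "RunSet",
    "DeviationReport",
    "AlignmentError",
    "sorted_normalized",
    "mean_chain",
    "xy_deviation",
    "symmetric_deviation",
]

#: Bound widths at or below this are treated as degenerate (ub = lb).
_WIDTH_TOL = 1e-12


class AlignmentError(ValueError):
    """Run sets disagree on reactions or sample counts."""


@dataclass
class RunSet:
    """r repeated runs of one sampler configuration plus normalisation bounds."""

    runs: list[SampleMatrix]
    lb: np.ndarray
    ub: np.ndarray

    def __post_init__(self) -> None:
        if not self.runs:
            raise ValueError("a RunSet needs at least one run")
        self.lb = np.asarray(self.lb, dtype=float).ravel()
        self.ub = np.asarray(self.ub, dtype=float).ravel()
        ids = self.runs[0].reaction_ids
        n = self.runs[0].n_samples
        for run in self.runs[1:]:
            if run.reaction_ids != ids:
                raise AlignmentError("runs disagree on reaction ids")
            if run.n_samples != n:
                raise AlignmentError("runs disagree on sample count")
        if self.lb.shape != (len(ids),) or self.ub.shape != (len(ids),):
            raise AlignmentError("bounds length does not match reactions")

    @classmethod
    def from_space(cls, space, runs: list[SampleMatrix]) -> "RunSet":
        return cls(runs, space.lb, space.ub)

    @property
    def reaction_ids(self) -> list[str]:
        return self.runs[0].reaction_ids

    @property
    def n_samples(self) -> int:
        return self.runs[0].n_samples

    @property
    def n_runs(self) -> int:
        return len(self.runs)


@dataclass
class DeviationReport:
    """Per-reaction deviations D_j and their average, the xy-deviation."""

    per_reaction: np.ndarray
    xy_deviation: float
    excluded_reactions: list[str]
    reaction_ids: list[str]
    config: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "xy_deviation": self.xy_deviation,
            "per_reaction": dict(zip(self.reaction_ids, map(float, self.per_reaction))),
            "excluded_reactions": self.excluded_reactions,
            "config": self.config,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"reaction_id": self.reaction_ids, "D_j": self.per_reaction}
        ).to_csv(path, sep="\t", index=False)


def sorted_normalized(run: SampleMatrix, lb: np.ndarray, ub: np.ndarray) -> np.ndarray:
    """Sort each reaction's fluxes ascending and divide by the bound width.

    Columns of reactions with ub = lb are set to zero (they carry no
    information and are excluded from the averaged deviation downstream).
    """
    if run.n_samples == 0:
        raise ValueError("empty run")
    width = np.asarray(ub, dtype=float) - np.asarray(lb, dtype=float)
    excluded = width <= _WIDTH_TOL
    safe = np.where(excluded, 1.0, width)
    out = np.sort(run.samples, axis=0) / safe
    out[:, excluded] = 0.0
    return out


def mean_chain(runs: RunSet) -> np.ndarray:
    """Element-wise mean of the sorted-normalised matrices of all runs."""
    mats = [sorted_normalized(run, runs.lb, runs.ub) for run in runs.runs]
    # Duplicated runs must give a bit-identical mean so that self-deviation
    # of copies is exactly zero; averaging would round in the last ulp.
    if all(np.array_equal(m, mats[0]) for m in mats[1:]):
        return mats[0]
    acc = np.zeros_like(mats[0])
    for m in mats:
        acc += m
    return acc / runs.n_runs


def xy_deviation(x_runs: RunSet, y_runs: RunSet) -> DeviationReport:
    """Deviation of sampler x's runs from the mean sorted chain of sampler y.

    Both run sets must share reactions, sample count N and normalisation
    bounds. All r * N absolute gaps per reaction are pooled into D_j; the
    scalar xy-deviation averages D_j over reactions with ub > lb.
    """
    if x_runs.reaction_ids != y_runs.reaction_ids:
        raise AlignmentError("x and y runs disagree on reaction ids")
    if x_runs.n_samples != y_runs.n_samples:
        raise AlignmentError(
            f"x runs have N={x_runs.n_samples}, y runs N={y_runs.n_samples}"
        )
    if not (
        np.allclose(x_runs.lb, y_runs.lb) and np.allclose(x_runs.ub, y_runs.ub)
    ):
        raise AlignmentError("x and y runs use different normalisation bounds")
    width = x_runs.ub - x_runs.lb
    excluded = width <= _WIDTH_TOL
    y_bar = mean_chain(y_runs)
    n_reactions = len(x_runs.reaction_ids)
    d = np.zeros(n_reactions)
    for run in x_runs.runs:
        d += np.abs(sorted_normalized(run, x_runs.lb, x_runs.ub) - y_bar).sum(axis=0)
    d /= x_runs.n_runs * x_runs.n_samples
    d[excluded] = 0.0
    included = ~excluded
    scalar = float(d[included].mean()) if included.any() else 0.0
    return DeviationReport(
        per_reaction=d,
        xy_deviation=scalar,
        excluded_reactions=[r for r, e in zip(x_runs.reaction_ids, excluded) if e],
        reaction_ids=list(x_runs.reaction_ids),
        config={
            "x_sampler": x_runs.runs[0].meta.get("sampler"),
            "x_step_count": x_runs.runs[0].meta.get("step_count"),
            "y_sampler": y_runs.runs[0].meta.get("sampler"),
            "y_step_count": y_runs.runs[0].meta.get("step_count"),
            "r_x": x_runs.n_runs,
            "r_y": y_runs.n_runs,
            "N": x_runs.n_samples,
        },
    )


def symmetric_deviation(x_runs: RunSet, y_runs: RunSet) -> float:
    """Convenience symmetric variant: max of the two directed xy-deviations.

    Not part of the published measure; useful when neither sampler is the
    designated reference.
    """
    return max(
        xy_deviation(x_runs, y_runs).xy_deviation,
        xy_deviation(y_runs, x_runs).xy_deviation,
    )
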