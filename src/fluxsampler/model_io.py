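"""Metabolic model and sample-matrix containers plus their file formats.

A constraint-based metabolic model is an m x n stoichiometric matrix ``S``
(metabolites x reactions) together with per-reaction flux bounds ``lb``,
``ub`` (conventionally mmol/gDW/h). The steady-state flux polytope is

    {v : S v = 0,  lb <= v <= ub}.

Reversible reactions are represented by a negative lower bound; reactions
are never split into forward/backward halves, so the samplers operate on
the signed flux polytope directly.

Supported model formats: SBML (Level 3 + FBC, read through cobrapy), the
cobra-style JSON dialect, and a plain tab-separated pair of files (matrix +
bounds) convenient for fixtures. Sample matrices round-trip through TSV
(17-significant-digit repr-faithful text) or HDF5 (bit-exact).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Sequence

import numpy as np
import pandas as pd

from ._lp import InfeasibleError, solve_flux_lp

__all__ = [
    "MetabolicModel",
    "SampleMatrix",
    "ModelValidationError",
    "ModelFormatError",
    "DEFAULT_BOUND",
    "read_model",
    "write_model_tsv",
    "flux_variability",
    "remove_blocked_reactions",
    "write_samples",
    "read_samples",
]

logger = logging.getLogger(__name__)

#: Bound magnitude substituted when a format carries no explicit bound;
#: arbitrarily large relative to realistic flux rates.
DEFAULT_BOUND = 1000.0


class ModelValidationError(ValueError):
    """The model violates a structural invariant (shape, bounds, ids)."""


class ModelFormatError(ValueError):
    """A model file could not be parsed in the named dialect."""


@dataclass
class MetabolicModel:
    """Stoichiometric matrix with flux bounds and identifiers.

    Attributes
    ----------
    reaction_ids : list of str
        Unique reaction identifiers, one per column of ``S``.
    metabolite_ids : list of str
        Unique metabolite identifiers, one per row of ``S``.
    S : ndarray, shape (m, n)
        Stoichiometric coefficients; positive = produced, negative = consumed.
    lb, ub : ndarray, shape (n,)
        Lower/upper flux bounds with ``lb <= ub`` elementwise.
    """

    reaction_ids: list[str]
    metabolite_ids: list[str]
    S: np.ndarray
    lb: np.ndarray
    ub: np.ndarray

    def __post_init__(self) -> None:
        self.S = np.atleast_2d(np.asarray(self.S, dtype=float))
        if self.S.size == 0:
            self.S = self.S.reshape(len(self.metabolite_ids), len(self.reaction_ids))
        self.lb = np.asarray(self.lb, dtype=float).ravel()
        self.ub = np.asarray(self.ub, dtype=float).ravel()
        m, n = self.S.shape
        if len(self.reaction_ids) != n:
            raise ModelValidationError(
                f"{len(self.reaction_ids)} reaction ids for {n} matrix columns"
            )
        if len(self.metabolite_ids) != m:
            raise ModelValidationError(
                f"{len(self.metabolite_ids)} metabolite ids for {m} matrix rows"
            )
        if self.lb.shape != (n,) or self.ub.shape != (n,):
            raise ModelValidationError("bound vectors must have one entry per reaction")
        bad = np.nonzero(self.lb > self.ub)[0]
        if bad.size:
            rid = self.reaction_ids[bad[0]]
            raise ModelValidationError(
                f"lower bound exceeds upper bound for reaction {rid!r} "
                f"(lb={self.lb[bad[0]]}, ub={self.ub[bad[0]]})"
            )
        if len(set(self.reaction_ids)) != n:
            raise ModelValidationError("reaction ids are not unique")
        if len(set(self.metabolite_ids)) != m:
            raise ModelValidationError("metabolite ids are not unique")

    @property
    def n_reactions(self) -> int:
        return self.S.shape[1]

    @property
    def n_metabolites(self) -> int:
        return self.S.shape[0]

    def nullspace_dimension(self) -> int:
        """Dimension of the nullspace of S (degrees of freedom of the flux space)."""
        if self.S.shape[0] == 0:
            return self.S.shape[1]
        return self.S.shape[1] - np.linalg.matrix_rank(self.S)

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            list(self.reaction_ids),
            list(self.metabolite_ids),
            self.S.copy(),
            self.lb.copy(),
            self.ub.copy(),
        )


@dataclass
class SampleMatrix:
    """A set of sampled flux vectors plus the provenance needed to rerun them.

    ``samples`` has one row per stored sample and one column per reaction,
    in the generating model's reaction order. ``meta`` records at minimum
    the sampler name, step count, chain count, master seed and per-chain
    sample counts; rows are in deterministic chain-major order.
    """

    samples: np.ndarray
    reaction_ids: list[str]
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.samples.shape[1] != len(self.reaction_ids):
            raise ModelValidationError(
                f"sample matrix has {self.samples.shape[1]} columns for "
                f"{len(self.reaction_ids)} reactions"
            )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.samples, columns=self.reaction_ids)


# ---------------------------------------------------------------------------
# model readers


def _model_from_cobra(cm) -> MetabolicModel:
    from cobra.util.array import create_stoichiometric_matrix

    S = create_stoichiometric_matrix(cm, array_type="dense")
    lb = np.array([r.lower_bound for r in cm.reactions], dtype=float)
    ub = np.array([r.upper_bound for r in cm.reactions], dtype=float)
    missing = ~np.isfinite(lb) | ~np.isfinite(ub)
    if missing.any():
        logger.warning(
            "%d reactions had non-finite bounds; substituting +/-%g",
            int(missing.sum()),
            DEFAULT_BOUND,
        )
        lb = np.where(np.isfinite(lb), lb, -DEFAULT_BOUND)
        ub = np.where(np.isfinite(ub), ub, DEFAULT_BOUND)
    return MetabolicModel(
        [r.id for r in cm.reactions],
        [m.id for m in cm.metabolites],
        S,
        lb,
        ub,
    )


def _read_sbml(path: Path) -> MetabolicModel:
    import cobra.io

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cm = cobra.io.read_sbml_model(str(path))
    except Exception as exc:  # cobra raises several exception types
        raise ModelFormatError(f"could not parse SBML file {path}: {exc}") from exc
    return _model_from_cobra(cm)


def _read_json(path: Path) -> MetabolicModel:
    import cobra.io

    try:
        cm = cobra.io.load_json_model(str(path))
    except Exception as exc:
        raise ModelFormatError(f"could not parse model JSON {path}: {exc}") from exc
    return _model_from_cobra(cm)


def _read_tsv(path: Path, bounds_path: Path | None) -> MetabolicModel:
    if bounds_path is None:
        bounds_path = path.with_suffix(".bounds.tsv")
    try:
        mat = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    except Exception as exc:
        raise ModelFormatError(f"could not parse matrix file {path}: {exc}") from exc
    try:
        bnd = pd.read_csv(bounds_path, sep="\t", float_precision="round_trip")
    except Exception as exc:
        raise ModelFormatError(f"could not parse bounds file {bounds_path}: {exc}") from exc
    for col in ("reaction_id", "lb", "ub"):
        if col not in bnd.columns:
            raise ModelFormatError(f"bounds file {bounds_path} lacks column {col!r}")
    bnd = bnd.set_index("reaction_id")
    reaction_ids = [str(c) for c in mat.columns]
    missing = [r for r in reaction_ids if r not in bnd.index]
    if missing:
        raise ModelFormatError(f"bounds file lacks reactions: {missing[:5]}")
    lb = bnd.loc[reaction_ids, "lb"].to_numpy(dtype=float)
    ub = bnd.loc[reaction_ids, "ub"].to_numpy(dtype=float)
    return MetabolicModel(
        reaction_ids,
        [str(r) for r in mat.index],
        mat.to_numpy(dtype=float),
        lb,
        ub,
    )


def read_model(
    path: str | Path,
    format: str | None = None,
    *,
    bounds_path: str | Path | None = None,
) -> MetabolicModel:
    """Read a metabolic model from ``path``.

    Parameters
    ----------
    path : path
        Model file. For the ``tsv`` dialect this is the matrix file
        (metabolites x reactions, tab-separated, id header row and column);
        the bounds table (columns reaction_id, lb, ub) is ``bounds_path`` or,
        by default, the sibling file ``<stem>.bounds.tsv``.
    format : {"sbml", "json", "tsv"}, optional
        Inferred from the suffix when omitted (.xml/.sbml, .json, .tsv).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = {".xml": "sbml", ".sbml": "sbml", ".json": "json", ".tsv": "tsv"}.get(
            path.suffix.lower()
        )
        if format is None:
            raise ModelFormatError(f"cannot infer model format from suffix of {path}")
    if format == "sbml":
        return _read_sbml(path)
    if format == "json":
        return _read_json(path)
    if format == "tsv":
        return _read_tsv(path, Path(bounds_path) if bounds_path else None)
    raise ModelFormatError(f"unknown model format {format!r}")


def write_model_tsv(
    model: MetabolicModel, path: str | Path, bounds_path: str | Path | None = None
) -> None:
    """Write ``model`` in the tsv dialect (matrix file + bounds file).

    Numbers use 17-significant-digit repr so the files diff and round-trip
    exactly at double precision.
    """
    path = Path(path)
    if bounds_path is None:
        bounds_path = path.with_suffix(".bounds.tsv")
    mat = pd.DataFrame(model.S, index=model.metabolite_ids, columns=model.reaction_ids)
    mat.to_csv(path, sep="\t", float_format="%.17g")
    bnd = pd.DataFrame(
        {"reaction_id": model.reaction_ids, "lb": model.lb, "ub": model.ub}
    )
    bnd.to_csv(bounds_path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# preprocessing: blocked-reaction removal


def flux_variability(
    model: MetabolicModel, reactions: Sequence[int] | None = None
) -> np.ndarray:
    """Min and max attainable flux of each reaction (FVA), as an (n, 2) array.

    Solves two LPs per reaction over {S v = 0, lb <= v <= ub}.
    """
    idx = range(model.n_reactions) if reactions is None else reactions
    out = np.empty((len(list(idx)) if reactions is not None else model.n_reactions, 2))
    for row, i in enumerate(range(model.n_reactions) if reactions is None else reactions):
        c = np.zeros(model.n_reactions)
        c[i] = 1.0
        vmin = solve_flux_lp(model.S, model.lb, model.ub, c, context=model.reaction_ids[i])
        vmax = solve_flux_lp(
            model.S, model.lb, model.ub, c, maximize=True, context=model.reaction_ids[i]
        )
        out[row, 0] = vmin[i]
        out[row, 1] = vmax[i]
    return out


def remove_blocked_reactions(
    model: MetabolicModel, flux_tol: float = 1e-9
) -> tuple[MetabolicModel, list[str]]:
    """Drop reactions that cannot carry flux, then orphaned metabolites.

    A reaction is blocked when both its FVA minimum and maximum are within
    ``flux_tol`` of zero. Returns the reduced model (the input is untouched)
    and the list of removed reaction ids. Raises
    :class:`~fluxsampler._lp.InfeasibleError` when the polytope is empty.
    """
    if flux_tol <= 0:
        raise ValueError("flux_tol must be positive")
    ranges = flux_variability(model)
    blocked = (np.abs(ranges[:, 0]) <= flux_tol) & (np.abs(ranges[:, 1]) <= flux_tol)
    removed = [rid for rid, b in zip(model.reaction_ids, blocked) if b]
    if not removed:
        return model.copy(), []
    keep = ~blocked
    S = model.S[:, keep]
    met_keep = np.any(S != 0.0, axis=1)
    reduced = MetabolicModel(
        [r for r, k in zip(model.reaction_ids, keep) if k],
        [m for m, k in zip(model.metabolite_ids, met_keep) if k],
        S[met_keep, :],
        model.lb[keep],
        model.ub[keep],
    )
    logger.info("removed %d blocked reactions: %s", len(removed), removed)
    return reduced, removed


# ---------------------------------------------------------------------------
# sample matrices


def write_samples(samples: SampleMatrix, path: str | Path, format: str | None = None) -> None:
    """Write a sample matrix to ``path`` as tsv or hdf5 (lossless round-trip)."""
    path = Path(path)
    if samples.n_samples == 0:
        raise ValueError("refusing to write an empty SampleMatrix")
    if format is None:
        format = {".tsv": "tsv", ".h5": "hdf5", ".hdf5": "hdf5"}.get(path.suffix.lower())
        if format is None:
            raise ValueError(f"cannot infer sample format from suffix of {path}")
    if format == "tsv":
        df = samples.to_dataframe()
        with open(path, "w") as fh:
            fh.write("#meta\t" + json.dumps(samples.meta, sort_keys=True) + "\n")
            df.to_csv(fh, sep="\t", index=False, float_format="%.17g")
    elif format == "hdf5":
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("samples", data=samples.samples)
            f.create_dataset(
                "reaction_ids",
                data=np.array(samples.reaction_ids, dtype=object),
                dtype=h5py.string_dtype(),
            )
            f.attrs["meta"] = json.dumps(samples.meta, sort_keys=True)
            for key in ("sampler", "step_count", "seed"):
                if key in samples.meta and samples.meta[key] is not None:
                    f.attrs[key] = samples.meta[key]
    else:
        raise ValueError(f"unknown sample format {format!r}")


def read_samples(path: str | Path, format: str | None = None) -> SampleMatrix:
    """Read back a sample matrix written by :func:`write_samples`."""
    path = Path(path)
    if format is None:
        format = {".tsv": "tsv", ".h5": "hdf5", ".hdf5": "hdf5"}.get(path.suffix.lower())
    if format == "tsv":
        with open(path) as fh:
            first = fh.readline()
            meta = json.loads(first.split("\t", 1)[1]) if first.startswith("#meta") else {}
            df = pd.read_csv(fh, sep="\t", float_precision="round_trip")
        return SampleMatrix(df.to_numpy(dtype=float), [str(c) for c in df.columns], meta)
    if format == "hdf5":
        import h5py

        with h5py.File(path, "r") as f:
            mat = f["samples"][()]
            rids = [s.decode() if isinstance(s, bytes) else str(s) for s in f["reaction_ids"][()]]
            meta = json.loads(f.attrs.get("meta", "{}"))
        return SampleMatrix(mat, rids, meta)
    raise ValueError(f"unknown sample format {format!r}")
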