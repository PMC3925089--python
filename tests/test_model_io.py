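"""Model containers, file dialects and blocked-reaction preprocessing."""

import numpy as np
import pytest
from scipy.optimize import linprog

from fluxsampler import (
    MetabolicModel,
    SampleMatrix,
    flux_variability,
    read_model,
    read_samples,
    remove_blocked_reactions,
    write_model_tsv,
    write_samples,
)
from fluxsampler.model_io import ModelValidationError
from fluxsampler.synthetic import make_random_network


def toy_model() -> MetabolicModel:
    # A -> B chain: R1 produces A, R2 converts A to B, R3 consumes B.
    S = np.array([[1.0, -1.0, 0.0], [0.0, 1.0, -1.0]])
    return MetabolicModel(
        ["R1", "R2", "R3"], ["A", "B"], S, np.array([0.0, -5.0, 0.0]), np.array([10.0, 5.0, 10.0])
    )


class TestModelContainer:
    def test_shape_and_id_validation(self):
        with pytest.raises(ModelValidationError, match="reaction ids"):
            MetabolicModel(["R1"], ["A"], np.ones((1, 2)), [0, 0], [1, 1])
        with pytest.raises(ModelValidationError, match="lower bound exceeds"):
            MetabolicModel(["R1"], [], np.empty((0, 1)), [5.0], [3.0])
        with pytest.raises(ModelValidationError, match="not unique"):
            MetabolicModel(["R1", "R1"], [], np.empty((0, 2)), [0, 0], [1, 1])

    def test_nullspace_dimension(self):
        assert toy_model().nullspace_dimension() == 1


class TestModelFormats:
    def test_tsv_round_trip_identity(self, tmp_path):
        model = toy_model()
        path = tmp_path / "toy.tsv"
        write_model_tsv(model, path)
        back = read_model(path, "tsv")
        assert back.reaction_ids == model.reaction_ids
        assert back.metabolite_ids == model.metabolite_ids
        np.testing.assert_array_equal(back.S, model.S)
        np.testing.assert_array_equal(back.lb, model.lb)
        np.testing.assert_array_equal(back.ub, model.ub)

    def test_tsv_invalid_bounds_rejected(self, tmp_path):
        model = toy_model()
        path = tmp_path / "toy.tsv"
        write_model_tsv(model, path)
        bounds = path.with_suffix(".bounds.tsv")
        text = bounds.read_text().replace("R2\t-5\t5", "R2\t5\t3")
        bounds.write_text(text)
        with pytest.raises(ModelValidationError, match="R2"):
            read_model(path, "tsv")

    def _cobra_toy(self):
        from cobra import Metabolite, Model, Reaction

        cm = Model("toy")
        a = Metabolite("A", compartment="c")
        b = Metabolite("B", compartment="c")
        r1 = Reaction("R1")
        r1.add_metabolites({a: 1.0})
        r1.bounds = (0, 10)
        r2 = Reaction("R2")
        r2.add_metabolites({a: -1.0, b: 1.0})
        r2.bounds = (-5, 5)
        r3 = Reaction("R3")
        r3.add_metabolites({b: -1.0})
        r3.bounds = (0, 10)
        cm.add_reactions([r1, r2, r3])
        return cm

    @pytest.mark.parametrize("fmt", ["sbml", "json"])
    def test_cobra_dialects_match_reference(self, tmp_path, fmt):
        import cobra.io

        cm = self._cobra_toy()
        path = tmp_path / ("toy.xml" if fmt == "sbml" else "toy.json")
        if fmt == "sbml":
            cobra.io.write_sbml_model(cm, str(path))
        else:
            cobra.io.save_json_model(cm, str(path))
        model = read_model(path)
        ref = toy_model()
        assert model.reaction_ids == ref.reaction_ids
        np.testing.assert_array_equal(model.S, ref.S)
        np.testing.assert_array_equal(model.lb, ref.lb)
        np.testing.assert_array_equal(model.ub, ref.ub)

    def test_unbounded_reaction_gets_documented_defaults(self, tmp_path, caplog):
        import cobra.io

        cm = self._cobra_toy()
        cm.reactions.R3.bounds = (-np.inf, np.inf)
        path = tmp_path / "toy.json"
        cobra.io.save_json_model(cm, str(path))
        with caplog.at_level("WARNING", logger="fluxsampler.model_io"):
            model = read_model(path)
        assert model.lb[2] == -1000.0 and model.ub[2] == 1000.0
        assert any("non-finite bounds" in r.message for r in caplog.records)


class TestBlockedReactionRemoval:
    def test_dead_end_reaction_and_orphan_metabolite_removed(self):
        # R3 consumes metabolite C that nothing produces -> R3 blocked, C orphaned.
        S = np.array([[1.0, -1.0, 0.0], [0.0, 0.0, -1.0]])
        model = MetabolicModel(
            ["R1", "R2", "R3"], ["A", "C"], S, np.zeros(3), np.full(3, 10.0)
        )
        reduced, removed = remove_blocked_reactions(model)
        assert removed == ["R3"]
        assert reduced.reaction_ids == ["R1", "R2"]
        assert reduced.metabolite_ids == ["A"]

    def test_unblocked_model_is_untouched(self, network_space):
        model = network_space.model
        reduced, removed = remove_blocked_reactions(model)
        assert removed == []
        assert reduced.reaction_ids == model.reaction_ids
        np.testing.assert_array_equal(reduced.S, model.S)

    def test_zero_capped_parallel_reaction_removed(self):
        # Two parallel routes A -> (R2|R3) -> consumed; R3 capped to [0, 0].
        S = np.array([[1.0, -1.0, -1.0]])
        model = MetabolicModel(
            ["R1", "R2", "R3"], ["A"], S,
            np.array([0.0, 0.0, 0.0]), np.array([10.0, 10.0, 0.0]),
        )
        reduced, removed = remove_blocked_reactions(model)
        assert removed == ["R3"]
        assert reduced.n_reactions == model.n_reactions - 1
        # Independent LP oracle: exhaustive FVA straight through scipy.
        for j, rid in enumerate(model.reaction_ids):
            c = np.zeros(3)
            c[j] = 1.0
            lo = linprog(c, A_eq=S, b_eq=[0.0], bounds=list(zip(model.lb, model.ub)), method="highs").fun
            hi = -linprog(-c, A_eq=S, b_eq=[0.0], bounds=list(zip(model.lb, model.ub)), method="highs").fun
            assert (abs(lo) <= 1e-9 and abs(hi) <= 1e-9) == (rid in removed)

    def test_removal_is_idempotent_and_preserves_fva(self):
        S = np.array([[1.0, -1.0, 0.0, -1.0], [0.0, 1.0, -1.0, 0.0]])
        model = MetabolicModel(
            ["R1", "R2", "R3", "R4"], ["A", "B"], S,
            np.array([0.0, 0.0, 0.0, 0.0]), np.array([10.0, 10.0, 10.0, 0.0]),
        )
        once, removed = remove_blocked_reactions(model)
        twice, removed2 = remove_blocked_reactions(once)
        assert removed == ["R4"] and removed2 == []
        assert twice.reaction_ids == once.reaction_ids
        before = flux_variability(model)
        after = flux_variability(once)
        keep = [model.reaction_ids.index(r) for r in once.reaction_ids]
        np.testing.assert_allclose(before[keep], after, atol=1e-6)


class TestSampleRoundTrip:
    def _matrix(self, rng):
        return SampleMatrix(
            rng.normal(size=(100, 10)),
            [f"R{i}" for i in range(10)],
            {"sampler": "optgp", "step_count": 50, "seed": 7},
        )

    def test_hdf5_bit_exact(self, tmp_path, rng):
        sm = self._matrix(rng)
        path = tmp_path / "s.h5"
        write_samples(sm, path)
        back = read_samples(path)
        np.testing.assert_array_equal(back.samples, sm.samples)
        assert back.reaction_ids == sm.reaction_ids
        assert back.meta == sm.meta

    def test_tsv_header_and_precision(self, tmp_path, rng):
        sm = self._matrix(rng)
        path = tmp_path / "s.tsv"
        write_samples(sm, path)
        lines = path.read_text().splitlines()
        assert lines[1].split("\t") == sm.reaction_ids
        back = read_samples(path)
        np.testing.assert_allclose(back.samples, sm.samples, rtol=1e-15)
        assert back.meta["seed"] == 7

    def test_empty_matrix_rejected(self, tmp_path):
        sm = SampleMatrix(np.empty((0, 2)), ["R1", "R2"])
        with pytest.raises(ValueError, match="empty"):
            write_samples(sm, tmp_path / "s.tsv")


def test_random_networks_survive_preprocessing():
    """Generator quality guard: >= 80% of reactions carry flux, 20 seeds."""
    for seed in range(20):
        model = make_random_network(4, 8, seed=seed)
        reduced, _ = remove_blocked_reactions(model)
        assert reduced.n_reactions >= int(0.8 * model.n_reactions)
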