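"""Model reading, FVA, reduction and the average flux range."""

import json

import numpy as np
import pytest

import fluxpolytope as fp
from fluxpolytope.model_io import MetabolicModel, write_bigg_json


def test_two_flux_model_shape(two_flux_model):
    assert two_flux_model.m == 1
    assert two_flux_model.n == 2
    np.testing.assert_array_equal(two_flux_model.S, [[1.0, -1.0]])


def test_bigg_json_roundtrip(tmp_path, random_model):
    model, _ = random_model
    path = tmp_path / "model.json"
    write_bigg_json(model, path)
    back = fp.load_model(path, "bigg_json")
    np.testing.assert_allclose(back.S, model.S)
    np.testing.assert_allclose(back.v_lb, model.v_lb)
    np.testing.assert_allclose(back.v_ub, model.v_ub)
    assert back.reaction_ids == model.reaction_ids


def test_bigg_json_agrees_with_cobra(tmp_path, random_model):
    """Independent reader cross-check: cobra parses the same JSON dialect."""
    cobra = pytest.importorskip("cobra")
    from cobra.util.array import create_stoichiometric_matrix

    model, _ = random_model
    path = tmp_path / "model.json"
    write_bigg_json(model, path)
    cm = cobra.io.load_json_model(str(path))
    S_cobra = create_stoichiometric_matrix(cm, array_type="dense")
    order = [cm.reactions.index(r) for r in model.reaction_ids]
    met_order = [cm.metabolites.index(m) for m in model.metabolite_ids]
    np.testing.assert_allclose(S_cobra[np.ix_(met_order, order)], model.S)
    np.testing.assert_allclose(
        [cm.reactions.get_by_id(r).lower_bound for r in model.reaction_ids], model.v_lb
    )


def test_duplicate_reaction_id_rejected(tmp_path):
    doc = {
        "id": "dup",
        "metabolites": [{"id": "m1"}],
        "reactions": [
            {"id": "r", "lower_bound": 0, "upper_bound": 1, "metabolites": {"m1": 1}},
            {"id": "r", "lower_bound": 0, "upper_bound": 1, "metabolites": {"m1": -1}},
        ],
    }
    path = tmp_path / "dup.json"
    path.write_text(json.dumps(doc))
    with pytest.raises(ValueError, match="duplicate"):
        fp.load_model(path)


def test_missing_bounds_default_with_warning(tmp_path):
    doc = {
        "id": "nb",
        "metabolites": [{"id": "m1"}],
        "reactions": [
            {"id": "a", "metabolites": {"m1": 1}},
            {"id": "b", "lower_bound": 0, "upper_bound": 5, "metabolites": {"m1": -1}},
        ],
    }
    path = tmp_path / "nb.json"
    path.write_text(json.dumps(doc))
    with pytest.warns(UserWarning, match="missing bounds"):
        model = fp.load_model(path)
    assert model.v_lb[0] == -1000.0 and model.v_ub[0] == 1000.0


def test_unparseable_file_raises(tmp_path):
    path = tmp_path / "garbage.json"
    path.write_text("not json {{{")
    with pytest.raises(ValueError, match="not valid JSON"):
        fp.load_model(path)


def test_sbml_roundtrip_via_cobra(tmp_path, random_model):
    cobra = pytest.importorskip("cobra")
    model, _ = random_model
    cm = cobra.Model("rt")
    mets = {mid: cobra.Metabolite(mid, compartment="c") for mid in model.metabolite_ids}
    for j, rid in enumerate(model.reaction_ids):
        rxn = cobra.Reaction(rid, lower_bound=float(model.v_lb[j]), upper_bound=float(model.v_ub[j]))
        cm.add_reactions([rxn])
        rxn.add_metabolites(
            {mets[model.metabolite_ids[i]]: model.S[i, j] for i in np.nonzero(model.S[:, j])[0]}
        )
    path = tmp_path / "model.xml"
    cobra.io.write_sbml_model(cm, str(path))
    back = fp.load_model(path, "sbml")
    assert back.n == model.n and back.m == model.m
    np.testing.assert_allclose(back.v_lb, model.v_lb)


class TestFluxVariability:
    def test_toy_box_bounds(self, two_flux_model):
        fva = fp.flux_variability(two_flux_model)
        np.testing.assert_allclose(fva.v_min, [0.0, 0.0], atol=1e-8)
        np.testing.assert_allclose(fva.v_max, [10.0, 10.0], atol=1e-8)

    def test_toy_tightened_by_partner_bound(self):
        # v1 = v2 and v2 <= 4 pins both maxima at 4
        model = fp.synthetic_data.make_two_flux_model(ub=(10.0, 4.0))
        fva = fp.flux_variability(model)
        np.testing.assert_allclose(fva.v_max, [4.0, 4.0], atol=1e-8)

    def test_stoichiometrically_blocked_reaction(self):
        # m1 produced by r0 only and consumed by nothing: r0 must carry zero
        model = MetabolicModel(
            S=np.array([[1.0, 0.0], [0.0, 1.0]]),
            v_lb=np.array([-5.0, -5.0]),
            v_ub=np.array([5.0, 5.0]),
            reaction_ids=["r0", "r1"],
            metabolite_ids=["m1", "m2"],
        )
        fva = fp.flux_variability(model)
        np.testing.assert_allclose(fva.v_min, 0.0, atol=1e-8)
        np.testing.assert_allclose(fva.v_max, 0.0, atol=1e-8)

    def test_infeasible_model_raises(self):
        model = MetabolicModel(
            S=np.array([[1.0, -1.0]]),
            v_lb=np.array([5.0, 0.0]),
            v_ub=np.array([10.0, 4.0]),
            reaction_ids=["v1", "v2"],
            metabolite_ids=["x"],
        )
        with pytest.raises(ValueError, match="infeasible"):
            fp.flux_variability(model)

    def test_fva_respects_bounds_invariant(self, random_model):
        model, _ = random_model
        fva = fp.flux_variability(model)
        assert np.all(fva.v_min >= model.v_lb - 1e-7)
        assert np.all(fva.v_max <= model.v_ub + 1e-7)
        assert np.all(fva.v_min <= fva.v_max + 1e-9)


class TestReduceModel:
    def test_blocked_reactions_removed(self):
        model = MetabolicModel(
            S=np.array([[1.0, -1.0, 1.0], [0.0, 0.0, 1.0]]),
            v_lb=np.array([0.0, 0.0, -5.0]),
            v_ub=np.array([10.0, 10.0, 5.0]),
            reaction_ids=["a", "b", "c"],
            metabolite_ids=["m1", "m2"],
        )
        # c is the only reaction touching m2, so it is stoichiometrically blocked
        red = fp.reduce_model(model)
        assert red.reaction_ids == ["a", "b"]
        assert "m2" not in red.metabolite_ids

    def test_idempotent(self, random_model):
        model, _ = random_model
        red1 = fp.reduce_model(model)
        red2 = fp.reduce_model(red1)
        assert red2.reaction_ids == red1.reaction_ids
        np.testing.assert_allclose(red2.v_lb, red1.v_lb, atol=1e-6)
        np.testing.assert_allclose(red2.v_ub, red1.v_ub, atol=1e-6)

    def test_no_blocked_reactions_tightens_only(self, two_flux_model):
        red = fp.reduce_model(two_flux_model)
        assert red.reaction_ids == two_flux_model.reaction_ids

    def test_kept_reactions_exceed_threshold(self, random_model):
        model, _ = random_model
        red = fp.reduce_model(model, null_threshold=1e-9)
        fva = fp.flux_variability(red)
        mag = np.maximum(np.abs(fva.v_min), np.abs(fva.v_max))
        assert np.all(mag >= 1e-9 - 1e-7)

    def test_all_blocked_raises(self):
        model = MetabolicModel(
            S=np.array([[1.0], [1.0]]),
            v_lb=np.array([-5.0]),
            v_ub=np.array([5.0]),
            reaction_ids=["only"],
            metabolite_ids=["m1", "m2"],
        )
        with pytest.raises(ValueError, match="blocked"):
            fp.reduce_model(model)


@pytest.mark.parametrize(
    "lb, ub, expected",
    [
        ([-1000.0, -1000.0], [1000.0, 1000.0], 2000.0),
        ([0.0, 0.0], [4.0, 6.0], 5.0),
    ],
)
def test_average_flux_range(lb, ub, expected):
    model = fp.synthetic_data.make_two_flux_model(lb, ub)
    assert fp.average_flux_range(model) == pytest.approx(expected)
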