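import numpy as np
import pytest

from metaboflux.fluxmodel import (MetabolicModel, Metabolite, ModelError,
                                  Reaction, apply_eflux_bounds,
                                  check_mass_balance, flux_activity,
                                  maxmin_normalize, per_sample_fba,
                                  reaction_gpr_scores, read_model, read_sbml,
                                  run_fba, write_sbml)
from metaboflux.simulate import make_toy_model, toy_chain_model

from conftest import make_matrix


class TestModelStructure:
    def test_unknown_metabolite_rejected(self):
        with pytest.raises(ModelError, match="unknown metabolites"):
            MetabolicModel("m", [Metabolite("a")],
                           [Reaction("r", {"a": -1, "ghost": 1})], "r")

    def test_bounds_ordering_enforced(self):
        with pytest.raises(ModelError, match="lb"):
            Reaction("r", {}, 5.0, 1.0)

    def test_exchange_detection(self):
        ex = Reaction("EX", {"a": 1.0})
        internal = Reaction("R", {"a": -1.0, "b": 1.0})
        assert ex.is_exchange and not internal.is_exchange

    def test_json_round_trip_exact(self, tmp_path):
        model = toy_chain_model()
        path = tmp_path / "m.json"
        model.to_json(path)
        back = MetabolicModel.from_json(path)
        assert back.to_json() == model.to_json()
        assert [r.stoichiometry for r in back.reactions] == \
               [r.stoichiometry for r in model.reactions]

    def test_sbml_round_trip(self, tmp_path):
        model = make_toy_model(5, n_pathways=2, reactions_per_pathway=2)
        path = tmp_path / "m.xml"
        write_sbml(model, path)
        back = read_sbml(path)
        assert sorted(back.metabolite_ids) == sorted(model.metabolite_ids)
        assert sorted(back.reaction_ids) == sorted(model.reaction_ids)
        assert back.objective == model.objective
        assert back.genes == model.genes
        for rid in model.reaction_ids:
            r0, r1 = model.reaction(rid), back.reaction(rid)
            assert r1.stoichiometry == r0.stoichiometry
            assert r1.lower_bound == pytest.approx(r0.lower_bound)
            assert r1.upper_bound == pytest.approx(r0.upper_bound)
            assert r1.subsystem == r0.subsystem
        sol0, sol1 = run_fba(model), run_fba(back)
        assert sol1.objective_value == pytest.approx(sol0.objective_value, abs=1e-9)

    def test_read_model_json_counts(self, tmp_path):
        model = make_toy_model(2, n_pathways=3, reactions_per_pathway=2)
        path = tmp_path / "toy.json"
        model.to_json(path)
        loaded = read_model(path)
        s = loaded.summary()
        assert s["n_reactions"] == 3 * 2 + 2  # internals + exchange + biomass
        assert s["n_subsystems"] == 3 + 2  # pathways + Exchange + Biomass


class TestMaxMinNormalize:
    def test_basic(self):
        out = maxmin_normalize({"a": 2.0, "b": 4.0, "c": 6.0})
        assert out == {"a": 0.0, "b": 0.5, "c": 1.0}

    def test_affine_invariance(self, rng):
        scores = {f"r{i}": float(v) for i, v in enumerate(rng.uniform(1, 9, 8))}
        transformed = {k: 3.7 * v + 11.0 for k, v in scores.items()}
        base, moved = maxmin_normalize(scores), maxmin_normalize(transformed)
        for k in scores:
            assert moved[k] == pytest.approx(base[k], abs=1e-12)

    def test_degenerate_all_equal_gives_ones(self):
        assert maxmin_normalize({"a": 3.0, "b": 3.0}) == {"a": 1.0, "b": 1.0}

    def test_empty_passthrough(self):
        assert maxmin_normalize({}) == {}


class TestEfluxBounds:
    def test_score_zero_blocks_reaction(self):
        model = toy_chain_model()
        out = apply_eflux_bounds(model, {"R2": 0.0})
        r = out.reaction("R2")
        assert r.lower_bound == 0.0 and r.upper_bound == 0.0

    def test_score_one_identity(self):
        model = toy_chain_model()
        out = apply_eflux_bounds(model, {"R2": 1.0})
        assert out.reaction("R2").upper_bound == model.reaction("R2").upper_bound

    def test_reversible_shrinks_symmetrically(self):
        model = MetabolicModel(
            "m", [Metabolite("a"), Metabolite("b")],
            [Reaction("EX_a", {"a": 1.0}, 0, 10),
             Reaction("R", {"a": -1, "b": 1}, -10.0, 10.0),
             Reaction("out", {"b": -1.0}, 0, 10)], "out")
        out = apply_eflux_bounds(model, {"R": 0.5})
        assert out.reaction("R").lower_bound == -5.0
        assert out.reaction("R").upper_bound == 5.0
        upper_only = apply_eflux_bounds(model, {"R": 0.5}, symmetric=False)
        assert upper_only.reaction("R").lower_bound == -10.0

    def test_exchange_reactions_exempt(self):
        model = toy_chain_model()
        out = apply_eflux_bounds(model, {"EX_nut": 0.0, "biomass": 0.0})
        assert out.reaction("EX_nut").upper_bound == 5.0
        # biomass drains a single metabolite: boundary reaction, also exempt
        assert out.reaction("biomass").upper_bound == \
               model.reaction("biomass").upper_bound


class TestFba:
    def test_chain_bottleneck_optimum(self):
        sol = run_fba(toy_chain_model(uptake_bound=5.0, internal_bound=3.0))
        assert sol.optimal
        assert sol.objective_value == pytest.approx(3.0, abs=1e-9)
        assert check_mass_balance(toy_chain_model(), sol) <= 1e-6

    @pytest.mark.parametrize("gamma", [1.0, 0.7, 0.25])
    def test_uniform_eflux_scaling_scales_growth(self, gamma):
        model = toy_chain_model()
        scaled = apply_eflux_bounds(model, {"R1": gamma, "R2": gamma})
        sol = run_fba(scaled)
        assert sol.objective_value == pytest.approx(3.0 * gamma, abs=1e-9)

    def test_zero_uptake_zero_growth(self):
        sol = run_fba(toy_chain_model(uptake_bound=0.0))
        assert sol.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_infeasible_status_reported(self):
        model = MetabolicModel(
            "bad", [Metabolite("a")],
            [Reaction("make", {"a": 1.0}, 2.0, 5.0),  # forced production
             Reaction("obj", {"a": -1.0}, 0.0, 1.0)], "obj")
        sol = run_fba(model, variant="fba")
        assert sol.status == "infeasible"
        assert not sol.optimal

    def test_matches_cobra_oracle_on_toy_models(self):
        cobra = pytest.importorskip("cobra")
        for seed in (1, 2, 3):
            model = make_toy_model(seed, n_pathways=3, reactions_per_pathway=3)
            mine = run_fba(model, variant="fba").objective_value
            cm = cobra.Model(model.id)
            cm.add_metabolites([cobra.Metabolite(m.id) for m in model.metabolites])
            rxns = []
            for r in model.reactions:
                cr = cobra.Reaction(r.id, lower_bound=r.lower_bound,
                                    upper_bound=r.upper_bound)
                rxns.append((cr, r.stoichiometry))
            cm.add_reactions([cr for cr, _ in rxns])
            for cr, stoich in rxns:
                cr.add_metabolites({cm.metabolites.get_by_id(k): v
                                    for k, v in stoich.items()})
            cm.objective = model.objective
            theirs = cm.optimize().objective_value
            assert mine == pytest.approx(theirs, abs=1e-6)

    def test_pfba_canonical_under_reaction_reordering(self, rng):
        model = make_toy_model(4, n_pathways=3, reactions_per_pathway=3)
        perm = list(rng.permutation(len(model.reactions)))
        shuffled = MetabolicModel(
            model.id, model.metabolites,
            [model.reactions[i] for i in perm], model.objective)
        a = run_fba(model, variant="pfba")
        b = run_fba(shuffled, variant="pfba")
        fa = flux_activity(a, model)
        fb = flux_activity(b, shuffled)
        assert np.allclose(fa.to_numpy(), fb.reindex(fa.index).to_numpy(), atol=1e-6)

    def test_raising_a_score_never_decreases_growth(self, rng):
        model = make_toy_model(7, n_pathways=2, reactions_per_pathway=3)
        internal = [r.id for r in model.reactions
                    if not r.is_exchange and r.id != "biomass"]
        scores = {rid: float(rng.uniform(0.1, 0.9)) for rid in internal}
        base = run_fba(apply_eflux_bounds(model, scores)).objective_value
        for rid in internal:
            bumped = dict(scores)
            bumped[rid] = min(1.0, scores[rid] + 0.3)
            grown = run_fba(apply_eflux_bounds(model, bumped)).objective_value
            assert grown >= base - 1e-8


class TestFluxActivity:
    def test_chain_pathway_sums_absolute_fluxes(self):
        model = toy_chain_model()
        sol = run_fba(model)
        acts = flux_activity(sol, model)
        assert acts["ChainPathway"] == pytest.approx(6.0, abs=1e-8)  # 3 + 3
        assert (acts >= 0).all()
        assert set(acts.index) == set(model.subsystems)

    def test_zero_flux_zero_activities(self):
        model = toy_chain_model(uptake_bound=0.0)
        acts = flux_activity(run_fba(model), model)
        assert np.allclose(acts.to_numpy(), 0.0, atol=1e-9)


class TestPerSampleFba:
    def _expr(self, values_by_gene, sample_ids):
        genes = sorted(values_by_gene)
        vals = np.array([values_by_gene[g] for g in genes], dtype=float)
        return make_matrix(vals, feature_ids=genes, sample_ids=sample_ids)

    def test_identical_samples_identical_outputs(self):
        model = toy_chain_model()
        expr = self._expr({"g_r1": [4.0, 4.0], "g_r2a": [2.0, 2.0],
                           "g_r2b": [1.0, 1.0]}, ["sA", "sB"])
        growth, acts = per_sample_fba(model, expr)
        assert growth["sA"] == pytest.approx(growth["sB"], abs=1e-12)
        np.testing.assert_allclose(acts["sA"], acts["sB"])

    def test_equal_reaction_scores_leave_model_unconstrained(self):
        # GPR scores R1 = 4, R2 = 2 + 2 = 4: degenerate max-min -> all 1
        model = toy_chain_model()
        expr = self._expr({"g_r1": [4.0], "g_r2a": [2.0], "g_r2b": [2.0]}, ["s"])
        growth, _ = per_sample_fba(model, expr)
        assert growth["s"] == pytest.approx(3.0, abs=1e-9)

    @staticmethod
    def _parallel_model():
        """Two redundant routes into the biomass precursor plus a shared tail."""
        mets = [Metabolite("nut_c"), Metabolite("pre_c"), Metabolite("bm_c")]
        rxns = [Reaction("EX_nut", {"nut_c": 1.0}, 0, 10, subsystem="Exchange"),
                Reaction("RA", {"nut_c": -1, "pre_c": 1}, 0, 8,
                         subsystem="P", gpr="gA"),
                Reaction("RB", {"nut_c": -1, "pre_c": 1}, 0, 8,
                         subsystem="P", gpr="gB"),
                Reaction("RC", {"pre_c": -1, "bm_c": 1}, 0, 8,
                         subsystem="P", gpr="gC"),
                Reaction("biomass", {"bm_c": -1.0}, 0, 1000,
                         subsystem="Biomass")]
        return MetabolicModel("parallel", mets, rxns, "biomass")

    def test_halving_bottleneck_gene_decreases_growth(self):
        model = self._parallel_model()
        # scores {RA: 4, RB: 2, RC: 8} -> normalized {1/3, 0, 1}: RA is the
        # sole open route at capacity 8/3
        g0, _ = per_sample_fba(model, self._expr(
            {"gA": [4.0], "gB": [2.0], "gC": [8.0]}, ["s"]))
        g1, _ = per_sample_fba(model, self._expr(
            {"gA": [2.0], "gB": [2.0], "gC": [8.0]}, ["s"]))
        assert g0["s"] == pytest.approx(8.0 / 3.0, abs=1e-6)
        assert g1["s"] < g0["s"] - 1e-6

    def test_no_gene_overlap_rejected(self):
        model = toy_chain_model()
        expr = self._expr({"unrelated": [1.0]}, ["s"])
        with pytest.raises(ModelError, match="no overlap"):
            per_sample_fba(model, expr)

    def test_gpr_scores_use_sum_and_min(self):
        model = toy_chain_model()  # R2 gated by "g_r2a or g_r2b"
        scores = reaction_gpr_scores(model, {"g_r1": 4.0, "g_r2a": 1.5,
                                             "g_r2b": 2.5})
        assert scores["R2"] == pytest.approx(4.0)  # OR = sum
        assert scores["R1"] == pytest.approx(4.0)
        assert "EX_nut" not in scores  # no GPR on the exchange
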