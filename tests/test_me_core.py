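import inspect
import math

import numpy as np
import pytest

from meomics import me_core
from meomics.me_core import (
    BracketError,
    MEModel,
    ModelValidationError,
    Reaction,
    evaluate_stoichiometry,
    flux_variability,
    gene_essentiality,
    grid_max_growth,
    is_feasible,
    maximize_growth,
    strip_expression,
    substrate_scan,
)
from meomics.synthetic_data import make_minicell, random_minicell_params

from _oracles import dense_stoichiometry


class TestEvaluateStoichiometry:
    def test_constant_and_dilution_entries(self):
        model = MEModel(
            metabolite_ids=["m"],
            reactions=[
                Reaction("R1", 0, 1, [("m", -1.0, 0.0)]),
                Reaction("R2", 0, 1, [("m", 0.0, -1.0)]),
                Reaction("BIOMASS", 0, 1, [("m", -1.0, 0.0)]),
            ],
            growth_reaction_id="BIOMASS",
        )
        S = evaluate_stoichiometry(model, 0.5).toarray()
        assert S[0, 0] == -1.0  # mu-independent stoichiometry
        assert S[0, 1] == -0.5  # pure dilution term -mu

    def test_matches_per_entry_hand_evaluation(self, minicell_me):
        S = evaluate_stoichiometry(minicell_me, 0.2).toarray()
        np.testing.assert_allclose(S, dense_stoichiometry(minicell_me, 0.2))

    def test_unknown_metabolite_rejected(self):
        with pytest.raises(ModelValidationError, match="ghost"):
            MEModel(
                metabolite_ids=["m"],
                reactions=[Reaction("BIOMASS", 0, 1, [("ghost", -1.0, 0.0)])],
                growth_reaction_id="BIOMASS",
            )

    def test_negative_mu_rejected(self, minicell_me):
        with pytest.raises(ValueError):
            evaluate_stoichiometry(minicell_me, -0.1)


class TestFeasibility:
    def test_zero_growth_is_feasible(self, minicell_me):
        assert is_feasible(minicell_me, 0.0)

    def test_no_substrate_no_growth(self, minicell_me):
        starved = minicell_me.copy()
        starved.reaction("EX_substrate").lower_bound = 0.0
        assert not is_feasible(starved, 0.1)
        assert is_feasible(starved, 0.0)

    def test_boundary_brackets_grid_optimum(self, minicell_me):
        mu_grid = grid_max_growth(minicell_me, step=1e-3)
        assert is_feasible(minicell_me, mu_grid)
        assert not is_feasible(minicell_me, mu_grid + 2e-3)

    def test_monotone_over_mu_grid(self, minicell_me):
        feas = [is_feasible(minicell_me, mu) for mu in np.linspace(0, 1.0, 11)]
        # once infeasible, stays infeasible
        assert all(a or not b for a, b in zip(feas, feas[1:]))


class TestMaximizeGrowth:
    def test_yield_times_uptake_without_expression_cost(self, m_analog_simple):
        sol = maximize_growth(m_analog_simple)
        assert sol.status == "optimal"
        assert sol.mu_star == pytest.approx(0.5, abs=2e-6)

    def test_agrees_with_grid_scan_oracle(self, minicell_me):
        sol = maximize_growth(minicell_me, bisect_tol=1e-6)
        oracle = grid_max_growth(minicell_me, step=1e-4)
        assert abs(sol.mu_star - oracle) <= 1e-4 + 2e-6

    def test_seeded_variant_agrees_with_oracle(self):
        me, _ = make_minicell(random_minicell_params(7))
        sol = maximize_growth(me, bisect_tol=1e-6)
        oracle = grid_max_growth(me, step=1e-4)
        assert sol.status == "optimal"
        assert abs(sol.mu_star - oracle) <= 1e-4 + 2e-6

    def test_starvation_limit(self, minicell_me):
        starved = minicell_me.copy()
        starved.reaction("EX_substrate").lower_bound = 0.0
        sol = maximize_growth(starved, mu_lo=0.01)
        assert sol.status == "infeasible_at_floor"
        sol0 = maximize_growth(starved, mu_lo=0.0)
        assert sol0.status == "optimal"
        assert sol0.mu_star == pytest.approx(0.0, abs=2e-6)

    def test_feasible_upper_bracket_raises(self, m_analog_simple):
        with pytest.raises(BracketError):
            maximize_growth(m_analog_simple, mu_hi=0.4)

    def test_solution_satisfies_conservation(self, minicell_me):
        sol = maximize_growth(minicell_me)
        S = evaluate_stoichiometry(minicell_me, sol.mu_star).toarray()
        v = np.array([sol.fluxes[r] for r in minicell_me.reaction_ids])
        assert np.abs(S @ v).max() <= 10 * 1e-9 + 1e-10


class TestFluxVariability:
    def test_blocked_reaction_has_zero_range(self, minicell_me):
        model = minicell_me.copy()
        model.reaction("RESP_B").lower_bound = 0.0
        model.reaction("RESP_B").upper_bound = 0.0
        sol = maximize_growth(model)
        fva = flux_variability(model, sol.mu_star)
        assert fva.table.loc["RESP_B", "v_min"] == pytest.approx(0.0, abs=1e-9)
        assert fva.table.loc["RESP_B", "range"] == pytest.approx(0.0, abs=1e-9)

    def test_linear_chain_fluxes_unique(self, linear_chain_model):
        sol = maximize_growth(linear_chain_model)
        fva = flux_variability(linear_chain_model, sol.mu_star)
        assert (fva.table["range"] <= 1e-6).all()

    def test_ranges_contain_returned_fluxes(self, minicell_me):
        sol = maximize_growth(minicell_me)
        fva = flux_variability(minicell_me, sol.mu_star)
        for rxn, (lo, hi) in fva.table[["v_min", "v_max"]].iterrows():
            assert lo - 1e-6 <= sol.fluxes[rxn] <= hi + 1e-6

    def test_me_ranges_never_exceed_m_ranges(self, minicell_me, minicell_m):
        # tight bisection: the residual slack in an FVA range at a bisected
        # mu* is ~ bisect_tol / (dmu/dflux), so it must be driven below the
        # flux comparison tolerance
        sol_me = maximize_growth(minicell_me, bisect_tol=1e-9)
        sol_m = maximize_growth(minicell_m, bisect_tol=1e-9)
        fva_me = flux_variability(minicell_me, sol_me.mu_star)
        fva_m = flux_variability(minicell_m, sol_m.mu_star)
        for rxn in fva_m.table.index:
            assert fva_me.range_of(rxn) <= fva_m.range_of(rxn) + 1e-6

    def test_infeasible_mu_rejected(self, minicell_me):
        with pytest.raises(ValueError):
            flux_variability(minicell_me, 3.0)


class TestGeneEssentiality:
    def test_ribosomal_gene_essential(self, minicell_me):
        assert gene_essentiality(minicell_me, "g_ribosome")

    def test_overflow_gene_dispensable(self, minicell_me):
        assert not gene_essentiality(minicell_me, "g_ovf")

    def test_respiration_isozymes_back_each_other_up(self, minicell_me):
        assert not gene_essentiality(minicell_me, "g_resp_a")
        assert not gene_essentiality(minicell_me, "g_resp_b")

    def test_bounds_restored_after_probe(self, minicell_me):
        rxn = minicell_me.reaction(minicell_me.translation_of["g_ovf"])
        before = (rxn.lower_bound, rxn.upper_bound)
        gene_essentiality(minicell_me, "g_ovf")
        assert (rxn.lower_bound, rxn.upper_bound) == before

    def test_default_probe_growth_rate(self):
        sig = inspect.signature(gene_essentiality)
        assert sig.parameters["mu_test"].default == 1e-3

    def test_unknown_gene(self, minicell_me):
        with pytest.raises(KeyError):
            gene_essentiality(minicell_me, "g_nonexistent")


class TestSubstrateScan:
    def test_zero_uptake_means_zero_growth_and_secretion(self, minicell_me):
        res = substrate_scan(minicell_me, "EX_substrate", [0.0])
        row = res.table.iloc[0]
        assert row["mu_star"] == pytest.approx(0.0, abs=2e-6)
        assert row["EX_overflow"] == pytest.approx(0.0, abs=1e-9)

    def test_growth_non_decreasing_in_uptake(self, minicell_me):
        res = substrate_scan(minicell_me, "EX_substrate", [0.0, 2.0, 5.0, 10.0])
        mu = res.table["mu_star"].to_numpy()
        assert (np.diff(mu) >= -2e-6).all()

    def test_input_validation(self, minicell_me):
        with pytest.raises(ValueError):
            substrate_scan(minicell_me, "EX_substrate", [])
        with pytest.raises(ValueError):
            substrate_scan(minicell_me, "EX_substrate", [2.0, 1.0])
        with pytest.raises(KeyError):
            substrate_scan(minicell_me, "EX_nope", [1.0])

    def test_original_model_untouched(self, minicell_me):
        before = minicell_me.reaction("EX_substrate").lower_bound
        substrate_scan(minicell_me, "EX_substrate", [0.0, 1.0])
        assert minicell_me.reaction("EX_substrate").lower_bound == before


class TestStripExpression:
    def test_pure_metabolic_model_unchanged(self, m_analog_simple):
        stripped = strip_expression(m_analog_simple)
        assert stripped.reaction_ids == m_analog_simple.reaction_ids
        assert stripped.metabolite_ids == m_analog_simple.metabolite_ids
        for r1, r2 in zip(stripped.reactions, m_analog_simple.reactions):
            assert r1.entries == r2.entries

    def test_only_metabolic_reactions_survive(self, minicell_me, minicell_m):
        expression = {"translation", "transcription"}
        expected = [
            r.id for r in minicell_me.reactions if r.subsystem not in expression
        ]
        assert minicell_m.reaction_ids == expected
        assert minicell_m.translation_of == {}

    def test_no_mu_dependence_left(self, minicell_m):
        for rxn in minicell_m.reactions:
            assert all(b == 0.0 for _, _, b in rxn.entries)

    def test_relaxation_dominance(self, minicell_me, minicell_m):
        mu_me = maximize_growth(minicell_me).mu_star
        mu_m = maximize_growth(minicell_m).mu_star
        assert mu_m >= mu_me - 2e-6

    def test_relaxation_dominance_on_seeded_variants(self):
        for seed in (3, 11):
            me, m = make_minicell(random_minicell_params(seed))
            assert (
                maximize_growth(m).mu_star
                >= maximize_growth(me).mu_star - 2e-6
            )

    def test_expression_growth_reaction_rejected(self):
        model = MEModel(
            metabolite_ids=["m"],
            reactions=[Reaction("BIOMASS", 0, 1, [("m", -1.0, 0.0)], "translation")],
            growth_reaction_id="BIOMASS",
        )
        with pytest.raises(ModelValidationError):
            strip_expression(model)


class TestCobraCrossCheck:
    """The metabolism-only analog is an ordinary FBA problem; cobrapy with
    its GLPK backend is an independent solver stack for it."""

    @staticmethod
    def _to_cobra(model: MEModel):
        import cobra

        cm = cobra.Model("m_analog")
        mets = {m: cobra.Metabolite(m) for m in model.metabolite_ids}
        for rxn in model.reactions:
            cr = cobra.Reaction(rxn.id)
            cr.lower_bound = rxn.lower_bound
            cr.upper_bound = rxn.upper_bound
            cr.add_metabolites({mets[m]: a for m, a, _ in rxn.entries})
            cm.add_reactions([cr])
        cm.objective = model.growth_reaction_id
        return cm

    def test_growth_and_fva_match_cobra(self, minicell_m):
        from cobra.flux_analysis import flux_variability_analysis

        cm = self._to_cobra(minicell_m)
        mu_cobra = cm.optimize().objective_value
        mu_ours = maximize_growth(minicell_m).mu_star
        assert mu_ours == pytest.approx(mu_cobra, abs=1e-5)

        fva_cobra = flux_variability_analysis(cm, fraction_of_optimum=1.0)
        fva_ours = flux_variability(minicell_m, mu_ours)
        for rxn in minicell_m.reaction_ids:
            assert fva_ours.table.loc[rxn, "v_min"] == pytest.approx(
                fva_cobra.loc[rxn, "minimum"], abs=1e-4
            )
            assert fva_ours.table.loc[rxn, "v_max"] == pytest.approx(
                fva_cobra.loc[rxn, "maximum"], abs=1e-4
            )
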