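"""FBA and FVA against analytic optima and two independent oracles."""

import numpy as np
import pytest

from atzgem import (
    Media,
    Reaction,
    apply_media,
    degradation_capacity,
    make_random_balanced_model,
    run_fva,
    solve_fba,
)
from _oracles import to_cobra, vertex_optimum


class TestSolveFba:
    def test_toy1_bottleneck_optimum(self, toy1):
        """mu* = min(glc, 2 nh4): the scarcer of C and N limits growth."""
        assert solve_fba(toy1, Media({"EX_glc": 10, "EX_nh4": 10})) \
            .objective_value == pytest.approx(10.0, abs=1e-6)
        assert solve_fba(toy1, Media({"EX_glc": 10, "EX_nh4": 2})) \
            .objective_value == pytest.approx(4.0, abs=1e-6)

    def test_empty_media_no_growth(self, toy2):
        assert solve_fba(toy2, Media({})).objective_value == \
            pytest.approx(0.0, abs=1e-9)

    def test_steady_state_and_bounds_hold_at_optimum(self, toy2, glc_nh4_media):
        from atzgem.core import build_stoichiometric_matrix
        constrained = apply_media(toy2, glc_nh4_media)
        sol = solve_fba(constrained)
        matrix = build_stoichiometric_matrix(constrained)
        v = np.array([sol.fluxes[rid] for rid in matrix.col_ids])
        net = matrix.S @ v
        for i, mid in enumerate(matrix.row_ids):
            if not constrained.metabolite(mid).boundary:
                assert abs(net[i]) < 1e-6
        for rxn in constrained.reactions:
            assert rxn.lower_bound - 1e-6 <= sol.fluxes[rxn.id] <= rxn.upper_bound + 1e-6

    def test_unbounded_is_reported(self, toy1):
        toy1.reaction("BIOMASS").upper_bound = float("inf")
        toy1.reaction("T_glc").upper_bound = float("inf")
        toy1.reaction("T_nh4").upper_bound = float("inf")
        toy1.reaction("EX_glc").lower_bound = -float("inf")
        toy1.reaction("EX_nh4").lower_bound = -float("inf")
        assert solve_fba(toy1).status == "unbounded"

    def test_matches_vertex_oracle_on_toy1(self, toy1):
        constrained = apply_media(toy1, Media({"EX_glc": 7, "EX_nh4": 3}))
        assert solve_fba(constrained).objective_value == \
            pytest.approx(vertex_optimum(constrained), abs=1e-6)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_vertex_oracle_on_random_networks(self, seed):
        model = make_random_balanced_model(seed=seed, n_reactions=seed % 4 + 5)
        constrained = apply_media(model, Media({"EX_s0": 5.0}))
        assert solve_fba(constrained).objective_value == \
            pytest.approx(vertex_optimum(constrained), abs=1e-6)

    def test_matches_cobra_on_pathway_model(self, toy2_pathway, atrazine_media):
        """Cross-check against an independent FBA implementation (GLPK)."""
        constrained = apply_media(toy2_pathway, atrazine_media)
        ours = solve_fba(constrained).objective_value
        theirs = to_cobra(constrained).optimize().objective_value
        assert ours == pytest.approx(theirs, abs=1e-6)
        assert ours == pytest.approx(5.0 / 6.0, abs=1e-6)

    def test_uptake_scaling_scales_growth(self, toy1):
        base = solve_fba(toy1, Media({"EX_glc": 4, "EX_nh4": 4})).objective_value
        for k in (0.0, 0.5, 2.0):
            scaled = solve_fba(toy1, Media({"EX_glc": 4 * k, "EX_nh4": 4 * k}))
            assert scaled.objective_value == pytest.approx(k * base, abs=1e-6)

    def test_enlarging_any_uptake_never_decreases_growth(self, toy2_pathway,
                                                         atrazine_media):
        base = solve_fba(toy2_pathway, atrazine_media).objective_value
        for ex_id, bound in atrazine_media.uptakes.items():
            wider = atrazine_media.with_supplements({ex_id: bound * 2 + 1})
            assert solve_fba(toy2_pathway, wider).objective_value >= base - 1e-9


class TestRunFva:
    def test_single_pathway_forces_exchange_flux(self, toy1, glc_nh4_media):
        constrained = apply_media(toy1, glc_nh4_media)
        fva = run_fva(constrained, reaction_ids=["EX_glc"])
        lo, hi = fva["EX_glc"]
        assert lo == pytest.approx(-10.0, abs=1e-6)
        assert hi == pytest.approx(-10.0, abs=1e-6)

    def test_redundant_transporters_share_a_forced_sum(self, toy1, glc_nh4_media):
        toy1.reactions.append(Reaction("T_glc2", {"glc_e": -1, "glc_c": 1},
                                       0, 1000, rtype="transport"))
        toy1._reindex()
        constrained = apply_media(toy1, glc_nh4_media)
        fva = run_fva(constrained, reaction_ids=["T_glc", "T_glc2"])
        for rid in ("T_glc", "T_glc2"):
            assert fva[rid][0] == pytest.approx(0.0, abs=1e-6)
            assert fva[rid][1] == pytest.approx(10.0, abs=1e-6)

    def test_fraction_zero_is_plain_bounds_propagation(self, toy1, glc_nh4_media):
        constrained = apply_media(toy1, glc_nh4_media)
        fva = run_fva(constrained, reaction_ids=["BIOMASS"], objective_fraction=0.0)
        assert fva["BIOMASS"][0] == pytest.approx(0.0, abs=1e-6)
        assert fva["BIOMASS"][1] == pytest.approx(10.0, abs=1e-6)

    def test_sandwich_fba_flux_inside_fva_range(self, toy2_pathway, atrazine_media):
        constrained = apply_media(toy2_pathway, atrazine_media)
        sol = solve_fba(constrained)
        fva = run_fva(constrained)
        for rid in fva:
            lo, hi = fva[rid]
            assert lo <= hi
            assert lo - 1e-6 <= sol.fluxes[rid] <= hi + 1e-6
            rxn = constrained.reaction(rid)
            assert rxn.lower_bound - 1e-6 <= lo and hi <= rxn.upper_bound + 1e-6

    def test_matches_cobra_fva(self, toy2_pathway, atrazine_media):
        constrained = apply_media(toy2_pathway, atrazine_media)
        ours = run_fva(constrained, objective_fraction=0.9)
        cobra_model = to_cobra(constrained)
        from cobra.flux_analysis import flux_variability_analysis
        theirs = flux_variability_analysis(cobra_model, fraction_of_optimum=0.9)
        for rid in ours:
            assert ours[rid][0] == pytest.approx(theirs.loc[rid, "minimum"], abs=1e-5)
            assert ours[rid][1] == pytest.approx(theirs.loc[rid, "maximum"], abs=1e-5)

    def test_bad_fraction_rejected(self, toy1, glc_nh4_media):
        with pytest.raises(ValueError, match="fraction"):
            run_fva(apply_media(toy1, glc_nh4_media), objective_fraction=1.5)


class TestDegradationCapacity:
    def test_sole_source_forces_uptake(self, toy2_pathway, atrazine_media):
        lo, hi = degradation_capacity(toy2_pathway, atrazine_media, "EX_atz")
        assert lo == pytest.approx(1.0, abs=1e-6)
        assert hi == pytest.approx(1.0, abs=1e-6)

    def test_glucose_relaxes_the_lower_end(self, toy2_pathway, atrazine_media):
        """With glucose the N demand can be met with less atrazine."""
        with_glc = atrazine_media.with_supplements({"EX_glc": 1.0})
        lo_sole, hi_sole = degradation_capacity(toy2_pathway, atrazine_media, "EX_atz")
        lo_glc, hi_glc = degradation_capacity(toy2_pathway, with_glc, "EX_atz")
        assert hi_glc >= hi_sole - 1e-6
        assert lo_glc <= lo_sole + 1e-6

    def test_closed_exchange_gives_zero_range(self, toy2_pathway):
        media = Media({"EX_glc": 5.0, "EX_nh4": 5.0, "EX_hpo4": 5.0})
        lo, hi = degradation_capacity(toy2_pathway, media, "EX_atz")
        assert (lo, hi) == (0.0, 0.0)
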