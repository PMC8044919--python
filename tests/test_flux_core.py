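"""flux_core: FBA/pFBA/FVA correctness, deletions and screens."""

from __future__ import annotations

import numpy as np
import pytest

from succdesign.flux_core import (
    delete_reactions,
    essential_reactions,
    find_blocked,
    flux_variability,
    single_deletion_screen,
    solve_fba,
    solve_pfba_reference,
)
from succdesign.model_io import MetabolicNetwork

from conftest import build_net


def mass_balance_residual(net, sol):
    S = net.stoichiometric_matrix()
    v = sol.as_vector(net.reaction_ids())
    return np.max(np.abs(S @ v))


# ---------------------------------------------------------------------------
# FBA
# ---------------------------------------------------------------------------

class TestFBA:
    def test_linear_chain_reaches_uptake_limit(self, chain_net):
        sol = solve_fba(chain_net, "EX_b")
        assert sol.status == "optimal"
        assert sol.objective_value == pytest.approx(10.0, abs=1e-9)

    def test_solution_satisfies_mass_balance_and_bounds(self, toy_net):
        sol = solve_fba(toy_net)
        assert sol.status == "optimal"
        assert mass_balance_residual(toy_net, sol) <= 1e-6
        for r in toy_net.reactions:
            assert r.lower_bound - 1e-6 <= sol.fluxes[r.id] <= r.upper_bound + 1e-6

    def test_all_zero_bounds_gives_zero_objective(self, chain_net):
        dead = delete_reactions(chain_net, set(chain_net.reaction_ids()))
        sol = solve_fba(dead, "EX_b")
        assert sol.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_infeasible_model_reported(self):
        # forced uptake with no consuming reaction
        net = build_net([("EX_a", {"a_c": -1}, -10, -5)], objective="EX_a")
        sol = solve_fba(net)
        assert sol.status == "infeasible"
        assert sol.fluxes == {}

    def test_objective_invariant_to_column_permutation(self, toy_net, rng):
        base = solve_fba(toy_net).objective_value
        perm = list(rng.permutation(len(toy_net.reactions)))
        cp = toy_net.copy()
        shuffled = MetabolicNetwork(
            cp.metabolites,
            [cp.reactions[i] for i in perm],
            [],
            toy_net.objective_reaction,
        )
        assert solve_fba(shuffled).objective_value == pytest.approx(base, abs=1e-8)

    def test_matches_cobrapy_on_toy_network(self, toy_net, tmp_path):
        """Independent LP oracle: cobrapy/GLPK on the identical model."""
        cobra = pytest.importorskip("cobra")
        import warnings

        from succdesign.model_io import write_model

        path = tmp_path / "toy.xml"
        write_model(toy_net, path, "sbml")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cm = cobra.io.read_sbml_model(str(path))
        oracle = cm.optimize().objective_value
        ours = solve_fba(toy_net).objective_value
        assert ours == pytest.approx(oracle, abs=1e-6)


# ---------------------------------------------------------------------------
# pFBA
# ---------------------------------------------------------------------------

class TestPFBA:
    def test_biomass_matches_fba_optimum(self, toy_net):
        fba = solve_fba(toy_net)
        pfba = solve_pfba_reference(toy_net)
        assert pfba.objective_value == pytest.approx(fba.objective_value, abs=1e-9)
        assert mass_balance_residual(toy_net, pfba) <= 1e-6

    def test_parallel_paths_resolved_parsimoniously(self):
        """Two equivalent routes: pFBA picks the minimal-total-flux split,
        which for identical single-step paths means any split, but never
        the wasteful loop; total |v| must equal the enumerated optimum."""
        net = build_net(
            [
                ("EX_a", {"a_c": -1}, -10, 0),
                ("P1", {"a_c": -1, "b_c": 1}, 0, 1000, "g1"),
                ("P2", {"a_c": -1, "c_c": 1}, 0, 1000, "g2"),
                ("C2B", {"c_c": -1, "b_c": 1}, 0, 1000, "g3"),
                ("EX_b", {"b_c": -1}, 0, 1000),
            ],
            objective="EX_b",
        )
        pfba = solve_pfba_reference(net)
        # direct path P1 (1 step) beats P2+C2B (2 steps): all flux via P1
        assert pfba.fluxes["P1"] == pytest.approx(10.0, abs=1e-6)
        assert pfba.fluxes["P2"] == pytest.approx(0.0, abs=1e-6)
        total = sum(abs(v) for v in pfba.fluxes.values())
        assert total == pytest.approx(30.0, abs=1e-6)  # EX_a + P1 + EX_b

    def test_unique_optimum_identical_to_fba(self, chain_net):
        fba = solve_fba(chain_net, "EX_b")
        pfba = solve_pfba_reference(chain_net, "EX_b")
        for rid in chain_net.reaction_ids():
            assert pfba.fluxes[rid] == pytest.approx(fba.fluxes[rid], abs=1e-6)


# ---------------------------------------------------------------------------
# FVA
# ---------------------------------------------------------------------------

class TestFVA:
    def test_dead_end_reaction_is_pinned_to_zero(self):
        net = build_net(
            [
                ("EX_a", {"a_c": -1}, -10, 1000),
                ("AB", {"a_c": -1, "b_c": 1}, 0, 1000),
                ("EX_b", {"b_c": -1}, 0, 1000),
                ("AD", {"a_c": -1, "d_c": 1}, 0, 1000, "gd"),  # d has no sink
            ],
            objective="EX_b",
        )
        rng_ = flux_variability(net, ["AD"], 0.0)[0]
        assert rng_.min_flux == pytest.approx(0.0, abs=1e-9)
        assert rng_.max_flux == pytest.approx(0.0, abs=1e-9)

    def test_fva_brackets_fba_flux(self, toy_net):
        sol = solve_fba(toy_net)
        for rng_ in flux_variability(toy_net, toy_net.reaction_ids()[:12], 0.9):
            v = sol.fluxes[rng_.reaction_id]
            assert rng_.min_flux <= v + 1e-6
            assert v <= rng_.max_flux + 1e-6

    def test_fraction_zero_nests_fraction_one(self, toy_net):
        ids = ["EX_succ_e", "PDH", "FUM", "TPI", "LDH_D"]
        loose = {r.reaction_id: r for r in flux_variability(toy_net, ids, 0.0)}
        tight = {r.reaction_id: r for r in flux_variability(toy_net, ids, 1.0)}
        for rid in ids:
            assert loose[rid].min_flux <= tight[rid].min_flux + 1e-6
            assert tight[rid].max_flux <= loose[rid].max_flux + 1e-6

    def test_invalid_fraction_rejected(self, toy_net):
        with pytest.raises(ValueError):
            flux_variability(toy_net, ["PDH"], 1.5)


# ---------------------------------------------------------------------------
# Deletions and screens
# ---------------------------------------------------------------------------

class TestDeletions:
    def test_empty_deletion_is_identity(self, toy_net):
        out = delete_reactions(toy_net, set())
        assert solve_fba(out).objective_value == pytest.approx(
            solve_fba(toy_net).objective_value, abs=1e-9
        )

    def test_deletions_compose(self, toy_net):
        a_then_b = delete_reactions(delete_reactions(toy_net, {"PDH"}), {"FUM"})
        both = delete_reactions(toy_net, {"PDH", "FUM"})
        assert solve_fba(a_then_b).objective_value == pytest.approx(
            solve_fba(both).objective_value, abs=1e-9
        )

    def test_original_untouched(self, toy_net):
        before = toy_net.reaction("PDH").upper_bound
        delete_reactions(toy_net, {"PDH"})
        assert toy_net.reaction("PDH").upper_bound == before

    def test_unknown_id_rejected(self, toy_net):
        with pytest.raises(ValueError, match="NOPE"):
            delete_reactions(toy_net, {"NOPE"})

    def test_deleting_biomass_zeroes_growth(self, toy_net):
        sol = solve_fba(delete_reactions(toy_net, {"BIOMASS_toy"}))
        assert sol.objective_value == pytest.approx(0.0, abs=1e-9)


class TestScreens:
    def test_unused_reaction_has_full_relative_growth(self, toy_net):
        rows = {r.reaction_id: r for r in single_deletion_screen(toy_net)}
        # POX carries no flux in any optimum of the default toy
        assert rows["POX"].relative_growth == pytest.approx(1.0, abs=1e-6)

    def test_pdh_deletion_costs_a_few_percent(self, toy_net):
        """PDH loss reroutes pyruvate through PFL at a small energetic
        cost: a single-digit percentage growth reduction."""
        rows = {r.reaction_id: r for r in single_deletion_screen(toy_net)}
        reduction = 1.0 - rows["PDH"].relative_growth
        assert 0.005 < reduction < 0.10

    def test_named_five_reduce_growth_more_than_pdh(self, toy_net):
        """FUM, GAPD, PGK, PGM and TPI deletions all cut growth more deeply
        than the PDH deletion (qualitative ordering of the screen)."""
        rows = {r.reaction_id: r for r in single_deletion_screen(toy_net)}
        for rid in ("FUM", "GAPD", "PGK", "PGM", "TPI"):
            assert rows[rid].relative_growth < rows["PDH"].relative_growth
            assert rows[rid].relative_growth > 0.05  # reduced, not essential

    def test_blocked_detection_matches_exhaustive_fva(self):
        net = build_net(
            [
                ("EX_a", {"a_c": -1}, -10, 1000),
                ("AB", {"a_c": -1, "b_c": 1}, 0, 1000),
                ("EX_b", {"b_c": -1}, 0, 1000),
                ("ORPHAN", {"x_c": -1, "y_c": 1}, 0, 1000, "gx"),
                ("EX_y", {"y_c": -1}, 0, 1000),
            ],
            objective="EX_b",
        )
        blocked = find_blocked(net)
        oracle = set()
        for rng_ in flux_variability(net, objective_fraction=0.0):
            if abs(rng_.min_flux) <= 1e-9 and abs(rng_.max_flux) <= 1e-9:
                oracle.add(rng_.reaction_id)
        assert blocked == oracle == {"ORPHAN", "EX_y"}

    def test_fully_connected_chain_has_no_blocked(self, chain_net):
        assert find_blocked(chain_net) == set()

    def test_essentials_match_screen_threshold(self, toy_net):
        cutoff = 0.05
        ess = essential_reactions(toy_net, cutoff)
        rows = single_deletion_screen(toy_net, gene_associated_only=False)
        oracle = {r.reaction_id for r in rows if r.relative_growth < cutoff}
        assert ess == oracle

    def test_redundant_parallel_path_not_essential(self):
        net = build_net(
            [
                ("EX_a", {"a_c": -1}, -10, 1000),
                ("P1", {"a_c": -1, "b_c": 1}, 0, 1000, "g1"),
                ("P2", {"a_c": -1, "b_c": 1}, 0, 1000, "g2"),
                ("EX_b", {"b_c": -1}, 0, 1000),
            ],
            objective="EX_b",
        )
        ess = essential_reactions(net, 0.5)
        assert "P1" not in ess and "P2" not in ess
        assert "EX_a" in ess
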