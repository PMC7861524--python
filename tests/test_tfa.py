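import math
from dataclasses import replace

import numpy as np
import pytest

from thermoflux.model import (
    Compartment,
    MetabolicModel,
    Reaction,
    Species,
    SpeciesThermoRecord,
)
from thermoflux.physchem import PhysChemConditions, reaction_records_for_model
from thermoflux import tfa

from conftest import build_toy_problem


class TestFBA:
    def test_toy_objective_matches_independent_lp(self, toy):
        sol = tfa.solve_fba(toy.model, uptake_rate=toy.manifest["uptake"])
        assert sol.status == "optimal"
        assert sol.objective_value == pytest.approx(
            toy.manifest["fba_objective"], rel=1e-6
        )
        # independent route: same LP through cobrapy
        cm = toy.model.to_cobra()
        cm.reactions.EX_glc.bounds = (-toy.manifest["uptake"],
                                      -toy.manifest["uptake"])
        assert cm.optimize().objective_value == pytest.approx(
            sol.objective_value, rel=1e-6
        )

    def test_steady_state_residual(self, toy):
        sol = tfa.solve_fba(toy.model, uptake_rate=10)
        S = toy.model.stoichiometric_matrix().to_numpy()
        v = np.array([sol.fluxes[r] for r in toy.model.reactions])
        assert np.abs(S @ v).max() <= 1e-9

    def test_zero_uptake_gives_no_growth(self, toy):
        sol = tfa.solve_fba(toy.model, uptake_rate=0)
        assert sol.status == "no_growth"
        assert sol.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_contradictory_bounds_infeasible(self, toy):
        model = toy.model.copy()
        # demand flux through the isomerase while cutting off all carbon
        model.reactions["EX_glc"].lower_bound = 0.0
        model.reactions["EX_glc"].upper_bound = 0.0
        model.reactions["PGI"].lower_bound = 5.0
        sol = tfa.solve_fba(model)
        assert sol.status == "infeasible"


class TestConcentrationConstraints:
    def test_experimental_band_is_90_to_110_percent(self, toy):
        cs = tfa.apply_concentration_constraints(
            toy.metabolomics, "experimental", model=toy.model
        )
        row = toy.metabolomics.set_index("species_id")["concentration_M"]
        lo, hi = cs.bounds["pyr_c"]
        assert lo == pytest.approx(0.9 * row["pyr_c"])
        assert hi == pytest.approx(1.1 * row["pyr_c"])
        lo_ln, hi_ln = cs.ln_bounds("pyr_c")
        assert lo_ln == pytest.approx(math.log(0.9 * row["pyr_c"]))
        assert hi_ln == pytest.approx(math.log(1.1 * row["pyr_c"]))

    def test_default_mode_touches_only_cofactors(self, toy):
        cs = tfa.apply_concentration_constraints(
            toy.metabolomics, "default_cofactors", model=toy.model
        )
        assert set(cs.bounds) == {"atp_c", "adp_c", "amp_c"}
        # a measured non-cofactor keeps the global window
        assert cs.ln_bounds("pyr_c") == (
            math.log(tfa.DEFAULT_CONC_LB), math.log(tfa.DEFAULT_CONC_UB)
        )

    def test_unknown_species_skipped_with_warning(self, toy, caplog):
        import pandas as pd

        data = pd.DataFrame(
            {"species_id": ["nosuch_c"], "concentration_M": [1e-3]}
        )
        with caplog.at_level("WARNING"):
            cs = tfa.apply_concentration_constraints(
                data, "experimental", model=toy.model
            )
        assert "nosuch_c" not in cs.bounds
        assert any("nosuch_c" in rec.message for rec in caplog.records)


class TestTFA:
    def test_objective_bounded_by_fba(self, toy, toy_solution):
        _, sol = toy_solution
        fba = tfa.solve_fba(toy.model, uptake_rate=toy.manifest["uptake"])
        assert sol.objective_value <= fba.objective_value + 1e-9

    def test_covered_count_matches_records(self, toy, toy_solution):
        problem, _ = toy_solution
        records = problem.reaction_records
        assert set(problem.covered) == {
            rid for rid, rec in records.items() if rec.covered
        }
        assert sorted(problem.covered) == toy.manifest["covered_reactions"]

    def test_solution_passes_consistency_check(self, toy_solution):
        problem, sol = toy_solution
        report = tfa.verify_thermo_consistency(problem, sol)
        assert report.ok, report.violations

    def test_negated_flux_is_flagged(self, toy_solution):
        problem, sol = toy_solution
        broken = replace(sol)
        broken.fluxes = dict(sol.fluxes)
        broken.fluxes["GLY"] = -broken.fluxes["GLY"]
        report = tfa.verify_thermo_consistency(problem, broken)
        assert len(report.violations) == 1
        assert "GLY" in report.violations[0]

    def test_zero_flux_with_positive_energy_not_flagged(self, toy_solution):
        problem, sol = toy_solution
        # B2 is inactive at I = 0.25 and its drG' is positive: no violation
        assert abs(sol.fluxes["B2"]) < 1e-9
        assert sol.drg_prime["B2"] > 0
        assert tfa.verify_thermo_consistency(problem, sol).ok

    def test_ionic_strength_blocks_efficient_branch(self, toy):
        """At I = 0 the substrate-level-phosphorylation branch is blocked
        and flux reroutes through the direct branch at lower growth."""
        problem = build_toy_problem(toy, ionic_strength=0.0)
        sol = tfa.solve_tfa(problem)
        assert sol.status == "optimal"
        assert abs(sol.fluxes["B1"]) < 1e-9
        assert sol.fluxes["B2"] < -1e-6  # runs in its reverse (mapped) sense
        assert sol.objective_value == pytest.approx(
            toy.manifest["tfa_objective_I0"], rel=1e-6
        )

    def test_reference_conditions_use_efficient_branch(self, toy, toy_solution):
        _, sol = toy_solution
        assert sol.fluxes["B1"] == pytest.approx(2 * toy.manifest["uptake"], rel=1e-6)
        assert sol.objective_value == pytest.approx(
            toy.manifest["tfa_objective_I025"], rel=1e-6
        )

    def test_fingerprint_mismatch_rejected(self, toy):
        cond_a = PhysChemConditions(ionic_strength=0.25)
        cond_b = PhysChemConditions(ionic_strength=0.0)
        records = reaction_records_for_model(toy.model, toy.thermo, cond_a)
        with pytest.raises(tfa.TFAError, match="different conditions"):
            tfa.build_tfa_problem(toy.model, records, cond_b)

    def test_indicator_forces_negative_drg_when_forward(self, toy_solution):
        problem, sol = toy_solution
        for rid in problem.covered:
            zp, _ = sol.binaries[rid]
            if zp == 1:
                assert sol.drg_prime[rid] <= -problem.epsilon + 1e-9


class TestRelaxation:
    def test_feasible_problem_needs_zero_slack(self, toy):
        problem = build_toy_problem(toy)
        target = toy.manifest["tfa_objective_I025"]
        relaxed = tfa.relax_dg_bounds(problem, required_growth=target - 1e-9)
        assert relaxed.status == "optimal"
        assert all(s == 0.0 for s in relaxed.slacks.values())

    def test_minimal_slack_localizes_on_perturbed_reaction(self, toy):
        problem = build_toy_problem(toy)
        base = tfa.solve_tfa(problem)
        records = dict(problem.reaction_records)
        records["B1"] = replace(
            records["B1"], drg0_transformed=records["B1"].drg0_transformed + 15.0
        )
        perturbed = tfa.build_tfa_problem(
            problem.model, records, problem.conditions, problem.constraints
        )
        worse = tfa.solve_tfa(perturbed)
        assert worse.objective_value < base.objective_value - 1e-6
        relaxed = tfa.relax_dg_bounds(perturbed, required_growth=base.objective_value)
        assert relaxed.status == "optimal"
        report = relaxed.slack_report()
        assert report[0][0] == "B1" and report[0][1] > 0
        assert all(s == pytest.approx(0.0, abs=1e-6) for rid, s in report[1:])
        # ordering is descending by magnitude
        mags = [abs(s) for _, s in report]
        assert mags == sorted(mags, reverse=True)


def _chain_model_with_uphill_steps():
    """s_e -> s_c -> m_c -> p_c -> out, with two +15 kJ/mol steps that are
    jointly infeasible inside the default concentration window but feasible
    once the window is wide."""
    comps = {"c": Compartment("c"), "e": Compartment("e")}
    species = {
        "s_e": Species("s_e", compartment="e"),
        "s_c": Species("s_c", compartment="c"),
        "m_c": Species("m_c", compartment="c"),
        "p_c": Species("p_c", compartment="c"),
    }
    reactions = {
        "EX_s": Reaction("EX_s", {"s_e": -1.0}, -10, -10, is_exchange=True,
                         thermo_active=False),
        "T": Reaction("T", {"s_e": -1.0, "s_c": 1.0}, -1000, 1000,
                      thermo_active=False),
        "R1": Reaction("R1", {"s_c": -1.0, "m_c": 1.0}),
        "R2": Reaction("R2", {"m_c": -1.0, "p_c": 1.0}),
        "EX_p": Reaction("EX_p", {"p_c": -1.0}, 0, 1000, is_exchange=True,
                         thermo_active=False),
    }
    model = MetabolicModel(compartments=comps, species=species,
                           reactions=reactions, objective_reaction="EX_p",
                           id="chain")
    thermo = {
        "s_c": SpeciesThermoRecord("s_c", 0.0),
        "m_c": SpeciesThermoRecord("m_c", 15.0),
        "p_c": SpeciesThermoRecord("p_c", 30.0),
    }
    return model, thermo


def test_loose_concentration_bounds_recover_fba_objective():
    model, thermo = _chain_model_with_uphill_steps()
    cond = PhysChemConditions()
    records = reaction_records_for_model(model, thermo, cond)
    fba = tfa.solve_fba(model)
    assert fba.objective_value == pytest.approx(10.0)

    tight = tfa.build_tfa_problem(model, records, cond)
    assert tfa.solve_tfa(tight).objective_value < fba.objective_value - 1e-6

    wide = tfa.ConcentrationConstraintSet(
        mode="default_cofactors",
        bounds={s: (1e-9, 10.0) for s in ("s_c", "m_c", "p_c")},
    )
    loose = tfa.build_tfa_problem(model, records, cond, wide)
    assert tfa.solve_tfa(loose).objective_value == pytest.approx(
        fba.objective_value, rel=1e-9
    )
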