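import math

import pytest
from hypothesis import given, strategies as st
from scipy.optimize import brentq

from thermoflux.constants import R_KJ
from thermoflux.model import Compartment, Reaction, SpeciesThermoRecord
from thermoflux import physchem as pc


DH = pc.PhysChemConditions(adjustment_method="debye_huckel")
DAVIES = pc.PhysChemConditions(adjustment_method="davies")


class TestParamA:
    def test_quadratic_values(self):
        assert pc.param_A_temperature(298.15) == pytest.approx(1.17585, abs=1e-4)
        assert pc.param_A_temperature(310.15) == pytest.approx(1.20078, abs=1e-4)

    def test_out_of_range(self):
        with pytest.raises(pc.PhysChemError):
            pc.param_A_temperature(200.0)

    def test_strictly_increasing_over_liquid_range(self):
        temps = [273.16 + i for i in range(100)]
        values = [pc.param_A_temperature(t) for t in temps]
        assert all(b > a for a, b in zip(values, values[1:]))


class TestSeawaterSubmodels:
    def test_density_values(self):
        assert pc.seawater_density(25, 0) == pytest.approx(997.05, abs=0.1)
        assert pc.seawater_density(25, 35) == pytest.approx(1023.3, abs=0.3)

    def test_density_monotone_in_salinity(self):
        assert pc.seawater_density(25, 35) > pc.seawater_density(25, 0)

    def test_density_range_check(self):
        with pytest.raises(pc.PhysChemError):
            pc.seawater_density(55, 0)

    def test_permittivity_values_and_monotonicity(self):
        assert pc.seawater_rel_permittivity(25, 0) == pytest.approx(78.4, abs=0.3)
        assert pc.seawater_rel_permittivity(37, 0) < pc.seawater_rel_permittivity(25, 0)
        assert pc.seawater_rel_permittivity(25, 35) < pc.seawater_rel_permittivity(25, 0)
        with pytest.raises(pc.PhysChemError):
            pc.seawater_rel_permittivity(90, 0)


class TestParamATS:
    def test_matches_temperature_form_at_zero_salinity(self):
        for t in range(5, 41):
            a_t = pc.param_A_temperature(t + 273.15)
            a_ts = pc.param_A_temp_salinity(t, 0.0)
            assert abs(a_ts / a_t - 1.0) < 0.02

    def test_increasing_in_salinity(self):
        assert pc.param_A_temp_salinity(25, 13.74) > pc.param_A_temp_salinity(25, 0)

    def test_negative_salinity_rejected(self):
        with pytest.raises(pc.PhysChemError):
            pc.param_A_temp_salinity(25, -1.0)


class TestSalinityRelation:
    def test_reference_point(self):
        assert pc.salinity_from_ionic_strength(0.25, 1.11) == pytest.approx(
            13.74, abs=0.01
        )

    def test_zero(self):
        assert pc.salinity_from_ionic_strength(0.0, 1.11) == 0.0

    def test_against_root_finding_oracle(self):
        # invert I*rho = 19.92 S / (1000 - 1.005 S) numerically
        def forward(s, i, rho):
            return 19.92 * s / (1000.0 - 1.005 * s) - i * rho

        expected = brentq(forward, 0.0, 900.0, args=(0.15, 1.00), xtol=1e-12)
        assert expected == pytest.approx(7.47, abs=0.01)
        assert pc.salinity_from_ionic_strength(0.15, 1.00) == pytest.approx(
            expected, abs=1e-9
        )


class TestIonicTerm:
    def test_zero_at_zero(self):
        assert pc.ionic_term_factor(0.0, DH) == 0.0
        assert pc.ionic_term_factor(0.0, DAVIES) == 0.0

    def test_hand_values_at_quarter_molar(self):
        assert pc.ionic_term_factor(0.25, DH) == pytest.approx(0.27778, abs=1e-5)
        assert pc.ionic_term_factor(0.25, DAVIES) == pytest.approx(0.25833, abs=1e-5)

    @given(st.floats(min_value=1e-8, max_value=1e-4))
    def test_methods_agree_to_first_order_at_low_I(self, ionic_strength):
        ratio = pc.ionic_term_factor(ionic_strength, DAVIES) / pc.ionic_term_factor(
            ionic_strength, DH
        )
        assert ratio == pytest.approx(1.0, abs=2e-2)

    def test_davies_below_debye_huckel_above_crossover(self):
        # with B = 1.6 the two corrections cross near I ~ 0.1 M: Davies is
        # the smaller factor throughout the upper part of its validity range
        for i in (0.15, 0.25, 0.4, 0.5):
            assert pc.ionic_term_factor(i, DAVIES) < pc.ionic_term_factor(i, DH)
        # ...and the larger one below the crossover
        assert pc.ionic_term_factor(0.05, DAVIES) > pc.ionic_term_factor(0.05, DH)


class TestFormationTransform:
    record = SpeciesThermoRecord("x_c", dfg0_ref=-100.0, charge=-4, n_hydrogen=12)
    neutral = SpeciesThermoRecord("n_c", dfg0_ref=-50.0, charge=0, n_hydrogen=0)

    def test_neutral_species_unchanged(self):
        comp = Compartment("c", pH=7.0)
        cond = pc.PhysChemConditions(ionic_strength=0.25, temperature_c=37.0)
        te = pc.transform_formation_energy(self.neutral, comp, cond)
        assert te.dfg0_transformed == pytest.approx(-50.0, abs=1e-12)

    def test_zero_ionic_strength_closed_form(self):
        comp = Compartment("c", pH=7.0)
        for method in ("debye_huckel", "davies"):
            cond = pc.PhysChemConditions(ionic_strength=0.0,
                                         adjustment_method=method)
            te = pc.transform_formation_energy(self.record, comp, cond)
            expected = -100.0 + 12 * R_KJ * 298.15 * math.log(10) * 7.0
            assert te.dfg0_transformed == pytest.approx(expected, rel=1e-12)

    def test_linear_in_ph(self):
        cond = pc.PhysChemConditions(ionic_strength=0.1)
        values = [
            pc.transform_formation_energy(
                self.record, Compartment("c", pH=ph), cond
            ).dfg0_transformed
            for ph in (5.0, 6.0, 7.0)
        ]
        assert values[1] - values[0] == pytest.approx(values[2] - values[1], rel=1e-12)

    def test_debye_huckel_ionic_part_exceeds_davies_at_quarter_molar(self):
        comp = Compartment("c", pH=7.0)
        base = pc.transform_formation_energy(
            self.record, comp, pc.PhysChemConditions(ionic_strength=0.0)
        ).dfg0_transformed
        dh = pc.transform_formation_energy(
            self.record, comp, pc.PhysChemConditions(ionic_strength=0.25)
        ).dfg0_transformed
        davies = pc.transform_formation_energy(
            self.record, comp,
            pc.PhysChemConditions(ionic_strength=0.25, adjustment_method="davies"),
        ).dfg0_transformed
        assert abs(dh - base) > abs(davies - base) > 0

    def test_unknown_record_rejected(self):
        unknown = SpeciesThermoRecord("u_c", dfg0_ref=None)
        with pytest.raises(pc.PhysChemError):
            pc.transform_formation_energy(unknown, Compartment("c"), DH)


class TestReactionDg0:
    cond = pc.PhysChemConditions()
    fp = cond.fingerprint()

    def energies(self, **values):
        return {
            sid: pc.TransformedEnergy(sid, v, self.fp) for sid, v in values.items()
        }

    def test_identity_reaction_cancels(self):
        rxn = Reaction("ID", {"a_c": -1.0, "b_c": 1.0})
        rec = pc.reaction_transformed_dg0(
            rxn, self.energies(a_c=-100.0, b_c=-100.0), self.cond
        )
        assert rec.covered and rec.drg0_transformed == pytest.approx(0.0)

    def test_hand_sum(self):
        rxn = Reaction("R", {"a_c": -1.0, "b_c": 1.0})
        rec = pc.reaction_transformed_dg0(
            rxn, self.energies(a_c=-100.0, b_c=-120.0), self.cond
        )
        assert rec.drg0_transformed == pytest.approx(-20.0)

    def test_reverse_sums_to_zero(self, toy):
        records = pc.reaction_records_for_model(toy.model, toy.thermo, self.cond)
        energies = {}  # reuse the model transform through a reversed copy
        for rid, rxn in toy.model.reactions.items():
            if not records[rid].covered:
                continue
            reverse = Reaction(
                rid + "_rev",
                {s: -c for s, c in rxn.stoichiometry.items()},
                thermo_active=True,
            )
            comp_by_sp = {
                sid: toy.model.compartments[sp.compartment]
                for sid, sp in toy.model.species.items()
            }
            all_energies = pc.transform_all(toy.thermo, comp_by_sp, self.cond)
            rev = pc.reaction_transformed_dg0(reverse, all_energies, self.cond)
            assert records[rid].drg0_transformed + rev.drg0_transformed == (
                pytest.approx(0.0, abs=1e-9)
            )

    def test_missing_species_marks_uncovered(self):
        rxn = Reaction("R", {"a_c": -1.0, "b_c": 1.0})
        rec = pc.reaction_transformed_dg0(rxn, self.energies(a_c=-100.0), self.cond)
        assert not rec.covered and rec.drg0_transformed is None

    def test_protons_and_water_excluded(self):
        rxn = Reaction("R", {"a_c": -1.0, "h_c": -2.0, "h2o_c": 1.0, "b_c": 1.0})
        rec = pc.reaction_transformed_dg0(
            rxn,
            self.energies(a_c=-100.0, b_c=-120.0, h_c=-1.0, h2o_c=-157.0),
            self.cond,
        )
        assert rec.drg0_transformed == pytest.approx(-20.0)

    def test_exchange_never_covered(self):
        rxn = Reaction("EX_a", {"a_c": -1.0}, is_exchange=True, thermo_active=False)
        rec = pc.reaction_transformed_dg0(rxn, self.energies(a_c=-1.0), self.cond)
        assert not rec.covered


class TestFluxForce:
    def test_zero_energy_gives_unity(self):
        assert pc.flux_force_ratio(0.0, 298.15) == 1.0

    def test_algebraic_inversion(self):
        drg = -R_KJ * 298.15 * math.log(2.0)
        assert pc.flux_force_ratio(drg, 298.15) == pytest.approx(2.0, rel=1e-12)

    @given(st.floats(min_value=-50, max_value=-0.01))
    def test_negative_energy_drives_forward(self, drg):
        assert pc.flux_force_ratio(drg, 310.15) > 1.0
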