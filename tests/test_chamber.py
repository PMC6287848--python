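"""CSTR chamber model: steady states, mass conservation, chemistry."""

import numpy as np
import pytest

from bvocflux.chamber import (ChamberScenario, EmissionSchedule, SpeciesConfig,
                              cstr_steady_state, simulate_chamber)
from bvocflux.constants import nmol_m3_to_ppbv
from bvocflux.kinetics import fractional_loss


def single_species_scenario(E=0.05, k_o3=0.0, o3=0.0, t_end=7200.0, **kw):
    o3_schedule = [(0.0, o3)]
    return ChamberScenario(
        species_leaf={"monoterpenes": SpeciesConfig(
            emission=EmissionSchedule(E), k_o3_gas=k_o3)},
        species_root={"methanethiol": SpeciesConfig(
            emission=EmissionSchedule(0.04))},
        o3_schedule=o3_schedule, fumigation_start=0.0, t_end=t_end, **kw)


class TestSteadyState:
    def test_zero_emission_zero_inflow_all_zero(self):
        sc = single_species_scenario(E=0.0)
        df = simulate_chamber(sc, "leaf")
        assert np.all(df["monoterpenes"].to_numpy() == 0.0)

    def test_no_chemistry_steady_state_is_EA_over_Q(self):
        sc = single_species_scenario(E=0.05)
        df = simulate_chamber(sc, "leaf")
        expected = nmol_m3_to_ppbv(0.05 * sc.A_leaf / sc.Q_leaf, sc.T, sc.P)
        assert df["monoterpenes"].iloc[-1] == pytest.approx(expected, rel=1e-8)

    def test_mass_conservation_outflow_equals_emission(self):
        """Q*C at steady state balances E*A within 0.1% (no chemistry)."""
        sc = single_species_scenario(E=0.05)
        df = simulate_chamber(sc, "leaf")
        c_nmol = df["monoterpenes"].iloc[-1] * sc.P / (8.314 * sc.T)
        outflow = sc.Q_leaf * c_nmol              # nmol s^-1
        emitted = 0.05 * sc.A_leaf
        assert outflow == pytest.approx(emitted, rel=1e-3)

    def test_ozonolysis_suppression_matches_fractional_loss(self):
        """Steady-state drop with an O3 step equals the closed-form CSTR
        chemical fraction."""
        k_o3 = 2.0e-16
        sc_clean = single_species_scenario(E=0.05, k_o3=k_o3, o3=0.0)
        sc_o3 = single_species_scenario(E=0.05, k_o3=k_o3, o3=135.0)
        c0 = simulate_chamber(sc_clean, "leaf")["monoterpenes"].iloc[-1]
        c1 = simulate_chamber(sc_o3, "leaf")["monoterpenes"].iloc[-1]
        k_chem = k_o3 * 135e-9 * 2.46e19
        f = fractional_loss(k_chem, sc_o3.residence_time("leaf"))
        assert 1 - c1 / c0 == pytest.approx(f, rel=1e-3)

    def test_converges_to_closed_form_within_5_residence_times(self):
        sc = single_species_scenario(E=0.05, k_o3=2e-16, o3=135.0, t_end=7200.0)
        tau = sc.residence_time("leaf")
        df = simulate_chamber(sc, "leaf", init="zero")
        c_ss = cstr_steady_state(0.05, sc.A_leaf, sc.V_leaf, sc.Q_leaf,
                                 k_chem=2e-16 * 135e-9 * 2.46e19,
                                 T=sc.T, P=sc.P)
        t5 = df.index[df.index >= 5 * tau]
        assert abs(df.loc[t5[0], "monoterpenes"] - c_ss) / c_ss < 0.01


class TestSchedulesAndValidation:
    def test_negative_schedule_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            single_species_scenario(o3=-1.0)

    def test_negative_emission_rejected(self):
        with pytest.raises(ValueError):
            EmissionSchedule(-0.1)

    def test_surface_sink_fraction_bounds(self):
        with pytest.raises(ValueError):
            SpeciesConfig(surface_sink=1.5)

    def test_induced_burst_rises_to_plateau(self):
        e = EmissionSchedule(basal=1.0, induced_delta=2.0, rise_tau=600.0)
        assert e.rate(0.0, 1000.0) == 1.0
        assert e.rate(1000.0, 1000.0) == pytest.approx(1.0)
        # one time constant: 1 - e^-1 of the step
        assert e.rate(1600.0, 1000.0) == pytest.approx(1.0 + 2.0 * (1 - np.exp(-1)))
        assert e.rate(1000.0 + 20 * 600.0, 1000.0) == pytest.approx(3.0)

    def test_residence_time_is_V_over_Q(self):
        sc = single_species_scenario()
        assert sc.residence_time("leaf") == pytest.approx(sc.V_leaf / sc.Q_leaf)
        # default study-condition flow honors the stated ca. 6.5 min
        from bvocflux.datasets import study_scenario
        assert study_scenario().residence_time("leaf") == pytest.approx(
            389.4, abs=0.5)


class TestChemistryCoupling:
    def test_product_formation_balances_parent_gas_loss(self):
        """Molar product formation equals parent gas-phase ozonolysis loss
        times yield at steady state."""
        sc = ChamberScenario(
            species_leaf={
                "sesquiterpenes": SpeciesConfig(
                    emission=EmissionSchedule(0.04), k_o3_gas=5.9e-16,
                    products={"acetone": 0.25}),
                "acetone": SpeciesConfig(emission=EmissionSchedule(0.0)),
            },
            species_root={"methanethiol": SpeciesConfig(
                emission=EmissionSchedule(0.01))},
            o3_schedule=[(0.0, 135.0)], fumigation_start=0.0, t_end=7200.0)
        df = simulate_chamber(sc, "leaf")
        k_chem = 5.9e-16 * 135e-9 * 2.46e19
        flush = sc.Q_leaf / sc.V_leaf
        c_parent = df["sesquiterpenes"].iloc[-1]
        c_prod = df["acetone"].iloc[-1]
        # steady state of product: flush*C_prod = yield*k_chem*C_parent
        assert flush * c_prod == pytest.approx(0.25 * k_chem * c_parent, rel=1e-6)

    def test_scavenger_inflow_reaches_flush_limited_level(self):
        sc = single_species_scenario(scavenger_schedule=[(0.0, 1000.0)])
        sc.species_leaf["cyclohexane"] = SpeciesConfig(k_oh=7e-12)
        df = simulate_chamber(sc, "leaf")
        assert df["cyclohexane"].iloc[-1] == pytest.approx(1000.0, rel=1e-6)
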