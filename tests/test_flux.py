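"""Mass-balance outputs: emission rates, ozone budget, carbon flux, windows."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bvocflux.constants import nmol_m3_to_ppbv, ppbv_to_nmol_m3
from bvocflux.flux import (carbon_flux, emission_rate, ozone_budget,
                           per_minute, window_means)


class TestEmissionRate:
    def test_equal_in_out_is_zero(self):
        assert emission_rate(5.0, 5.0, 1e-4, 0.05) == 0.0

    def test_hand_computed_value(self):
        # 2 ppbv at 296 K, 100 kPa = 81.3 nmol m^-3
        dc = ppbv_to_nmol_m3(2.0, 296.0, 1e5)
        assert dc == pytest.approx(81.3, abs=0.1)
        assert emission_rate(dc, 0.0, 5e-5, 0.05) == pytest.approx(0.0813, abs=2e-4)

    def test_uptake_preserved_as_negative(self):
        assert emission_rate(1.0, 2.0, 1e-4, 0.05) < 0

    def test_nonpositive_geometry_rejected(self):
        with pytest.raises(ValueError):
            emission_rate(1.0, 0.0, 0.0, 0.05)

    @given(st.floats(0.01, 100.0))
    def test_unit_conversion_order_invariance(self, ppbv):
        """ppbv -> nmol m^-3 -> E equals E computed in ppbv then converted."""
        Q, A, T, P = 5e-5, 0.05, 296.0, 1e5
        e1 = emission_rate(ppbv_to_nmol_m3(ppbv, T, P), 0.0, Q, A)
        e2 = ppbv_to_nmol_m3(emission_rate(ppbv, 0.0, Q, A), T, P)
        assert e1 == pytest.approx(e2, rel=1e-12)

    def test_per_minute_units(self):
        assert per_minute(1.0) == 60.0


class TestOzoneBudget:
    def test_no_loss_no_uptake(self):
        b = ozone_budget(135.0, 135.0, 0.0, 5e-5, 0.05, 296.0, 1e5)
        assert b.plant_uptake_flux == 0.0
        assert b.deposition_velocity == 0.0

    def test_deposition_velocity_hand_value(self):
        """An uptake flux of 3.4 nmol m^-2 s^-1 referenced to 76 ppbv O3
        gives v_d ~ 0.11 cm s^-1."""
        flux = 3.4
        ref = ppbv_to_nmol_m3(76.0, 296.0, 1e5)  # nmol m^-3
        v_d = flux / ref * 100.0
        assert v_d == pytest.approx(0.11, abs=0.005)

    def test_budget_reproduces_hand_value(self):
        # choose inlet/outlet/wall so plant uptake ppbv maps to 3.4 nmol m-2 s-1
        Q, A, T, P = 4.417e-5, 0.05, 296.0, 1e5
        uptake_ppbv = 3.4 * A / Q / ppbv_to_nmol_m3(1.0, T, P)
        b = ozone_budget(76.0 + 42.0 + uptake_ppbv, 76.0, 42.0, Q, A, T, P)
        assert b.plant_uptake_flux == pytest.approx(3.4, rel=1e-6)
        assert b.deposition_velocity == pytest.approx(0.11, abs=0.005)

    def test_doubling_area_halves_flux_and_vd(self):
        b1 = ozone_budget(140.0, 90.0, 40.0, 5e-5, 0.05, 296.0, 1e5)
        b2 = ozone_budget(140.0, 90.0, 40.0, 5e-5, 0.10, 296.0, 1e5)
        assert b2.plant_uptake_flux == pytest.approx(b1.plant_uptake_flux / 2)
        assert b2.deposition_velocity == pytest.approx(
            b1.deposition_velocity / 2)

    def test_reference_concentration_selectable(self):
        kw = dict(Q=5e-5, A=0.05, T=296.0, P=1e5)
        out = ozone_budget(140.0, 90.0, 40.0, reference="outlet", **kw)
        inl = ozone_budget(140.0, 90.0, 40.0, reference="inlet", **kw)
        assert out.deposition_velocity > inl.deposition_velocity

    def test_outlet_above_inlet_rejected(self):
        with pytest.raises(ValueError):
            ozone_budget(100.0, 110.0, 0.0, 5e-5, 0.05, 296.0, 1e5)


class TestCarbonFlux:
    def test_single_compounds(self, registry):
        assert carbon_flux({"methanol": 1.0}, registry) == 1.0
        assert carbon_flux({"monoterpenes": 0.5}, registry) == 5.0

    def test_linear_and_permutation_invariant(self, registry):
        e = {"methanol": 0.4, "monoterpenes": 0.06, "sesquiterpenes": 0.04}
        total = carbon_flux(e, registry)
        assert total == pytest.approx(0.4 * 1 + 0.06 * 10 + 0.04 * 15)
        rev = dict(reversed(list(e.items())))
        assert carbon_flux(rev, registry) == pytest.approx(total)
        doubled = {k: 2 * v for k, v in e.items()}
        assert carbon_flux(doubled, registry) == pytest.approx(2 * total)

    def test_zero_emissions_zero_carbon(self, registry):
        assert carbon_flux({}, registry) == 0.0

    def test_unknown_compound_named_in_error(self, registry):
        with pytest.raises(KeyError, match="frobnitol"):
            carbon_flux({"frobnitol": 1.0}, registry)


class TestWindowMeans:
    @staticmethod
    def series(values, times, compound="methanol"):
        return pd.DataFrame({"time_s": times, "compound": compound,
                             "emission": values})

    def test_constant_series_pre_equals_post_se_zero(self):
        t = np.arange(0.0, 14400.0, 400.0)
        res = window_means(self.series(np.full(len(t), 2.5), t), 7200.0)
        by = {r.window: r for r in res}
        assert by["pre"].E == by["post"].E == 2.5
        assert by["pre"].se == 0.0

    def test_step_drop_gives_expected_percent_change(self):
        t = np.arange(0.0, 14400.0, 400.0)
        vals = np.where(t < 7200.0, 100.0, 18.0)
        res = window_means(self.series(vals, t), 7200.0)
        by = {r.window: r for r in res}
        change = (by["post"].E - by["pre"].E) / by["pre"].E
        assert change == pytest.approx(-0.82)

    def test_missing_coverage_raises_with_span(self):
        t = np.arange(0.0, 7000.0, 400.0)
        with pytest.raises(ValueError, match="9000"):
            window_means(self.series(np.ones(len(t)), t), 9000.0, width=7200.0)
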