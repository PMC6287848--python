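"""Compound registry: masses, ion channels, loading and validation."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from bvocflux.registry import (MASS_MATCH_TOLERANCE, Compound, IonChannel,
                               Registry, channel_mz, default_registry,
                               load_registry, monoisotopic_mass)


class TestMonoisotopicMass:
    # hand-summed IUPAC most-abundant-isotope masses
    @pytest.mark.parametrize("formula, expected", [
        ("CH4S", 48.0034),        # 12 + 4*1.007825 + 31.972071
        ("H2O", 18.0106),         # 2*1.007825 + 15.994915
        ("C10H16", 136.1252),
        ("C15H24", 204.1878),
    ])
    def test_hand_summed_values(self, formula, expected):
        assert monoisotopic_mass(formula) == pytest.approx(expected, abs=5e-4)

    def test_empty_formula_rejected(self):
        with pytest.raises(ValueError):
            monoisotopic_mass("")

    def test_unknown_element_named_in_error(self):
        with pytest.raises(ValueError, match="Xx"):
            monoisotopic_mass("Xx2O")


class TestChannelMz:
    @pytest.mark.parametrize("formula, mechanism, mode, expected", [
        # printed instrument labels for the two sulfur compounds
        ("CH4S", "protonation", "H3O+", 49.011),
        ("C2H6S", "protonation", "H3O+", 63.026),
    ])
    def test_printed_labels_at_3_decimals(self, formula, mechanism, mode, expected):
        assert channel_mz(formula, mechanism, mode, display=True) == expected

    def test_charge_transfer_equals_monoisotopic_mass(self):
        # exact identity, and within display tolerance of the printed 136.130
        mz = channel_mz("C10H16", "charge_transfer", "NO+")
        assert mz == monoisotopic_mass("C10H16")
        assert mz == pytest.approx(136.130, abs=0.006)

    def test_hydride_abstraction_below_parent(self):
        m = monoisotopic_mass("C5H8O2")
        assert channel_mz("C5H8O2", "hydride_abstraction", "NO+") == pytest.approx(
            m - 1.00783)

    @pytest.mark.parametrize("mechanism, mode", [
        ("protonation", "NO+"),
        ("hydride_abstraction", "H3O+"),
        ("NO_cluster", "H3O+"),
        ("charge_transfer", "H3O+"),
    ])
    def test_mechanism_mode_mismatch_rejected(self, mechanism, mode):
        with pytest.raises(ValueError):
            channel_mz("C3H6O", mechanism, mode)


class TestDefaultRegistry:
    def test_seven_terpenes_with_measured_k_o3(self, registry):
        printed = {
            "limonene": 2.0e-16, "alpha-pinene": 8.4e-17,
            "beta-pinene": 1.5e-17, "gamma-terpinene": 1.4e-16,
            "beta-caryophyllene": 1.2e-16, "isolongifolene": 2.5e-17,
            "alpha-farnesene": 5.9e-16,
        }
        for name, k in printed.items():
            assert registry[name].k_O3 == k
            assert "k_o3_surrogate" not in registry[name].flags

    def test_surrogate_rate_constants_flagged(self, registry):
        assert registry["alpha-thujene"].k_O3 == 8.4e-17
        assert "k_o3_surrogate" in registry["alpha-thujene"].flags
        assert registry["beta-elemene"].k_O3 == 3.15e-15
        assert "k_o3_surrogate" in registry["beta-elemene"].flags

    def test_protonated_mz_matches_printed_labels(self, registry):
        """Computed MH+ agrees with every printed, non-anomalous H3O+ label
        within 0.004 Da (instrument-calibrated labels; exact agreement not
        expected, e.g. C15H24 at 205.198 vs computed 205.195)."""
        checked = 0
        for compound in registry:
            for ch in compound.channels:
                if (ch.mode == "H3O+" and ch.mechanism == "protonation"
                        and ch.observed_mz is not None and not ch.anomalous):
                    computed = compound.mz("protonation", "H3O+")
                    assert abs(computed - ch.observed_mz) <= 0.004, compound.name
                    checked += 1
        assert checked >= 8

    def test_anomalous_labels_are_actually_irreconcilable(self, registry):
        """The flagged peaks (e.g. dimethyl disulfide at 94.991 vs computed
        94.998) really do miss the matching tolerance."""
        flagged = [
            (c, ch) for c in registry for ch in c.channels
            if ch.anomalous and ch.observed_mz is not None
        ]
        assert flagged
        for compound, ch in flagged:
            computed = compound.mz(ch.mechanism, ch.mode)
            assert abs(computed - ch.observed_mz) > MASS_MATCH_TOLERANCE

    def test_every_compound_has_a_channel_and_consistent_carbon(self, registry):
        from bvocflux.registry import formula_carbon_count

        for c in registry:
            assert len(c.channels) >= 1
            assert c.n_carbon == formula_carbon_count(c.formula)


class TestLoadRegistry:
    def test_round_trip_from_yaml_text(self):
        doc = """
compounds:
  - name: acetone
    formula: C3H6O
    n_carbon: 3
    class: ketone
    k_OH: 1.8e-13
    channels:
      - {mode: "H3O+", mechanism: protonation, observed_mz: 59.050}
      - {mode: "NO+", mechanism: NO_cluster}
"""
        reg = load_registry(doc)
        assert reg.names == ["acetone"]
        assert reg["acetone"].mz("protonation", "H3O+", display=True) == 59.049

    def test_carbon_count_mismatch_cites_compound(self):
        doc = {"compounds": [{
            "name": "badmt", "formula": "C10H16", "n_carbon": 9,
            "channels": [{"mode": "H3O+", "mechanism": "protonation"}],
        }]}
        with pytest.raises(ValueError, match="badmt"):
            load_registry(doc)

    def test_empty_document_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            reg = load_registry(None)
        assert len(reg) == 0

    def test_duplicate_names_rejected(self):
        c = Compound("x", "CH4O", 1,
                     channels=[IonChannel("H3O+", "protonation")])
        with pytest.raises(ValueError, match="duplicate"):
            Registry([c, c])


@given(st.sampled_from(["CH4O", "C3H6O", "C10H16", "C2H6S", "C8H8O3"]))
def test_protonation_hydride_gap_is_two_hydrogen_like_masses(formula):
    """MH+ minus [M-H]+ equals the proton plus H-atom mass for any formula."""
    gap = channel_mz(formula, "protonation", "H3O+") - channel_mz(
        formula, "hydride_abstraction", "NO+")
    assert gap == pytest.approx(1.00728 + 1.00783, abs=1e-9)
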