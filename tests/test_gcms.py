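"""GC-MS conventions: retention indices, calibration/LOD, drift, blends."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bvocflux.gcms import (RILadder, blend_composition, calibrate_and_quantify,
                           internal_standard_correct, kovats_ri)

LADDER = RILadder(carbon_numbers=(9, 10, 11, 12),
                  retention_times=(7.0, 10.0, 14.0, 17.5))


class TestKovats:
    def test_exact_at_every_rung(self):
        for n, rt in zip(LADDER.carbon_numbers, LADDER.retention_times):
            assert kovats_ri(rt, LADDER) == pytest.approx(100 * n)

    def test_midpoint_between_c10_and_c11(self):
        assert kovats_ri(12.0, LADDER) == pytest.approx(1050.0)

    def test_hand_computed_interpolation(self):
        # 100*(10 + (12.3-10)/(14-10)) = 1057.5
        assert kovats_ri(12.3, LADDER) == pytest.approx(1057.5)

    def test_no_extrapolation(self):
        with pytest.raises(ValueError):
            kovats_ri(6.0, LADDER)
        with pytest.raises(ValueError):
            kovats_ri(18.0, LADDER)

    @given(st.floats(7.0, 17.5), st.floats(7.0, 17.5))
    def test_strictly_increasing_in_rt(self, a, b):
        if a == b:
            return
        lo, hi = sorted((a, b))
        assert kovats_ri(lo, LADDER) < kovats_ri(hi, LADDER)

    def test_ladder_validation(self):
        with pytest.raises(ValueError):
            RILadder((10, 11), (5.0, 4.0))
        with pytest.raises(ValueError):
            RILadder((10,), (5.0,))


class TestCalibrateAndQuantify:
    LEVELS7 = [(a, 3.0 * a + 5.0) for a in (20, 50, 100, 200, 400, 600, 800)]

    def test_perfect_line_r2_one_and_exact_amount(self):
        res = calibrate_and_quantify(3.0 * 300 + 5.0, self.LEVELS7, blank_sd=1.5)
        assert res.r2 == pytest.approx(1.0)
        assert res.amount == pytest.approx(300.0)
        assert res.flag == "ok"

    def test_lod_loq_multipliers(self):
        # blank_sd expressed through a unit slope: lod = 2*sd, loq = 5*lod
        res = calibrate_and_quantify(10.0, [(0, 0), (10, 10), (20, 20)],
                                     blank_sd=0.5)
        assert res.lod == pytest.approx(1.0)
        assert res.loq == pytest.approx(5.0)

    def test_flags_below_lod_and_loq(self):
        levels = [(0, 0), (10, 10), (20, 20)]
        assert calibrate_and_quantify(0.5, levels, 0.5).flag == "below_lod"
        assert calibrate_and_quantify(3.0, levels, 0.5).flag == "below_loq"
        assert calibrate_and_quantify(8.0, levels, 0.5).flag == "ok"

    def test_noisy_seven_level_recovery_within_5_percent(self):
        rng = np.random.default_rng(3)
        slope_true = 2.5
        levels = [(a, slope_true * a * (1 + 0.03 * rng.standard_normal()))
                  for a in (20, 50, 100, 200, 400, 600, 800)]
        res = calibrate_and_quantify(slope_true * 100, levels, blank_sd=1.0)
        assert res.slope == pytest.approx(slope_true, rel=0.05)
        assert 0.97 <= res.r2 <= 1.0

    def test_zero_slope_rejected(self):
        with pytest.raises(ValueError):
            calibrate_and_quantify(1.0, [(0, 5.0), (10, 5.0)], 0.1)


class TestInternalStandard:
    def test_reference_response_unchanged(self):
        assert internal_standard_correct(42.0, 100.0, 100.0) == 42.0

    def test_halved_is_response_doubles_sample(self):
        assert internal_standard_correct(42.0, 50.0, 100.0) == 84.0

    def test_drift_profile_recovery_within_3_percent(self):
        rng = np.random.default_rng(5)
        true_amounts = np.array([10.0, 20.0, 40.0])
        drift = np.array([1.0, 0.8, 1.25])  # per-run sensitivity factor
        jitter = 1 + 0.01 * rng.standard_normal(3)
        observed = true_amounts * drift * jitter
        is_obs = 100.0 * drift
        corrected = internal_standard_correct(observed, is_obs, 100.0)
        assert np.allclose(corrected, true_amounts, rtol=0.03)

    def test_nonpositive_is_rejected(self):
        with pytest.raises(ValueError):
            internal_standard_correct(1.0, 0.0, 100.0)


class TestBlendComposition:
    def test_single_compound_is_100(self):
        assert blend_composition({"limonene": 3.3}) == {"limonene": 100.0}

    def test_monoterpene_blend_percentages(self):
        # the measured blend: 90/4/4/1/1
        pct = blend_composition({
            "limonene": 90, "alpha-thujene": 4, "alpha-pinene": 4,
            "beta-pinene": 1, "gamma-terpinene": 1,
        })
        assert pct["limonene"] == pytest.approx(90.0)
        assert pct["beta-pinene"] == pytest.approx(1.0)
        assert sum(pct.values()) == pytest.approx(100.0)

    def test_largest_remainder_rounding_sums_to_100(self):
        pct = blend_composition({"a": 1, "b": 1, "c": 1}, round_to_int=True)
        assert sum(pct.values()) == 100

    @given(st.lists(st.floats(0.1, 50.0), min_size=2, max_size=6))
    def test_permutation_invariance_and_sum(self, amounts):
        names = [f"x{i}" for i in range(len(amounts))]
        fwd = blend_composition(dict(zip(names, amounts)))
        rev = blend_composition(dict(zip(reversed(names), reversed(amounts))))
        assert fwd == {k: pytest.approx(rev[k]) for k in fwd}
        assert sum(fwd.values()) == pytest.approx(100.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            blend_composition({"a": 0.0})
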