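import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sdaflux.fluxes import (AcidCostModel, FluxInterval, SpeciationParams,
                            TitrationRecord, acid_cost, cumulative_tan,
                            interval_fluxes, meal_tan_fraction,
                            net_acid_base, net_flux, nh3_speciation,
                            titratable_alkalinity)


def iv(ci, cf, v=0.05, m=4e-4, t=3.0, start=None):
    return FluxInterval("A1", "TAN", ci, cf, v, m, t, start_h=start)


class TestNetFlux:
    def test_no_change_is_zero(self):
        assert net_flux(iv(50.0, 50.0)) == 0.0

    def test_hand_example(self):
        # 0→50 µmol/l in 50 ml over 3 h, 0.4 g fish
        assert net_flux(iv(0.0, 50.0)) == pytest.approx(2083.333333, rel=1e-6)

    def test_linearity_in_volume(self):
        assert net_flux(iv(0.0, 50.0, v=0.10)) == pytest.approx(
            2.0 * net_flux(iv(0.0, 50.0, v=0.05)))

    def test_zero_duration_rejected(self):
        with pytest.raises(ValueError, match="duration"):
            net_flux(iv(0.0, 50.0, t=0.0))

    @given(dc=st.floats(-500.0, 500.0), v=st.floats(0.01, 1.0),
           m=st.floats(1e-4, 1e-2), t=st.floats(0.5, 24.0),
           k=st.floats(0.1, 5.0))
    @settings(max_examples=50, deadline=None)
    def test_scaling_properties(self, dc, v, m, t, k):
        j = net_flux(iv(10.0, 10.0 + dc, v=v, m=m, t=t))
        assert net_flux(iv(10.0, 10.0 + k * dc, v=v, m=m, t=t)) == \
            pytest.approx(k * j, rel=1e-9, abs=1e-12)
        assert net_flux(iv(10.0, 10.0 + dc, v=v, m=k * m, t=t)) == \
            pytest.approx(j / k, rel=1e-9, abs=1e-12)
        assert net_flux(iv(10.0, 10.0 + dc, v=v, m=m, t=k * t)) == \
            pytest.approx(j / k, rel=1e-9, abs=1e-12)


class TestTitratableAlkalinity:
    def test_hand_examples(self):
        rec = TitrationRecord(0.010, 0.01, 0.250e-3)
        assert titratable_alkalinity(rec) == pytest.approx(250.0)
        rec = TitrationRecord(0.010, 0.01, 1e-3)
        assert titratable_alkalinity(rec) == pytest.approx(1000.0)

    def test_zero_titrant(self):
        assert titratable_alkalinity(TitrationRecord(0.010, 0.01, 0.0)) == 0.0

    def test_negative_titrant_rejected(self):
        with pytest.raises(ValueError):
            TitrationRecord(0.010, 0.01, -1e-3)

    def test_two_stage_volumes_sum(self):
        rec = TitrationRecord.from_stages(0.010, 0.01, [0.2e-3, 0.05e-3])
        assert titratable_alkalinity(rec) == pytest.approx(250.0)


class TestNetAcidBase:
    def test_balance_and_sign(self):
        assert net_acid_base(100.0, 100.0) == 0.0
        assert net_acid_base(100.0, 300.0) == -200.0  # net base uptake
        assert net_acid_base(300.0, 100.0) == -net_acid_base(100.0, 300.0)


class TestCumulativeTAN:
    def _intervals(self, fluxes, dur=3.0, m=4e-4):
        out, t = [], 0.0
        for j in fluxes:
            # concentrations that reproduce flux j in a 0.05 l chamber
            dc = j * m * dur / 0.05
            out.append(iv(0.0, dc, m=m, t=dur, start=t))
            t += dur
        return out

    def test_baseline_only_is_zero(self):
        ivs = self._intervals([100.0] * 4)
        assert cumulative_tan(ivs, baseline=100.0) == pytest.approx(0.0)

    def test_hand_sum(self):
        ivs = self._intervals([300.0, 200.0, 150.0, 100.0])
        assert cumulative_tan(ivs, baseline=100.0) == pytest.approx(0.42)

    def test_sub_baseline_clamps(self):
        ivs = self._intervals([50.0, 300.0])
        expected = (300.0 - 100.0) * 4e-4 * 3.0
        assert cumulative_tan(ivs, baseline=100.0) == pytest.approx(expected)

    def test_overlap_rejected(self):
        ivs = [iv(0.0, 10.0, start=0.0), iv(0.0, 10.0, start=1.0)]
        with pytest.raises(ValueError, match="overlap"):
            cumulative_tan(ivs, baseline=0.0)

    def test_matches_fine_grid_mass_balance(self):
        # brute-force Riemann summation of the piecewise-constant series
        fluxes = [320.0, 180.0, 140.0, 90.0]
        base, m, dur = 120.0, 4e-4, 3.0
        ivs = self._intervals(fluxes, dur=dur, m=m)
        grid = np.linspace(0.0, dur * len(fluxes), 48001)[:-1]
        jt = np.repeat(fluxes, len(grid) // len(fluxes))
        brute = np.sum(np.maximum(jt - base, 0.0) * m) * (grid[1] - grid[0])
        assert cumulative_tan(ivs, baseline=base) == pytest.approx(
            brute, rel=1e-9)


class TestMealTanFraction:
    def test_examples(self):
        assert meal_tan_fraction(0.0, 0.077).percent == 0.0
        assert meal_tan_fraction(0.0385, 0.077).percent == pytest.approx(50.0)
        full = meal_tan_fraction(0.077, 0.077)
        assert full.percent == pytest.approx(100.0)
        assert not full.exceeds_meal

    def test_catabolic_excess_flagged(self):
        res = meal_tan_fraction(0.154, 0.077)
        assert res.percent == pytest.approx(200.0)
        assert res.exceeds_meal

    def test_zero_meal_rejected(self):
        with pytest.raises(ValueError):
            meal_tan_fraction(0.01, 0.0)


class TestSpeciation:
    params = SpeciationParams(pK_prime=9.5, alpha_nh3=8.1e4)

    def test_half_dissociation_at_pk(self):
        res = nh3_speciation(1000.0, 9.5, self.params)
        assert res.nh3 == pytest.approx(500.0)

    def test_closed_form(self):
        res = nh3_speciation(1000.0, 7.0, self.params)
        assert res.nh3 == pytest.approx(1000.0 / (1 + 10**2.5), rel=1e-9)
        assert res.nh3 == pytest.approx(3.152, abs=5e-4)
        assert res.p_nh3 == pytest.approx(res.nh3 / 8.1e4, rel=1e-12)

    def test_zero_tan(self):
        assert nh3_speciation(0.0, 7.5, self.params) == (0.0, 0.0)

    @given(tan=st.floats(0.0, 5000.0), ph=st.floats(5.0, 10.5),
           dph=st.floats(0.01, 2.0))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_ph_and_bounded_by_tan(self, tan, ph, dph):
        lo = nh3_speciation(tan, ph, self.params).nh3
        hi = nh3_speciation(tan, ph + dph, self.params).nh3
        assert lo <= tan and hi <= tan
        if tan > 1e-6:
            assert hi > lo


class TestAcidCost:
    def test_backleak_ratio_reproduces_printed_cost(self):
        model = AcidCostModel(h_o2_ratio=2.3, acid_load=0.564 * 5.0)
        done = acid_cost(model, sda_magnitude=21.47)
        assert done.o2_cost == pytest.approx(1.226, abs=5e-4)

    def test_share_of_sda(self):
        done = acid_cost(AcidCostModel(h_o2_ratio=5.0, acid_load=2.82),
                         sda_magnitude=21.47)
        assert done.o2_cost == pytest.approx(0.564)
        assert done.sda_share == pytest.approx(2.6, abs=0.05)

    def test_zero_delta_ph(self):
        model = AcidCostModel(h_o2_ratio=5.0, delta_ph=0.0,
                              buffer_capacity=30.0, ration=0.05)
        done = acid_cost(model, sda_magnitude=21.47)
        assert done.o2_cost == 0.0
        assert done.sda_share == 0.0

    def test_stoichiometric_consistency(self):
        load = 2.82
        costs = [acid_cost(AcidCostModel(h_o2_ratio=r, acid_load=load),
                           21.47).o2_cost for r in (5.0, 2.3, 1.7)]
        for r, c in zip((5.0, 2.3, 1.7), costs):
            assert c * r == pytest.approx(load, rel=1e-12)

    def test_invalid_ratio(self):
        with pytest.raises(ValueError):
            acid_cost(AcidCostModel(h_o2_ratio=0.0, acid_load=1.0), 21.47)


def test_interval_fluxes_table():
    import pandas as pd
    samples = pd.DataFrame({"time_h": [0.0, 3.0, 6.0],
                            "tan_umol_l": [0.0, 50.0, 80.0],
                            "talk_ueq_l": [1000.0, 940.0, 910.0]})
    tab = interval_fluxes(samples, volume_l=0.05, mass_kg=4e-4)
    assert len(tab) == 2
    assert tab["j_tamm"].iloc[0] == pytest.approx(2083.333333, rel=1e-6)
    assert tab["j_talk"].iloc[0] == pytest.approx(-2500.0)
    assert tab["net_acid_base"].iloc[0] == pytest.approx(
        tab["j_talk"].iloc[0] - tab["j_tamm"].iloc[0])
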