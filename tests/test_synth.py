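from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from sdaflux.growth import growth_table
from sdaflux.fluxes import cumulative_tan, FluxInterval, interval_fluxes
from sdaflux.qpcr import ddct
from sdaflux.study import analyze_trace
from sdaflux.synth import (SimConfig, bump_area, bump_profile,
                           bump_return_time, simulate_ct_table,
                           simulate_flux_series, simulate_growth,
                           simulate_resp_group, simulate_resp_trace)

NOISE_FREE = dict(cycle_noise_sd=0.0, smr_sd=0.0, sda_peak_sd=0.0,
                  sda_duration_sd=0.0, mass_sd_g=0.0)


class TestBumpShape:
    def test_profile_bounds_and_support(self):
        x = np.linspace(-0.5, 1.5, 401)
        p = bump_profile(x)
        assert p.min() >= 0.0
        assert p.max() == pytest.approx(1.0, rel=1e-6)
        assert np.all(p[x < 0] == 0.0) and np.all(p[x > 1] == 0.0)

    def test_area_scales_with_peak_and_duration(self):
        a = bump_area(3.0, 15.0)
        assert bump_area(6.0, 15.0) == pytest.approx(2 * a, rel=1e-9)
        assert bump_area(3.0, 30.0) == pytest.approx(2 * a, rel=1e-9)

    def test_return_time_is_threshold_crossing(self):
        t = bump_return_time(3.0, 15.0, smr=5.3, return_fraction=0.10)
        level = float(bump_profile(t / 15.0)) * 3.0
        assert level == pytest.approx(0.10 * 5.3, rel=1e-9)
        assert 0 < t < 15.0


class TestRespirometrySim:
    def test_seed_determinism(self):
        cfg = SimConfig(seed=7, cycle_noise_sd=0.25,
                        activity_spike_rate=0.2)
        t1, u1 = simulate_resp_trace(cfg)
        t2, u2 = simulate_resp_trace(cfg)
        pd.testing.assert_frame_equal(t1.samples, t2.samples)
        assert u1["smr"] == u2["smr"]

    def test_noise_free_pipeline_inverts_generator(self):
        cfg = SimConfig(seed=3, **NOISE_FREE)
        trace, truth = simulate_resp_trace(cfg)
        series, smr, sda = analyze_trace(trace)
        mo2 = series.cycles["mo2"].to_numpy()
        assert np.allclose(mo2, truth["mo2_midpoints"], rtol=1e-8)
        assert series.cycles["qc_pass"].all()
        assert smr == pytest.approx(truth["smr"], rel=1e-9)
        # grid-limited agreement for the derived SDA metrics
        assert sda.duration == pytest.approx(truth["duration"],
                                             abs=cfg.cycle_period_h)
        assert sda.magnitude == pytest.approx(truth["magnitude"], rel=0.05)
        assert sda.net_peak == pytest.approx(truth["peak"], rel=0.01)

    def test_regurgitation_forces_exclusion(self):
        cfg = SimConfig(seed=5, n_per_group=3, regurgitation_prob=1.0)
        traces, truths = simulate_resp_group(cfg)
        for trace in traces:
            _, _, sda = analyze_trace(trace)
            assert sda.excluded
            assert sda.exclusion_reason == "regurgitation"

    def test_activity_spikes_fail_qc(self):
        cfg = SimConfig(seed=5, activity_spike_rate=2.0)
        trace, _ = simulate_resp_trace(cfg)
        series, _, sda = analyze_trace(trace)
        assert (~series.cycles["qc_pass"]).any()

    def test_group_effects_applied(self):
        cfg = SimConfig(seed=2, n_per_group=2, **NOISE_FREE)
        _, truths = simulate_resp_group(cfg)
        wt = [u for u in truths if u["genotype"] == "wt"][0]
        ko = [u for u in truths if u["genotype"] == "ko"][0]
        assert ko["duration_drawn"] == pytest.approx(
            wt["duration_drawn"] * (1 + cfg.duration_effect))
        assert ko["magnitude"] == pytest.approx(
            wt["magnitude"] * (1 + cfg.magnitude_effect), rel=1e-6)


class TestFluxSim:
    def test_noise_free_round_trip(self):
        cfg = SimConfig(seed=4)
        samples, truth = simulate_flux_series(cfg)
        tab = interval_fluxes(samples, truth["volume_l"], truth["mass_kg"])
        assert np.allclose(tab["j_tamm"], truth["j_tamm"], rtol=1e-9)
        assert np.allclose(tab["j_talk"], truth["j_talk"], rtol=1e-9)

    def test_cumulative_tan_matches_analytic_integral(self):
        cfg = SimConfig(seed=4)
        samples, truth = simulate_flux_series(cfg)
        t = samples["time_h"].to_numpy()
        ivs = [FluxInterval("A1", "TAN",
                            samples["tan_umol_l"].iloc[k],
                            samples["tan_umol_l"].iloc[k + 1],
                            truth["volume_l"], truth["mass_kg"],
                            t[k + 1] - t[k], start_h=t[k])
               for k in range(len(t) - 1)]
        base = truth["baseline_tamm"]
        analytic = sum(max(j - base, 0.0) * truth["mass_kg"] * dt
                       for j, dt in zip(truth["j_tamm"], np.diff(t)))
        assert cumulative_tan(ivs, baseline=base) == pytest.approx(
            analytic, rel=1e-9)

    def test_seed_determinism(self):
        cfg = SimConfig(seed=9, flux_conc_noise_sd=2.0)
        s1, _ = simulate_flux_series(cfg)
        s2, _ = simulate_flux_series(cfg)
        pd.testing.assert_frame_equal(s1, s2)


class TestGrowthSim:
    def test_noise_free_recovers_weekly_rates(self):
        cfg = SimConfig(seed=6, n_per_group=3)
        records, truth = simulate_growth(cfg)
        tab = growth_table(records)
        weekly = tab.groupby("week")["sgr_pct_per_day"].mean()
        for w, g in truth["weekly_g_pct_per_day"].items():
            assert weekly.loc[w] == pytest.approx(g, rel=1e-9)

    def test_drug_window_depression(self):
        cfg = SimConfig(seed=6, n_per_group=2)
        records, truth = simulate_growth(cfg)
        tab = growth_table(records)
        weekly = tab.groupby("week")["sgr_pct_per_day"].mean()
        for w in truth["depressed_weeks"]:
            assert weekly.loc[w] == pytest.approx(
                cfg.base_sgr_pct_per_day *
                (1 - cfg.drug_depression_fraction), rel=1e-9)

    def test_zero_depression_flat_rates(self):
        cfg = SimConfig(seed=6, n_per_group=2, drug_depression_fraction=0.0)
        records, _ = simulate_growth(cfg)
        tab = growth_table(records)
        assert np.allclose(tab["sgr_pct_per_day"],
                           cfg.base_sgr_pct_per_day, rtol=1e-9)

    def test_period_labels(self):
        records, _ = simulate_growth(SimConfig(seed=1, n_per_group=1))
        labels = records[records["animal_id"] == "wt01"].sort_values(
            "week")["period"].tolist()
        assert labels == ["start"] + ["control"] * 3 + \
            ["omeprazole"] * 2 + ["recovery"] * 3


class TestQpcrSim:
    def test_zero_effect_mean_fold_one(self):
        cfg = SimConfig(seed=8, n_per_group=4,
                        target_log2_effect={"cck": 0.0},
                        qpcr_loading_sd=0.0)
        table, _ = simulate_ct_table(cfg)
        res = ddct(table, "cck", "wt")
        assert np.allclose(res["fold"], 1.0)

    def test_noise_free_recovers_fold_exactly(self):
        cfg = SimConfig(seed=8, n_per_group=4)
        table, truth = simulate_ct_table(cfg)
        res = ddct(table, "cck", "wt")
        ko = res.loc[res["group"] == "ko", "fold"]
        assert np.allclose(ko, truth["cck"], rtol=1e-9)

    def test_noisy_recovery_at_scale(self):
        cfg = SimConfig(seed=8, n_per_group=50, ct_noise_sd=0.2)
        table, truth = simulate_ct_table(cfg)
        res = ddct(table, "cck", "wt")
        ko_log = np.log2(res.loc[res["group"] == "ko", "fold"])
        assert 2.0 ** ko_log.mean() == pytest.approx(truth["cck"], rel=0.1)

    def test_seed_determinism(self):
        cfg = SimConfig(seed=8, ct_noise_sd=0.2)
        t1, _ = simulate_ct_table(cfg)
        t2, _ = simulate_ct_table(cfg)
        pd.testing.assert_frame_equal(t1, t2)
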