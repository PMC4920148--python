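"""Normalization formulas, Z'-factor QC and viability-gated hit calling."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from htsrepurpose import (
    HitCallingConfig,
    call_hits,
    compute_effect,
    compute_viability,
    compute_well_metrics,
    normalize_activity,
    qc_screen,
    simulate_screen,
    zprime,
)
from htsrepurpose.errors import ConfigError, PlateError
from htsrepurpose.plate import ScreenDataset
from htsrepurpose.screen import RUN_KEYS

from conftest import manual_dataset, small_layout


class TestFormulas:
    @pytest.mark.parametrize("fluo,mean,expected", [
        (1000.0, 1000.0, 100.0),   # at the vehicle mean
        (0.0, 1000.0, 0.0),        # dead well
        (750.0, 1000.0, 75.0),
        (1300.0, 1000.0, 130.0),   # above 100 is preserved, not clamped
    ])
    def test_viability(self, fluo, mean, expected):
        assert compute_viability(fluo, mean) == pytest.approx(expected, abs=1e-12)

    def test_viability_requires_positive_vehicle_mean(self):
        with pytest.raises(PlateError):
            compute_viability(100.0, 0.0)

    @pytest.mark.parametrize("lum,fluo,expected", [
        (1000.0, 1000.0, 1.0),
        (0.0, 1000.0, 0.0),
        (5000.0, 1000.0, 5.0),
    ])
    def test_normalized_activity(self, lum, fluo, expected):
        assert normalize_activity(lum, fluo) == pytest.approx(expected, abs=1e-12)

    def test_normalized_activity_invalid_for_zero_fluo(self):
        assert math.isnan(normalize_activity(100.0, 0.0))

    @pytest.mark.parametrize("nx,mean,expected", [
        (1.25, 1.25, 100.0),
        (0.0, 1.25, 0.0),
        (0.5, 1.25, 40.0),
    ])
    def test_effect(self, nx, mean, expected):
        assert compute_effect(nx, mean) == pytest.approx(expected, abs=1e-12)


class TestZPrime:
    @pytest.mark.parametrize("mu_s,sd_s,mu_c,sd_c,expected", [
        (200.0, 0.0, 100.0, 0.0, 1.0),      # noiseless limit
        (200.0, 5.0, 100.0, 5.0, 0.7),      # 1 - 30/100
        (240.0, 12.0, 100.0, 5.0, 1 - 3 * 17 / 140),
    ])
    def test_hand_values(self, mu_s, sd_s, mu_c, sd_c, expected):
        assert zprime(mu_s, sd_s, mu_c, sd_c) == pytest.approx(expected, abs=1e-12)

    def test_equal_means_yield_nan_sentinel(self):
        assert math.isnan(zprime(100.0, 1.0, 100.0, 1.0))

    def test_matches_direct_formula_on_random_tuples(self, rng):
        for _ in range(1000):
            mu_s, mu_c = rng.uniform(-500, 500, 2)
            sd_s, sd_c = rng.uniform(0, 50, 2)
            if mu_s == mu_c:
                continue
            expected = 1.0 - 3.0 * (sd_s + sd_c) / abs(mu_s - mu_c)
            assert zprime(mu_s, sd_s, mu_c, sd_c) == pytest.approx(expected, abs=1e-12)

    @settings(derandomize=True, max_examples=200)
    @given(mu_s=st.floats(-1e4, 1e4), mu_c=st.floats(-1e4, 1e4),
           sd_s=st.floats(0, 1e3), sd_c=st.floats(0, 1e3))
    def test_never_exceeds_one(self, mu_s, mu_c, sd_s, sd_c):
        z = zprime(mu_s, sd_s, mu_c, sd_c)
        assert math.isnan(z) or z <= 1.0

    def test_strictly_decreasing_in_either_sd(self, rng):
        for _ in range(50):
            mu_s, mu_c = 200.0, 100.0
            sd_s, sd_c = rng.uniform(0, 20, 2)
            bump = rng.uniform(0.1, 5)
            base = zprime(mu_s, sd_s, mu_c, sd_c)
            assert zprime(mu_s, sd_s + bump, mu_c, sd_c) < base
            assert zprime(mu_s, sd_s, mu_c, sd_c + bump) < base

    def test_scale_invariant_so_E_and_N_scales_agree(self, rng):
        # controls contribute on the E scale; the N scale gives the same Z'
        for _ in range(20):
            mu_s, sd_s = rng.uniform(50, 400), rng.uniform(0.1, 30)
            mu_c, sd_c = rng.uniform(50, 400), rng.uniform(0.1, 30)
            if mu_s == mu_c:
                continue
            k = rng.uniform(0.01, 100)
            assert zprime(k * mu_s, k * sd_s, k * mu_c, k * sd_c) == \
                pytest.approx(zprime(mu_s, sd_s, mu_c, sd_c), rel=1e-12)


class TestWellMetrics:
    def test_vehicle_anchor_exact_on_noisy_screen(self, paperlike_screen):
        # mean vehicle E and Vi are 100 per run, an exact consequence of the
        # normalization formulas, regardless of noise
        ds, _ = paperlike_screen
        m = compute_well_metrics(ds)
        veh = m[m["role"] == "vehicle"].groupby(RUN_KEYS)[["E", "Vi"]].mean()
        np.testing.assert_allclose(veh["E"], 100.0, rtol=1e-12)
        np.testing.assert_allclose(veh["Vi"], 100.0, rtol=1e-12)

    def test_plate_lum_rescaling_leaves_E_unchanged(self, paperlike_screen):
        ds, _ = paperlike_screen
        base = compute_well_metrics(ds)
        scaled = ds.wells.copy()
        rng = np.random.default_rng(3)
        for pid, k in zip(scaled["plate_id"].unique(),
                          rng.uniform(0.2, 5.0, scaled["plate_id"].nunique())):
            scaled.loc[scaled["plate_id"] == pid, "lum"] *= k
        ds2 = ScreenDataset(ds.layouts, scaled)
        m2 = compute_well_metrics(ds2)
        np.testing.assert_allclose(m2["E"], base["E"], rtol=1e-9)

    def test_plate_fluo_rescaling_leaves_Vi_unchanged(self, paperlike_screen):
        ds, _ = paperlike_screen
        base = compute_well_metrics(ds)
        scaled = ds.wells.copy()
        scaled["fluo"] *= 3.7
        scaled["lum"] = scaled["lum"]  # lum untouched
        m2 = compute_well_metrics(ScreenDataset(ds.layouts, scaled))
        np.testing.assert_allclose(m2["Vi"], base["Vi"], rtol=1e-9)

    def test_run_without_vehicle_wells_raises(self):
        ds = manual_dataset({})
        wells = ds.wells[ds.wells["role"] != "vehicle"].reset_index(drop=True)
        with pytest.raises(PlateError, match="vehicle"):
            compute_well_metrics(ScreenDataset(ds.layouts, wells))

    def test_vi_over_100_flagged(self):
        ds = manual_dataset({}, vi={("P1-C1", 20.0, 1): 130.0})
        m = compute_well_metrics(ds)
        flagged = m[m["vi_over_100"]]
        assert set(flagged["compound_id"]) == {"P1-C1"}


class TestPlateQC:
    def test_exact_controls_give_zprime_one_and_pass(self):
        # all control wells sit exactly on their class means -> sd = 0
        qc = qc_screen(compute_well_metrics(manual_dataset({})))
        assert qc.loc[0, "zprime_positive"] == pytest.approx(1.0)
        assert qc.loc[0, "zprime_negative"] == pytest.approx(1.0)
        assert bool(qc.loc[0, "pass"])

    def test_degenerate_controls_fail_without_raising(self):
        ds = manual_dataset({}, control_effects={"positive_control": 100.0,
                                                 "negative_control": 40.0})
        qc = qc_screen(compute_well_metrics(ds))
        assert qc.loc[0, "zprime_positive_status"] == "degenerate"
        assert not bool(qc.loc[0, "pass"])

    def test_missing_negative_pair_uses_positive_only(self):
        # mirrors a first plate screened before an inhibitor control existed
        ds = manual_dataset({})
        wells = ds.wells[ds.wells["role"] != "negative_control"].reset_index(drop=True)
        lay = ds.layouts["P1"]
        qc = qc_screen(compute_well_metrics(ScreenDataset({"P1": lay}, wells)))
        assert qc.loc[0, "zprime_negative_status"] == "absent"
        assert math.isnan(qc.loc[0, "zprime_negative"])
        assert bool(qc.loc[0, "pass"])

    def test_borderline_separation_fails_threshold(self):
        # mean separation 100 with both sd 10: Z' = 1 - 60/100 = 0.4 < 0.5
        assert zprime(200.0, 10.0, 100.0, 10.0) == pytest.approx(0.4)


class TestHitCalling:
    def test_boundary_is_inclusive(self):
        # E exactly at the 0.4-fold threshold in both replicates
        ds = manual_dataset({("P1-C1", 20.0, r): 40.0 for r in (1, 2)},
                            replicates=(1, 2))
        calls = call_hits(ds).calls.set_index("compound_id")
        assert calls.loc["P1-C1", "direction"] == "inhibitor"
        assert calls.loc["P1-C2", "direction"] == "none"

    def test_viability_gate_blocks_toxic_inhibitor(self):
        ds = manual_dataset({("P1-C1", 20.0, 1): 40.0},
                            vi={("P1-C1", 20.0, 1): 30.0})
        calls = call_hits(ds).calls.set_index("compound_id")
        assert calls.loc["P1-C1", "direction"] == "none"

    def test_replicate_rule_all_vs_any(self):
        effects = {("P1-C1", 20.0, 1): 250.0, ("P1-C1", 20.0, 2): 100.0}
        ds = manual_dataset(effects, replicates=(1, 2))
        strict = call_hits(ds, HitCallingConfig(replicate_rule="all"))
        loose = call_hits(ds, HitCallingConfig(replicate_rule="any"))
        assert strict.calls.set_index("compound_id").loc["P1-C1", "direction"] == "none"
        assert loose.calls.set_index("compound_id").loc["P1-C1", "direction"] == "activator"

    def test_hit_at_one_concentration_is_enough(self):
        effects = {("P1-C1", 20.0, 1): 30.0, ("P1-C1", 2.0, 1): 80.0}
        ds = manual_dataset(effects, concentrations=(20.0, 2.0))
        calls = call_hits(ds).calls.set_index("compound_id")
        assert calls.loc["P1-C1", "direction"] == "inhibitor"

    def test_conflicting_directions_across_concentrations(self):
        effects = {("P1-C1", 20.0, 1): 30.0, ("P1-C1", 2.0, 1): 260.0}
        ds = manual_dataset(effects, concentrations=(20.0, 2.0))
        calls = call_hits(ds).calls.set_index("compound_id")
        assert calls.loc["P1-C1", "direction"] == "none"
        assert bool(calls.loc["P1-C1", "conflict"])

    def test_no_data_flag_for_compound_without_valid_wells(self):
        ds = manual_dataset({}, vi={("P1-C1", 20.0, 1): 0.0})  # dead well
        calls = call_hits(ds).calls.set_index("compound_id")
        assert calls.loc["P1-C1", "direction"] == "none"
        assert bool(calls.loc["P1-C1", "no_data"])

    def test_qc_failing_plate_contributes_nothing(self):
        ds = manual_dataset({("P1-C1", 20.0, 1): 30.0},
                            control_effects={"positive_control": 100.0,
                                             "negative_control": 40.0})
        calls = call_hits(ds).calls.set_index("compound_id")
        assert calls.loc["P1-C1", "direction"] == "none"

    def test_config_threshold_ordering_enforced(self):
        with pytest.raises(ConfigError):
            HitCallingConfig(low_threshold=120.0)
        with pytest.raises(ConfigError):
            HitCallingConfig(replicate_rule="majority")


class TestNoiselessRecovery:
    def test_hits_match_injected_truth_and_brute_force_oracle(self, noiseless_config):
        ds, truth = simulate_screen(noiseless_config, seed=11)
        table = call_hits(ds)
        called = table.calls.set_index("compound_id")["direction"]
        inh = set(called[called == "inhibitor"].index)
        act = set(called[called == "activator"].index)
        assert inh == set(truth.inhibitor_ids)
        assert act == set(truth.activator_ids)

        # independent oracle: re-apply the thresholds per well by hand
        cfg = table.config
        m = compute_well_metrics(ds)
        obs = m[(m["role"] == "compound") & m["valid"]]
        oracle_inh, oracle_act = set(), set()
        for (cid, _conc), grp in obs.groupby(["compound_id", "concentration_uM"]):
            ok_vi = (grp["Vi"] >= cfg.viability_min).all()
            if ok_vi and (grp["E"] <= cfg.low_threshold).all():
                oracle_inh.add(cid)
            if ok_vi and (grp["E"] >= cfg.high_threshold).all():
                oracle_act.add(cid)
        assert inh == oracle_inh
        assert act == oracle_act
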