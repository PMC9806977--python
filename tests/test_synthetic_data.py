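import dataclasses

import numpy as np
import pandas as pd
import pandas.testing as pdt
import pytest

from trialcea import (
    ConfigurationError,
    TrialConfig,
    apply_missingness,
    generate_trial,
    ground_truth,
)
from trialcea.synthetic_data import (
    GroundTruth,
    default_cost_distributions,
    read_bundle,
    write_bundle,
)


def zero_effect_config(n=30, seed=0):
    return TrialConfig(
        n_per_arm=n,
        phq_time_effect={"ST": {3: 0.0, 12: 0.0}, "T+P": {3: 0.0, 12: 0.0}},
        whodas_item_means={
            "ST": {0: 2.0, 3: 2.0, 12: 2.0},
            "T+P": {0: 2.0, 3: 2.0, 12: 2.0},
        },
        seed=seed,
    )


class TestGenerateTrial:
    def test_counts_by_construction(self):
        data = generate_trial(TrialConfig(n_per_arm=60, seed=1))
        assert len(data.roster) == 120
        assert (data.roster["arm"].value_counts() == 60).all()

    def test_item_vectors_complete_before_missingness(self, small_trial, small_config):
        n = 2 * small_config.n_per_arm
        assert len(small_trial.phq) == n * 3 * 9
        assert len(small_trial.whodas) == n * 3 * 12
        per_pt = small_trial.phq.groupby(["participant_id", "timepoint_months"]).size()
        assert (per_pt == 9).all()

    def test_item_ranges(self, small_trial):
        assert small_trial.phq["value"].between(0, 3).all()
        assert small_trial.whodas["value"].between(0, 4).all()

    def test_costs_nonnegative(self, small_trial):
        assert (small_trial.service_use["quantity"] >= 0).all()

    def test_determinism_same_seed(self, small_config):
        a = generate_trial(small_config)
        b = generate_trial(small_config)
        for attr in ("roster", "phq", "whodas", "service_use", "unit_costs"):
            pdt.assert_frame_equal(getattr(a, attr), getattr(b, attr))

    def test_different_seed_differs(self, small_config):
        a = generate_trial(small_config)
        b = generate_trial(dataclasses.replace(small_config, seed=small_config.seed + 1))
        assert not a.phq["value"].equals(b.phq["value"])

    def test_zero_arm_effect_mc(self):
        # arm difference in mean 12-month PHQ should be 0 within MC error
        diffs = []
        for seed in range(200):
            data = generate_trial(zero_effect_config(n=30, seed=seed))
            m12 = data.phq[data.phq["timepoint_months"] == 12]
            totals = m12.groupby("participant_id")["value"].sum()
            arm = data.roster.set_index("participant_id")["arm"]
            by_arm = totals.groupby(arm).mean()
            diffs.append(by_arm["T+P"] - by_arm["ST"])
        diffs = np.asarray(diffs)
        se = diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert abs(diffs.mean()) < 3 * se + 1e-12

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            TrialConfig(n_per_arm=0)
        with pytest.raises(ConfigurationError):
            TrialConfig(dropout_prob={"ST": 1.5, "T+P": 0.2})
        with pytest.raises(ConfigurationError):
            TrialConfig(baseline_phq_mean=40.0)
        with pytest.raises(ConfigurationError):
            TrialConfig(baseline_phq_sd=0.1)  # below the binomial noise floor

    def test_config_yaml_roundtrip(self, tmp_path, small_config):
        path = tmp_path / "cfg.yaml"
        small_config.to_yaml(path)
        loaded = TrialConfig.from_yaml(path)
        pdt.assert_frame_equal(generate_trial(loaded).phq, generate_trial(small_config).phq)


class TestApplyMissingness:
    def test_zero_dropout_no_missing(self, small_config, small_trial):
        cfg = dataclasses.replace(small_config, dropout_prob={"ST": 0.0, "T+P": 0.0})
        out = apply_missingness(small_trial, cfg)
        assert out.roster["dropout_time"].isna().all()
        assert len(out.phq) == len(small_trial.phq)

    def test_full_dropout_baseline_intact(self, small_config, small_trial):
        cfg = dataclasses.replace(small_config, dropout_prob={"ST": 1.0, "T+P": 1.0})
        out = apply_missingness(small_trial, cfg)
        assert out.roster["dropout_time"].notna().all()
        cutoff = out.roster.set_index("participant_id")["dropout_time"]
        limits = cutoff.reindex(out.phq["participant_id"]).to_numpy()
        assert (out.phq["timepoint_months"].to_numpy() < limits).all()
        # baseline visit never removed
        base = out.phq[out.phq["timepoint_months"] == 0]
        assert base["participant_id"].nunique() == len(out.roster)
        # with all dropout at the first follow-up, no follow-up data remain
        cfg_early = dataclasses.replace(cfg, dropout_early_fraction=1.0)
        out_early = apply_missingness(small_trial, cfg_early)
        assert (out_early.phq["timepoint_months"] == 0).all()
        assert (out_early.whodas["timepoint_months"] == 0).all()
        assert len(out_early.service_use) == 0

    def test_monotone_dropout(self, small_config, small_trial):
        out = apply_missingness(small_trial, small_config)
        present = out.phq.groupby("participant_id")["timepoint_months"].apply(set)
        for pid, times in present.items():
            if 3 not in times:
                assert 12 not in times  # no intermittent return

    def test_dropout_depends_only_on_observed(self, small_config, small_trial):
        # MAR by construction: same data, same seed -> same dropout pattern
        a = apply_missingness(small_trial, small_config)
        b = apply_missingness(small_trial, small_config)
        pdt.assert_frame_equal(a.roster, b.roster)

    def test_realized_dropout_mc(self):
        rates = {"ST": [], "T+P": []}
        for seed in range(500):
            cfg = TrialConfig(n_per_arm=30, seed=seed)
            data = apply_missingness(generate_trial(cfg), cfg)
            frac = data.roster.groupby("arm")["dropout_time"].apply(lambda s: s.notna().mean())
            for arm in rates:
                rates[arm].append(frac[arm])
        assert abs(np.mean(rates["ST"]) - 0.15) < 0.02
        assert abs(np.mean(rates["T+P"]) - 0.23) < 0.02


class TestGroundTruth:
    def test_zero_effects_zero_deltas(self):
        gt = ground_truth(zero_effect_config())
        assert gt.true_delta_phq == 0
        assert gt.true_delta_qaly == pytest.approx(0)
        # identical delivery by default still leaves the implementation gap
        cfg = dataclasses.replace(
            zero_effect_config(),
            implementation_cost_per_user={"ST": 100.0, "T+P": 100.0},
            cost_distributions={
                k: dataclasses.replace(v, mean_quantity={"ST": {3: 1.0, 12: 1.0}, "T+P": {3: 1.0, 12: 1.0}})
                for k, v in default_cost_distributions().items()
            },
        )
        assert ground_truth(cfg).true_delta_cost == pytest.approx(0)

    def test_cost_shift_linearity(self):
        base = zero_effect_config(n=60)
        cats = dict(default_cost_distributions())
        shifted = dataclasses.replace(
            base,
            implementation_cost_per_user={"ST": 329.0, "T+P": 329.0 + 200.0},
            cost_distributions={
                k: dataclasses.replace(v, mean_quantity={"ST": {3: 0.0, 12: 0.0}, "T+P": {3: 0.0, 12: 0.0}})
                for k, v in cats.items()
            },
        )
        gt = ground_truth(shifted)
        assert gt.true_delta_cost == pytest.approx(200.0 * 60)

    def test_phq_closed_form(self):
        cfg = TrialConfig(
            n_per_arm=10,
            phq_time_effect={"ST": {3: -2.0, 12: -3.0}, "T+P": {3: -5.0, 12: -7.5}},
        )
        gt = ground_truth(cfg)
        # hand computation: per-person change difference (-7.5) - (-3.0) = -4.5
        assert gt.true_delta_phq == pytest.approx(-4.5 * 10)

    def test_implied_icer_invariant(self):
        gt = ground_truth(TrialConfig())
        assert gt.implied_icer == pytest.approx(gt.true_delta_cost / gt.true_delta_qaly)

    def test_json_roundtrip(self, tmp_path):
        gt = ground_truth(TrialConfig())
        gt.to_json(tmp_path / "gt.json")
        back = GroundTruth.from_json(tmp_path / "gt.json")
        assert back.implied_icer == pytest.approx(gt.implied_icer)


class TestBundleIO:
    def test_roundtrip(self, tmp_path, small_trial):
        write_bundle(small_trial, tmp_path)
        back = read_bundle(tmp_path)
        pdt.assert_frame_equal(back.phq, small_trial.phq)
        pdt.assert_frame_equal(back.unit_costs, small_trial.unit_costs)

    def test_byte_identical_under_seed(self, tmp_path, small_config):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_bundle(generate_trial(small_config), d1)
        write_bundle(generate_trial(small_config), d2)
        for name in ("roster.csv", "phq_long.csv", "service_use.csv"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()
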