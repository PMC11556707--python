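"""Scenario engine: aggregation, protocol behaviours, symmetries, controls."""

import numpy as np
import pandas as pd
import pytest

from painfilter import ScenarioConfig, aggregate, run_scenario
from painfilter.params import ConfigurationError
from painfilter.scenarios import (
    run_chronic_pain,
    run_conditioning_hier,
    run_history_risk,
    run_neuropathic_hier_sweep,
    run_neuropathic_single_sweep,
    run_offset_analgesia,
    run_placebo_nocebo_single,
    run_uncued_injury,
)


class TestAggregate:
    def test_order_statistics_by_hand(self):
        out = aggregate(np.array([[1.0, 2.0, 3.0, 4.0, 5.0]]))
        assert out["median"][0] == 3.0
        assert out["q25"][0] == 2.0 and out["q75"][0] == 4.0

    def test_degenerate_spread(self):
        out = aggregate(np.full((3, 10), 2.5))
        np.testing.assert_array_equal(out["q75"] - out["q25"], 0.0)
        ind = aggregate(np.full((3, 10), 2.5), mode="individual")
        np.testing.assert_array_equal(ind["se"], 0.0)

    def test_standard_error_formula(self):
        g = np.random.default_rng(0)
        v = g.normal(size=(4, 28))
        out = aggregate(v, mode="individual")
        np.testing.assert_allclose(out["se"], v.std(axis=-1, ddof=1) / np.sqrt(28))

    def test_quantile_sandwich_on_random_data(self):
        v = np.random.default_rng(1).normal(size=(50, 31))
        out = aggregate(v)
        assert np.all(out["q25"] <= out["median"]) and np.all(out["median"] <= out["q75"])

    def test_rejects_single_trajectory(self):
        with pytest.raises(ValueError):
            aggregate(np.ones((5, 1)))


class TestPlaceboNocebo:
    def test_noise_free_priors_are_gain_times_cue(self):
        res = run_placebo_nocebo_single(
            seed=0,
            b_laws={"placebo": (0.7, 0.0), "nocebo": (1.3, 0.0)},
            sample_process_noise=False,
        )
        cells = res.cells.set_index(["cue", "temperature"])
        for t in ("low", "high"):
            assert cells.loc[("placebo", t), "expected_mean"] == pytest.approx(2.59)
            assert cells.loc[("nocebo", t), "expected_mean"] == pytest.approx(4.81)

    def test_expectations_shift_perceived_pain(self):
        res = run_placebo_nocebo_single(seed=2)
        cells = res.cells.set_index(["cue", "temperature"])
        for t in ("low", "high"):
            assert (
                cells.loc[("nocebo", t), "perceived_mean"]
                > cells.loc[("placebo", t), "perceived_mean"]
            )
        for c in ("placebo", "nocebo"):
            assert (
                cells.loc[(c, "high"), "perceived_mean"]
                > cells.loc[(c, "low"), "perceived_mean"]
            )

    def test_perfect_sensing_removes_expectation_effect(self):
        res = run_placebo_nocebo_single(seed=3, R=1e-12, sample_process_noise=False)
        cells = res.cells.set_index(["cue", "temperature"])
        for c in ("placebo", "nocebo"):
            assert cells.loc[(c, "low"), "perceived_mean"] == pytest.approx(3.1, abs=1e-4)
            assert cells.loc[(c, "high"), "perceived_mean"] == pytest.approx(4.3, abs=1e-4)

    def test_label_symmetry_swaps_cells_exactly(self):
        a = run_placebo_nocebo_single(seed=3)
        b = run_placebo_nocebo_single(
            seed=3, b_laws={"placebo": (1.3, 0.5), "nocebo": (0.7, 0.5)}
        )
        ca = a.cells.set_index(["cue", "temperature"])
        cb = b.cells.set_index(["cue", "temperature"])
        for t in ("low", "high"):
            for col in ("expected_mean", "expected_se", "perceived_mean", "perceived_se"):
                assert ca.loc[("placebo", t), col] == cb.loc[("nocebo", t), col]
                assert ca.loc[("nocebo", t), col] == cb.loc[("placebo", t), col]


class TestConditioning:
    def test_gains_separate_in_the_conditioned_direction(self):
        res = run_conditioning_hier(seed=4)
        traj = res.trajectories
        baseline_gap = abs(traj.b_nocebo_median.iloc[0] - traj.b_placebo_median.iloc[0])
        final_gap = traj.b_nocebo_median.iloc[-1] - traj.b_placebo_median.iloc[-1]
        assert final_gap > 0.3
        assert final_gap > 2 * baseline_gap
        cells = res.cells.set_index(["cue", "temperature"])
        for t in ("low", "high"):
            assert (
                cells.loc[("nocebo", t), "perceived_mean"]
                > cells.loc[("placebo", t), "perceived_mean"]
            )

    def test_equal_pairings_produce_no_separation(self):
        res = run_conditioning_hier(seed=4, n_repetitions=10, z_low=3.7, z_high=3.7)
        diff = res.extras["terminal_b_nocebo_median"] - res.extras["terminal_b_placebo_median"]
        assert np.abs(diff).max() < 0.25

    def test_frozen_parameters_learn_nothing(self):
        res = run_conditioning_hier(seed=4, freeze_params=True)
        traj = res.trajectories
        assert traj.b_placebo_median.iloc[0] == pytest.approx(traj.b_placebo_median.iloc[-1])
        assert traj.b_nocebo_median.iloc[0] == pytest.approx(traj.b_nocebo_median.iloc[-1])


class TestChronicPain:
    def test_ambiguous_sensation_sustains_pain_after_recovery(self):
        res = run_chronic_pain(seed=5)
        post = res.extras["post_recovery_median"]
        assert post["R=3.24"] > 2 * post["R=0.64"]
        assert post["R=3.24"] > 1.0

    def test_memoryless_prior_removes_persistence(self):
        persistent = run_chronic_pain(seed=5, R_values=(1.8**2,))
        memoryless = run_chronic_pain(seed=5, R_values=(1.8**2,), A_hat=0.0)
        assert (
            memoryless.extras["post_recovery_median"]["R=3.24"]
            < 0.7 * persistent.extras["post_recovery_median"]["R=3.24"]
        )

    def test_uncued_injury_prior_lags_stimulus(self):
        cued = run_chronic_pain(seed=6, n_replicates=50, R_values=(0.64,))
        uncued = run_uncued_injury(seed=6, n_replicates=50, R=0.64)
        k = 20  # impulse step
        exp_cued = cued.trajectories.query("step == @k").expected_median.iloc[0]
        exp_uncued = uncued.trajectories.query("step == @k").expected_median.iloc[0]
        assert exp_cued > exp_uncued + 1.0  # the cue announces the damage
        # pain still arises from sensation alone, one step later
        after = uncued.trajectories.query("step == @k + 1").pain_median.iloc[0]
        before = uncued.trajectories.query("step == @k - 1").pain_median.iloc[0]
        assert after > before + 0.5


class TestNeuropathicSweeps:
    def test_single_layer_grid_pattern(self):
        res = run_neuropathic_single_sweep(
            seed=7, n_replicates=50, baseline_steps=150, post_steps=250
        )
        post = res.extras["post_injury_median"]
        assert post["A_hat=0.9,R=640000"] < 0.2  # decaying prior: no pain
        assert post["A_hat=1.1,R=640000"] > 8.0  # escalating prior saturates
        for a in (0.9, 1.0, 1.1):
            assert post[f"A_hat={a:g},R=0.64"] < 1.0  # sensation dominates

    def test_hier_intermediate_noise_pulls_persistence_to_one(self):
        res = run_neuropathic_hier_sweep(
            seed=7, n_replicates=40, A0_values=(0.9, 1.1), R_values=(8.0**2,),
            n_steps=600,
        )
        for label, val in res.extras["terminal_A_median"].items():
            assert val == pytest.approx(1.0, abs=0.03), label

    def test_hier_extreme_noise_keeps_persistence_near_start(self):
        res = run_neuropathic_hier_sweep(
            seed=7, n_replicates=40, A0_values=(0.9, 1.1), R_values=(800.0**2,),
            n_steps=600,
        )
        a = res.extras["terminal_A_median"]
        assert a["A0=0.9,R=640000"] == pytest.approx(0.9, abs=0.1)
        assert a["A0=1.1,R=640000"] == pytest.approx(1.1, abs=0.1)
        pain = res.extras["post_injury_pain_median"]
        assert pain["A0=1.1,R=640000"] > 5 * max(pain["A0=0.9,R=640000"], 0.2)

    def test_hier_without_parameter_noise_or_uncertainty_is_frozen(self):
        res = run_neuropathic_hier_sweep(
            seed=7, n_replicates=10, A0_values=(0.9,), R_values=(800.0**2,),
            n_steps=200, q_p=0.0, Pp_init_scale=0.0,
        )
        traj = res.trajectories
        np.testing.assert_array_equal(traj.A_median, 0.9)


class TestHistoryRisk:
    def test_history_orders_persistence_and_post_injury_pain(self):
        res = run_history_risk(seed=8, n_replicates=60)
        a = res.extras["terminal_A_median"]
        pain = res.extras["post_injury_pain_median"]
        assert a["A=0.99,stimuli"] > a["A=0.9,stimuli"]
        assert a["A=0.9,no_stimuli"] == pytest.approx(1.0, abs=0.05)
        assert pain["A=0.99,stimuli"] > pain["A=0.9,stimuli"]
        assert pain["A=0.9,no_stimuli"] >= pain["A=0.9,stimuli"]


class TestOffsetAnalgesia:
    def test_control_condition_is_flat(self):
        res = run_offset_analgesia(seed=9, n_replicates=60)
        ctrl = res.cells.query("condition == 'control'")
        assert ctrl["median"].max() - ctrl["median"].min() < 0.25

    def test_offset_undershoots_control_then_recovers(self):
        res = run_offset_analgesia(seed=9, n_replicates=100)
        cells = res.cells.set_index(["condition", "interval"])["median"]
        assert cells[("offset", "T3_1")] < cells[("control", "T3_1")] - 0.05
        t3 = [cells[("offset", f"T3_{j}")] for j in (1, 2, 3, 4)]
        assert t3[0] < t3[-1]  # recovery toward the control level

    def test_null_stimulus_gives_no_pain(self):
        res = run_offset_analgesia(
            seed=9, n_replicates=30, level_low=0.0, level_high=0.0, R=1e-6
        )
        assert res.cells["median"].abs().max() < 0.01


class TestDispatchAndReproducibility:
    def test_scenarios_are_bit_reproducible(self):
        cfg = ScenarioConfig(
            name="chronic_pain", seed=13, n_replicates=20, overrides={"n_steps": 40}
        )
        a = run_scenario(cfg)
        b = run_scenario(cfg)
        pd.testing.assert_frame_equal(a.trajectories, b.trajectories)

    def test_reported_pain_respects_the_scale(self):
        res = run_neuropathic_single_sweep(
            seed=1, n_replicates=20, baseline_steps=50, post_steps=100
        )
        cols = ["pain_median", "pain_q25", "pain_q75"]
        v = res.trajectories[cols].to_numpy()
        assert v.min() >= 0.0 and v.max() <= 10.0

    def test_unknown_override_rejected(self):
        with pytest.raises(ConfigurationError):
            ScenarioConfig(name="chronic_pain", overrides={"nonsense": 1})

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ConfigurationError):
            ScenarioConfig(name="untitled")

    def test_model_mismatch_rejected(self):
        with pytest.raises(ConfigurationError):
            ScenarioConfig(name="chronic_pain", model="hierarchical")
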