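"""Analysis-pipeline tests: filtering, ΔF, weight scaling, accuracy, stats."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import permutation_test as scipy_permutation_test

from springmatch import (
    CatchSpring,
    CohortConfig,
    ScheduleEntry,
    SchemaError,
    compute_delta_f,
    condition_summaries,
    draw_subject,
    estimate_weights,
    filter_trials,
    force_gap,
    group_permutation_test,
    predict_delta_f,
    sensor_accuracy,
    simulate_cohort,
    simulate_trial,
    summarize,
    trial_mean_force,
    weight_slope_per_decade,
    weights_table,
)

from conftest import noise_free_config


def make_trials(rows):
    defaults = dict(
        subject="S01", group="control", block=0, stiffness=100.0,
        type="blind", spring="linear", x_m=0.1, mean_force_N=10.0, valid=True,
    )
    return pd.DataFrame([{**defaults, **r} for r in rows])


class TestTrialMeanForce:
    def test_constant_window(self):
        assert trial_mean_force([10.0] * 150) == 10.0

    def test_simple_average(self):
        assert trial_mean_force([9.0, 10.0, 11.0]) == 10.0

    def test_noisy_window_near_truth(self):
        rng = np.random.default_rng(0)
        samples = 10.0 + 0.05 * rng.standard_normal(150)
        assert trial_mean_force(samples) == pytest.approx(10.0, abs=0.02)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            trial_mean_force([])


class TestFilterTrials:
    def test_threshold_is_strict(self):
        trials = make_trials(
            [{"mean_force_N": 4.9}, {"mean_force_N": 5.0}, {"mean_force_N": 10.0}]
        )
        kept = filter_trials(trials)
        assert kept["mean_force_N"].tolist() == [5.0, 10.0]

    def test_invalid_trials_removed(self):
        trials = make_trials([{"valid": False, "mean_force_N": 10.0}, {}])
        assert len(filter_trials(trials)) == 1

    def test_empty_input_passes_through(self):
        trials = make_trials([{}]).iloc[:0]
        assert len(filter_trials(trials)) == 0

    def test_order_preserved(self):
        trials = make_trials([{"mean_force_N": f} for f in (12.0, 3.0, 8.0, 6.0)])
        assert filter_trials(trials)["mean_force_N"].tolist() == [12.0, 8.0, 6.0]


def noise_free_pair(w_f: float, stiffness: float = 100.0, bias: float = 0.0):
    """Blind + catch records of a noise-free fixed-weight subject."""
    cfg = noise_free_config(w_f=w_f, bias=bias, stiffness_list=(stiffness,))
    sub = draw_subject("control", 1, cfg)
    rng = np.random.default_rng(0)
    blind = simulate_trial(sub, ScheduleEntry(0, stiffness, "blind"), rng, cfg)
    catch = simulate_trial(sub, ScheduleEntry(0, stiffness, "catch"), rng, cfg)
    return blind, catch, cfg


class TestDeltaF:
    @pytest.mark.parametrize("w_f, expected", [(0.0, 1.0), (1.0, 0.0), (0.5, 0.4555)])
    def test_noise_free_anchor_values(self, w_f, expected):
        blind, catch, cfg = noise_free_pair(w_f)
        frame = pd.DataFrame(
            [
                {"subject": "S01", "group": "control", "block": 0, "stiffness": 100.0,
                 "type": r.trial_type, "spring": r.spring_kind, "x_m": r.position,
                 "mean_force_N": r.mean_force, "valid": r.valid}
                for r in (blind, catch)
            ]
        )
        summaries = condition_summaries(frame)
        assert compute_delta_f(summaries, "S01", 100.0) == pytest.approx(expected, abs=1e-4)

    def test_missing_cell_reported_absent(self):
        summaries = condition_summaries(make_trials([{"type": "blind"}]))
        assert compute_delta_f(summaries, "S01", 100.0) is None
        assert compute_delta_f(summaries, "S99", 100.0) is None


class TestEstimateWeights:
    def test_pure_position_subject(self):
        blind, catch, _ = noise_free_pair(0.0)
        est = estimate_weights(
            delta_f=catch.mean_force - blind.mean_force,
            blind_position=blind.position,
            blind_force=blind.mean_force,
            catch_position=catch.position,
            stiffness=100.0,
            catch=CatchSpring(100.0),
        )
        assert est.w_p_hat == pytest.approx(1.0, abs=1e-9)
        assert est.w_f_hat == pytest.approx(0.0, abs=1e-9)
        assert not est.flagged

    def test_pure_force_subject(self):
        blind, catch, _ = noise_free_pair(1.0)
        est = estimate_weights(
            delta_f=catch.mean_force - blind.mean_force,
            blind_position=blind.position,
            blind_force=blind.mean_force,
            catch_position=catch.position,
            stiffness=100.0,
            catch=CatchSpring(100.0),
        )
        assert est.w_f_hat == pytest.approx(1.0, abs=1e-9)
        assert est.w_p_hat == pytest.approx(0.0, abs=1e-9)

    def test_half_weight_subject_oracle_values(self):
        # w_p_hat = 0.4555/1.0; w_f_hat = (0.1 - 0.0954451)/0.0083920 = 0.54277
        blind, catch, _ = noise_free_pair(0.5)
        est = estimate_weights(
            delta_f=catch.mean_force - blind.mean_force,
            blind_position=blind.position,
            blind_force=blind.mean_force,
            catch_position=catch.position,
            stiffness=100.0,
            catch=CatchSpring(100.0),
        )
        assert est.w_p_hat == pytest.approx(0.45549, abs=1e-4)
        assert est.w_f_hat == pytest.approx(0.54277, abs=1e-4)

    def test_flagging_outside_plausible_range(self):
        est = estimate_weights(
            delta_f=2.0, blind_position=0.1, blind_force=10.0,
            catch_position=0.09, stiffness=100.0, catch=CatchSpring(100.0),
        )
        assert est.w_p_hat == pytest.approx(2.0)
        assert est.flagged

    def test_degenerate_gap_rejected(self):
        with pytest.raises(ValueError):
            estimate_weights(
                delta_f=0.5, blind_position=0.0, blind_force=0.0,
                catch_position=0.0, stiffness=100.0, catch=CatchSpring(100.0),
            )

    @pytest.mark.parametrize("w_p", np.linspace(0.0, 1.0, 21).tolist())
    def test_pipeline_matches_prediction_oracle(self, w_p):
        """Noise-free pipeline w_p_hat equals predict_delta_f / force_gap to 1e-9."""
        blind, catch_rec, cfg = noise_free_pair(1.0 - w_p, bias=2.0)
        catch = cfg.catch_spring(100.0)
        est = estimate_weights(
            delta_f=catch_rec.mean_force - blind.mean_force,
            blind_position=blind.position,
            blind_force=blind.mean_force,
            catch_position=catch_rec.position,
            stiffness=100.0,
            catch=catch,
        )
        expected = predict_delta_f(w_p, 100.0, catch, 12.0) / force_gap(
            100.0, catch, blind.position
        )
        assert est.w_p_hat == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("stiffness", [30.0, 100.0, 300.0, 1000.0])
    @pytest.mark.parametrize("w_p", [0.1, 0.5, 0.9])
    def test_weight_estimates_are_complementary(self, stiffness, w_p):
        """w_p_hat + w_f_hat within [0.95, 1.05] for noise-free subjects."""
        blind, catch_rec, cfg = noise_free_pair(1.0 - w_p, stiffness, bias=2.0)
        est = estimate_weights(
            delta_f=catch_rec.mean_force - blind.mean_force,
            blind_position=blind.position,
            blind_force=blind.mean_force,
            catch_position=catch_rec.position,
            stiffness=stiffness,
            catch=cfg.catch_spring(stiffness),
        )
        assert 0.95 <= est.w_p_hat + est.w_f_hat <= 1.05


class TestSensorAccuracy:
    def test_constant_reproductions_have_zero_sd(self):
        trials = make_trials(
            [{"stiffness": np.inf, "mean_force_N": 12.0} for _ in range(5)]
            + [{"stiffness": 0.0, "x_m": 0.1, "mean_force_N": 0.0} for _ in range(5)]
        )
        acc = sensor_accuracy(trials, "S01")
        assert acc.sigma_f_hat == 0.0
        assert acc.sigma_x_hat == 0.0

    def test_insufficient_repetitions_give_absent_result(self):
        trials = make_trials([{"stiffness": np.inf}, {"stiffness": 0.0, "mean_force_N": 0.0}])
        assert sensor_accuracy(trials, "S01") is None

    def test_recovers_generating_sigmas(self):
        """Monte-Carlo recovery of sigma_f within 5% over 10^4 repetitions."""
        cfg = CohortConfig(sensor_noise_sd=1e-9, slip_prob=0.0)
        sub = draw_subject("control", 8, cfg)
        rng = np.random.default_rng(31)
        rows = []
        for _ in range(10_000):
            rec = simulate_trial(sub, ScheduleEntry(0, np.inf, "blind"), rng, cfg)
            rows.append({"stiffness": np.inf, "mean_force_N": rec.mean_force})
        for _ in range(10_000):
            rec = simulate_trial(sub, ScheduleEntry(1, 0.0, "blind"), rng, cfg)
            rows.append({"stiffness": 0.0, "x_m": rec.position, "mean_force_N": 0.0})
        acc = sensor_accuracy(make_trials(rows), "S01")
        assert acc.sigma_f_hat == pytest.approx(sub.sigma_f, rel=0.05)
        assert acc.sigma_x_hat == pytest.approx(sub.sigma_x, rel=0.05)

    def test_ratio_of_printed_group_means(self):
        # 1.82 N / 9.2 mm = 197.8 N/m (a ratio of means, not the mean of
        # per-subject ratios, which is why it differs from per-cohort values)
        trials = make_trials(
            [{"stiffness": np.inf, "mean_force_N": f} for f in (10.0, 10.0 + 1.82 * np.sqrt(2))]
            + [{"stiffness": 0.0, "x_m": x, "mean_force_N": 0.0} for x in (0.1, 0.1 + 0.0092 * np.sqrt(2))]
        )
        acc = sensor_accuracy(trials, "S01")
        assert acc.ratio == pytest.approx(197.8, abs=0.1)


class TestPermutationTest:
    def test_null_calibration(self):
        """Under the null, p exceeds 0.05 in at least 90% of seeded runs."""
        rng = np.random.default_rng(5)
        labels = np.array(["a"] * 10 + ["b"] * 10)
        hits = 0
        for seed in range(100):
            values = rng.standard_normal(20)
            if group_permutation_test(values, labels, n_perm=2000, seed=seed) > 0.05:
                hits += 1
        assert hits >= 90

    def test_separated_groups_detected(self):
        values = np.concatenate([np.zeros(8), np.full(8, 10.0)]) + 0.1 * np.random.default_rng(0).standard_normal(16)
        labels = np.array(["a"] * 8 + ["b"] * 8)
        assert group_permutation_test(values, labels, n_perm=10_000, seed=1) <= 0.001

    def test_seeded_determinism(self):
        rng = np.random.default_rng(9)
        values = rng.standard_normal(12)
        labels = np.array(["a"] * 6 + ["b"] * 6)
        p1 = group_permutation_test(values, labels, seed=4)
        p2 = group_permutation_test(values, labels, seed=4)
        assert p1 == p2

    def test_degenerate_values_give_p_one(self):
        labels = np.array(["a"] * 5 + ["b"] * 5)
        assert group_permutation_test(np.ones(10), labels, n_perm=500, seed=0) == 1.0

    def test_agrees_with_scipy_reference(self):
        rng = np.random.default_rng(2)
        values = np.concatenate([rng.normal(0, 1, 9), rng.normal(1.2, 1, 9)])
        labels = np.array(["a"] * 9 + ["b"] * 9)
        ours = group_permutation_test(values, labels, n_perm=20_000, seed=3)
        ref = scipy_permutation_test(
            (values[:9], values[9:]),
            lambda a, b, axis=-1: a.mean(axis=axis) - b.mean(axis=axis),
            n_resamples=20_000,
            alternative="two-sided",
            rng=np.random.default_rng(3),
        ).pvalue
        assert ours == pytest.approx(ref, abs=0.02)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            group_permutation_test([1.0, 2.0, 3.0], np.array(["a", "b", "b"]))


class TestPipelineSummary:
    def test_summary_structure_and_slopes(self):
        trials = simulate_cohort(n_per_group=4, master_seed=11)
        summary = summarize(trials, n_perm=500, seed=2)
        assert summary["n_subjects"] == {"control": 4, "patient": 4}
        assert set(summary["delta_f_N"]) == {"control", "patient"}
        for group in ("control", "patient"):
            assert set(summary["delta_f_N"][group]) == {"30", "100", "300", "1000"}
            assert summary["slopes_per_decade"][group] is not None
            assert group in summary["accuracy"]
        assert set(summary["permutation_p"]["per_stiffness"]) == {"30", "100", "300", "1000"}

    def test_weights_table_round_trips_through_csv(self, tmp_path):
        trials = simulate_cohort(n_per_group=2, master_seed=13)
        path = tmp_path / "trials.csv"
        trials.to_csv(path, index=False)
        direct = weights_table(trials)
        loaded = weights_table(pd.read_csv(path))
        pd.testing.assert_frame_equal(direct, loaded, rtol=1e-12)

    def test_schema_violations_rejected(self):
        with pytest.raises(SchemaError):
            weights_table(pd.DataFrame({"subject": ["a"]}))
        with pytest.raises(SchemaError):
            weights_table(make_trials([{}]).iloc[:0])

    def test_slope_needs_two_stiffness_levels(self):
        trials = simulate_cohort(n_per_group=2, stiffness_list=[100.0], master_seed=1)
        with pytest.raises(ValueError):
            weight_slope_per_decade(weights_table(trials), "control")
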