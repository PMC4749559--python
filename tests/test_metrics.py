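"""Model-free behavioral metrics."""

import numpy as np
import pytest

import pulsecount as pc
from pulsecount.core import Trial, TrialTable
from pulsecount.metrics import (
    InsufficientDataError,
    RegressionResult,
    _wls,
    delta_performance_vs_duration,
    delta_performance_vs_flashes,
    duration_vs_number,
    history_bias,
    history_kernel_regression,
    ratio_analysis,
    reverse_correlation,
)
from pulsecount.sdt import SigmaTable


@pytest.fixture(scope="module")
def static_8bin_cohort():
    cfg = pc.StimulusConfig.fixed_gamma(n_bins=8)
    return pc.simulate_cohort(cfg, pc.ObserverSpec("sv", {"k": 0.3}), 20_000, seed=71)


class TestReverseCorrelation:
    def test_baseline_is_gamma_gap_signed_by_correctness(self, static_8bin_cohort):
        rc = reverse_correlation(static_8bin_cohort, 8)
        went_right = [t for t in static_8bin_cohort if t.choice == "R"]
        expected = np.mean([0.4 if t.correct else -0.4 for t in went_right])
        assert rc.baseline == pytest.approx(expected, abs=1e-12)

    def test_static_observer_curves_are_flat(self, static_8bin_cohort):
        rc = reverse_correlation(static_8bin_cohort, 8)
        for curve, se in [(rc.went_right_curve, rc.se_right), (rc.went_left_curve, rc.se_left)]:
            assert np.all(np.abs(curve - curve.mean()) <= 3 * se)

    def test_filter_without_matches_is_error(self, static_8bin_cohort):
        with pytest.raises(InsufficientDataError):
            reverse_correlation(static_8bin_cohort, n_bins_required=5)

    def test_grouped_mode_averages_subjects(self):
        cfg = pc.StimulusConfig.fixed_gamma(n_bins=8)
        tabs = [
            pc.simulate_cohort(cfg, pc.ObserverSpec("sv", {"k": 0.3}), 2000, seed=s, subject_id=f"r{s}")
            for s in (81, 82, 83)
        ]
        merged = TrialTable([t for tab in tabs for t in tab], validate=False)
        rc = reverse_correlation(merged, 8, grouped=True)
        assert rc.n_right_trials == 3  # subjects, in grouped mode
        assert rc.went_right_curve.shape == (8,)


class TestDeltaPerformance:
    def test_count_noise_shows_negative_flash_slope(self, sv_cohort_50k):
        reg = delta_performance_vs_flashes(sv_cohort_50k)
        assert reg.slope < 0
        assert reg.z < -3

    def test_constant_noise_shows_no_flash_slope(self):
        cfg = pc.StimulusConfig.unrestrained()
        table = pc.simulate_cohort(cfg, pc.ObserverSpec("constant", {"sigma": 1.5}), 20_000, seed=72)
        reg = delta_performance_vs_flashes(table)
        assert abs(reg.z) < 3

    def test_static_observer_shows_no_duration_slope(self, sv_cohort_50k):
        reg = delta_performance_vs_duration(sv_cohort_50k)
        lo, hi = reg.ci()
        assert lo <= 0 <= hi

    def test_wls_matches_naive_two_pass_computation(self, rng):
        x = rng.normal(size=40)
        y = 2.0 * x + 1.0 + rng.normal(size=40)
        w = rng.uniform(0.5, 2.0, size=40)
        reg = _wls(x, y, w, units="u")
        # naive weighted normal equations
        X = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.solve(X.T @ (w[:, None] * X), X.T @ (w * y))
        assert reg.intercept == pytest.approx(beta[0], abs=1e-10)
        assert reg.slope == pytest.approx(beta[1], abs=1e-10)


class TestRatioAnalysis:
    def test_pure_sv_model_prediction_is_flat_within_ratio(self, static_8bin_cohort):
        sig = SigmaTable.from_sigma(0.3 * np.arange(16))
        out = ratio_analysis(static_8bin_cohort, sig)
        for key, pts in out.items():
            if key == "0:1" or len(pts) < 2:
                continue
            preds = [p["model_pct"] for p in pts]
            assert max(preds) - min(preds) < 1e-9, key

    def test_inflated_small_count_noise_breaks_flatness_upward(self):
        sigma = 0.3 * np.arange(16)
        sigma[1] += 1.0
        sigma[2] += 1.0
        sig = SigmaTable.from_sigma(sigma)
        cfg = pc.StimulusConfig.fixed_gamma(n_bins=8)
        table = pc.simulate_cohort(cfg, pc.ObserverSpec("sv", {"k": 0.3}), 2000, seed=73)
        out = ratio_analysis(table, sig)
        pts = out.get("1:2", [])
        by_scale = {p["scale"]: p["model_pct"] for p in pts}
        if 1 in by_scale and 3 in by_scale:
            assert by_scale[1] < by_scale[3]

    def test_one_sided_trials_form_their_own_group(self, static_8bin_cohort):
        out = ratio_analysis(static_8bin_cohort)
        assert "0:1" in out


class TestHistory:
    def test_history_free_observer_recovers_null(self):
        cfg = pc.StimulusConfig.unrestrained()
        table = pc.simulate_cohort(
            cfg, pc.ObserverSpec("sv", {"k": 0.5}), 3000, n_sessions=3, seed=174
        )
        hb = history_bias(table, max_lag=4)
        for row in hb["lags"]:
            lo, hi = row["ci_reward"]
            assert lo <= row["null_reward"] <= hi, row

    def test_kernel_regression_recovers_lag_structure(self):
        kern = ((1, 0.6, -0.3), (2, 0.35, -0.15))
        cfg = pc.StimulusConfig.head_fixed()
        table = pc.simulate_cohort(
            cfg, pc.ObserverSpec("sv", {"k": 0.4}, history_kernel=kern), 4000, n_sessions=5, seed=75
        )
        reg = history_kernel_regression(table, max_lag=4)
        rew = {r["lag"]: r for r in reg if r["outcome"] == "reward"}
        assert rew[1]["z"] > 3 and rew[2]["z"] > 3
        assert abs(rew[4]["z"]) < 3
        assert rew[1]["coef"] > rew[2]["coef"]

    def test_unordered_sessions_not_constructible(self):
        # TrialTable sorts on construction, so history always sees ordered
        # sessions; verify the ordering invariant holds after a shuffled build
        cfg = pc.StimulusConfig.head_fixed()
        table = pc.simulate_cohort(cfg, pc.ObserverSpec("sv", {"k": 0.4}), 50, seed=76)
        rng = np.random.default_rng(0)
        rebuilt = TrialTable([table[i] for i in rng.permutation(len(table))], validate=False)
        assert [t.trial_index for t in rebuilt] == sorted(t.trial_index for t in rebuilt)
        history_bias(rebuilt, max_lag=2)  # does not raise


class TestDurationVsNumber:
    def test_normalised_regressor_is_bounded(self, jitter_cohort):
        for t in jitter_cohort:
            dl, dr = sum(t.flash_durs_left), sum(t.flash_durs_right)
            if dl + dr > 0:
                assert abs((dr - dl) / (dr + dl)) <= 1 + 1e-12

    def test_count_integrating_observer_verdict(self, jitter_cohort):
        res = duration_vs_number(jitter_cohort)
        lo, hi = res["equal_count_duration_slope"].ci()
        assert lo <= 0 <= hi
        assert res["verdict"] == "number"

    def test_duration_integrating_observer_is_the_positive_control(self):
        cfg = pc.StimulusConfig.head_fixed(jitter=True)
        table = pc.generate_stimuli(cfg, 10_000, seed=77)
        rng = np.random.default_rng(78)
        for t in table.trials:
            # observer accumulates summed flash duration with mild noise
            ev = sum(t.flash_durs_right) - sum(t.flash_durs_left) + rng.normal(0, 0.01)
            t.choice = "R" if ev > 0 else "L"
            t.correct = t.choice == t.rewarded_side
        res = duration_vs_number(table)
        assert res["verdict"] == "duration"
        assert res["equal_count_duration_slope"].z > 3

    def test_no_jitter_trials_is_error(self, sv_cohort_small):
        with pytest.raises(InsufficientDataError):
            duration_vs_number(sv_cohort_small)
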