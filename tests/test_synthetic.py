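"""Stimulus generator statistics and observer models."""

import numpy as np
import pytest
from scipy.special import ndtr

import pulsecount as pc
from pulsecount.core import StimulusConfig, Trial
from pulsecount.synthetic import DDMParams, ObserverSpec, sdt_choice, simulate_ddm


def _bare_trial(times_l, times_r, n_bins=15, delay=0.0):
    return Trial(
        "s", "x", 0, n_bins,
        list(times_l), list(times_r),
        [0.01] * len(times_l), [0.01] * len(times_r),
        delay, None, "R" if len(times_r) >= len(times_l) else "L", None,
    )


class TestStimuli:
    def test_deterministic_probabilities_give_full_and_empty_sides(self):
        cfg = StimulusConfig(p_high_range=(1.0, 1.0), p_low_range=(0.0, 0.0))
        table = pc.generate_stimuli(cfg, 50, seed=0)
        for t in table:
            assert {t.n_left, t.n_right} == {0, 15}

    def test_per_bin_count_difference_approaches_gamma_gap(self):
        # fixed 70/30 generative probabilities: the expected per-bin count
        # difference between the designated high and low side is 0.4
        cfg = StimulusConfig.fixed_gamma()
        table = pc.generate_stimuli(cfg, 20_000, seed=1)
        per_bin = np.array(
            [
                (t.n_right - t.n_left) / t.n_bins * (1 if t.high_side == "R" else -1)
                for t in table
            ]
        )
        se = per_bin.std(ddof=1) / np.sqrt(len(per_bin))
        assert abs(per_bin.mean() - 0.4) < 3 * se

    def test_high_side_bin_rate_matches_p_high(self):
        cfg = StimulusConfig.fixed_gamma(n_bins=10)
        table = pc.generate_stimuli(cfg, 5000, seed=2)
        counts = np.array([max(t.n_left, t.n_right) for t in table])
        rate = counts.mean() / 10
        assert abs(rate - 0.7) < 3 * np.sqrt(0.7 * 0.3 / (5000 * 10)) + 0.01

    def test_jitter_durations_positive_and_near_10ms(self):
        cfg = StimulusConfig.fixed_gamma(jitter=True)
        table = pc.generate_stimuli(cfg, 500, seed=3)
        durs = np.concatenate([t.flash_durs_left + t.flash_durs_right for t in table])
        assert np.all(durs > 0)
        assert abs(durs.mean() - 0.010) < 0.0005

    def test_same_seed_is_deterministic(self):
        cfg = StimulusConfig.unrestrained()
        a = pc.generate_stimuli(cfg, 100, seed=5)
        b = pc.generate_stimuli(cfg, 100, seed=5)
        for x, y in zip(a, b):
            assert x.flash_times_left == y.flash_times_left
            assert x.flash_times_right == y.flash_times_right

    def test_bad_probability_range_rejected(self):
        with pytest.raises(ValueError):
            StimulusConfig(p_high_range=(0.7, 1.2))


class TestSdtObserver:
    def test_zero_noise_always_picks_majority(self, rng):
        spec = ObserverSpec("sigma_table", {"sigma": np.zeros(16)})
        t = _bare_trial([0.0], [0.25, 0.5, 0.75])
        assert all(sdt_choice(t, spec, rng) == "R" for _ in range(20))

    def test_equal_counts_symmetric_noise_is_fair(self, rng):
        spec = ObserverSpec("sv", {"k": 0.4})
        t = _bare_trial([0.0, 0.25], [0.5, 0.75])
        picks = [sdt_choice(t, spec, rng) for _ in range(4000)]
        p = np.mean([c == "R" for c in picks])
        assert abs(p - 0.5) < 3 * np.sqrt(0.25 / 4000)

    def test_choice_rate_matches_gaussian_closed_form(self, rng):
        # n_L=4, n_R=6 with sigma_4=2, sigma_6=3: P(R) = Phi(2/sqrt(13))
        sigma = np.zeros(16)
        sigma[4], sigma[6] = 2.0, 3.0
        spec = ObserverSpec("sigma_table", {"sigma": sigma})
        t = _bare_trial([0.25 * i for i in range(4)], [0.25 * i for i in range(6)])
        n = 200_000
        picks = np.array([sdt_choice(t, spec, rng) == "R" for _ in range(n)])
        expected = ndtr(2 / np.sqrt(13.0))
        assert expected == pytest.approx(0.7104, abs=5e-4)
        assert abs(picks.mean() - expected) < 3 * np.sqrt(expected * (1 - expected) / n)

    def test_lapse_floors_performance(self, rng):
        spec = ObserverSpec("sigma_table", {"sigma": np.zeros(16)}, lapse=0.4)
        t = _bare_trial([], [0.0])
        picks = np.array([sdt_choice(t, spec, rng) == "R" for _ in range(4000)])
        # lapse/2 of trials flip to L: P(R) = 1 - lapse/2
        assert abs(picks.mean() - 0.8) < 3 * np.sqrt(0.8 * 0.2 / 4000)


class TestDDM:
    def test_noiseless_limit_counts_flashes_exactly(self, rng):
        t = _bare_trial([0.25, 0.75], [0.0, 0.5, 1.0, 1.25], n_bins=6)
        _, (tt, a) = simulate_ddm(t, DDMParams(dt=1e-3), rng, return_trajectory=True)
        assert a[-1] == pytest.approx(2.0, abs=1e-12)

    def test_leak_matches_closed_form(self, rng):
        # single right flash at t0, no noise: a(T) = exp(lam * (T - t0))
        t0, lam = 0.5, -2.0
        t = _bare_trial([], [t0], n_bins=8)
        _, (_, a) = simulate_ddm(t, DDMParams(lam=lam, dt=1e-4), rng, return_trajectory=True)
        assert a[-1] == pytest.approx(np.exp(lam * (t.duration_s - t0)), abs=1e-3)

    def test_sticky_bound_commits_at_first_flash(self, rng):
        # bound below the unit pulse: decision fixed by the first flash,
        # later opposing flashes are ignored
        t = _bare_trial([0.5, 0.75, 1.0], [0.25], n_bins=6)
        for _ in range(10):
            choice, _ = simulate_ddm(t, DDMParams(B=0.5, dt=1e-3), rng)
            assert choice == "R"

    def test_diffusion_variance_calibration(self, rng):
        # no flashes, lam=0: Var[a(T)] = sigma_a^2 * T
        t = _bare_trial([], [], n_bins=4)
        finals = []
        for _ in range(300):
            _, (_, a) = simulate_ddm(t, DDMParams(sigma_a=0.8, dt=1e-3), rng, return_trajectory=True)
            finals.append(a[-1])
        target = 0.8**2 * t.duration_s
        var = np.var(finals)
        # chi^2 spread of a 300-sample variance is ~sqrt(2/300)
        assert abs(var - target) < 4 * target * np.sqrt(2 / 300)

    def test_cohort_engine_agrees_with_euler_on_choice_rates(self):
        # same trials, same parameters: the exact-transition cohort engine
        # and the per-trial Euler path must produce the same choice law
        cfg = StimulusConfig.fixed_gamma(n_bins=4)
        params = DDMParams(sigma_a=0.5, sigma_s=0.4, lam=-1.0, dt=1e-3)
        spec = ObserverSpec("ddm", {"ddm": params})
        table = pc.simulate_cohort(cfg, spec, 1500, seed=9)
        rng = np.random.default_rng(10)
        euler = []
        for t in list(table)[:400]:
            c, _ = simulate_ddm(t, params, rng)
            euler.append(c == t.rewarded_side)
        p_cohort = np.mean([t.correct for t in table])
        p_euler = np.mean(euler)
        se = np.sqrt(p_cohort * (1 - p_cohort) / 400 + p_cohort * (1 - p_cohort) / 1500)
        assert abs(p_cohort - p_euler) < 4 * se

    def test_dt_larger_than_bin_rejected(self, rng):
        with pytest.raises(ValueError, match="dt"):
            simulate_ddm(_bare_trial([], [0.0]), DDMParams(dt=0.3), rng)


class TestHistoryKernelObserver:
    def test_kernel_shifts_tie_trials_toward_rewarded_side(self):
        # closed form: P(repeat | previous reward, Delta F = 0) = Phi(w / sigma_eff)
        w = 0.8
        spec = ObserverSpec("sv", {"k": 0.4}, history_kernel=((1, w, 0.0),))
        cfg = StimulusConfig.head_fixed()
        table = pc.simulate_cohort(cfg, spec, 30_000, seed=12)
        trials = list(table)
        repeats, preds = [], []
        for prev, cur in zip(trials, trials[1:]):
            if not prev.correct or cur.flash_diff != 0:
                continue
            sig = 0.4 * np.sqrt(cur.n_left**2 + cur.n_right**2)
            if sig == 0:
                continue
            shift = w if prev.choice == "R" else -w
            preds.append(ndtr(shift / sig) if prev.choice == "R" else 1 - ndtr(shift / sig))
            repeats.append(cur.choice == prev.choice)
        p_obs = np.mean(repeats)
        p_pred = np.mean(preds)
        assert abs(p_obs - p_pred) < 3 * np.sqrt(p_pred * (1 - p_pred) / len(repeats))
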