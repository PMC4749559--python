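"""Synthetic stimuli and model observers.

Generates flash-train stimuli with the task's statistics (250-ms bins,
10-ms flashes, per-trial Bernoulli generative probabilities drawn from
70-80% / 20-30% ranges, uniform post-cue delay, optional onset/duration
jitter) and produces choices from explicit observer models: static
signal-detection observers with any per-count noise law, the eight
accumulator variants, additive trial-history kernels, and a pulse-driven
drift-diffusion simulator.  Every downstream analysis is testable against
these known generative truths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import StimulusConfig, Trial, TrialTable
from . import variants as _variants

__all__ = [
    "ObserverSpec",
    "DDMParams",
    "generate_stimuli",
    "sdt_choice",
    "simulate_ddm",
    "simulate_cohort",
    "generate_click_trains",
]


@dataclass(frozen=True)
class ObserverSpec:
    """A choice model used to generate synthetic behavior.

    ``family`` selects the noise rule; ``params`` its parameters:

    * ``"sv"``        sigma(n) = k*n                       (params: k)
    * ``"lv"``        sigma(n) = sqrt(k*n)                 (params: k)
    * ``"sub_sv"``    sigma(n) = 0 for n <= c else k*n     (params: k, c)
    * ``"sv_offset"`` sigma(n) = k0 + k*n                  (params: k0, k)
    * ``"constant"``  sigma(n) = sigma                     (params: sigma)
    * ``"sigma_table"`` explicit vector                    (params: sigma)
    * ``"variant_a"``..``"variant_h"``                     (params: beta1, beta2)
    * ``"ddm"``       drift-diffusion                      (params: ddm=DDMParams)

    For the count-indexed families the decision variable is
    est_R - est_L with est_S ~ N(n_S, sigma(n_S)^2).  A history kernel,
    a list of (lag, reward_weight, error_weight) tuples, shifts the
    decision variable additively by the summed weights of past outcomes
    (signed + for past rightward choices).  With probability ``lapse``
    the choice is replaced by a fair coin.
    """

    family: str
    params: dict = field(default_factory=dict)
    lapse: float = 0.0
    history_kernel: tuple[tuple[int, float, float], ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.lapse <= 1.0:
            raise ValueError("lapse must be in [0, 1]")
        for lag, _, _ in self.history_kernel:
            if int(lag) < 1:
                raise ValueError("history kernel lags must be positive integers")

    def sigma_of(self, n) -> np.ndarray:
        """Per-count noise sigma(n) for the count-indexed families."""
        n = np.asarray(n, dtype=float)
        p = self.params
        if self.family == "sv":
            return p["k"] * n
        if self.family == "lv":
            return np.sqrt(p["k"] * n)
        if self.family == "sub_sv":
            return np.where(n <= p.get("c", 3), 0.0, p["k"] * n)
        if self.family == "sv_offset":
            return p["k0"] + p["k"] * n
        if self.family == "constant":
            return np.full_like(n, float(p["sigma"]))
        if self.family == "sigma_table":
            sigma = np.asarray(p["sigma"], dtype=float)
            idx = n.astype(int)
            if np.any(idx >= len(sigma)):
                raise ValueError("count outside the provided sigma table")
            return sigma[idx]
        raise ValueError(f"family {self.family!r} has no per-count sigma")


@dataclass(frozen=True)
class DDMParams:
    """Parameters of the pulse-driven drift-diffusion simulator.

    a(0) = bias; between pulses da = lam*a dt + sigma_a dW; each pulse
    adds +/- eta*C with eta ~ N(1, sigma_s^2) and C the shared sensory
    adaptation state (dC/dt = (1-C)/tau_phi between pulses, C -> phi*C
    at a pulse after contributing its pre-update value; C(0) = 1, the
    fixed point of the recovery dynamics).  If |a| ever reaches the
    sticky bound B, integration stops and the decision is committed.
    """

    sigma_a: float = 0.0
    sigma_s: float = 0.0
    lam: float = 0.0
    B: float = np.inf
    bias: float = 0.0
    lapse: float = 0.0
    phi: float = 1.0
    tau_phi: float = 0.2
    dt: float = 1e-4

    def __post_init__(self) -> None:
        if self.B <= 0:
            raise ValueError("bound B must be positive")
        if self.tau_phi <= 0:
            raise ValueError("tau_phi must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")


# -- stimulus generation --------------------------------------------------


def generate_stimuli(
    cfg: StimulusConfig,
    n_trials: int,
    seed: int | None = None,
    subject_id: str = "sim",
    session_id: str = "s000",
    rng: np.random.Generator | None = None,
) -> TrialTable:
    """Generate a table of stimuli (no choices yet).

    Per trial one side is designated high-probability uniformly at
    random; per-bin flashes are Bernoulli draws with probabilities drawn
    once per trial from the configured ranges.  The rewarded side is the
    side with more *actual* flashes; ties are rewarded uniformly at
    random (and recorded), so equal-count trials exist for the
    duration-vs-number analyses.
    """
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    rng = rng if rng is not None else np.random.default_rng(seed)
    nb = cfg.n_bins
    bin_s = cfg.bin_ms / 1000.0

    high_is_right = rng.random(n_trials) < 0.5
    p_high = rng.uniform(*cfg.p_high_range, size=n_trials)
    p_low = rng.uniform(*cfg.p_low_range, size=n_trials)
    p_right = np.where(high_is_right, p_high, p_low)
    p_left = np.where(high_is_right, p_low, p_high)
    if cfg.n_bins_range is not None:
        nb_trial = rng.integers(cfg.n_bins_range[0], cfg.n_bins_range[1] + 1, size=n_trials)
    else:
        nb_trial = np.full(n_trials, nb)
    live_bins = np.arange(nb)[None, :] < nb_trial[:, None]
    flashes_r = (rng.random((n_trials, nb)) < p_right[:, None]) & live_bins
    flashes_l = (rng.random((n_trials, nb)) < p_left[:, None]) & live_bins
    delays = rng.uniform(*cfg.delay_range_s, size=n_trials)

    if cfg.jitter:
        # bin onsets share a jittered clock; durations jitter per flash
        isi = rng.normal(cfg.isi_mean_ms / 1000.0, cfg.isi_sd_ms / 1000.0, size=(n_trials, nb - 1))
        while np.any(isi <= cfg.flash_ms / 1000.0):
            bad = isi <= cfg.flash_ms / 1000.0
            isi[bad] = rng.normal(cfg.isi_mean_ms / 1000.0, cfg.isi_sd_ms / 1000.0, size=int(bad.sum()))
        onsets = np.concatenate([np.zeros((n_trials, 1)), np.cumsum(isi, axis=1)], axis=1)
    else:
        onsets = np.tile(np.arange(nb) * bin_s, (n_trials, 1))

    def _durs(k: int) -> list[float]:
        if not cfg.jitter:
            return [cfg.flash_ms / 1000.0] * k
        d = rng.normal(cfg.flash_ms / 1000.0, cfg.dur_sd_ms / 1000.0, size=k)
        while np.any(d <= 0):
            bad = d <= 0
            d[bad] = rng.normal(cfg.flash_ms / 1000.0, cfg.dur_sd_ms / 1000.0, size=int(bad.sum()))
        return [float(x) for x in d]

    trials = []
    ties = rng.random(n_trials) < 0.5
    for i in range(n_trials):
        tl = [float(x) for x in onsets[i][flashes_l[i]]]
        tr = [float(x) for x in onsets[i][flashes_r[i]]]
        n_l, n_r = len(tl), len(tr)
        if n_r > n_l:
            rewarded = "R"
        elif n_l > n_r:
            rewarded = "L"
        else:
            rewarded = "R" if ties[i] else "L"
        trials.append(
            Trial(
                subject_id=subject_id,
                session_id=session_id,
                trial_index=i,
                n_bins=int(nb_trial[i]),
                bin_ms=cfg.bin_ms,
                flash_times_left=tl,
                flash_times_right=tr,
                flash_durs_left=_durs(n_l),
                flash_durs_right=_durs(n_r),
                delay_s=float(delays[i]),
                choice=None,
                rewarded_side=rewarded,
                correct=None,
                p_high=float(p_high[i]),
                p_low=float(p_low[i]),
                jitter=cfg.jitter,
                high_side="R" if high_is_right[i] else "L",
            )
        )
    return TrialTable(trials, configs={session_id: cfg}, validate=False)


# -- static observers -----------------------------------------------------


def _effective_std(table_or_trials, spec: ObserverSpec) -> np.ndarray:
    """sigma_eff per trial for the count-indexed and variant families."""
    trials = list(table_or_trials)
    if spec.family.startswith("variant_"):
        vid = spec.family.split("_", 1)[1]
        model = _variants.VariantModel(vid, spec.params["beta1"], spec.params["beta2"])
        rows = [_variants.path_stats(t) for t in trials]
        stats = {k: np.array([r[k] for r in rows]) for k in rows[0]}
        return np.sqrt(_variants.effective_variance(stats, model))
    nl = np.array([t.n_left for t in trials], dtype=float)
    nr = np.array([t.n_right for t in trials], dtype=float)
    return np.sqrt(spec.sigma_of(nl) ** 2 + spec.sigma_of(nr) ** 2)


def sdt_choice(
    trial: Trial,
    spec: ObserverSpec,
    rng: np.random.Generator,
    history_shift: float = 0.0,
) -> str:
    """Draw one choice from a static observer for one trial."""
    sig = float(_effective_std([trial], spec)[0])
    a = trial.flash_diff + history_shift + (sig * rng.standard_normal() if sig > 0 else 0.0)
    if a == 0:
        choice = "R" if rng.random() < 0.5 else "L"
    else:
        choice = "R" if a > 0 else "L"
    if spec.lapse > 0 and rng.random() < spec.lapse:
        choice = "R" if rng.random() < 0.5 else "L"
    return choice


def _kernel_shift(spec: ObserverSpec, past: list[Trial]) -> float:
    shift = 0.0
    for lag, w_reward, w_error in spec.history_kernel:
        if lag <= len(past):
            prev = past[-lag]
            side = 1.0 if prev.choice == "R" else -1.0
            shift += (w_reward if prev.correct else w_error) * side
    return shift


def _apply_static_choices(table: TrialTable, spec: ObserverSpec, rng: np.random.Generator) -> None:
    """Fill in choices for a whole (single-session) table, in place."""
    trials = table.trials
    if not spec.history_kernel:
        sig = _effective_std(trials, spec)
        d = np.array([t.flash_diff for t in trials], dtype=float)
        a = d + sig * rng.standard_normal(len(trials))
        coin = rng.random(len(trials)) < 0.5
        choice = np.where(a > 0, "R", np.where(a < 0, "L", np.where(coin, "R", "L")))
        if spec.lapse > 0:
            lapse = rng.random(len(trials)) < spec.lapse
            lapse_choice = rng.random(len(trials)) < 0.5
            choice = np.where(lapse, np.where(lapse_choice, "R", "L"), choice)
        for t, c in zip(trials, choice):
            t.choice = str(c)
            t.correct = t.choice == t.rewarded_side
    else:
        sig = _effective_std(trials, spec)
        for i, t in enumerate(trials):
            shift = _kernel_shift(spec, trials[:i])
            a = t.flash_diff + shift + (sig[i] * rng.standard_normal() if sig[i] > 0 else 0.0)
            c = ("R" if a > 0 else "L") if a != 0 else ("R" if rng.random() < 0.5 else "L")
            if spec.lapse > 0 and rng.random() < spec.lapse:
                c = "R" if rng.random() < 0.5 else "L"
            t.choice = c
            t.correct = c == t.rewarded_side


# -- drift-diffusion simulator -------------------------------------------


def simulate_ddm(
    trial: Trial,
    p: DDMParams,
    rng: np.random.Generator,
    return_trajectory: bool = False,
):
    """Euler-Maruyama integration of the pulse-driven diffusion for one trial.

    Integrates from t = 0 to cue end plus the post-cue delay with step
    ``p.dt``; pulses are applied instantaneously at their onset step.
    Returns (choice, trajectory) where trajectory is (t, a) arrays when
    requested, else None.
    """
    bin_s = trial.bin_ms / 1000.0
    if p.dt >= bin_s:
        raise ValueError("dt must be smaller than the bin duration")
    T = trial.duration_s
    n_steps = int(np.ceil(T / p.dt))
    events = sorted(
        [(t, -1.0) for t in trial.flash_times_left] + [(t, +1.0) for t in trial.flash_times_right],
        key=lambda e: (e[0], e[1]),
    )
    event_steps = [int(round(t / p.dt)) for t, _ in events]
    a = p.bias
    C = 1.0
    last_event_t = 0.0
    traj = np.empty(n_steps + 1) if return_trajectory else None
    if traj is not None:
        traj[0] = a
    sqrt_dt = np.sqrt(p.dt)
    decay = np.exp(-p.dt / p.tau_phi)
    pinned = abs(a) >= p.B
    if pinned:
        a = np.sign(a) * p.B
    ev = 0
    noise = rng.standard_normal(n_steps) if p.sigma_a > 0 else None
    for step in range(n_steps):
        if not pinned:
            while ev < len(events) and event_steps[ev] == step:
                sign = events[ev][1]
                eta = 1.0 + (p.sigma_s * rng.standard_normal() if p.sigma_s > 0 else 0.0)
                a += sign * eta * C
                C *= p.phi
                ev += 1
                if abs(a) >= p.B:
                    a = np.sign(a) * p.B
                    pinned = True
                    break
        if not pinned:
            da = p.lam * a * p.dt
            if noise is not None:
                da += p.sigma_a * sqrt_dt * noise[step]
            a += da
            C = 1.0 - (1.0 - C) * decay
            if abs(a) >= p.B:
                a = np.sign(a) * p.B
                pinned = True
        if traj is not None:
            traj[step + 1] = a
    if a == 0:
        choice = "R" if rng.random() < 0.5 else "L"
    else:
        choice = "R" if a > 0 else "L"
    if p.lapse > 0 and rng.random() < p.lapse:
        choice = "R" if rng.random() < 0.5 else "L"
    if return_trajectory:
        return choice, (np.arange(n_steps + 1) * p.dt, traj)
    return choice, None


def _apply_ddm_choices(table: TrialTable, p: DDMParams, rng: np.random.Generator) -> None:
    """Vectorised cohort version of the diffusion observer (in place).

    Requires non-jittered stimuli (pulses on the shared bin grid).  The
    Ornstein-Uhlenbeck segments between bin onsets are advanced with
    their exact transition (mean a*exp(lam*dt), variance
    sigma_a^2*(exp(2*lam*dt)-1)/(2*lam)), which is equivalent in law to
    Euler integration in the small-step limit; sticky-bound crossings are
    checked at bin boundaries.  Simultaneous left+right pulses share the
    pre-update adaptation state and C is scaled by phi once per pulse.
    """
    trials = table.trials
    n = len(trials)
    nb = max(t.n_bins for t in trials)
    bin_s = trials[0].bin_ms / 1000.0
    sign_mat = np.zeros((n, nb))  # eta_R*C - eta_L*C net pulse per bin
    has_l = np.zeros((n, nb), bool)
    has_r = np.zeros((n, nb), bool)
    for i, t in enumerate(trials):
        for x in t.flash_times_left:
            has_l[i, int(round(x / bin_s))] = True
        for x in t.flash_times_right:
            has_r[i, int(round(x / bin_s))] = True
    a = np.full(n, p.bias)
    C = np.ones(n)
    bounded = np.isfinite(p.B)
    pinned = np.abs(a) >= p.B if bounded else np.zeros(n, bool)
    if bounded:
        a = np.where(pinned, np.sign(a) * p.B, a)

    def _ou_step(a, dt, active):
        if p.lam != 0.0:
            g = np.exp(p.lam * dt)
            sd = p.sigma_a * np.sqrt((np.exp(2 * p.lam * dt) - 1.0) / (2.0 * p.lam))
        else:
            g, sd = 1.0, p.sigma_a * np.sqrt(dt)
        new = a * g + (sd * rng.standard_normal(n) if p.sigma_a > 0 else 0.0)
        return np.where(active, new, a)

    durations = np.array([t.duration_s for t in trials])
    n_bins_arr = np.array([t.n_bins for t in trials])
    for b in range(nb):
        live = (~pinned) & (b < n_bins_arr)
        # pulses at bin onset: both sides see the same pre-update C
        inc = np.zeros(n)
        any_pulse = live & (has_l[:, b] | has_r[:, b])
        if np.any(any_pulse):
            eta_r = 1.0 + (p.sigma_s * rng.standard_normal(n) if p.sigma_s > 0 else 0.0)
            eta_l = 1.0 + (p.sigma_s * rng.standard_normal(n) if p.sigma_s > 0 else 0.0)
            inc = np.where(has_r[:, b], eta_r * C, 0.0) - np.where(has_l[:, b], eta_l * C, 0.0)
            a = np.where(any_pulse, a + inc, a)
            n_pulses = has_l[:, b].astype(int) + has_r[:, b].astype(int)
            C = np.where(any_pulse, C * p.phi ** n_pulses, C)
            if bounded:
                newly = live & (np.abs(a) >= p.B)
                a = np.where(newly, np.sign(a) * p.B, a)
                pinned |= newly
                live = live & ~newly
        # evolve to next bin onset (or through the tail for finished trials)
        a = _ou_step(a, bin_s, live)
        C = 1.0 - (1.0 - C) * np.exp(-bin_s / p.tau_phi)
        if bounded:
            newly = live & (np.abs(a) >= p.B)
            a = np.where(newly, np.sign(a) * p.B, a)
            pinned |= newly
    # remaining post-cue delay of each trial (a froze at its own cue end)
    tail = durations - n_bins_arr * bin_s
    tail_live = (~pinned) & (tail > 0)
    if np.any(tail_live):
        if p.lam != 0.0:
            g = np.exp(p.lam * tail)
            sd = p.sigma_a * np.sqrt((np.exp(2 * p.lam * tail) - 1.0) / (2.0 * p.lam))
        else:
            g, sd = np.ones(n), p.sigma_a * np.sqrt(np.maximum(tail, 0.0))
        new = a * g + (sd * rng.standard_normal(n) if p.sigma_a > 0 else 0.0)
        a = np.where(tail_live, new, a)
        if bounded:
            newly = tail_live & (np.abs(a) >= p.B)
            a = np.where(newly, np.sign(a) * p.B, a)
    coin = rng.random(n) < 0.5
    choice = np.where(a > 0, "R", np.where(a < 0, "L", np.where(coin, "R", "L")))
    if p.lapse > 0:
        lapse = rng.random(n) < p.lapse
        lc = rng.random(n) < 0.5
        choice = np.where(lapse, np.where(lc, "R", "L"), choice)
    for t, c in zip(trials, choice):
        t.choice = str(c)
        t.correct = t.choice == t.rewarded_side


# -- cohorts --------------------------------------------------------------


def simulate_cohort(
    cfg: StimulusConfig,
    spec: ObserverSpec,
    n_trials: int,
    n_sessions: int = 1,
    seed: int | None = None,
    subject_id: str = "sim",
) -> TrialTable:
    """Full synthetic cohort: stimuli plus observer choices.

    ``n_trials`` is per session.  History kernels are applied using the
    simulated outcome sequence within each session.
    """
    rng = np.random.default_rng(seed)
    all_trials: list[Trial] = []
    configs = {}
    for s in range(n_sessions):
        sid = f"s{s:03d}"
        tab = generate_stimuli(cfg, n_trials, rng=rng, subject_id=subject_id, session_id=sid)
        if spec.family == "ddm":
            if spec.history_kernel:
                raise ValueError("history kernels are not supported for the ddm family")
            _apply_ddm_choices(tab, spec.params["ddm"], rng)
        else:
            _apply_static_choices(tab, spec, rng)
        all_trials.extend(tab.trials)
        configs[sid] = cfg
    return TrialTable(all_trials, configs=configs, validate=False)


# -- click trains ---------------------------------------------------------


def generate_click_trains(
    n_trials: int,
    seed: int | None = None,
    rate_total: float = 40.0,
    duration_range: tuple[float, float] = (0.2, 1.0),
    log_ratio_range: tuple[float, float] = (0.5, 3.5),
    subject_id: str = "clicks",
    session_id: str = "s000",
    rng: np.random.Generator | None = None,
) -> TrialTable:
    """Poisson click-train stimuli in the trial-table format.

    Left/right rates sum to ``rate_total`` with log rate ratio drawn
    uniformly from ``log_ratio_range`` (sign randomised); the cue duration
    is uniform on ``duration_range``.  No simultaneous onset click is
    generated, so all clicks are informative.  Click times occupy the
    flash-time columns; trials are flagged as jittered so bin-alignment
    validation does not apply.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    trials = []
    for i in range(n_trials):
        T = rng.uniform(*duration_range)
        gamma = rng.uniform(*log_ratio_range) * (1 if rng.random() < 0.5 else -1)
        rate_r = rate_total * np.exp(gamma) / (1.0 + np.exp(gamma))
        rate_l = rate_total - rate_r
        # clicks live on a 0.1-ms grid so serialisation round-trips exactly
        tr = np.unique(np.round(rng.uniform(0, T, rng.poisson(rate_r * T)), 4))
        tl = np.unique(np.round(rng.uniform(0, T, rng.poisson(rate_l * T)), 4))
        n_r, n_l = len(tr), len(tl)
        if n_r > n_l:
            rewarded = "R"
        elif n_l > n_r:
            rewarded = "L"
        else:
            rewarded = "R" if rng.random() < 0.5 else "L"
        trials.append(
            Trial(
                subject_id=subject_id,
                session_id=session_id,
                trial_index=i,
                n_bins=15,
                bin_ms=250.0,
                flash_times_left=[float(x) for x in tl],
                flash_times_right=[float(x) for x in tr],
                flash_durs_left=[0.0] * n_l,
                flash_durs_right=[0.0] * n_r,
                delay_s=0.0,
                choice=None,
                rewarded_side=rewarded,
                correct=None,
                jitter=True,
            )
        )
    return TrialTable(trials, validate=False)
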