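"""Model-free behavioral statistics.

Everything here works directly on trial tables with no fitted model:
choice-conditioned reverse correlation (the temporal weighting of
evidence), performance-vs-count and performance-vs-duration regressions
that dissociate pulse-indexed from time-indexed noise, ratio-invariance
curves, trial-history biases, and the flash-number-vs-flash-duration
dissociation on jittered stimuli.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.stats import norm

from .core import EmptyInputError, TrialTable
from .sdt import SigmaTable, p_choose_right

#: default minimum trials per analysis cell
MIN_CELL = 10


class InsufficientDataError(ValueError):
    pass


@dataclass
class RegressionResult:
    """A weighted linear regression summary."""

    slope: float
    slope_se: float
    intercept: float
    n_points: int
    units: str

    @property
    def z(self) -> float:
        return self.slope / self.slope_se if self.slope_se > 0 else math.inf

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        half = norm.ppf(0.5 + level / 2) * self.slope_se
        return (self.slope - half, self.slope + half)

    def to_dict(self) -> dict:
        return {
            "slope": float(self.slope),
            "slope_se": float(self.slope_se),
            "intercept": float(self.intercept),
            "n_points": int(self.n_points),
            "units": self.units,
        }


@dataclass
class RevCorrResult:
    """Choice-conditioned excess-flash curves per time bin."""

    bins: np.ndarray
    went_right_curve: np.ndarray
    went_left_curve: np.ndarray
    se_right: np.ndarray
    se_left: np.ndarray
    n_right_trials: int
    n_left_trials: int
    baseline: float


def _wls(x: np.ndarray, y: np.ndarray, w: np.ndarray | None, units: str) -> RegressionResult:
    X = sm.add_constant(np.asarray(x, float))
    model = sm.WLS(np.asarray(y, float), X, weights=np.ones_like(x, dtype=float) if w is None else np.asarray(w, float))
    res = model.fit()
    return RegressionResult(
        slope=float(res.params[1]),
        slope_se=float(res.bse[1]),
        intercept=float(res.params[0]),
        n_points=int(len(x)),
        units=units,
    )


def _bin_counts(table: TrialTable, n_bins: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(left, right) per-bin flash indicator matrices and bin width."""
    n = len(table)
    left = np.zeros((n, n_bins))
    right = np.zeros((n, n_bins))
    for i, t in enumerate(table):
        bin_s = t.bin_ms / 1000.0
        for x in t.flash_times_left:
            left[i, int(round(x / bin_s))] += 1
        for x in t.flash_times_right:
            right[i, int(round(x / bin_s))] += 1
    return left, right, np.arange(n_bins)


# -- reverse correlation --------------------------------------------------


def reverse_correlation(
    table: TrialTable,
    n_bins_required: int = 8,
    gamma: tuple[float, float] = (0.7, 0.3),
    min_trials: int = MIN_CELL,
    grouped: bool = False,
) -> RevCorrResult:
    """Psychophysical reverse correlation on fixed-geometry trials.

    Pools trials with exactly ``n_bins_required`` bins and the stated
    generative probabilities, computes the mean per-bin flash-count
    difference conditioned on the choice, and subtracts the expected
    difference (+(p_high-p_low) on correct trials, -(p_high-p_low) on
    errors, averaged over the choice group).  The went-left curve is
    negated so both curves read in units of excess right flashes.  A flat
    curve means early, middle and late pulses weigh equally on the choice.

    ``grouped=True`` computes per-subject curves and returns their mean
    and between-subject standard error.
    """
    p_high, p_low = gamma
    keep = [
        t
        for t in table
        if t.n_bins == n_bins_required
        and t.choice is not None
        and not np.isnan(t.p_high)
        and abs(t.p_high - p_high) < 1e-9
        and abs(t.p_low - p_low) < 1e-9
    ]
    if not keep:
        raise InsufficientDataError(
            f"no trials with n_bins={n_bins_required} and gamma={gamma}"
        )
    sub = TrialTable(keep, validate=False)
    if grouped:
        subjects = sorted({t.subject_id for t in sub})
        curves_r, curves_l = [], []
        base = []
        for s in subjects:
            part = TrialTable([t for t in sub if t.subject_id == s], validate=False)
            try:
                rc = reverse_correlation(part, n_bins_required, gamma, min_trials, grouped=False)
            except InsufficientDataError:
                continue
            curves_r.append(rc.went_right_curve)
            curves_l.append(rc.went_left_curve)
            base.append(rc.baseline)
        if not curves_r:
            raise InsufficientDataError("no subject passes the reverse-correlation filter")
        R = np.vstack(curves_r)
        L = np.vstack(curves_l)
        k = R.shape[0]
        return RevCorrResult(
            bins=np.arange(n_bins_required),
            went_right_curve=R.mean(0),
            went_left_curve=L.mean(0),
            se_right=R.std(0, ddof=1) / np.sqrt(k) if k > 1 else np.zeros(n_bins_required),
            se_left=L.std(0, ddof=1) / np.sqrt(k) if k > 1 else np.zeros(n_bins_required),
            n_right_trials=k,
            n_left_trials=k,
            baseline=float(np.mean(base)),
        )

    left, right, bins = _bin_counts(sub, n_bins_required)
    choice_r = np.array([t.choice == "R" for t in sub])
    correct = np.array([bool(t.correct) for t in sub])
    if choice_r.sum() < min_trials or (~choice_r).sum() < min_trials:
        raise InsufficientDataError("too few trials on one choice side")
    expected = np.where(correct, p_high - p_low, -(p_high - p_low))

    diff_r = (right - left)[choice_r]  # went right: R - L per bin
    diff_l = (left - right)[~choice_r]  # went left: L - R per bin
    base_r = expected[choice_r].mean()
    base_l = expected[~choice_r].mean()
    curve_r = diff_r.mean(0) - base_r
    curve_l = -(diff_l.mean(0) - base_l)
    se_r = diff_r.std(0, ddof=1) / np.sqrt(diff_r.shape[0])
    se_l = diff_l.std(0, ddof=1) / np.sqrt(diff_l.shape[0])
    return RevCorrResult(
        bins=bins,
        went_right_curve=curve_r,
        went_left_curve=curve_l,
        se_right=se_r,
        se_left=se_l,
        n_right_trials=int(choice_r.sum()),
        n_left_trials=int((~choice_r).sum()),
        baseline=float(base_r),
    )


# -- performance regressions ----------------------------------------------


def delta_performance_vs_flashes(table: TrialTable, min_cell: int = MIN_CELL) -> RegressionResult:
    """Slope of performance against total flash count at fixed difference.

    Within each |#R-#L| stratum, percent correct is computed per total
    flash count and centred on the stratum's weighted mean; the pooled
    points are regressed on the total count, weighted by trial counts.
    A negative slope means extra pulses *hurt* at fixed difference —
    the signature of count-indexed (not time-indexed) noise.
    """
    df = table.to_dataframe()
    df = df[df["choice"].notna()].copy()
    if df.empty:
        raise EmptyInputError("no completed trials")
    df["abs_diff"] = df["flash_diff"].abs()
    pts = (
        df.groupby(["abs_diff", "flash_total"])
        .agg(pct=("correct", lambda c: 100.0 * np.mean(c)), w=("correct", "size"))
        .reset_index()
    )
    pts = pts[pts["w"] >= min_cell]
    rows = []
    for _, grp in pts.groupby("abs_diff"):
        if len(grp) < 2:
            continue  # degenerate stratum: no variation in total count
        center = np.average(grp["pct"], weights=grp["w"])
        for _, r in grp.iterrows():
            rows.append((r["flash_total"], r["pct"] - center, r["w"]))
    if len(rows) < 3:
        raise InsufficientDataError("too few (difference, total) cells")
    x, y, w = map(np.array, zip(*rows))
    return _wls(x, y, w, units="% per flash")


def delta_performance_vs_duration(
    table: TrialTable, bin_ms: float = 50.0, min_cell: int = MIN_CELL
) -> RegressionResult:
    """Slope of performance against trial duration at fixed flash counts.

    Performance is centred within each (|#R-#L|, total) cell, then
    regressed on trial duration binned at ``bin_ms``; cells with a single
    duration bin contribute no points.  Near-zero slope means time in
    the trial adds no noise once the pulse counts are fixed.
    """
    df = table.to_dataframe()
    df = df[df["choice"].notna()].copy()
    if df.empty:
        raise EmptyInputError("no completed trials")
    df["abs_diff"] = df["flash_diff"].abs()
    df["dur_bin"] = np.floor(df["duration_s"] / (bin_ms / 1000.0)).astype(int)
    rows = []
    for _, cell in df.groupby(["abs_diff", "flash_total"]):
        pts = (
            cell.groupby("dur_bin")
            .agg(
                pct=("correct", lambda c: 100.0 * np.mean(c)),
                w=("correct", "size"),
                dur=("duration_s", "mean"),
            )
            .reset_index()
        )
        pts = pts[pts["w"] >= min_cell]
        if len(pts) < 2:
            continue
        center = np.average(pts["pct"], weights=pts["w"])
        for _, r in pts.iterrows():
            rows.append((r["dur"], r["pct"] - center, r["w"]))
    if len(rows) < 3:
        raise InsufficientDataError("no duration variation within count cells")
    x, y, w = map(np.array, zip(*rows))
    return _wls(x, y, w, units="% per s")


# -- ratio analysis -------------------------------------------------------


def ratio_analysis(table: TrialTable, sig: SigmaTable | None = None) -> dict:
    """Performance on trials grouped by low:high flash ratio and scale.

    Under pure scalar variability (sigma = k*n), performance depends on
    the counts only through their ratio, so points within a ratio group
    should lie on a horizontal line.  One-sided trials (low count 0) form
    their own group keyed ``"0:1"``.  If a sigma table is given, the
    model's predicted percent correct is attached per point.
    """
    df = table.to_dataframe()
    df = df[df["choice"].notna()].copy()
    if df.empty:
        raise EmptyInputError("no completed trials")
    low = np.minimum(df["n_left"], df["n_right"]).to_numpy()
    high = np.maximum(df["n_left"], df["n_right"]).to_numpy()
    correct = df["correct"].astype(bool).to_numpy()
    groups: dict[str, dict] = {}
    for lo, hi, corr in zip(low, high, correct):
        if hi == 0:
            continue  # nothing to discriminate
        if lo == 0:
            key, scale = "0:1", int(hi)
        else:
            g = math.gcd(int(lo), int(hi))
            key, scale = f"{lo // g}:{hi // g}", int(g)
        d = groups.setdefault(key, {})
        cell = d.setdefault(scale, {"n": 0, "k": 0, "low": int(lo), "high": int(hi)})
        cell["n"] += 1
        cell["k"] += int(corr)
    out = {}
    for key, cells in groups.items():
        pts = []
        for scale in sorted(cells):
            c = cells[scale]
            p = c["k"] / c["n"]
            se = math.sqrt(max(p * (1 - p), 1e-12) / c["n"])
            entry = {
                "scale": scale,
                "low": c["low"],
                "high": c["high"],
                "pct_correct": 100.0 * p,
                "ci95": (100.0 * (p - 1.96 * se), 100.0 * (p + 1.96 * se)),
                "n": c["n"],
            }
            if sig is not None:
                entry["model_pct"] = 100.0 * float(
                    p_choose_right(c["low"], c["high"], sig)
                )
            pts.append(entry)
        out[key] = pts
    return out


# -- trial history --------------------------------------------------------


def _binom_ci(k: int, n: int, exact: bool = False) -> tuple[float, float]:
    if n == 0:
        return (float("nan"), float("nan"))
    p = k / n
    if exact:
        from scipy.stats import beta

        lo = beta.ppf(0.025, k, n - k + 1) if k > 0 else 0.0
        hi = beta.ppf(0.975, k + 1, n - k) if k < n else 1.0
        return (float(lo), float(hi))
    se = math.sqrt(max(p * (1 - p), 1e-12) / n)
    return (p - 1.96 * se, p + 1.96 * se)


def history_bias(table: TrialTable, max_lag: int = 6, exact_ci: bool = False) -> dict:
    """Trial-history side biases: lag profile, persistence and additivity.

    For each lag l, computes P(the current choice matches the side chosen
    l trials back) separately for earlier trials that were rewarded vs
    errors, with binomial CIs.  The null for each probability is the
    *marginal* probability of choosing the matching side (averaged over
    the conditioning events), which is what a history-free observer
    produces at every lag.  Additivity is tested by comparing the
    observed repeat probability after runs of exactly m consecutive
    same-side rewards against the null plus the sum of the single-lag
    reward biases.
    """
    df = table.to_dataframe()
    if df["choice"].isna().any():
        raise EmptyInputError("table contains trials without choices")
    per_session = []
    for _, grp in df.groupby(["subject_id", "session_id"], sort=True):
        if not grp["trial_index"].is_monotonic_increasing:
            raise ValueError("sessions must be ordered by trial_index")
        choice = (grp["choice"] == "R").to_numpy()
        correct = grp["correct"].astype(bool).to_numpy()
        per_session.append((choice, correct))
    all_choices = np.concatenate([c for c, _ in per_session])
    p_right_marg = float(all_choices.mean())

    def _null(sides: np.ndarray) -> float:
        # marginal probability of choosing the side of each event, averaged
        return float(np.where(sides, p_right_marg, 1.0 - p_right_marg).mean())

    lag_rows = []
    for lag in range(1, max_lag + 1):
        same_r: list[np.ndarray] = []
        same_e: list[np.ndarray] = []
        sides_r: list[np.ndarray] = []
        sides_e: list[np.ndarray] = []
        for choice, correct in per_session:
            if len(choice) <= lag:
                continue
            prev_c = choice[:-lag]
            cur = choice[lag:]
            rew = correct[:-lag]
            same = cur == prev_c
            same_r.append(same[rew])
            sides_r.append(prev_c[rew])
            same_e.append(same[~rew])
            sides_e.append(prev_c[~rew])
        sr = np.concatenate(same_r) if same_r else np.array([], bool)
        se_ = np.concatenate(same_e) if same_e else np.array([], bool)
        nr, ne = sr.size, se_.size
        null_r = _null(np.concatenate(sides_r)) if nr else float("nan")
        null_e = _null(np.concatenate(sides_e)) if ne else float("nan")
        lag_rows.append(
            {
                "lag": lag,
                "p_same_after_reward": sr.mean() if nr else float("nan"),
                "ci_reward": _binom_ci(int(sr.sum()), nr, exact_ci),
                "n_reward": nr,
                "null_reward": null_r,
                "p_same_after_error": se_.mean() if ne else float("nan"),
                "ci_error": _binom_ci(int(se_.sum()), ne, exact_ci),
                "n_error": ne,
                "null_error": null_e,
            }
        )
    # at least m consecutive same-side rewards immediately before a trial
    # (the "at least" frame makes the additive single-lag prediction exact
    # up to the nonlinearity of the choice rule)
    run_obs: dict[int, list[int]] = {m: [] for m in range(1, max_lag + 1)}
    run_sides: dict[int, list[bool]] = {m: [] for m in range(1, max_lag + 1)}
    for choice, correct in per_session:
        n = len(choice)
        for t in range(1, n):
            if not correct[t - 1]:
                continue
            side = choice[t - 1]
            m = 0
            while t - 1 - m >= 0 and choice[t - 1 - m] == side and correct[t - 1 - m]:
                m += 1
                run_obs[m].append(int(choice[t] == side))
                run_sides[m].append(bool(side))
                if m >= max_lag:
                    break
    biases = {
        r["lag"]: r["p_same_after_reward"] - r["null_reward"] for r in lag_rows
    }
    runs = []
    for m in range(1, max_lag + 1):
        obs = run_obs[m]
        if not obs:
            continue
        k, n = int(np.sum(obs)), len(obs)
        null_m = _null(np.asarray(run_sides[m], bool))
        runs.append(
            {
                "run_length": m,
                "p_same": k / n,
                "ci": _binom_ci(k, n, exact_ci),
                "n": n,
                "null": null_m,
                "predicted_additive": float(
                    null_m + sum(biases[l] for l in range(1, m + 1) if l in biases)
                ),
            }
        )
    return {"lags": lag_rows, "runs": runs}


def history_kernel_regression(table: TrialTable, max_lag: int = 6) -> list[dict]:
    """Probit regression of choice on signed past-outcome regressors.

    For each lag l two regressors are built: the signed side (+1 right,
    -1 left) of the choice l trials back if it was rewarded (else 0), and
    the same if it was an error.  Because all lags enter jointly, the
    fitted coefficients recover the observer's additive kernel directly,
    without the chain contamination that inflates marginal repeat
    probabilities at long lags.  Returns one record per (lag, outcome)
    with coefficient, standard error and z.
    """
    df = table.to_dataframe()
    ys, Xs = [], []
    for _, grp in df.groupby(["subject_id", "session_id"], sort=True):
        choice = np.where((grp["choice"] == "R").to_numpy(), 1.0, -1.0)
        correct = grp["correct"].astype(bool).to_numpy()
        n = len(choice)
        if n <= max_lag:
            continue
        cols = []
        for lag in range(1, max_lag + 1):
            prev = choice[max_lag - lag : n - lag]
            rew = correct[max_lag - lag : n - lag]
            cols.append(np.where(rew, prev, 0.0))
            cols.append(np.where(~rew, prev, 0.0))
        Xs.append(np.column_stack(cols))
        ys.append((choice[max_lag:] > 0).astype(float))
    if not Xs:
        raise InsufficientDataError("sessions too short for the requested max_lag")
    X = sm.add_constant(np.vstack(Xs))
    y = np.concatenate(ys)
    res = sm.GLM(y, X, family=sm.families.Binomial(link=sm.families.links.Probit())).fit()
    out = []
    for lag in range(1, max_lag + 1):
        for j, outcome in enumerate(("reward", "error")):
            idx = 1 + 2 * (lag - 1) + j
            out.append(
                {
                    "lag": lag,
                    "outcome": outcome,
                    "coef": float(res.params[idx]),
                    "se": float(res.bse[idx]),
                    "z": float(res.params[idx] / res.bse[idx]),
                }
            )
    return out


# -- flash number vs duration --------------------------------------------


def duration_vs_number(table: TrialTable) -> dict:
    """Dissociate count integration from duration integration.

    On jittered-duration trials with equal flash counts, only the summed
    flash durations differ between sides; the slope of choice on the
    normalised duration difference (durR-durL)/(durR+durL) restricted to
    those trials is compared against (a) zero (count integration) and
    (b) the all-trials duration slope (the reference a duration
    integrator would produce).  Returns the three regressions and a
    verdict string.
    """
    jit = [t for t in table if t.jitter and t.choice is not None]
    if not jit:
        raise InsufficientDataError("no jittered trials with choices")
    dur_l = np.array([sum(t.flash_durs_left) for t in jit])
    dur_r = np.array([sum(t.flash_durs_right) for t in jit])
    tot = dur_l + dur_r
    keep = tot > 0
    x_dur = np.where(keep, (dur_r - dur_l) / np.where(keep, tot, 1.0), 0.0)
    n_l = np.array([t.n_left for t in jit])
    n_r = np.array([t.n_right for t in jit])
    n_tot = n_l + n_r
    x_num = np.where(n_tot > 0, (n_r - n_l) / np.maximum(n_tot, 1), 0.0)
    went_r = np.array([t.choice == "R" for t in jit], dtype=float) * 100.0

    all_dur = _wls(x_dur[keep], went_r[keep], None, units="% per unit duration diff")
    all_num = _wls(x_num[n_tot > 0], went_r[n_tot > 0], None, units="% per unit count diff")
    zero = (n_l == n_r) & keep
    if zero.sum() < MIN_CELL:
        raise InsufficientDataError("no equal-count trials with duration differences")
    zero_diff = _wls(x_dur[zero], went_r[zero], None, units="% per unit duration diff")

    z_vs_zero = zero_diff.z
    z_vs_dur = (zero_diff.slope - all_dur.slope) / math.sqrt(
        zero_diff.slope_se**2 + all_dur.slope_se**2
    )
    # count integration: the equal-count slope is consistent with zero and
    # inconsistent with the duration reference; duration integration: the
    # slope is significantly positive (it may exceed the all-trials
    # reference, which is attenuated by saturation at extreme ratios)
    if abs(z_vs_zero) < 2 and abs(z_vs_dur) > 2:
        verdict = "number"
    elif z_vs_zero > 2:
        verdict = "duration"
    else:
        verdict = "ambiguous"
    return {
        "equal_count_duration_slope": zero_diff,
        "duration_model_slope": all_dur,
        "flash_model_slope": all_num,
        "z_vs_zero": float(z_vs_zero),
        "z_vs_duration_model": float(z_vs_dur),
        "verdict": verdict,
    }
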