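"""Eight two-parameter accumulator-noise models and their ranking.

Each model predicts the choice on a trial from a decision variable
a ~ N(#R - #L, sigma_eff^2); they differ in three binary assumptions:

* arity     — single accumulator (noise indexed by the count *difference*)
              vs dual accumulators (noise indexed by the count *total*);
* sampling  — static (noise depends only on the final accumulator value)
              vs sequential (an independent noise draw is added at each
              flash, scaled by the accumulator value at that flash, so
              variances sum along the deterministic accumulation path);
* law       — SV (sigma = b1*n + b2) vs LV (sigma^2 = b1*n + b2).

All eight have exactly two free parameters (b1, b2 >= 0), so best-fit
log-likelihoods are directly comparable.  The sequential path uses the
deterministic (expected) running count, which keeps the likelihood a
closed-form Gaussian; simultaneous left/right flashes are processed
left-then-right.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import ndtr

from .core import EmptyInputError, Trial, TrialTable
from .sdt import EPS
from .scaling import permutation_compare

#: id -> (arity, sampling, law)
VARIANT_SPECS: dict[str, tuple[str, str, str]] = {
    "a": ("single", "static", "SV"),
    "b": ("dual", "static", "SV"),
    "c": ("single", "static", "LV"),
    "d": ("dual", "static", "LV"),
    "e": ("single", "sequential", "SV"),
    "f": ("dual", "sequential", "SV"),
    "g": ("single", "sequential", "LV"),
    "h": ("dual", "sequential", "LV"),
}

_BETA_BOUNDS = ((0.0, 50.0), (0.0, 50.0))
_STARTS = ((0.3, 0.1), (0.1, 0.5), (0.6, 0.05), (0.05, 2.0))


class FitError(RuntimeError):
    pass


@dataclass
class VariantModel:
    """One of the eight accumulator-noise models."""

    id: str
    beta1: float = np.nan
    beta2: float = np.nan
    loglik: float = np.nan
    fitted: bool = False

    def __post_init__(self) -> None:
        if self.id not in VARIANT_SPECS:
            raise ValueError(f"unknown variant id {self.id!r}")

    @property
    def arity(self) -> str:
        return VARIANT_SPECS[self.id][0]

    @property
    def sampling(self) -> str:
        return VARIANT_SPECS[self.id][1]

    @property
    def law(self) -> str:
        return VARIANT_SPECS[self.id][2]

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "arity": self.arity,
            "sampling": self.sampling,
            "law": self.law,
            "beta1": float(self.beta1),
            "beta2": float(self.beta2),
            "loglik": float(self.loglik),
        }


# -- sufficient statistics ------------------------------------------------


def _merged_signs(trial: Trial) -> np.ndarray:
    """+1/-1 per flash of the merged stream, time-sorted (L before R on ties)."""
    events = [(t, -1) for t in trial.flash_times_left] + [(t, +1) for t in trial.flash_times_right]
    events.sort(key=lambda e: (e[0], e[1]))
    return np.array([s for _, s in events], dtype=float)


def path_stats(trial: Trial) -> dict:
    """Per-trial sufficient statistics for every variant's sigma_eff.

    For the sequential models the accumulator value *just after* flash i
    along the deterministic path sets the noise scale of that flash.
    Single accumulator: v_i = |running R-L| along the merged stream.
    Dual accumulators: each flash updates its own side's accumulator, so
    the right flashes see v = 1..n_R and the left flashes v = 1..n_L
    (the per-side running counts).  sigma_eff^2 = sum_i sigma(v_i)^2
    needs only sum(v), sum(v^2) and the flash count.
    """
    signs = _merged_signs(trial)
    run = np.cumsum(signs)
    v_single = np.abs(run)
    m = signs.size
    nr, nl = trial.n_right, trial.n_left

    def _tri(n):  # 1 + 2 + ... + n
        return n * (n + 1) / 2

    def _sq(n):  # 1^2 + 2^2 + ... + n^2
        return n * (n + 1) * (2 * n + 1) / 6

    return {
        "d": float(trial.flash_diff),
        "m": float(m),
        "abs_d": float(abs(trial.flash_diff)),
        "s1_single": float(v_single.sum()),
        "s2_single": float((v_single**2).sum()),
        "s1_dual": float(_tri(nr) + _tri(nl)),
        "s2_dual": float(_sq(nr) + _sq(nl)),
    }


def table_stats(table: TrialTable) -> dict[str, np.ndarray]:
    """Vectorised :func:`path_stats` plus the choice indicator."""
    rows = [path_stats(t) for t in table]
    out = {k: np.array([r[k] for r in rows]) for k in rows[0]}
    out["chose_right"] = np.array([t.choice == "R" for t in table], dtype=float)
    return out


def effective_variance(stats: dict, model: VariantModel) -> np.ndarray:
    """sigma_eff^2 per trial for ``model`` given :func:`table_stats` output."""
    b1, b2 = model.beta1, model.beta2
    if model.sampling == "static":
        n = stats["abs_d"] if model.arity == "single" else stats["m"]
        if model.law == "SV":
            return (b1 * n + b2) ** 2
        return b1 * n + b2
    s1 = stats["s1_single"] if model.arity == "single" else stats["s1_dual"]
    s2 = stats["s2_single"] if model.arity == "single" else stats["s2_dual"]
    m = stats["m"]
    if model.law == "SV":
        # sum over flashes of (b1*v + b2)^2
        return b1**2 * s2 + 2 * b1 * b2 * s1 + b2**2 * m
    # LV: sum of (b1*v + b2)
    return b1 * s1 + b2 * m


def _p_right_from_stats(stats: dict, model: VariantModel) -> np.ndarray:
    var = effective_variance(stats, model)
    d = stats["d"]
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(var > 0, d / np.sqrt(np.maximum(var, 1e-300)),
                     np.where(d == 0, 0.0, np.sign(d) * np.inf))
    return np.clip(ndtr(z), EPS, 1.0 - EPS)


def variant_p_right(trial: Trial, model: VariantModel) -> float:
    """P(choose right) for one trial under a variant model.

    Zero effective noise with equal counts returns 0.5 by convention.
    """
    stats = {k: np.array([v]) for k, v in path_stats(trial).items()}
    return float(_p_right_from_stats(stats, model)[0])


# -- fitting and ranking --------------------------------------------------


def _nll(beta, stats, model) -> float:
    model.beta1, model.beta2 = beta
    p = _p_right_from_stats(stats, model)
    r = stats["chose_right"]
    return float(-(r * np.log(p) + (1 - r) * np.log1p(-p)).sum())


def fit_variant(table: TrialTable, id: str, stats: dict | None = None) -> VariantModel:
    """MLE of (beta1, beta2) for one variant by multi-start bounded search."""
    if len(table) == 0:
        raise EmptyInputError("empty table")
    if stats is None:
        stats = table_stats(table)
    model = VariantModel(id)
    best = None
    for x0 in _STARTS:
        res = minimize(_nll, x0, args=(stats, model), method="L-BFGS-B", bounds=_BETA_BOUNDS)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise FitError(f"variant {id}: optimisation failed")
    return VariantModel(id, float(best.x[0]), float(best.x[1]), -float(best.fun), fitted=True)


def rank_variants(
    table: TrialTable,
    n_boot: int = 100,
    n_perm: int = 1000,
    seed: int | None = None,
    ids: tuple[str, ...] = tuple(VARIANT_SPECS),
) -> dict:
    """Bootstrap log-likelihood distributions for every variant and rank.

    ``n_boot`` surrogate tables are drawn by resampling trials with
    replacement; each variant is refit to each surrogate and its best-fit
    log-likelihood recorded.  Variants are ranked by mean bootstrap
    log-likelihood and the winner is compared pairwise against every
    other variant with the permutation test on distribution means.
    """
    stats = table_stats(table)
    n = len(table)
    rng = np.random.default_rng(seed)
    full_fits = {i: fit_variant(table, i, stats=stats) for i in ids}
    dists: dict[str, list[float]] = {i: [] for i in ids}
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boot_stats = {k: v[idx] for k, v in stats.items()}
        for i in ids:
            model = VariantModel(i)
            warm = (full_fits[i].beta1, full_fits[i].beta2)
            res = minimize(_nll, warm, args=(boot_stats, model), method="L-BFGS-B", bounds=_BETA_BOUNDS)
            dists[i].append(-float(res.fun))
    means = {i: float(np.mean(dists[i])) for i in ids}
    order = sorted(ids, key=lambda i: -means[i])
    winner = order[0]
    pvals = {}
    for i in ids:
        if i == winner:
            continue
        p, diff, _ = permutation_compare(
            np.asarray(dists[winner]), np.asarray(dists[i]),
            n_perm=n_perm, seed=int(rng.integers(2**31)),
        )
        # every variant is fit to the *same* surrogate tables, so the
        # per-resample likelihood differences are paired; a sign-flip
        # permutation on them cancels the shared resampling noise that the
        # pooled-split test leaves in
        paired = np.asarray(dists[winner]) - np.asarray(dists[i])
        signs = rng.choice([-1.0, 1.0], size=(n_perm, paired.size))
        null = (signs * paired).mean(axis=1)
        p_paired = (int(np.sum(np.abs(null) >= abs(paired.mean()))) + 1.0) / (n_perm + 1.0)
        pvals[i] = {"p": p, "p_paired": p_paired, "observed_diff": diff}
    # flag under-powered rankings: overlapping winner/runner-up distributions
    runner = order[1] if len(order) > 1 else None
    overlap = None
    if runner is not None:
        w, r = np.asarray(dists[winner]), np.asarray(dists[runner])
        overlap = bool(np.percentile(w, 2.5) <= np.percentile(r, 97.5))
    return {
        "ranking": order,
        "winner": winner,
        "mean_loglik": means,
        "full_fits": {i: full_fits[i].to_dict() for i in ids},
        "pairwise_vs_winner": pvals,
        "winner_overlaps_runner_up": overlap,
        "dists": {i: np.asarray(d) for i, d in dists.items()},
    }
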