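"""Adaptation-corrected click-train reanalysis.

High-rate auditory click trains drive strong sensory adaptation: each
click's effective magnitude is the current adaptation state C, which is
multiplied by phi at every click (phi < 1 depresses, phi > 1 facilitates)
and relaxes back to 1 between clicks with time constant tau_phi.  The
per-side sums of these magnitudes — rounded to the nearest integer so the
count-indexed noise model applies — are the "effective" click numbers
handed to the signal-detection fit, where the offset noise laws
(sigma = k0 + k*n vs sigma^2 = k0 + k*n) are compared.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import TrialTable
from .scaling import bootstrap_r2, fit_law, permutation_compare
from .sdt import SigmaTable, fit_sigma_from_counts
from .synthetic import generate_click_trains


@dataclass(frozen=True)
class AdaptationParams:
    """Per-event multiplicative adaptation with exponential recovery."""

    phi: float = 0.5
    tau_phi: float = 0.2
    C0: float = 1.0

    def __post_init__(self) -> None:
        if self.tau_phi <= 0:
            raise ValueError("tau_phi must be positive")
        if self.phi < 0:
            raise ValueError("phi must be non-negative")


def _round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero."""
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def effective_counts(
    click_times_left,
    click_times_right,
    p: AdaptationParams,
    shared_state: bool = True,
) -> tuple[int, int, float, float]:
    """Effective per-side click numbers after adaptation.

    Walks the merged, time-sorted click stream: between events the state
    relaxes as C(t) = 1 - (1 - C) * exp(-dt/tau_phi); at each event the
    click contributes its pre-update C to its side's sum and C is scaled
    by phi.  By default one state is shared across sides (both event
    streams drive the same adaptation); ``shared_state=False`` keeps an
    independent state per side.  Returns (eff_left, eff_right, raw_left,
    raw_right) with the integer fields rounded half-away-from-zero.
    """
    tl = np.asarray(click_times_left, float)
    tr = np.asarray(click_times_right, float)
    for arr, side in ((tl, "left"), (tr, "right")):
        if arr.size > 1 and np.any(np.diff(arr) < 0):
            raise ValueError(f"{side} click times must be sorted")

    def _walk(events: list[tuple[float, int]]) -> tuple[float, float]:
        C = p.C0
        t_prev = None
        sums = [0.0, 0.0]
        for t, side in events:
            if t_prev is not None:
                C = 1.0 - (1.0 - C) * np.exp(-(t - t_prev) / p.tau_phi)
            sums[side] += C
            C *= p.phi
            t_prev = t
        return sums[0], sums[1]

    if shared_state:
        merged = sorted([(t, 0) for t in tl] + [(t, 1) for t in tr])
        raw_l, raw_r = _walk(merged)
    else:
        raw_l, _ = _walk([(t, 0) for t in tl])
        _, raw_r = _walk([(t, 1) for t in tr])
    return _round_half_away(raw_l), _round_half_away(raw_r), raw_l, raw_r


def effective_counts_table(
    table: TrialTable, p: AdaptationParams, shared_state: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Rounded effective (left, right) counts for every trial of a table."""
    eff_l = np.empty(len(table), int)
    eff_r = np.empty(len(table), int)
    for i, t in enumerate(table):
        eff_l[i], eff_r[i], _, _ = effective_counts(
            t.flash_times_left, t.flash_times_right, p, shared_state
        )
    return eff_l, eff_r


@dataclass
class ClicksFit:
    """Result bundle of the clicks pipeline."""

    sigma_table: SigmaTable
    sv_offset: object
    lv_offset: object
    p_sv_vs_lv: float
    mean_r2_sv: float
    mean_r2_lv: float

    def to_dict(self) -> dict:
        return {
            "sigma_table": self.sigma_table.to_dict(),
            "sv_offset": self.sv_offset.to_dict(),
            "lv_offset": self.lv_offset.to_dict(),
            "p_sv_vs_lv": float(self.p_sv_vs_lv),
            "mean_r2_sv": float(self.mean_r2_sv),
            "mean_r2_lv": float(self.mean_r2_lv),
        }


def fit_clicks_sdt(
    table: TrialTable,
    p: AdaptationParams,
    n_boot: int = 1000,
    seed: int | None = None,
    n_perm: int = 1000,
    shared_state: bool = True,
) -> ClicksFit:
    """Adaptation-corrected signal-detection fit plus offset-law comparison.

    Computes effective counts per trial, fits the per-count sigma vector
    by MLE, fits the SV-with-offset and LV-with-offset laws, and compares
    their bootstrapped r^2 distributions with the permutation test.
    """
    rng = np.random.default_rng(seed)
    eff_l, eff_r = effective_counts_table(table, p, shared_state)
    chose_right = np.array([t.choice == "R" for t in table])
    n_max = int(max(eff_l.max(), eff_r.max()))
    sig = fit_sigma_from_counts(
        eff_l, eff_r, chose_right, n_max, n_boot=n_boot, seed=int(rng.integers(2**31))
    )
    sv = fit_law(sig, "SV_OFFSET")
    lv = fit_law(sig, "LV_OFFSET")

    class _CountTable:
        def __len__(self):
            return len(eff_l)

        def counts_choices(self):
            return eff_l, eff_r, chose_right

    shim = _CountTable()
    dist_sv = bootstrap_r2(shim, "SV_OFFSET", n_boot=n_boot, seed=int(rng.integers(2**31)), n_max=n_max)  # type: ignore[arg-type]
    dist_lv = bootstrap_r2(shim, "LV_OFFSET", n_boot=n_boot, seed=int(rng.integers(2**31)), n_max=n_max)  # type: ignore[arg-type]
    p_val, _, _ = permutation_compare(dist_sv, dist_lv, n_perm=n_perm, seed=int(rng.integers(2**31)))
    return ClicksFit(sig, sv, lv, p_val, float(dist_sv.mean()), float(dist_lv.mean()))


def simulate_clicks_cohort(
    n_trials: int,
    adaptation: AdaptationParams,
    k0: float = 2.0,
    k: float = 0.3,
    seed: int | None = None,
    lapse: float = 0.0,
    **train_kw,
) -> TrialTable:
    """Synthetic click cohort whose observer sees effective counts.

    Click trains are Poisson; the observer's estimate of each side is
    N(n_eff, (k0 + k*n_eff)^2) on the *rounded* effective counts under
    the given adaptation — the generative twin of the offset-SV model
    that :func:`fit_clicks_sdt` should recover.
    """
    rng = np.random.default_rng(seed)
    table = generate_click_trains(n_trials, rng=rng, **train_kw)
    eff_l, eff_r = effective_counts_table(table, adaptation)
    sig_l = k0 + k * eff_l
    sig_r = k0 + k * eff_r
    a = (eff_r - eff_l) + np.sqrt(sig_l**2 + sig_r**2) * rng.standard_normal(len(table))
    coin = rng.random(len(table)) < 0.5
    choice = np.where(a > 0, "R", np.where(a < 0, "L", np.where(coin, "R", "L")))
    if lapse > 0:
        mask = rng.random(len(table)) < lapse
        lc = rng.random(len(table)) < 0.5
        choice = np.where(mask, np.where(lc, "R", "L"), choice)
    for t, c in zip(table.trials, choice):
        t.choice = str(c)
        t.correct = t.choice == t.rewarded_side
    return table
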