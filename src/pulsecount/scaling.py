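"""Noise-scaling laws and their comparison.

Three hypotheses about how the noise standard deviation grows with the
pulse count n are fit to a fitted sigma table by weighted least squares:

* SV  (scalar variability):   sigma_n = k * n          (Weber-like)
* LV  (linear variance):      sigma_n^2 = k * n        (diffusion-like)
* SUB (subitizing + SV):      sigma_n = 0 for n <= c, else k * n

plus offset variants SV_OFFSET (sigma = k0 + k*n) and LV_OFFSET
(sigma^2 = k0 + k*n) used for click-train data.  All fits are weighted by
the number of trials contributing to each count, and r^2 is always
computed in sigma space so the laws are compared on a common scale.

Discrimination between laws uses bootstrap distributions of r^2
(resampling trials, refitting the sigma table, refitting the law) and a
nonparametric permutation test on the difference of distribution means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import TrialTable
from .sdt import SigmaTable, fit_sigma_table, _cells, _fit_sigma_cells

LAWS = ("SV", "LV", "SUB_SV", "SV_OFFSET", "LV_OFFSET")


class InsufficientDataError(ValueError):
    """Fewer than three defined sigma points with positive weight."""


@dataclass
class ScalingFit:
    """One fitted noise-scaling law."""

    law: str
    k: float
    k0: float
    c: int | None
    r2: float
    n_points: int
    weights: np.ndarray

    def predict(self, n) -> np.ndarray:
        n = np.asarray(n, float)
        if self.law in ("SV", "SV_OFFSET"):
            s = self.k0 + self.k * n
        elif self.law in ("LV", "LV_OFFSET"):
            s = np.sqrt(np.maximum(self.k0 + self.k * n, 0.0))
        elif self.law == "SUB_SV":
            s = np.where(n <= self.c, 0.0, self.k * n)
        else:  # pragma: no cover
            raise ValueError(self.law)
        return s

    def to_dict(self) -> dict:
        return {
            "law": self.law,
            "k": float(self.k),
            "k0": float(self.k0),
            "c": None if self.c is None else int(self.c),
            "r2": float(self.r2),
            "n_points": int(self.n_points),
        }


def _wls(x: np.ndarray, y: np.ndarray, w: np.ndarray, intercept: bool):
    """Weighted least squares of y on x; returns (slope, intercept)."""
    if intercept:
        X = np.column_stack([x, np.ones_like(x)])
    else:
        X = x[:, None]
    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    return (float(beta[0]), float(beta[1]) if intercept else 0.0)


def _weighted_r2(sigma: np.ndarray, pred: np.ndarray, w: np.ndarray) -> float:
    mean = np.average(sigma, weights=w)
    ss_res = np.sum(w * (sigma - pred) ** 2)
    ss_tot = np.sum(w * (sigma - mean) ** 2)
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else -np.inf
    return float(1.0 - ss_res / ss_tot)


def fit_law(sig: SigmaTable, law: str, force_origin: bool = True) -> ScalingFit:
    """Weighted LS fit of one scaling law to a sigma table.

    SV/LV/SUB_SV are constrained through the origin unless
    ``force_origin=False`` (which turns them into their offset variants);
    r^2 is computed in sigma space with the same trial-count weights used
    for the fit.  The subitizing cutoff c is chosen from {3, 4} by best r^2.
    """
    law = law.upper()
    if law not in LAWS:
        raise ValueError(f"unknown law {law!r}")
    defined = sig.defined() & (sig.weights > 0)
    n = np.nonzero(defined)[0].astype(float)
    s = sig.sigma[defined]
    w = sig.weights[defined]
    if n.size < 3:
        raise InsufficientDataError(f"only {n.size} defined sigma points")
    intercept = law.endswith("_OFFSET") or not force_origin

    if law == "SUB_SV":
        best = None
        for c in (3, 4):
            mask = n > c
            if mask.sum() < 2:
                continue
            k, _ = _wls(n[mask], s[mask], w[mask], intercept=False)
            k = max(k, 0.0)
            pred = np.where(n <= c, 0.0, k * n)
            r2 = _weighted_r2(s, pred, w)
            if best is None or r2 > best.r2:
                best = ScalingFit("SUB_SV", k, 0.0, c, r2, int(n.size), w)
        if best is None:
            raise InsufficientDataError("too few points above the subitizing cutoff")
        return best

    if law.startswith("SV"):
        k, k0 = _wls(n, s, w, intercept)
        k = max(k, 0.0)
        pred = k0 + k * n
    else:  # LV in variance space, reported in sigma space
        k, k0 = _wls(n, s**2, w, intercept)
        k = max(k, 0.0)
        pred = np.sqrt(np.maximum(k0 + k * n, 0.0))
    r2 = _weighted_r2(s, pred, w)
    name = law if intercept == law.endswith("_OFFSET") else law + "_OFFSET"
    return ScalingFit(name, k, k0, None, r2, int(n.size), w)


def bootstrap_r2(
    table: TrialTable,
    law: str,
    n_boot: int = 1000,
    seed: int | None = None,
    n_max: int | None = None,
    force_origin: bool = True,
) -> np.ndarray:
    """Bootstrap distribution of the law's weighted r^2.

    Each iteration resamples trials with replacement, refits the sigma
    table by MLE, refits the law, and records r^2.  Failed inner fits are
    skipped (the returned vector may be shorter than ``n_boot``; a count
    of skips is attached as ``.skipped``).
    """
    nl, nr, right = table.counts_choices()
    if n_max is None:
        n_max = int(max(nl.max(), nr.max()))
    cl, cr, k_right, k_tot = _cells(nl, nr, right, n_max)
    # full-data fit provides the warm start for every resample
    starts = [np.maximum(k * np.arange(n_max + 1, dtype=float), 0.05) for k in (0.1, 0.3, 0.8)]
    sigma_full, _ = _fit_sigma_cells(cl, cr, k_right, k_tot, n_max, starts)
    warm = [np.nan_to_num(sigma_full, nan=0.05)] + starts[:2]

    rng = np.random.default_rng(seed)
    n_trials = int(k_tot.sum())
    cat_p = np.concatenate([k_right, k_tot - k_right]) / n_trials
    out = []
    skipped = 0
    for _ in range(n_boot):
        draw = rng.multinomial(n_trials, cat_p)
        r_b = draw[: len(k_tot)].astype(float)
        t_b = r_b + draw[len(k_tot):]
        keep = t_b > 0
        try:
            s_b, _ = _fit_sigma_cells(cl[keep], cr[keep], r_b[keep], t_b[keep], n_max, warm)
            w_b = np.zeros(n_max + 1)
            np.add.at(w_b, cl[keep], t_b[keep])
            np.add.at(w_b, cr[keep], t_b[keep])
            sig_b = SigmaTable.from_sigma(s_b, w_b)
            out.append(fit_law(sig_b, law, force_origin=force_origin).r2)
        except Exception:
            skipped += 1
    bootstrap_r2.last_skipped = skipped  # type: ignore[attr-defined]
    return np.asarray(out)


def permutation_compare(
    dist_a: np.ndarray,
    dist_b: np.ndarray,
    n_perm: int = 1000,
    seed: int | None = None,
    alternative: str = "two-sided",
) -> tuple[float, float, np.ndarray]:
    """Permutation test on the difference of distribution means.

    Pools the two bootstrap distributions, repeatedly splits the pool at
    random into two groups of the original sizes rounded to equal halves
    (odd pools give the extra draw to one group at random), and compares
    the observed mean difference against the null sample.  Returns
    (p_value, observed_diff, null_sample); p uses add-one smoothing.
    ``alternative`` is "two-sided" or "greater" (mean(a) > mean(b)).
    """
    a = np.asarray(dist_a, float)
    b = np.asarray(dist_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty r2 distribution")
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    observed = float(a.mean() - b.mean())
    pool = np.concatenate([a, b])
    rng = np.random.default_rng(seed)
    half = pool.size // 2
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(pool.size)
        cut = half + (rng.integers(2) if pool.size % 2 else 0)
        null[i] = pool[perm[:cut]].mean() - pool[perm[cut:]].mean()
    if alternative == "two-sided":
        count = int(np.sum(np.abs(null) >= abs(observed)))
    elif alternative == "greater":
        count = int(np.sum(null >= observed))
    else:
        raise ValueError("alternative must be 'two-sided' or 'greater'")
    p = (count + 1.0) / (n_perm + 1.0)
    return p, observed, null


def classify_scaling(
    table: TrialTable,
    laws: tuple[str, ...] = ("SV", "LV", "SUB_SV"),
    n_boot: int = 100,
    n_perm: int = 1000,
    seed: int | None = None,
    n_max: int | None = None,
) -> dict:
    """Full discrimination pipeline: bootstrap r^2 per law, pick the law
    with the highest mean, and report pairwise permutation p-values of the
    winner against each alternative."""
    rng = np.random.default_rng(seed)
    dists = {
        law: bootstrap_r2(table, law, n_boot=n_boot, seed=int(rng.integers(2**31)), n_max=n_max)
        for law in laws
    }
    means = {law: float(d.mean()) for law, d in dists.items()}
    winner = max(means, key=means.get)
    pvals = {}
    for law in laws:
        if law == winner:
            continue
        p, diff, _ = permutation_compare(
            dists[winner], dists[law], n_perm=n_perm, seed=int(rng.integers(2**31))
        )
        pvals[law] = {"p": p, "observed_diff": diff}
    return {"winner": winner, "mean_r2": means, "pairwise_vs_winner": pvals, "dists": dists}
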