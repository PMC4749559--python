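"""Signal-detection model of flash-count discrimination.

The subject's estimate of the number of pulses on each side is modelled as
a Gaussian random variable with mean equal to the true count ``n`` and a
free per-count standard deviation ``sigma_n``; the choice is the side with
the larger draw.  The probability of choosing right on a trial with counts
(n_L, n_R) is therefore

    P(R) = Phi( (n_R - n_L) / sqrt(sigma_{n_R}^2 + sigma_{n_L}^2) )

The full vector sigma_0..sigma_N is fit to the observed choices by maximum
likelihood; confidence intervals come from refitting bootstrap resamples
of the trials.  Because the likelihood depends on the data only through
the contingency table over (n_L, n_R, choice), fitting and bootstrapping
are performed on that table, which makes them cheap at any trial count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import ndtr

from .core import EmptyInputError, TrialTable

#: probability clip for likelihood stability
EPS = 1e-12
#: box constraints for the per-count noise parameters
SIGMA_LO, SIGMA_HI = 1e-3, 50.0
#: log-spaced initial slopes for multi-start optimisation
_START_SLOPES = (0.05, 0.15, 0.3, 0.6, 1.2)


class FitError(RuntimeError):
    """The optimiser failed to converge on the full data after all restarts."""


@dataclass
class SigmaTable:
    """Fitted per-count noise magnitudes with bootstrap uncertainty.

    ``sigma[n]`` is the full-data MLE of the noise standard deviation for
    count ``n`` (NaN where the count was never observed); ``boot_mean``
    is the mean over bootstrap refits, reported alongside but never
    conflated with the MLE.  ``weights[n]`` counts how many times count
    ``n`` occurred across trials (both sides pooled).
    """

    sigma: np.ndarray
    n_max: int
    ci_low: np.ndarray
    ci_high: np.ndarray
    weights: np.ndarray
    loglik: float
    boot_mean: np.ndarray
    n_boot: int
    seed: int | None

    def defined(self) -> np.ndarray:
        """Boolean mask of counts with a defined (observed) sigma."""
        return ~np.isnan(self.sigma)

    def to_dict(self) -> dict:
        return {
            "sigma": [None if np.isnan(s) else float(s) for s in self.sigma],
            "n_max": int(self.n_max),
            "ci_low": [None if np.isnan(s) else float(s) for s in self.ci_low],
            "ci_high": [None if np.isnan(s) else float(s) for s in self.ci_high],
            "weights": [int(w) for w in self.weights],
            "loglik": float(self.loglik),
            "boot_mean": [None if np.isnan(s) else float(s) for s in self.boot_mean],
            "n_boot": int(self.n_boot),
            "seed": self.seed,
        }

    @classmethod
    def from_sigma(cls, sigma, weights=None) -> "SigmaTable":
        """Build a table from an explicit sigma vector (e.g. a known truth)."""
        sigma = np.asarray(sigma, float)
        n_max = len(sigma) - 1
        w = np.ones_like(sigma) if weights is None else np.asarray(weights, float)
        nan = np.full_like(sigma, np.nan)
        return cls(sigma, n_max, nan.copy(), nan.copy(), w, float("nan"), nan.copy(), 0, None)


# -- the per-trial choice probability ------------------------------------


def p_choose_right(n_left, n_right, sig: SigmaTable | np.ndarray):
    """Probability of a rightward choice for counts (n_left, n_right).

    Accepts scalars or arrays; ``sig`` may be a SigmaTable or a raw sigma
    vector.  When both sigmas are zero the probability is the step
    function of the count difference (0.5 at equality).  The result is
    clipped to [EPS, 1-EPS].
    """
    sigma = sig.sigma if isinstance(sig, SigmaTable) else np.asarray(sig, float)
    nl = np.asarray(n_left, dtype=int)
    nr = np.asarray(n_right, dtype=int)
    if np.any(nl < 0) or np.any(nr < 0) or np.any(nl >= len(sigma)) or np.any(nr >= len(sigma)):
        raise ValueError("flash count outside the range covered by the sigma table")
    var = sigma[nl] ** 2 + sigma[nr] ** 2
    diff = (nr - nl).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(var > 0, diff / np.sqrt(np.where(var > 0, var, 1.0)), np.sign(diff) * np.inf)
    p = ndtr(np.where((var == 0) & (diff == 0), 0.0, z))
    out = np.clip(p, EPS, 1.0 - EPS)
    return float(out) if out.ndim == 0 else out


# -- contingency aggregation ---------------------------------------------


def _cells(nl: np.ndarray, nr: np.ndarray, chose_right: np.ndarray, n_max: int):
    """Collapse trials into (n_left, n_right) cells with right-choice counts."""
    if np.any(nl > n_max) or np.any(nr > n_max):
        raise ValueError("trial counts exceed n_max")
    flat = nl * (n_max + 1) + nr
    n_cells = (n_max + 1) ** 2
    total = np.bincount(flat, minlength=n_cells)
    right = np.bincount(flat, weights=chose_right.astype(float), minlength=n_cells)
    keep = total > 0
    idx = np.nonzero(keep)[0]
    return idx // (n_max + 1), idx % (n_max + 1), right[keep], total[keep].astype(float)


def _cell_nll(sigma: np.ndarray, cl, cr, k_right, k_tot) -> float:
    var = sigma[cl] ** 2 + sigma[cr] ** 2
    diff = (cr - cl).astype(float)
    with np.errstate(invalid="ignore"):
        z = np.where(
            var > 0,
            diff / np.sqrt(np.maximum(var, 1e-300)),
            np.where(diff == 0, 0.0, np.sign(diff) * np.inf),
        )
    p = np.clip(ndtr(z), EPS, 1.0 - EPS)
    return float(-(k_right * np.log(p) + (k_tot - k_right) * np.log1p(-p)).sum())


def neg_log_likelihood(table: TrialTable, sig: SigmaTable | np.ndarray) -> float:
    """Negative log-likelihood of the observed choices under ``sig``."""
    if len(table) == 0:
        raise EmptyInputError("empty table")
    sigma = sig.sigma if isinstance(sig, SigmaTable) else np.asarray(sig, float)
    nl, nr, right = table.counts_choices()
    cl, cr, k_right, k_tot = _cells(nl, nr, right, len(sigma) - 1)
    return _cell_nll(np.nan_to_num(sigma, nan=SIGMA_LO), cl, cr, k_right, k_tot)


# -- fitting -------------------------------------------------------------


def _fit_sigma_cells(cl, cr, k_right, k_tot, n_max, x0_list):
    """MLE over the observed counts; returns (sigma_full_vector, nll)."""
    observed = np.zeros(n_max + 1, bool)
    observed[cl] = True
    observed[cr] = True
    obs_idx = np.nonzero(observed)[0]

    def nll_of(x):
        sigma = np.empty(n_max + 1)
        sigma[obs_idx] = x
        return _cell_nll(sigma, cl, cr, k_right, k_tot)

    best = None
    for x0 in x0_list:
        res = minimize(
            nll_of,
            np.clip(x0[obs_idx], SIGMA_LO, SIGMA_HI),
            method="L-BFGS-B",
            bounds=[(SIGMA_LO, SIGMA_HI)] * obs_idx.size,
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise FitError("sigma-table optimisation failed on all restarts")
    sigma = np.full(n_max + 1, np.nan)
    sigma[obs_idx] = best.x
    return sigma, float(best.fun)


def fit_sigma_table(
    table: TrialTable,
    n_max: int = 15,
    n_boot: int = 1000,
    seed: int | None = None,
    ci: tuple[float, float] = (2.5, 97.5),
) -> SigmaTable:
    """Maximum-likelihood per-count noise fit with bootstrap CIs.

    The point estimate is the full-data MLE (multi-start bounded
    L-BFGS-B); CIs are percentile intervals over ``n_boot`` refits to
    trial resamples (drawn with replacement, implemented as a multinomial
    resample of the contingency cells).  Counts never observed get
    sigma = NaN and are excluded from downstream scaling fits.
    """
    if len(table) == 0:
        raise EmptyInputError("empty table")
    nl, nr, right = table.counts_choices()
    cl, cr, k_right, k_tot = _cells(nl, nr, right, n_max)

    starts = [np.maximum(k * np.arange(n_max + 1, dtype=float), 0.05) for k in _START_SLOPES]
    sigma, nll = _fit_sigma_cells(cl, cr, k_right, k_tot, n_max, starts)

    weights = np.zeros(n_max + 1)
    np.add.at(weights, cl, k_tot)
    np.add.at(weights, cr, k_tot)

    rng = np.random.default_rng(seed)
    boot = np.full((n_boot, n_max + 1), np.nan)
    n_trials = int(k_tot.sum())
    # expand cells into (cell, outcome) categories for multinomial resampling
    cat_p = np.concatenate([k_right, k_tot - k_right]) / n_trials
    # bootstrap refits keep multi-start diversity: on flat likelihood
    # plateaus a warm start alone would under-disperse the CIs
    boot_starts = [np.nan_to_num(sigma, nan=0.05)] + starts
    for b in range(n_boot):
        draw = rng.multinomial(n_trials, cat_p)
        r_b = draw[: len(k_tot)].astype(float)
        t_b = r_b + draw[len(k_tot):]
        keep = t_b > 0
        try:
            s_b, _ = _fit_sigma_cells(
                cl[keep], cr[keep], r_b[keep], t_b[keep], n_max, boot_starts
            )
            boot[b] = s_b
        except FitError:  # pragma: no cover - rare; iteration skipped
            continue
    import warnings as _warnings

    with _warnings.catch_warnings():
        # unobserved counts are all-NaN columns by construction
        _warnings.simplefilter("ignore", RuntimeWarning)
        lo = np.nanpercentile(boot, ci[0], axis=0)
        hi = np.nanpercentile(boot, ci[1], axis=0)
        bm = np.nanmean(boot, axis=0)
    undef = np.isnan(sigma)
    lo[undef] = hi[undef] = bm[undef] = np.nan
    return SigmaTable(sigma, n_max, lo, hi, weights, -nll, bm, n_boot, seed)


def fit_sigma_from_counts(
    n_left: np.ndarray,
    n_right: np.ndarray,
    chose_right: np.ndarray,
    n_max: int,
    n_boot: int = 1000,
    seed: int | None = None,
) -> SigmaTable:
    """Like :func:`fit_sigma_table` but on raw count/choice arrays.

    Used by the clicks pipeline, where the counts are adaptation-corrected
    effective event numbers rather than trial flash counts.
    """
    nl = np.asarray(n_left, int)
    nr = np.asarray(n_right, int)
    right = np.asarray(chose_right, bool)

    class _Shim:
        def __len__(self):
            return len(nl)

        def counts_choices(self):
            return nl, nr, right

    return fit_sigma_table(_Shim(), n_max=n_max, n_boot=n_boot, seed=seed)  # type: ignore[arg-type]


# -- model predictions ---------------------------------------------------


def predict_surface(sig: SigmaTable) -> np.ndarray:
    """(N+1)x(N+1) matrix of P(choose right) over (n_left, n_right)."""
    n = sig.n_max + 1
    nl, nr = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    sigma = np.nan_to_num(sig.sigma, nan=SIGMA_LO)
    return p_choose_right(nl.ravel(), nr.ravel(), sigma).reshape(n, n)


def predict_psychometric(sig: SigmaTable, table: TrialTable) -> dict[int, float]:
    """Model P(correct) per |flash difference|, averaged over the table's
    observed (n_L, n_R) mix (matching how an empirical psychometric pools)."""
    df = table.to_dataframe()
    sigma = np.nan_to_num(sig.sigma, nan=SIGMA_LO)
    p_r = p_choose_right(df["n_left"].to_numpy(), df["n_right"].to_numpy(), sigma)
    p_corr = np.where(
        df["flash_diff"] > 0, p_r, np.where(df["flash_diff"] < 0, 1.0 - p_r, 0.5)
    )
    out = {}
    for d, grp in pd_groupby_abs(df, p_corr):
        out[int(d)] = float(np.mean(grp))
    return out


def pd_groupby_abs(df, values):
    """Yield (|flash_diff|, values) groups in ascending difficulty order."""
    abs_diff = df["flash_diff"].abs().to_numpy()
    for d in np.unique(abs_diff):
        yield d, values[abs_diff == d]


def lapse_asymptote(k: float) -> float:
    """Asymptotic error rate on the easiest trials under pure scalar
    variability sigma_n = k*n: the mass of N(0,1) above 1/k.

    With n flashes on one side only, P(error) = Phi(-n/(k*n)) = 1 - Phi(1/k)
    independent of n — an emergent lapse rate with no lapse parameter.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    return float(1.0 - ndtr(1.0 / k))
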