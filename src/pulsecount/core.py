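"""Domain types and trial-table I/O for pulsatile accumulation behavior.

A *trial* is one two-alternative flash-count discrimination: two pulse
trains (left / right) are presented in fixed 250-ms bins, and the subject
is rewarded for choosing the side with the greater number of pulses.
Tables of trials are stored as plain UTF-8 CSV so they are greppable and
language-neutral; pulse-onset/duration lists are encoded per cell as
semicolon-separated seconds with 6 decimal places.

Time convention: t = 0 at cue-period onset, all times in seconds.  Bin i
(0-based internally) occupies the half-open interval [i*bin, (i+1)*bin);
a non-jittered flash occupies the first ``flash_ms`` of its bin.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

SIDES = ("L", "R")

#: numeric precision (decimal places) used when serialising times/durations
TIME_DECIMALS = 6

_CSV_COLUMNS = [
    "subject_id",
    "session_id",
    "trial_index",
    "n_bins",
    "bin_ms",
    "flash_times_left",
    "flash_times_right",
    "flash_durs_left",
    "flash_durs_right",
    "delay_s",
    "choice",
    "rewarded_side",
    "correct",
    "p_high",
    "p_low",
    "jitter",
    "high_side",
]


class SchemaError(ValueError):
    """A trial-table file is missing mandatory columns."""


class ValidationError(ValueError):
    """A trial violates a structural invariant."""


class EmptyInputError(ValueError):
    """An operation that needs trials received none."""


@dataclass(frozen=True)
class StimulusConfig:
    """Stimulus statistics for one session.

    Per bin, the high-probability side flashes with probability drawn once
    per trial from ``p_high_range`` and the low side from ``p_low_range``
    (degenerate ranges give fixed probabilities).  ``n_bins`` is the
    maximum number of 250-ms cue bins; when ``n_bins_range`` is set each
    trial's bin count (its cue duration) is drawn uniformly from that
    inclusive range, mirroring the trial-by-trial variation of stimulus
    duration in the task.  The post-cue (memory) delay is drawn uniformly
    from ``delay_range_s``.  In jitter mode flash durations are
    N(flash_ms, dur_sd_ms) truncated positive and inter-flash intervals
    are N(isi_mean_ms, isi_sd_ms).
    """

    n_bins: int = 15
    bin_ms: float = 250.0
    flash_ms: float = 10.0
    p_high_range: tuple[float, float] = (0.7, 0.8)
    p_low_range: tuple[float, float] = (0.2, 0.3)
    n_bins_range: tuple[int, int] | None = None
    delay_range_s: tuple[float, float] = (0.005, 0.500)
    jitter: bool = False
    dur_sd_ms: float = 1.5
    isi_mean_ms: float = 250.0
    isi_sd_ms: float = 25.0

    def __post_init__(self) -> None:
        lo_l, hi_l = self.p_low_range
        lo_h, hi_h = self.p_high_range
        if not (0.0 <= lo_l <= hi_l <= 1.0 and 0.0 <= lo_h <= hi_h <= 1.0):
            raise ValueError("flash probabilities must lie in [0, 1]")
        if not hi_l <= lo_h:
            raise ValueError("p_low_range must lie below p_high_range")
        if not self.flash_ms < self.bin_ms:
            raise ValueError("flash_ms must be shorter than bin_ms")
        if not 1 <= self.n_bins <= 15:
            raise ValueError("n_bins must be in 1..15")
        if self.n_bins_range is not None:
            lo, hi = self.n_bins_range
            if not 1 <= lo <= hi <= self.n_bins:
                raise ValueError("n_bins_range must lie within 1..n_bins")

    @classmethod
    def unrestrained(cls, **kw) -> "StimulusConfig":
        """Freely-moving geometry: up to 15 bins (drawn per trial),
        probability ranges 70-80 / 20-30%."""
        kw.setdefault("n_bins_range", (2, 15))
        return cls(**kw)

    @classmethod
    def head_fixed(cls, **kw) -> "StimulusConfig":
        """Restrained geometry: up to 6 bins, fixed 70 / 30% probabilities."""
        kw.setdefault("n_bins", 6)
        kw.setdefault("n_bins_range", (2, 6))
        kw.setdefault("p_high_range", (0.7, 0.7))
        kw.setdefault("p_low_range", (0.3, 0.3))
        return cls(**kw)

    @classmethod
    def fixed_gamma(cls, p_high: float = 0.7, p_low: float = 0.3, **kw) -> "StimulusConfig":
        """Fixed generative probabilities (the reverse-correlation condition)."""
        kw["p_high_range"] = (p_high, p_high)
        kw["p_low_range"] = (p_low, p_low)
        return cls(**kw)


@dataclass
class Trial:
    """One behavioral trial (stimulus, outcome, bookkeeping)."""

    subject_id: str
    session_id: str
    trial_index: int
    n_bins: int
    flash_times_left: list[float]
    flash_times_right: list[float]
    flash_durs_left: list[float]
    flash_durs_right: list[float]
    delay_s: float
    choice: str | None
    rewarded_side: str
    correct: bool | None
    bin_ms: float = 250.0
    p_high: float = float("nan")
    p_low: float = float("nan")
    jitter: bool = False
    high_side: str = ""

    @property
    def n_left(self) -> int:
        return len(self.flash_times_left)

    @property
    def n_right(self) -> int:
        return len(self.flash_times_right)

    @property
    def flash_diff(self) -> int:
        """Signed right-minus-left flash count (#R - #L)."""
        return self.n_right - self.n_left

    @property
    def flash_total(self) -> int:
        return self.n_right + self.n_left

    @property
    def duration_s(self) -> float:
        """Cue period plus post-cue delay."""
        return self.n_bins * self.bin_ms / 1000.0 + self.delay_s


def _check_side(times: Sequence[float], durs: Sequence[float], trial: Trial, side: str) -> None:
    label = f"trial ({trial.subject_id},{trial.session_id},{trial.trial_index})"
    if len(times) != len(durs):
        raise ValidationError(f"{label}: flash time/duration length mismatch on {side}")
    if len(times) > trial.n_bins:
        raise ValidationError(f"{label}: {len(times)} flashes on {side} exceeds n_bins={trial.n_bins}")
    arr = np.asarray(times, dtype=float)
    if arr.size and np.any(np.diff(arr) <= 0):
        raise ValidationError(f"{label}: non-monotone flash times on {side}")
    if arr.size and (arr[0] < 0):
        raise ValidationError(f"{label}: negative flash time on {side}")
    if not trial.jitter and arr.size:
        bin_s = trial.bin_ms / 1000.0
        frac = arr - np.floor(arr / bin_s + 1e-9) * bin_s
        if np.any(frac > trial.bin_ms / 1000.0 * 0.04 + 1e-6):  # first 10 ms of a 250 ms bin
            raise ValidationError(f"{label}: flash onset not at a bin start on {side}")


def validate_trial(trial: Trial, require_choice: bool = True) -> None:
    """Raise :class:`ValidationError` on any structural-invariant violation."""
    label = f"trial ({trial.subject_id},{trial.session_id},{trial.trial_index})"
    if trial.trial_index < 0:
        raise ValidationError(f"{label}: negative trial_index")
    if not 1 <= trial.n_bins <= 15:
        raise ValidationError(f"{label}: n_bins={trial.n_bins} outside 1..15")
    _check_side(trial.flash_times_left, trial.flash_durs_left, trial, "L")
    _check_side(trial.flash_times_right, trial.flash_durs_right, trial, "R")
    if trial.delay_s < 0:
        raise ValidationError(f"{label}: negative delay")
    if trial.rewarded_side not in SIDES:
        raise ValidationError(f"{label}: rewarded_side must be L or R")
    if trial.n_right != trial.n_left:
        majority = "R" if trial.n_right > trial.n_left else "L"
        if trial.rewarded_side != majority:
            raise ValidationError(f"{label}: rewarded_side contradicts flash counts")
    if require_choice or trial.choice is not None:
        if trial.choice not in SIDES:
            raise ValidationError(f"{label}: choice must be L or R")
        if trial.correct is None or bool(trial.correct) != (trial.choice == trial.rewarded_side):
            raise ValidationError(f"{label}: correct flag contradicts choice/rewarded_side")


class TrialTable:
    """Ordered collection of :class:`Trial` with per-session stimulus configs.

    Trials are kept sorted by (subject, session, trial_index); within-session
    ordering is load-bearing for the trial-history analyses.
    """

    def __init__(
        self,
        trials: Iterable[Trial],
        configs: dict[str, StimulusConfig] | None = None,
        validate: bool = True,
        require_choices: bool = True,
    ) -> None:
        self.trials: list[Trial] = list(trials)
        self.configs: dict[str, StimulusConfig] = dict(configs or {})
        self.trials.sort(key=lambda t: (t.subject_id, t.session_id, t.trial_index))
        if validate:
            seen: set[tuple[str, str, int]] = set()
            for t in self.trials:
                key = (t.subject_id, t.session_id, t.trial_index)
                if key in seen:
                    raise ValidationError(f"duplicate trial key {key}")
                seen.add(key)
                validate_trial(t, require_choice=require_choices)
        self._df: pd.DataFrame | None = None

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self) -> Iterator[Trial]:
        return iter(self.trials)

    def __getitem__(self, i: int) -> Trial:
        return self.trials[i]

    # -- array views -----------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        """Flat per-trial view (list columns are python lists)."""
        if self._df is None:
            self._df = pd.DataFrame(
                {
                    "subject_id": [t.subject_id for t in self.trials],
                    "session_id": [t.session_id for t in self.trials],
                    "trial_index": [t.trial_index for t in self.trials],
                    "n_bins": [t.n_bins for t in self.trials],
                    "n_left": [t.n_left for t in self.trials],
                    "n_right": [t.n_right for t in self.trials],
                    "flash_diff": [t.flash_diff for t in self.trials],
                    "flash_total": [t.flash_total for t in self.trials],
                    "delay_s": [t.delay_s for t in self.trials],
                    "duration_s": [t.duration_s for t in self.trials],
                    "choice": [t.choice for t in self.trials],
                    "rewarded_side": [t.rewarded_side for t in self.trials],
                    "correct": [bool(t.correct) if t.correct is not None else None for t in self.trials],
                    "p_high": [t.p_high for t in self.trials],
                    "p_low": [t.p_low for t in self.trials],
                }
            )
        return self._df

    def counts_choices(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(n_left, n_right, chose_right) integer/bool arrays for fitting."""
        df = self.to_dataframe()
        if df["choice"].isna().any():
            raise ValidationError("table contains trials without choices")
        return (
            df["n_left"].to_numpy(int),
            df["n_right"].to_numpy(int),
            (df["choice"] == "R").to_numpy(bool),
        )

    def subset(self, mask: np.ndarray) -> "TrialTable":
        trials = [t for t, m in zip(self.trials, mask) if m]
        return TrialTable(trials, self.configs, validate=False)


# -- serialisation -------------------------------------------------------


def _fmt_list(vals: Sequence[float]) -> str:
    return ";".join(f"{v:.{TIME_DECIMALS}f}" for v in vals)


def _parse_list(cell: str) -> list[float]:
    cell = cell.strip()
    if not cell:
        return []
    return [float(x) for x in cell.split(";")]


def write_trials(table: TrialTable, path) -> str:
    """Write a trial table as CSV; returns the path written."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_CSV_COLUMNS)
        for t in table:
            w.writerow(
                [
                    t.subject_id,
                    t.session_id,
                    t.trial_index,
                    t.n_bins,
                    f"{t.bin_ms:.3f}",
                    _fmt_list(t.flash_times_left),
                    _fmt_list(t.flash_times_right),
                    _fmt_list(t.flash_durs_left),
                    _fmt_list(t.flash_durs_right),
                    f"{t.delay_s:.{TIME_DECIMALS}f}",
                    t.choice or "",
                    t.rewarded_side,
                    "" if t.correct is None else int(bool(t.correct)),
                    "" if np.isnan(t.p_high) else f"{t.p_high:.6f}",
                    "" if np.isnan(t.p_low) else f"{t.p_low:.6f}",
                    int(t.jitter),
                    t.high_side,
                ]
            )
    return str(path)


def read_trials(path, require_choices: bool = True) -> TrialTable:
    """Read and validate a trial-table CSV.

    Raises :class:`SchemaError` when mandatory columns are missing and
    :class:`ValidationError` (naming the offending row) on invariant
    violations.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, no header row")
        missing = [
            c
            for c in _CSV_COLUMNS
            if c not in reader.fieldnames and c not in ("p_high", "p_low", "jitter", "high_side")
        ]
        if missing:
            raise SchemaError(f"{path}: missing mandatory columns {missing}")
        trials = []
        for i, row in enumerate(reader, start=2):
            try:
                trials.append(
                    Trial(
                        subject_id=row["subject_id"],
                        session_id=row["session_id"],
                        trial_index=int(row["trial_index"]),
                        n_bins=int(row["n_bins"]),
                        bin_ms=float(row["bin_ms"]),
                        flash_times_left=_parse_list(row["flash_times_left"]),
                        flash_times_right=_parse_list(row["flash_times_right"]),
                        flash_durs_left=_parse_list(row["flash_durs_left"]),
                        flash_durs_right=_parse_list(row["flash_durs_right"]),
                        delay_s=float(row["delay_s"]),
                        choice=row["choice"] or None,
                        rewarded_side=row["rewarded_side"],
                        correct=None if row["correct"] == "" else bool(int(row["correct"])),
                        p_high=float(row["p_high"]) if row.get("p_high") else float("nan"),
                        p_low=float(row["p_low"]) if row.get("p_low") else float("nan"),
                        jitter=bool(int(row["jitter"])) if row.get("jitter") else False,
                        high_side=row.get("high_side") or "",
                    )
                )
            except (KeyError, ValueError) as exc:
                if isinstance(exc, ValidationError):
                    raise
                raise ValidationError(f"{path} row {i}: {exc}") from exc
    return TrialTable(trials, validate=True, require_choices=require_choices)


# -- summaries -----------------------------------------------------------


def summarize(table: TrialTable, min_trials_per_session: int | None = None) -> dict:
    """Descriptive summary: counts, % correct overall and by |flash diff|.

    ``min_trials_per_session`` optionally drops sessions below a trial
    count before summarising (no exclusion by default).
    """
    if len(table) == 0:
        raise EmptyInputError("cannot summarize an empty table")
    df = table.to_dataframe()
    if min_trials_per_session is not None:
        sizes = df.groupby(["subject_id", "session_id"])["trial_index"].transform("size")
        df = df[sizes >= min_trials_per_session]
        if df.empty:
            raise EmptyInputError("no sessions survive the min-trials filter")
    df = df[df["choice"].notna()]
    if df.empty:
        raise EmptyInputError("no completed trials to summarize")
    abs_diff = df["flash_diff"].abs()
    correct = df["correct"].astype(bool)
    by_diff = {
        int(d): float(100.0 * correct[abs_diff == d].mean())
        for d in sorted(abs_diff.unique())
    }
    sess_sizes = df.groupby(["subject_id", "session_id"]).size()
    return {
        "n_trials": int(len(df)),
        "n_subjects": int(df["subject_id"].nunique()),
        "n_sessions": int(sess_sizes.size),
        "trials_per_session_mean": float(sess_sizes.mean()),
        "percent_correct_overall": float(100.0 * correct.mean()),
        "percent_correct_by_abs_diff": by_diff,
        "percent_correct_easiest": by_diff[max(by_diff)] if by_diff else float("nan"),
    }
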