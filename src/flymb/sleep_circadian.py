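"""Sleep-bout detection, sleep/activity summaries and circadian period estimation.

A fly is asleep when it shows no beam crossings for at least 5 consecutive
minutes — the standard Drosophila activity-monitor criterion.  Bouts are
reported in half-open minute coordinates.  Free-running period in constant
darkness (DD) is estimated with a Lomb-Scargle periodogram over a configurable
period grid, with a Bonferroni-corrected exponential false-alarm threshold for
the rhythmicity call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import lombscargle

from .io_formats import ActivityMatrix


@dataclass(frozen=True)
class SleepParams:
    """min_bout_minutes: run length that counts as sleep (default 5).
    inactivity_threshold: counts strictly below this make a minute inactive
    (default 1, i.e., only zero-count minutes are inactive)."""

    min_bout_minutes: int = 5
    inactivity_threshold: int = 1

    def __post_init__(self) -> None:
        if self.min_bout_minutes < 1:
            raise ValueError("min_bout_minutes must be >= 1")


@dataclass(frozen=True)
class SleepBout:
    fly: int
    start_minute: int
    end_minute: int  # half-open

    @property
    def duration(self) -> int:
        return self.end_minute - self.start_minute


def detect_sleep_bouts(trace, params: SleepParams | None = None,
                       fly: int = 0) -> list[SleepBout]:
    """Maximal runs of inactive minutes of length >= min_bout_minutes.

    Runs truncated by either recording boundary still count when long enough:
    excluding them would bias total sleep downward.
    """
    params = params or SleepParams()
    x = np.asarray(trace)
    if x.ndim != 1 or not len(x):
        raise ValueError("trace must be a non-empty 1-D array")
    if (x < 0).any():
        raise ValueError("negative activity counts")
    inactive = x < params.inactivity_threshold
    # run boundaries of the inactive mask
    padded = np.concatenate([[False], inactive, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.nonzero(diff == 1)[0]
    ends = np.nonzero(diff == -1)[0]
    return [SleepBout(fly=fly, start_minute=int(s), end_minute=int(e))
            for s, e in zip(starts, ends) if e - s >= params.min_bout_minutes]


def sleep_mask(trace, params: SleepParams | None = None) -> np.ndarray:
    """Per-minute 0/1 asleep labels for one fly (1 = inside a sleep bout)."""
    mask = np.zeros(len(np.asarray(trace)), dtype=np.int8)
    for bout in detect_sleep_bouts(trace, params):
        mask[bout.start_minute: bout.end_minute] = 1
    return mask


def sleep_profile(matrix: ActivityMatrix, params: SleepParams | None = None) -> np.ndarray:
    """Mean sleep state across flies per minute: asleep flies score 1, awake 0."""
    if matrix.n_flies < 1:
        raise ValueError("need at least one fly")
    masks = np.stack([sleep_mask(matrix.counts[:, j], params)
                      for j in range(matrix.n_flies)], axis=1)
    return masks.mean(axis=1)


def sleep_summary(matrix: ActivityMatrix, params: SleepParams | None = None) -> pd.DataFrame:
    """Per-fly totals: sleep minutes (total / day / night) and activity counts.

    Day and night follow the matrix's lights_on/lights_off clock times; in DD
    the same clock split gives objective day and night.
    """
    params = params or SleepParams()
    day = matrix.is_day()
    rows = []
    for j in range(matrix.n_flies):
        asleep = sleep_mask(matrix.counts[:, j], params).astype(bool)
        rows.append({
            "fly": j,
            "total_sleep": int(asleep.sum()),
            "day_sleep": int(asleep[day].sum()),
            "night_sleep": int(asleep[~day].sum()),
            "total_activity": int(matrix.counts[:, j].sum()),
        })
    return pd.DataFrame(rows)


def _period_grid(n_minutes: int, lo_hours: float, hi_hours: float,
                 oversample: int) -> np.ndarray:
    """Frequency grid (cycles/min) spanning [1/hi, 1/lo] hours at the natural
    resolution 1/(oversample * T)."""
    T = n_minutes  # minutes
    df = 1.0 / (oversample * T)
    f_lo = 1.0 / (hi_hours * 60.0)
    f_hi = 1.0 / (lo_hours * 60.0)
    n = max(2, int(np.ceil((f_hi - f_lo) / df)))
    return np.linspace(f_lo, f_hi, n)


def estimate_period(matrix: ActivityMatrix,
                    period_range_hours: tuple[float, float] = (10.0, 40.0),
                    oversample: int = 4,
                    alpha: float = 0.05) -> pd.DataFrame:
    """Lomb-Scargle free-running period per fly on a DD activity trace.

    The classic normalized periodogram power z = P/sigma^2 is exponentially
    distributed under white noise; a fly is called rhythmic when its peak
    power clears the alpha-level false-alarm threshold Bonferroni-corrected
    for the number of grid frequencies.  Constant traces are non-rhythmic
    with an undefined (NaN) period.
    """
    lo, hi = period_range_hours
    if lo <= 0 or hi <= lo:
        raise ValueError("need 0 < lo < hi period bounds")
    if matrix.n_minutes < 2 * hi * 60:
        raise ValueError("trace shorter than two cycles of the longest test period")
    t = np.arange(matrix.n_minutes, dtype=float)
    freqs = _period_grid(matrix.n_minutes, lo, hi, oversample)
    omega = 2 * np.pi * freqs
    threshold = np.log(len(freqs) / alpha)  # exp-null, Bonferroni over grid
    rows = []
    for j in range(matrix.n_flies):
        y = matrix.counts[:, j].astype(float)
        var = y.var()
        if var == 0:
            rows.append({"fly": j, "period_hours": np.nan,
                         "peak_power": 0.0, "rhythmic": False})
            continue
        power = lombscargle(t, y - y.mean(), omega) / var
        k = int(np.argmax(power))
        rows.append({"fly": j,
                     "period_hours": 1.0 / freqs[k] / 60.0,
                     "peak_power": float(power[k]),
                     "rhythmic": bool(power[k] > threshold)})
    return pd.DataFrame(rows)


def compare_sleep_profiles(matrix_a: ActivityMatrix, matrix_b: ActivityMatrix,
                           params: SleepParams | None = None,
                           alpha: float = 0.05,
                           min_run: int = 2) -> pd.DataFrame:
    """Minute-wise two-sample t comparison of sleep state between genotypes.

    Returns runs of >= min_run contiguous minutes whose per-minute t-test
    p-value falls below alpha — the display convention of reporting at least
    two contiguous blocks of significant difference.
    """
    from scipy import stats as _st

    if matrix_a.n_minutes != matrix_b.n_minutes:
        raise ValueError("matrices must cover the same minutes")
    masks_a = np.stack([sleep_mask(matrix_a.counts[:, j], params)
                        for j in range(matrix_a.n_flies)], axis=1).astype(float)
    masks_b = np.stack([sleep_mask(matrix_b.counts[:, j], params)
                        for j in range(matrix_b.n_flies)], axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = _st.ttest_ind(masks_a, masks_b, axis=1)
    sig = np.nan_to_num(p, nan=1.0) < alpha
    padded = np.concatenate([[False], sig, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.nonzero(diff == 1)[0]
    ends = np.nonzero(diff == -1)[0]
    rows = [{"start_minute": int(s), "end_minute": int(e)}
            for s, e in zip(starts, ends) if e - s >= min_run]
    return pd.DataFrame(rows, columns=["start_minute", "end_minute"])
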