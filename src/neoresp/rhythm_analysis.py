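"""Integrated extracellular rhythm analysis.

Raw population recordings are full-wave rectified and integrated with a
leaky (exponential moving-average) filter, bursts are detected above a
rolling-median baseline, and burst metrics feed the irregularity score
IrS_n = 100 * |X_n - X_{n-1}| / X_{n-1}, plus an OLS fit of period
irregularity against cycle period.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from . import stats_core
from .trace import Trace

__all__ = [
    "IrregularitySeries",
    "preprocess_extracellular",
    "detect_bursts",
    "irregularity_score",
    "irs_period_relationship",
]


def preprocess_extracellular(raw: Trace, smoothing_tau_s: float) -> Trace:
    """Full-wave rectification then first-order leaky integration.

    The integrator is the discrete exponential moving average with time
    constant ``smoothing_tau_s``; its step response converges to the
    rectified input level, so a constant input c yields |c|
    asymptotically. Output is nonnegative.
    """
    if smoothing_tau_s <= 0:
        raise ValueError("smoothing_tau_s must be > 0")
    rect = np.abs(raw.value)
    alpha = 1.0 - np.exp(-raw.dt / smoothing_tau_s)
    y = lfilter([alpha], [1.0, -(1.0 - alpha)], rect)
    return Trace(time_s=raw.time_s, value=y, sample_rate_hz=raw.sample_rate_hz)


def detect_bursts(integrated: Trace,
                  threshold_frac: float = 0.3,
                  min_separation_s: Optional[float] = None,
                  baseline_window_periods: float = 5.0) -> pd.DataFrame:
    """Detect bursts in an integrated trace.

    Candidate peaks exceed baseline + threshold_frac * (robust max -
    baseline). Each burst's local baseline is a low (5th-percentile)
    quantile of its surrounding inter-peak window spanning
    ``baseline_window_periods`` estimated periods, which stays unbiased
    even when bursts fill much of the cycle. Peaks closer than
    ``min_separation_s`` (default: half the estimated period) are
    merged, keeping the higher. Amplitude is peak minus local baseline;
    the halfwidth is the full width at baseline + amplitude/2, located by
    linear interpolation between samples.

    Returns a BurstTable with columns ``peak_time_s``, ``amplitude``,
    ``period_s`` (to the next burst, NaN for the last) and
    ``halfwidth_s``.
    """
    v = integrated.value
    dt = integrated.dt
    b0 = float(np.median(v))
    robust_max = float(np.percentile(v, 99))
    if robust_max <= b0:
        warnings.warn("no suprathreshold events found", stacklevel=2)
        return pd.DataFrame(columns=["peak_time_s", "amplitude", "period_s", "halfwidth_s"])
    thr = b0 + threshold_frac * (robust_max - b0)

    # hysteresis: events are runs above a lower threshold that reach the
    # main one (noise cannot chatter across the hysteresis gap), one
    # candidate peak per run; then merge peaks closer than the
    # separation, keeping the higher one
    thr_lo = b0 + 0.5 * threshold_frac * (robust_max - b0)
    above = np.concatenate(([False], v > thr_lo, [False]))
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    runs = [(i0, i1) for i0, i1 in zip(edges[::2], edges[1::2])
            if np.max(v[i0:i1]) > thr]
    if not runs:
        warnings.warn("no suprathreshold events found", stacklevel=2)
        return pd.DataFrame(columns=["peak_time_s", "amplitude", "period_s", "halfwidth_s"])
    candidates = np.array([i0 + int(np.argmax(v[i0:i1])) for i0, i1 in runs])
    period_est = (float(np.median(np.diff(candidates))) * dt
                  if candidates.size > 1 else integrated.duration_s)
    if min_separation_s is None:
        min_separation_s = 0.5 * period_est
    distance = max(1, int(round(min_separation_s / dt)))
    peaks: list[int] = []
    for c in candidates:
        if peaks and c - peaks[-1] < distance:
            if v[c] > v[peaks[-1]]:
                peaks[-1] = c
        else:
            peaks.append(c)
    peaks = np.asarray(peaks)

    # local baseline per burst: a low quantile of the surrounding
    # inter-peak window. Unlike a rolling median it stays unbiased when
    # bursts occupy a large fraction of the cycle (wide bursts would pull
    # a median up and distort the half-maximum level).
    half_window = max(1, int(round(0.5 * baseline_window_periods * period_est / dt)))
    rows = []
    for j, p in enumerate(peaks):
        w_lo = (peaks[j - 1] + p) // 2 if j > 0 else max(0, p - half_window)
        w_hi = (peaks[j + 1] + p) // 2 if j + 1 < peaks.size else min(v.size, p + half_window)
        base = float(np.quantile(v[w_lo:w_hi], 0.05))
        amp = float(v[p] - base)
        if amp <= 0:
            continue
        level = base + amp / 2.0
        lo = peaks[j - 1] if j > 0 else 0
        hi = peaks[j + 1] if j + 1 < peaks.size else v.size - 1
        # walk left
        i = p
        while i > lo and v[i] > level:
            i -= 1
        if v[i] <= level and i < p:
            t_left = (i + (level - v[i]) / (v[i + 1] - v[i])) * dt
        else:
            t_left = i * dt
        # walk right
        i = p
        while i < hi and v[i] > level:
            i += 1
        if v[i] <= level and i > p:
            t_right = (i - (level - v[i]) / (v[i - 1] - v[i])) * dt
        else:
            t_right = i * dt
        rows.append((integrated.time_s[0] + p * dt, amp, t_right - t_left))

    table = pd.DataFrame(rows, columns=["peak_time_s", "amplitude", "halfwidth_s"])
    period = np.diff(table["peak_time_s"].to_numpy(), append=np.nan)
    table.insert(2, "period_s", period)
    return table


@dataclass(frozen=True)
class IrregularitySeries:
    """Per-event irregularity scores (percent) for one burst metric."""

    metric: str
    scores: np.ndarray
    mean_irs: float


def irregularity_score(values, metric: str = "metric") -> IrregularitySeries:
    """IrS_n = 100 * |X_n - X_{n-1}| / X_{n-1} for n >= 2.

    Scale-invariant (IrS(cX) = IrS(X) for c > 0); a constant series
    scores 0 everywhere. All values must be positive (the predecessor is
    the denominator).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("irregularity_score needs at least 2 values")
    if np.any(~np.isfinite(x)) or np.any(x <= 0):
        raise ValueError("all values must be finite and > 0")
    scores = 100.0 * np.abs(np.diff(x)) / x[:-1]
    return IrregularitySeries(metric=metric, scores=scores, mean_irs=float(scores.mean()))


def irs_period_relationship(bursts, per_animal: bool = True) -> "stats_core.LinearModelFit":
    """OLS of period irregularity on cycle period.

    Parameters
    ----------
    bursts : BurstTable or sequence of BurstTables
        With a sequence and ``per_animal=True`` (default), each table
        contributes one (mean period, mean period-IrS) point. With
        ``per_animal=False`` (or a single table) all per-burst pairs
        (predecessor period, score) are pooled.

    Returns a LinearModelFit (slope, intercept, r2, p-values).
    """
    if isinstance(bursts, pd.DataFrame):
        tables: Sequence[pd.DataFrame] = [bursts]
        per_animal = False
    else:
        tables = list(bursts)
    xs, ys = [], []
    for tb in tables:
        periods = tb["period_s"].to_numpy(dtype=float)
        periods = periods[np.isfinite(periods)]
        irs = irregularity_score(periods, metric="period_s")
        if per_animal:
            xs.append(float(np.mean(periods)))
            ys.append(float(irs.mean_irs))
        else:
            xs.extend(periods[:-1])
            ys.extend(irs.scores)
    x = np.asarray(xs)
    y = np.asarray(ys)
    if x.size < 3:
        raise ValueError("need at least 3 (IrS, period) pairs")
    if np.var(x) == 0:
        raise ValueError("degenerate predictor: period has zero variance")
    data = pd.DataFrame({"irs": y, "period": x})
    return stats_core.linear_model(data, "irs ~ period")
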