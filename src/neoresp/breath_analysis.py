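"""Breath segmentation, respiratory parameters, and apnea detection.

A flow trace is segmented at zero crossings into inspiratory/expiratory
lobe pairs; per-breath timing and flow-derived parameters (Ti, Te, V_T,
PIF, PEF, EF50, EIP, EEP, RT, PAU, Penh) populate a BreathTable, which
is aggregated into mass-normalized RespiratoryMetrics. Apneas are silent
flow intervals lasting more than two locally expected respiratory
cycles, the expected cycle being the trailing median breath duration.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .trace import Trace

__all__ = [
    "BREATH_COLUMNS",
    "RespiratoryMetrics",
    "ApneaEvent",
    "segment_breaths",
    "breath_metrics",
    "detect_apneas",
    "robust_flow_band",
]

log = logging.getLogger(__name__)

#: Columns of a BreathTable. Volumes/flows are in raw trace units
#: (mass normalization to /kg happens in breath_metrics).
BREATH_COLUMNS = [
    "onset_s", "insp_end_s", "exp_start_s", "exp_end_s", "end_s",
    "ti_s", "te_s", "eip_ms", "eep_ms",
    "vt", "pif", "pef", "ef50", "rt_s", "pau", "penh",
    "freq_bpm", "ve",
]


@dataclass(frozen=True)
class RespiratoryMetrics:
    """Recording-level summary. Volumes/flows are normalized per kg."""

    f_r_bpm: float
    vt_ml_kg: float
    ve_ml_min_kg: float
    ti_s: float
    te_s: float
    pif_ml_s_kg: float
    pef_ml_s_kg: float
    ef50_ml_s_kg: float
    eip_ms: float
    eep_ms: float
    pau: float
    penh: float
    n_breaths: int


@dataclass(frozen=True)
class ApneaEvent:
    start_s: float
    end_s: float
    duration_s: float
    expected_cycle_s: float


def robust_flow_band(flow: np.ndarray, fraction: float = 0.05) -> float:
    """Silence band: ``fraction`` of the robust flow amplitude (95th
    percentile of |flow|, insensitive to occasional artifacts)."""
    amp = float(np.percentile(np.abs(flow), 95))
    return fraction * amp


def _smooth(trace: Trace, smooth_sigma_s: float) -> np.ndarray:
    if smooth_sigma_s <= 0:
        return trace.value
    return gaussian_filter1d(trace.value, smooth_sigma_s * trace.sample_rate_hz)


def _lobes(sm: np.ndarray):
    """Maximal runs of strictly positive / strictly negative samples as
    (start_idx, stop_idx, sign) with stop exclusive."""
    s = np.sign(sm).astype(np.int8)
    change = np.flatnonzero(np.diff(s) != 0) + 1
    bounds = np.concatenate(([0], change, [s.size]))
    out = []
    for i0, i1 in zip(bounds[:-1], bounds[1:]):
        if s[i0] != 0:
            out.append((int(i0), int(i1), int(s[i0])))
    return out


def segment_breaths(trace: Trace,
                    min_cycle_s: float = 0.1,
                    flow_zero_band: Optional[float] = None,
                    smooth_sigma_s: float = 0.005,
                    insp_negative: bool = True) -> pd.DataFrame:
    """Segment a flow trace into breaths at signed zero crossings.

    A breath is an inspiratory lobe followed by the next expiratory lobe
    (inspiration negative by default). Lobes whose peak |flow| is below
    ``flow_zero_band`` (default: 5% of the robust amplitude) or shorter
    than ``min_cycle_s / 8`` are treated as noise ripples and merged into
    their neighbours. A flat trace yields an empty table.

    Returns a BreathTable (see BREATH_COLUMNS); per-breath volumes and
    flows are in raw trace units.
    """
    if trace.duration_s <= 3 * min_cycle_s:
        raise ValueError("trace shorter than 3 * min_cycle_s")
    flow = trace.value
    sm = _smooth(trace, smooth_sigma_s)
    if flow_zero_band is None:
        flow_zero_band = robust_flow_band(sm)
    dt = trace.dt
    min_lobe = max(1, int(round(min_cycle_s / 8 / dt)))

    kept = [(i0, i1, sg) for (i0, i1, sg) in _lobes(sm)
            if (i1 - i0) >= min_lobe and np.max(np.abs(sm[i0:i1])) >= flow_zero_band]
    # merge consecutive same-sign lobes left by discarded ripples
    merged: list[list[int]] = []
    for i0, i1, sg in kept:
        if merged and merged[-1][2] == sg:
            merged[-1][1] = i1
        else:
            merged.append([i0, i1, sg])

    insp_sign = -1 if insp_negative else 1
    t0 = trace.time_s[0]
    rows = []
    pairs = []  # (insp lobe, exp lobe)
    for j in range(len(merged) - 1):
        if merged[j][2] == insp_sign and merged[j + 1][2] == -insp_sign:
            pairs.append((merged[j], merged[j + 1]))

    for k, (li, le) in enumerate(pairs):
        onset = t0 + li[0] * dt
        insp_end = t0 + li[1] * dt
        exp_start = t0 + le[0] * dt
        exp_end = t0 + le[1] * dt
        if k + 1 < len(pairs):
            end = t0 + pairs[k + 1][0][0] * dt
        else:
            end = exp_end
        ti = insp_end - onset
        te = exp_end - exp_start
        eip_ms = (exp_start - insp_end) * 1e3
        eep_ms = (end - exp_end) * 1e3

        insp_flow = np.abs(flow[li[0]:li[1]])
        exp_flow = np.abs(flow[le[0]:le[1]])
        vt = float(np.trapezoid(insp_flow, dx=dt))
        pif = float(insp_flow.max())
        pef = float(exp_flow.max())
        vt_exp_cum = np.concatenate(([0.0], np.cumsum((exp_flow[1:] + exp_flow[:-1]) / 2 * dt)))
        vt_exp = vt_exp_cum[-1]
        if vt_exp <= 0:
            log.info("breath at t=%.3f s has zero expired volume; EF50/PAU undefined", onset)
            ef50 = rt = pau = penh = np.nan
        else:
            i50 = int(np.searchsorted(vt_exp_cum, 0.5 * vt_exp))
            ef50 = float(exp_flow[min(i50, exp_flow.size - 1)])
            i65 = int(np.searchsorted(vt_exp_cum, 0.65 * vt_exp))
            rt = min(i65, exp_flow.size - 1) * dt
            pau = (te - rt) / rt if rt > 0 else np.nan
            penh = pau * pef / pif if pif > 0 else np.nan
        dur = end - onset
        rows.append((onset, insp_end, exp_start, exp_end, end,
                     ti, te, eip_ms, eep_ms,
                     vt, pif, pef, ef50, rt, pau, penh,
                     60.0 / dur if dur > 0 else np.nan,
                     (60.0 / dur) * vt if dur > 0 else np.nan))
    return pd.DataFrame(rows, columns=BREATH_COLUMNS)


def breath_metrics(breaths: pd.DataFrame, body_mass_kg: float) -> RespiratoryMetrics:
    """Aggregate a BreathTable into mass-normalized RespiratoryMetrics.

    f_R = 60 * n / (total breath time); V_T = mean inspiratory integral
    per kg; V_E = f_R * V_T (exact identity by construction). Breaths
    with undefined EF50/PAU (zero expired volume) are excluded from the
    means of those parameters only.
    """
    if body_mass_kg is None or body_mass_kg <= 0:
        raise ValueError("body_mass_kg must be > 0")
    if len(breaths) < 1:
        raise ValueError("need at least one breath")
    total_s = float((breaths["end_s"] - breaths["onset_s"]).sum())
    n = len(breaths)
    f_r = 60.0 * n / total_s
    vt = float(breaths["vt"].mean()) / body_mass_kg
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        return RespiratoryMetrics(
            f_r_bpm=f_r,
            vt_ml_kg=vt,
            ve_ml_min_kg=f_r * vt,
            ti_s=float(breaths["ti_s"].mean()),
            te_s=float(breaths["te_s"].mean()),
            pif_ml_s_kg=float(breaths["pif"].mean()) / body_mass_kg,
            pef_ml_s_kg=float(breaths["pef"].mean()) / body_mass_kg,
            ef50_ml_s_kg=float(np.nanmean(breaths["ef50"])) / body_mass_kg,
            eip_ms=float(breaths["eip_ms"].mean()),
            eep_ms=float(breaths["eep_ms"].mean()),
            pau=float(np.nanmean(breaths["pau"])),
            penh=float(np.nanmean(breaths["penh"])),
            n_breaths=n,
        )


def detect_apneas(trace: Trace,
                  breaths: pd.DataFrame,
                  window_breaths: int = 10,
                  flow_zero_band: Optional[float] = None,
                  smooth_sigma_s: float = 0.005) -> list[ApneaEvent]:
    """Detect apneas: silent intervals longer than two expected cycles.

    A silent interval is a maximal run where the smoothed |flow| stays
    below ``flow_zero_band``. The expected cycle at an interval is the
    median duration of the preceding ``window_breaths`` breaths (the
    global median when fewer precede it). An interval is an apnea only if
    its duration strictly exceeds 2x the expected cycle ("more than two
    expected respiratory cycles"), so a gap of exactly two cycles is not
    scored.
    """
    if len(breaths) == 0:
        warnings.warn("no breaths segmented; apnea detection skipped "
                      "(expected cycle undefined)", stacklevel=2)
        return []
    sm = _smooth(trace, smooth_sigma_s)
    if flow_zero_band is None:
        flow_zero_band = robust_flow_band(sm)
    silent = np.abs(sm) < flow_zero_band
    padded = np.concatenate(([False], silent, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, stops = edges[::2], edges[1::2]

    durations = (breaths["end_s"] - breaths["onset_s"]).to_numpy()
    ends = breaths["end_s"].to_numpy()
    global_median = float(np.median(durations))
    dt = trace.dt
    t0 = trace.time_s[0]
    events: list[ApneaEvent] = []
    for i0, i1 in zip(starts, stops):
        start_s = t0 + i0 * dt
        dur = (i1 - i0) * dt
        preceding = np.flatnonzero(ends <= start_s + dt)
        if preceding.size >= window_breaths:
            expected = float(np.median(durations[preceding[-window_breaths:]]))
        else:
            expected = global_median
        if dur > 2.0 * expected:
            events.append(ApneaEvent(start_s=start_s, end_s=start_s + dur,
                                     duration_s=dur, expected_cycle_s=expected))
    return events
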