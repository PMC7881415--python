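"""Synthetic input generators with ground truth.

Every input the pipeline consumes can be generated here: newborn-mouse
plethysmography flow traces (breaths with apneic gaps), integrated
rhythmic population-burst traces, asynchronous cell-cycle populations
under a dual thymidine-analog pulse schedule, and multichannel
fluorescence images of elliptical nuclei whose channel intensities are
driven by the simulated cell states.

All generators are pure functions of their spec (the seed is a spec
field), so repeated calls are bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .trace import Trace

__all__ = [
    "PlethSpec",
    "BurstTrainSpec",
    "CellCycleSpec",
    "ChannelRule",
    "ImageSpec",
    "gen_pleth_trace",
    "gen_burst_train",
    "gen_cellcycle_population",
    "gen_microscopy_image",
]


def _lognormal_draws(rng: np.random.Generator, mean: float, cv: float, n: int) -> np.ndarray:
    """Lognormal samples with the requested arithmetic mean and CV.

    cv = 0 returns the mean exactly (no RNG consumption), so jitter-free
    constructions are bit-exact.
    """
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if cv == 0:
        return np.full(n, mean, dtype=float)
    sigma2 = math.log(1.0 + cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=n)


# ---------------------------------------------------------------------------
# plethysmography
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlethSpec:
    """Parameters of a synthetic head-out plethysmography recording.

    Defaults emulate a 10-minute newborn (P0) mouse recording: breathing
    around 180 breaths/min with moderate breath-to-breath jitter and a
    small additive sensor noise. Inspiration is rendered as negative flow
    (head-out convention) unless ``insp_negative`` is False.
    """

    duration_s: float = 600.0
    sample_rate_hz: float = 1000.0
    base_freq_bpm: float = 180.0
    freq_jitter_cv: float = 0.1
    amplitude: float = 1.0          # peak flow, mL/s
    amplitude_jitter_cv: float = 0.1
    apnea_intervals: tuple = ()     # ((start_s, duration_s), ...)
    noise_sd: float = 0.02
    insp_negative: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")
        if self.sample_rate_hz < 100:
            raise ValueError("sample_rate_hz must be >= 100")
        if self.base_freq_bpm <= 0 or self.amplitude <= 0:
            raise ValueError("base_freq_bpm and amplitude must be > 0")
        if self.freq_jitter_cv < 0 or self.amplitude_jitter_cv < 0 or self.noise_sd < 0:
            raise ValueError("cv and noise values must be >= 0")
        ivals = sorted(tuple((float(s), float(d)) for s, d in self.apnea_intervals))
        object.__setattr__(self, "apnea_intervals", tuple(ivals))
        prev_end = -math.inf
        for start, dur in ivals:
            if dur <= 0:
                raise ValueError("apnea duration must be > 0")
            if start < 0 or start + dur > self.duration_s:
                raise ValueError("apnea interval outside [0, duration_s]")
            if start < prev_end:
                raise ValueError("apnea intervals overlap")
            prev_end = start + dur


def gen_pleth_trace(spec: PlethSpec):
    """Generate a flow trace of concatenated half-sine breaths.

    Each breath is an inspiratory half-sine lobe followed by an
    expiratory half-sine lobe of equal duration (period and amplitude
    drawn lognormally with the spec CVs). Apneas are inserted as silent
    gaps of exactly the requested duration, starting at the breath
    boundary at/after the requested start so ground truth is exact.

    Returns
    -------
    (trace, onsets, apneas)
        ``trace`` : Trace of flow; ``onsets`` : ndarray of ground-truth
        onset times of complete breaths (s); ``apneas`` : list of
        (start_s, duration_s) ground-truth silent gaps as inserted.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.sample_rate_hz))
    flow = np.zeros(n)
    dt = 1.0 / spec.sample_rate_hz
    base_period = 60.0 / spec.base_freq_bpm

    pending = list(spec.apnea_intervals)
    onsets: list[float] = []
    apneas: list[tuple[float, float]] = []
    insp_sign = -1.0 if spec.insp_negative else 1.0

    t_cur = 0.0
    while t_cur < spec.duration_s - dt / 2:
        if pending and t_cur + base_period > pending[0][0]:
            _, gap = pending.pop(0)
            apneas.append((t_cur, gap))
            t_cur += gap
            continue
        period = float(_lognormal_draws(rng, base_period, spec.freq_jitter_cv, 1)[0])
        amp = float(_lognormal_draws(rng, spec.amplitude, spec.amplitude_jitter_cv, 1)[0])
        ti = period / 2.0
        i0 = int(round(t_cur * spec.sample_rate_hz))
        i1 = min(n, int(round((t_cur + period) * spec.sample_rate_hz)))
        if i1 > i0:
            t_local = np.arange(i0, i1) * dt - t_cur
            insp = t_local < ti
            seg = np.empty(i1 - i0)
            seg[insp] = insp_sign * amp * np.sin(np.pi * t_local[insp] / ti)
            seg[~insp] = -insp_sign * amp * np.sin(np.pi * (t_local[~insp] - ti) / ti)
            flow[i0:i1] = seg
        if t_cur + period <= spec.duration_s + dt / 2:
            onsets.append(t_cur)
        t_cur += period

    if spec.noise_sd > 0:
        flow = flow + rng.normal(0.0, spec.noise_sd, n)
    trace = Trace.from_values(flow, spec.sample_rate_hz)
    return trace, np.asarray(onsets), apneas


# ---------------------------------------------------------------------------
# integrated rhythmic bursts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BurstTrainSpec:
    """Parameters of a synthetic integrated population-rhythm trace.

    Emulates a rectified-and-integrated extracellular recording of a
    rhythmogenic population: Gaussian-shaped bursts at a jittered period
    riding on nonnegative baseline noise.
    """

    duration_s: float = 120.0
    sample_rate_hz: float = 1000.0
    mean_period_s: float = 3.0
    period_jitter_cv: float = 0.1
    burst_sigma_s: float = 0.2
    burst_amplitude: float = 1.0
    amplitude_jitter_cv: float = 0.1
    baseline_noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("duration_s", "sample_rate_hz", "mean_period_s",
                     "burst_sigma_s", "burst_amplitude"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.period_jitter_cv < 0 or self.amplitude_jitter_cv < 0 or self.baseline_noise_sd < 0:
            raise ValueError("cv and noise values must be >= 0")
        if self.mean_period_s <= 4.0 * self.burst_sigma_s:
            raise ValueError("mean_period_s must exceed 4 * burst_sigma_s (bursts separable)")


def gen_burst_train(spec: BurstTrainSpec):
    """Sum of Gaussian bursts at jittered period.

    Returns (trace, ground_truth) where ground_truth is a DataFrame with
    columns ``peak_time_s`` and ``amplitude``. Baseline noise is
    half-normal (the emulated signal is rectified, hence nonnegative).
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.sample_rate_hz))
    t = np.arange(n) / spec.sample_rate_hz
    value = np.zeros(n)

    times: list[float] = []
    amps: list[float] = []
    t_k = spec.mean_period_s
    while t_k <= spec.duration_s - 3.0 * spec.burst_sigma_s:
        amp = float(_lognormal_draws(rng, spec.burst_amplitude, spec.amplitude_jitter_cv, 1)[0])
        times.append(t_k)
        amps.append(amp)
        i0 = max(0, int((t_k - 5 * spec.burst_sigma_s) * spec.sample_rate_hz))
        i1 = min(n, int((t_k + 5 * spec.burst_sigma_s) * spec.sample_rate_hz) + 1)
        win = t[i0:i1] - t_k
        value[i0:i1] += amp * np.exp(-0.5 * (win / spec.burst_sigma_s) ** 2)
        t_k += float(_lognormal_draws(rng, spec.mean_period_s, spec.period_jitter_cv, 1)[0])

    if spec.baseline_noise_sd > 0:
        value = value + np.abs(rng.normal(0.0, spec.baseline_noise_sd, n))
    trace = Trace.from_values(value, spec.sample_rate_hz)
    truth = pd.DataFrame({"peak_time_s": times, "amplitude": amps})
    return trace, truth


# ---------------------------------------------------------------------------
# cell-cycle population under dual-pulse labeling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellCycleSpec:
    """Asynchronous cycling population under a CldU-then-EdU pulse schedule.

    The first analog (CldU, detected with an anti-BrdU antibody) is
    injected at t = 0, the second (EdU) ``t_cldu_to_edu_h`` later, and the
    tissue is collected ``t_edu_to_kill_h`` after that. The default
    schedule is the 2 h + 0.5 h protocol. Both analogs are assumed
    bioavailable from injection until collection, so EdU+ implies CldU+.
    """

    n_cells: int = 10_000
    t_cycle_h: float = 12.0
    t_s_h: float = 4.0
    t_cldu_to_edu_h: float = 2.0
    t_edu_to_kill_h: float = 0.5
    growth_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if not (0 < self.t_s_h < self.t_cycle_h):
            raise ValueError("need 0 < t_s_h < t_cycle_h")
        if self.t_cldu_to_edu_h <= 0 or self.t_edu_to_kill_h <= 0:
            raise ValueError("schedule times must be > 0")
        if not (0.0 <= self.growth_fraction <= 1.0):
            raise ValueError("growth_fraction must be in [0, 1]")


def _in_s_during(phase_h: np.ndarray, t_cycle: float, t_s: float,
                 a: float, b: float) -> np.ndarray:
    """True where a cell with cycle position phase_h at t=0 is in S-phase
    (defined as cycle positions [0, t_s)) at any time in [a, b]."""
    w = b - a
    if w >= t_cycle:
        return np.ones(phase_h.shape, dtype=bool)
    u = np.mod(phase_h + a, t_cycle)   # position at window start
    return (u < t_s) | (u + w >= t_cycle)


def gen_cellcycle_population(spec: CellCycleSpec) -> pd.DataFrame:
    """Per-cell label-state table for the dual-pulse schedule.

    Returns a DataFrame with columns ``cycling`` (bool), ``phase_h``
    (cycle position at the first injection, NaN for non-cycling cells),
    ``cldu_pos`` and ``edu_pos`` (bools). A cycling cell is CldU+ iff it
    is in S at any time between the CldU injection and collection, and
    EdU+ iff in S at any time between the EdU injection and collection.
    """
    rng = np.random.default_rng(spec.seed)
    cycling = rng.random(spec.n_cells) < spec.growth_fraction
    phase = np.full(spec.n_cells, np.nan)
    phase[cycling] = rng.uniform(0.0, spec.t_cycle_h, int(cycling.sum()))

    t_kill = spec.t_cldu_to_edu_h + spec.t_edu_to_kill_h
    cldu = np.zeros(spec.n_cells, dtype=bool)
    edu = np.zeros(spec.n_cells, dtype=bool)
    cldu[cycling] = _in_s_during(phase[cycling], spec.t_cycle_h, spec.t_s_h, 0.0, t_kill)
    edu[cycling] = _in_s_during(phase[cycling], spec.t_cycle_h, spec.t_s_h,
                                spec.t_cldu_to_edu_h, t_kill)
    return pd.DataFrame({
        "cycling": cycling,
        "phase_h": phase,
        "cldu_pos": cldu,
        "edu_pos": edu,
    })


# ---------------------------------------------------------------------------
# multichannel microscopy images
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChannelRule:
    """Per-channel intensity rule keyed by cell state.

    ``state_column`` of None means a counterstain: every nucleus gets
    ``positive_level``. Otherwise nuclei where the state column is truthy
    get ``positive_level`` and the rest ``negative_level``. ``cv`` adds
    per-nucleus lognormal intensity jitter around the chosen level.
    """

    state_column: Optional[str] = None
    positive_level: float = 200.0
    negative_level: float = 20.0
    cv: float = 0.0


@dataclass(frozen=True)
class ImageSpec:
    """Synthetic multichannel fluorescence field of elliptical nuclei.

    Nuclei are uniform-intensity rotated ellipses with a light Gaussian
    edge blur (``edge_sigma_px``); ``profile="gaussian"`` switches to an
    elliptical Gaussian intensity profile instead. ``nucleus_axes_px``
    gives (low, high) ranges of the full major and minor axis lengths.
    """

    shape_px: tuple = (512, 512)
    n_nuclei: int = 100
    nucleus_axes_px: tuple = ((10.0, 14.0), (7.0, 10.0))
    channel_model: dict = field(default_factory=lambda: {"dapi": ChannelRule()})
    background_level: float = 5.0
    noise_sd: float = 2.0
    min_separation_px: Optional[float] = 16.0
    edge_sigma_px: float = 1.0
    profile: str = "flat"
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.shape_px
        if h < 8 or w < 8:
            raise ValueError("image too small")
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be >= 0")
        (maj_lo, maj_hi), (min_lo, min_hi) = self.nucleus_axes_px
        if not (0 < maj_lo <= maj_hi and 0 < min_lo <= min_hi):
            raise ValueError("axis ranges must be positive and ordered")
        if maj_hi >= min(h, w):
            raise ValueError("nuclei do not fit inside the image")
        if self.profile not in ("flat", "gaussian"):
            raise ValueError("profile must be 'flat' or 'gaussian'")
        if self.noise_sd < 0 or self.background_level < 0:
            raise ValueError("noise_sd and background_level must be >= 0")


def _place_centers(rng: np.random.Generator, spec: ImageSpec, margin: float) -> np.ndarray:
    h, w = spec.shape_px
    centers: list[tuple[float, float]] = []
    max_tries = 200 * max(1, spec.n_nuclei)
    tries = 0
    min_sep = spec.min_separation_px
    while len(centers) < spec.n_nuclei:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {spec.n_nuclei} nuclei with min_separation_px="
                f"{min_sep} in a {h}x{w} image (too dense)")
        r = rng.uniform(margin, h - margin)
        c = rng.uniform(margin, w - margin)
        if min_sep is not None and centers:
            arr = np.asarray(centers)
            if np.min((arr[:, 0] - r) ** 2 + (arr[:, 1] - c) ** 2) < min_sep ** 2:
                continue
        centers.append((r, c))
    return np.asarray(centers).reshape(-1, 2)


def gen_microscopy_image(spec: ImageSpec, states: pd.DataFrame):
    """Render a multichannel image stack from per-cell states.

    Parameters
    ----------
    spec : ImageSpec
    states : DataFrame
        One row per cell (at least ``spec.n_nuclei`` rows); boolean state
        columns referenced by the spec's channel rules.

    Returns
    -------
    (stack, truth)
        ``stack`` : float32 array (n_channels, H, W), channel order =
        insertion order of ``spec.channel_model``; ``truth`` : DataFrame
        with one row per nucleus (centroid, axes, orientation,
        eccentricity, state flags, per-channel true mean intensity).
    """
    if spec.n_nuclei > len(states):
        raise ValueError("n_nuclei exceeds the number of state rows")
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape_px
    (maj_lo, maj_hi), (min_lo, min_hi) = spec.nucleus_axes_px

    margin = maj_hi / 2.0 + 2.0
    centers = _place_centers(rng, spec, margin)
    major = rng.uniform(maj_lo, maj_hi, spec.n_nuclei)
    minor = np.minimum(rng.uniform(min_lo, min_hi, spec.n_nuclei), major)
    theta = rng.uniform(0.0, np.pi, spec.n_nuclei)

    states = states.iloc[: spec.n_nuclei].reset_index(drop=True)
    channels = list(spec.channel_model.keys())
    stack = np.zeros((len(channels), h, w), dtype=np.float64)

    # per-nucleus per-channel intensity levels
    levels = np.zeros((len(channels), spec.n_nuclei))
    for ci, ch in enumerate(channels):
        rule = spec.channel_model[ch]
        if rule.state_column is None:
            base = np.full(spec.n_nuclei, rule.positive_level)
        else:
            if rule.state_column not in states.columns:
                raise ValueError(f"state column '{rule.state_column}' missing from states")
            pos = states[rule.state_column].to_numpy(dtype=bool)
            base = np.where(pos, rule.positive_level, rule.negative_level)
        jitter = _lognormal_draws(rng, 1.0, rule.cv, spec.n_nuclei)
        levels[ci] = base * jitter

    for k in range(spec.n_nuclei):
        a, b = major[k] / 2.0, minor[k] / 2.0
        r0, c0 = centers[k]
        half = int(math.ceil(a)) + 3
        rlo, rhi = int(r0) - half, int(r0) + half + 1
        clo, chi = int(c0) - half, int(c0) + half + 1
        rlo, clo = max(rlo, 0), max(clo, 0)
        rhi, chi = min(rhi, h), min(chi, w)
        rr, cc = np.mgrid[rlo:rhi, clo:chi]
        dr, dc = rr - r0, cc - c0
        cos_t, sin_t = math.cos(theta[k]), math.sin(theta[k])
        u = dr * cos_t + dc * sin_t
        v = -dr * sin_t + dc * cos_t
        q = (u / a) ** 2 + (v / b) ** 2
        if spec.profile == "flat":
            footprint = (q <= 1.0).astype(float)
        else:
            footprint = np.exp(-0.5 * q * 4.0)  # boundary at 2 sigma
        for ci in range(len(channels)):
            patch = levels[ci, k] * footprint
            np.maximum(stack[ci, rlo:rhi, clo:chi], patch,
                       out=stack[ci, rlo:rhi, clo:chi])

    if spec.edge_sigma_px > 0:
        for ci in range(len(channels)):
            stack[ci] = ndi.gaussian_filter(stack[ci], spec.edge_sigma_px)
    stack += spec.background_level
    if spec.noise_sd > 0:
        stack += rng.normal(0.0, spec.noise_sd, stack.shape)

    truth = pd.DataFrame({
        "nucleus_id": np.arange(1, spec.n_nuclei + 1),
        "centroid_row": centers[:, 0],
        "centroid_col": centers[:, 1],
        "major_axis_px": major,
        "minor_axis_px": minor,
        "orientation_rad": theta,
        "eccentricity": np.sqrt(1.0 - (minor / np.maximum(major, 1e-12)) ** 2),
    })
    for col in states.columns:
        truth[col] = states[col].to_numpy()
    for ci, ch in enumerate(channels):
        truth[f"true_mean_{ch}"] = levels[ci]
    return stack.astype(np.float32), truth
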