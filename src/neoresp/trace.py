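"""Uniformly sampled 1-D signal container shared by the physiology modules."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Trace"]


@dataclass(frozen=True)
class Trace:
    """A uniformly sampled 1-D signal (respiratory flow or integrated
    population activity).

    Attributes
    ----------
    time_s : np.ndarray
        Sample times in seconds, strictly increasing, uniform grid.
    value : np.ndarray
        Signal values, same length as ``time_s``.
    sample_rate_hz : float
        Sampling rate; must satisfy ``|dt * rate - 1| < 1e-6`` for every
        inter-sample interval.
    """

    time_s: np.ndarray
    value: np.ndarray
    sample_rate_hz: float

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        v = np.asarray(self.value, dtype=float)
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "value", v)
        if t.ndim != 1 or v.ndim != 1 or t.size != v.size:
            raise ValueError("time_s and value must be 1-D arrays of equal length")
        if t.size < 2:
            raise ValueError("a Trace needs at least two samples")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError("time_s must be strictly increasing")
        if np.any(np.abs(dt * self.sample_rate_hz - 1.0) >= 1e-6):
            raise ValueError("non-uniform sampling: time grid does not match sample_rate_hz")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(v))):
            raise ValueError("Trace contains non-finite samples")

    @classmethod
    def from_values(cls, value, sample_rate_hz: float, t0: float = 0.0) -> "Trace":
        """Build a Trace from raw samples assuming a uniform grid from ``t0``."""
        value = np.asarray(value, dtype=float)
        time_s = t0 + np.arange(value.size) / float(sample_rate_hz)
        return cls(time_s=time_s, value=value, sample_rate_hz=float(sample_rate_hz))

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate_hz

    @property
    def duration_s(self) -> float:
        return self.time_s[-1] - self.time_s[0] + self.dt

    def __len__(self) -> int:
        return self.time_s.size
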