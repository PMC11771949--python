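"""Synthetic Abeta-fiber bundle stimuli.

The circuits are driven by the mean spike rate of a bundle of low-threshold
mechanosensory (Abeta) afferents.  Each fiber spikes as an independent
Poisson process at a background rate outside the stimulus window and at the
stimulus rate ``f_ab`` inside it.  Only per-bin spike counts matter to a
rate-based model, so each bin draws a single Poisson count for the whole
bundle (sum of independent Poissons), which is distributionally identical to
event-time simulation and far cheaper.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["StimulusTrace", "generate_abeta_trace"]


@dataclass(frozen=True)
class StimulusTrace:
    """Mean bundle rate per time bin, with generation metadata."""

    time: np.ndarray      # bin start times, s (uniform, strictly increasing)
    rate: np.ndarray      # mean rate across fibers per bin, Hz
    dt: float
    n_fibers: int
    background: float
    f_ab: float
    window: tuple[float, float]
    seed: int | None

    @property
    def duration(self) -> float:
        return len(self.time) * self.dt

    def rate_at(self, t: np.ndarray) -> np.ndarray:
        """Zero-order-hold lookup of the bundle rate at times ``t``."""
        idx = np.clip((np.asarray(t) / self.dt).astype(int), 0, len(self.rate) - 1)
        return self.rate[idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.time, "rate_Hz": self.rate})


def constant_trace(f_ab: float, T: float = 1.0, dt: float = 1e-3) -> StimulusTrace:
    """Noise-free constant-rate trace (no background, whole-trace window)."""
    time = np.arange(int(round(T / dt))) * dt
    return StimulusTrace(
        time=time, rate=np.full_like(time, float(f_ab)), dt=dt, n_fibers=0,
        background=f_ab, f_ab=f_ab, window=(0.0, T), seed=None,
    )


def generate_abeta_trace(
    f_ab: float,
    t_on: float = 0.2,
    t_off: float = 0.7,
    T: float = 1.0,
    dt: float = 1e-3,
    n_fibers: int = 300,
    background: float = 1.0,
    seed: int | None = None,
) -> StimulusTrace:
    """Compound-Poisson bundle rate trace.

    Per bin of width ``dt``, the bundle spike count is Poisson with mean
    ``n_fibers * r * dt`` where ``r`` is ``background`` outside
    ``[t_on, t_off)`` and ``f_ab`` inside; the returned rate is
    ``count / (n_fibers * dt)``.  Bit-reproducible given ``seed``.
    """
    if f_ab < 0 or background < 0:
        raise ValueError("rates must be nonnegative")
    if not (0 <= t_on < t_off <= T):
        raise ValueError("need 0 <= t_on < t_off <= T")
    if dt <= 0 or n_fibers < 1:
        raise ValueError("dt must be positive and n_fibers >= 1")
    rng = np.random.default_rng(seed)
    n_bins = int(round(T / dt))
    time = np.arange(n_bins) * dt
    per_fiber = np.where((time >= t_on) & (time < t_off), float(f_ab), float(background))
    counts = rng.poisson(n_fibers * per_fiber * dt)
    return StimulusTrace(
        time=time, rate=counts / (n_fibers * dt), dt=dt, n_fibers=n_fibers,
        background=background, f_ab=f_ab, window=(t_on, t_off), seed=seed,
    )
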