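"""Firing-rate population parameters and sigmoidal activation.

A neural population is described by its mean membrane voltage V (mV) and mean
firing rate f (Hz).  The rate is a static sigmoidal function of voltage,

    f(V) = 0.5 * m * (1 + tanh((V - beta) / alpha)),

with maximum rate ``m``, half-activation voltage ``beta`` and slope scale
``alpha``.  Three derived voltage cutoffs are used throughout the analysis:
the firing threshold ``beta - alpha`` (rate = 0.5*(1+tanh(-1)) ~ 0.12 of max)
and the biological floor/ceiling ``beta -/+ 12*alpha`` (rate ~ 4e-11 and
1 - 4e-11 of max).  Cutoffs are computed, never stored, so they can never
drift out of sync with ``alpha`` and ``beta``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PopulationParams",
    "INHIBITORY",
    "EXCITATORY",
    "activation_rate",
]


@dataclass(frozen=True)
class PopulationParams:
    """Constants for one excitatory or inhibitory population.

    Parameters
    ----------
    role : str
        ``"excitatory"`` or ``"inhibitory"``.
    m : float
        Maximum firing rate (Hz).
    alpha : float
        Sigmoid slope scale (mV).
    beta : float
        Half-activation voltage (mV).
    V_rest : float
        Resting voltage (mV).
    tau : float
        Membrane time constant (s).
    """

    role: str
    m: float
    alpha: float
    beta: float
    V_rest: float
    tau: float

    def __post_init__(self) -> None:
        if self.role not in ("excitatory", "inhibitory"):
            raise ValueError(f"unknown role {self.role!r}")
        if self.m <= 0 or self.alpha <= 0 or self.tau <= 0:
            raise ValueError("m, alpha and tau must be positive")

    @property
    def V_thr(self) -> float:
        """Firing-threshold voltage beta - alpha (mV)."""
        return self.beta - self.alpha

    @property
    def V_min(self) -> float:
        """Lower biological voltage bound beta - 12*alpha (mV)."""
        return self.beta - 12.0 * self.alpha

    @property
    def V_max(self) -> float:
        """Upper biological voltage bound beta + 12*alpha (mV)."""
        return self.beta + 12.0 * self.alpha

    def rate(self, V):
        """Firing rate (Hz) at voltage ``V`` (mV, scalar or array)."""
        return activation_rate(V, self)


def activation_rate(V, pop: PopulationParams):
    """Sigmoidal steady-state firing rate 0.5*m*(1 + tanh((V - beta)/alpha)).

    Strictly increasing in ``V`` and bounded in (0, m).  ``V`` may be a
    scalar or an ndarray; non-finite voltages raise.
    """
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ValueError("voltage must be finite")
    out = 0.5 * pop.m * (1.0 + np.tanh((V - pop.beta) / pop.alpha))
    return float(out) if out.ndim == 0 else out


# Default parameter sets: tonic-firing lamina I neurons for inhibitory
# populations, delayed-firing lamina I-II neurons for excitatory populations.
INHIBITORY = PopulationParams(
    role="inhibitory", m=80.0, alpha=9.3, beta=-30.0, V_rest=-60.0, tau=0.02
)
EXCITATORY = PopulationParams(
    role="excitatory", m=50.0, alpha=7.9, beta=-17.0, V_rest=-60.0, tau=0.024
)
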