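"""Logistic reproduction over one generation.

Between dispersal events the density obeys dN/dt = a N (1 - N/K); integrating
that flow over a generation time T gives the exact per-generation operator

    R_T(N) = e^{aT} K N / (K + (e^{aT} - 1) N),

whose fixed points are 0 and K and whose slope at N = 0 is e^{aT} — the net
reproductive factor that enters the leading-edge characteristic equation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

__all__ = ["Demography", "logistic_step"]


@dataclass(frozen=True)
class Demography:
    """Logistic growth parameters: rate ``a`` (1/yr), generation time ``T``
    (yr), carrying capacity ``K`` (density units; the front speed does not
    depend on it, so it defaults to 1)."""

    a: float
    T: float
    K: float = 1.0

    def __post_init__(self):
        if not self.a > 0:
            raise ValidationError(f"growth rate a must be positive (got {self.a})")
        if not self.T > 0:
            raise ValidationError(f"generation time T must be positive (got {self.T})")
        if not self.K > 0:
            raise ValidationError(f"carrying capacity K must be positive (got {self.K})")

    @property
    def growth_factor(self) -> float:
        """e^{aT}, the linearized one-generation multiplication factor."""
        return math.exp(self.a * self.T)


def logistic_step(demog: Demography, N):
    """Apply the exact logistic flow over one generation to density ``N``.

    Accepts scalars or arrays; densities above K relax monotonically back
    toward K.  Negative densities are rejected.
    """
    N_arr = np.asarray(N, dtype=float)
    if np.any(N_arr < 0):
        raise ValidationError("population density must be nonnegative")
    g = demog.growth_factor
    out = g * demog.K * N_arr / (demog.K + (g - 1.0) * N_arr)
    return out if out.ndim else float(out)
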