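"""The two built-in range expansions and the derived figure quantities.

Khoi-khoi herders (southwestern Africa, 2300-1100 yr BP) and southern Bantu
farmers (southeastern Africa, 3400-1400 yr BP) share the demographic ranges
0.023 <= a <= 0.033 /yr and 29 <= T <= 35 yr but have different ethnographic
dispersal kernels.  The "fast" demographic extreme (a_max, T_min) gives the
upper predicted-speed curve, the "slow" extreme (a_min, T_max) the lower one.

Derived quantities:

* ``bias_effect`` — percentage of the front speed attributable to anisotropy,
  100 (c(p) - c(0.5)) / c(p), at a fixed demographic extreme;
* ``consistency_threshold`` — smallest bias p (on a grid) at which the fast
  curve reaches the observed lower speed bound, i.e. the predicted band first
  overlaps the observed interval;
* ``effect_range`` / ``figure_tables`` — caption-style summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ValidationError
from .frontspeed import front_speed
from .growth import Demography
from .kernels import AngularBias, RadialKernel

__all__ = [
    "CaseStudy",
    "builtin_case",
    "bias_effect",
    "consistency_threshold",
    "effect_range",
    "figure_tables",
]

#: herder (Khoi-khoi) ethnographic dispersal histogram
_HERDER_KERNEL = RadialKernel(
    r=(0.5, 3.0, 7.5, 15.0, 25.0, 35.0, 95.0),
    p=(0.67, 0.05, 0.04, 0.07, 0.08, 0.04, 0.05),
)
#: farmer (southern Bantu) ethnographic dispersal histogram
_FARMER_KERNEL = RadialKernel(
    r=(2.4, 14.5, 36.2, 60.4),
    p=(0.40, 0.17, 0.17, 0.26),
)

_A_RANGE = (0.023, 0.033)  # 1/yr
_T_RANGE = (29.0, 35.0)  # yr


@dataclass(frozen=True)
class CaseStudy:
    name: str
    kernel: RadialKernel
    a_range: Tuple[float, float]  # 1/yr
    T_range: Tuple[float, float]  # yr
    observed_speed: Tuple[float, float]  # km/yr

    def __post_init__(self):
        if not self.a_range[0] <= self.a_range[1]:
            raise ValidationError("a_range must be ordered")
        if not self.T_range[0] <= self.T_range[1]:
            raise ValidationError("T_range must be ordered")
        if not 0 < self.observed_speed[0] < self.observed_speed[1]:
            raise ValidationError("observed_speed must satisfy 0 < low < high")

    def demography(self, extreme: str) -> Demography:
        """``fast`` = (a_max, T_min): upper speed curve; ``slow`` = (a_min, T_max)."""
        if extreme == "fast":
            return Demography(a=self.a_range[1], T=self.T_range[0])
        if extreme == "slow":
            return Demography(a=self.a_range[0], T=self.T_range[1])
        raise ValidationError(f"extreme must be 'fast' or 'slow' (got {extreme!r})")


_CASES = {
    "khoikhoi": CaseStudy(
        name="khoikhoi",
        kernel=_HERDER_KERNEL,
        a_range=_A_RANGE,
        T_range=_T_RANGE,
        observed_speed=(1.4, 3.3),
    ),
    "bantu": CaseStudy(
        name="bantu",
        kernel=_FARMER_KERNEL,
        a_range=_A_RANGE,
        T_range=_T_RANGE,
        observed_speed=(1.5, 2.3),
    ),
}


def builtin_case(name: str) -> CaseStudy:
    """Return one of the built-in case studies: ``khoikhoi`` or ``bantu``."""
    try:
        return _CASES[name]
    except KeyError:
        raise ValidationError(
            f"unknown case {name!r}; available: {sorted(_CASES)}"
        ) from None


def _speed(case: CaseStudy, bias: AngularBias, extreme: str) -> float:
    return front_speed(case.demography(extreme), case.kernel, bias).c


def bias_effect(
    case: CaseStudy, variant: str, p: Optional[float], extreme: str
) -> float:
    """Percent of the front speed due to the bias: 100 (c(p) - c_iso) / c(p).

    Both speeds are evaluated at the same demographic extreme; ``p`` is
    ignored for the ``delta`` and ``isotropic`` variants.
    """
    bias = AngularBias(variant) if variant in ("delta", "isotropic") else AngularBias(variant, p)
    c_p = _speed(case, bias, extreme)
    c_iso = _speed(case, AngularBias("isotropic"), extreme)
    return 100.0 * (c_p - c_iso) / c_p


_MAX_P = {"model1": 1.0, "model2": 1.0}
_DEFAULT_STEP = {"model1": 0.1, "model2": 0.1, "model3": 0.01}


def consistency_threshold(
    case: CaseStudy, variant: str, p_step: Optional[float] = None
) -> Optional[float]:
    """Smallest grid value of p whose fast-curve speed reaches the observed low.

    The grid starts at p = 0.5 with step ``p_step`` (default 0.01 for model 3,
    0.1 for models 1-2).  Returns None ("inconsistent") when even the
    variant's maximal bias — p = 1 for models 1-2, the delta limit for
    model 3 — stays below the observed lower bound.
    """
    if p_step is None:
        p_step = _DEFAULT_STEP.get(variant)
    if p_step is None or p_step <= 0:
        raise ValidationError("p_step must be positive")
    low = case.observed_speed[0]
    if variant in ("model1", "model2"):
        c_cap = _speed(case, AngularBias(variant, _MAX_P[variant]), "fast")
    elif variant == "model3":
        c_cap = _speed(case, AngularBias("delta"), "fast")
    else:
        raise ValidationError(f"threshold search needs a parametric variant, got {variant!r}")
    if c_cap < low:
        return None
    k = 0
    while True:
        p = 0.5 + k * p_step
        if variant in ("model1", "model2") and p > _MAX_P[variant] + 1e-12:
            return None
        if _speed(case, AngularBias(variant, min(p, _MAX_P.get(variant, p))), "fast") >= low:
            return round(p, 10)
        k += 1


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def effect_range(
    case: CaseStudy, variant: str, p_step: Optional[float] = None
) -> Tuple[int, int]:
    """(min, max) bias effect in integer percent over the consistency range.

    The effect is scanned over p from the consistency threshold up to the
    variant's maximal bias (p = 1 for models 1-2; up to the delta saturation
    for model 3), at both demographic extremes, on a 0.01 grid, and the
    endpoints are rounded to the nearest integer percent.
    """
    thr = consistency_threshold(case, variant, p_step)
    if thr is None:
        raise ValidationError(f"{variant} is never consistent for case {case.name}")
    effects = []
    if variant in ("model1", "model2"):
        grid = np.arange(thr, _MAX_P[variant] + 1e-9, 0.01)
        for extreme in ("fast", "slow"):
            for p in grid:
                effects.append(bias_effect(case, variant, float(p), extreme))
    else:  # model3: effect is monotone in p and saturates at the delta limit
        grid = [thr, thr + 0.05, thr + 0.2, thr + 0.5, 1.0, 2.0]
        for extreme in ("fast", "slow"):
            for p in grid:
                effects.append(bias_effect(case, variant, float(p), extreme))
            effects.append(bias_effect(case, "delta", None, extreme))
    return _round_half_up(min(effects)), _round_half_up(max(effects))


def figure_tables(
    case: CaseStudy, variant: str, p_grid: Sequence[float]
) -> pd.DataFrame:
    """Per-p table (p, c_fast, c_slow, effect_fast, effect_slow).

    For model 3 a final row with p = inf carries the delta saturation values.
    """
    rows = []
    iso_fast = _speed(case, AngularBias("isotropic"), "fast")
    iso_slow = _speed(case, AngularBias("isotropic"), "slow")

    def make_row(p_label, bias):
        c_fast = _speed(case, bias, "fast")
        c_slow = _speed(case, bias, "slow")
        return {
            "p": p_label,
            "c_fast": c_fast,
            "c_slow": c_slow,
            "effect_fast": 100.0 * (c_fast - iso_fast) / c_fast,
            "effect_slow": 100.0 * (c_slow - iso_slow) / c_slow,
        }

    for p in p_grid:
        rows.append(make_row(float(p), AngularBias(variant, p)))
    if variant == "model3":
        rows.append(make_row(math.inf, AngularBias("delta")))
    return pd.DataFrame(rows)
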