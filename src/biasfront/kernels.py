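"""Separable dispersal kernels: radial histogram times angular bias density.

The per-generation displacement of an individual is modelled as a radial jump
of length ``Delta`` drawn from a histogram (distances ``r_i`` with
probabilities ``p_i``) combined with an independent direction ``theta``
measured from the local front-propagation axis (theta = 0 points into empty
territory).  Three angular families are supported:

* ``model1`` — piecewise-constant: probability ``p`` of moving forward
  (|theta| <= pi/2), ``1 - p`` backward;
* ``model2`` — raised cosine, ``(1 + (2p - 1) cos theta) / (2 pi)``;
* ``model3`` — wrapped-Gaussian-like density ``A exp(-q^2 theta^2)`` on
  [-pi, pi] with concentration ``q = 20 p - 10`` and normalization
  ``A = q / (sqrt(pi) erf(pi q))``;

plus the two limits ``isotropic`` (uniform, p = 0.5) and ``delta`` (all mass
at theta = 0, the p -> infinity limit of model 3, kept as an exact variant
rather than a large-q approximation).

``p = 0.5`` is isotropic in every family; ``p < 0.5`` (backward bias) is
rejected rather than given a meaning the model does not define.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, special

from .errors import ValidationError

__all__ = [
    "RadialKernel",
    "AngularBias",
    "angular_pdf",
    "angular_mgf",
    "angular_log_mgf",
    "Marginal1D",
    "marginal_forward_kernel",
    "random_kernel_fixture",
]

_TWO_PI = 2.0 * math.pi

# e^{-s} L0(s) is computed exactly up to this s; beyond it, L0 and I0 agree to
# far better than double precision (their difference decays like 1/s while
# both grow like e^s / sqrt(s)), so the scaled Struve falls back to i0e.
_STRUVE_EXACT_MAX = 500.0


@dataclass(frozen=True)
class RadialKernel:
    """Histogram of dispersal distances: ``r`` in km, ``p`` probabilities."""

    r: tuple
    p: tuple

    def __post_init__(self):
        r = np.asarray(self.r, dtype=float)
        p = np.asarray(self.p, dtype=float)
        if r.ndim != 1 or p.ndim != 1 or r.size != p.size:
            raise ValidationError("r and p must be 1-D sequences of equal length")
        if r.size < 1:
            raise ValidationError("kernel needs at least one bin")
        if np.any(r <= 0):
            raise ValidationError("all distances must be positive")
        if np.any(np.diff(r) <= 0):
            raise ValidationError("distances must be strictly increasing")
        if np.any(p < 0):
            raise ValidationError("probabilities must be nonnegative")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValidationError(
                f"probabilities must sum to 1 (got {p.sum():.15g})"
            )
        object.__setattr__(self, "r", tuple(float(x) for x in r))
        object.__setattr__(self, "p", tuple(float(x) for x in p))

    @property
    def distances(self) -> np.ndarray:
        return np.asarray(self.r, dtype=float)

    @property
    def probabilities(self) -> np.ndarray:
        return np.asarray(self.p, dtype=float)

    @property
    def n_bins(self) -> int:
        return len(self.r)

    @property
    def r_max(self) -> float:
        return self.r[-1]

    @property
    def r_min(self) -> float:
        return self.r[0]

    @classmethod
    def from_csv(cls, path) -> "RadialKernel":
        df = pd.read_csv(path)
        missing = {"r_km", "prob"} - set(df.columns)
        if missing:
            raise ValidationError(f"kernel CSV missing columns: {sorted(missing)}")
        return cls(tuple(df["r_km"]), tuple(df["prob"]))

    def to_csv(self, path) -> None:
        pd.DataFrame({"r_km": self.r, "prob": self.p}).to_csv(path, index=False)


_VARIANTS = ("model1", "model2", "model3", "delta", "isotropic")


@dataclass(frozen=True)
class AngularBias:
    """Angular dispersal family plus its bias parameter ``p``.

    ``p`` is the forward-migration probability for models 1-2 and the mapped
    Gaussian concentration ``p = (q + 10) / 20`` for model 3.  For the
    ``delta`` variant ``p`` is conventionally infinite; for ``isotropic`` it
    is 0.5.
    """

    variant: str
    p: float = 0.5

    def __post_init__(self):
        if self.variant not in _VARIANTS:
            raise ValidationError(
                f"unknown variant {self.variant!r}; expected one of {_VARIANTS}"
            )
        p = float(self.p)
        if self.variant == "delta":
            p = math.inf
        elif self.variant == "isotropic":
            p = 0.5
        elif self.variant in ("model1", "model2"):
            if not 0.5 <= p <= 1.0:
                raise ValidationError(
                    f"{self.variant} requires 0.5 <= p <= 1 (got {p}); "
                    "p > 1 would make the density negative"
                    if self.variant == "model2"
                    else f"{self.variant} requires 0.5 <= p <= 1 (got {p})"
                )
        else:  # model3
            if not (p >= 0.5 and math.isfinite(p)):
                raise ValidationError(
                    f"model3 requires finite p >= 0.5 (got {p}); "
                    "use variant='delta' for the p -> infinity limit"
                )
        object.__setattr__(self, "p", p)

    @property
    def q(self) -> float:
        """Gaussian concentration ``q = 20 p - 10`` (model 3 only)."""
        if self.variant != "model3":
            raise ValidationError("q is defined only for model3")
        return 20.0 * self.p - 10.0

    @property
    def normalization(self) -> float:
        """Model-3 prefactor ``A = q / (sqrt(pi) erf(pi q))``; -> 1/(2 pi) as q -> 0."""
        q = self.q
        if q < 1e-6:
            # erf(pi q) ~ 2 pi q / sqrt(pi); the ratio tends to 1 / (2 pi)
            return 1.0 / _TWO_PI
        return q / (math.sqrt(math.pi) * special.erf(math.pi * q))

    @property
    def is_isotropic(self) -> bool:
        return self.variant == "isotropic" or (
            self.variant in ("model1", "model2", "model3") and self.p == 0.5
        )


def angular_pdf(bias: AngularBias, theta):
    """Angular density Phi(theta) on [-pi, pi] (1/radian).

    Even in theta, nonnegative, integrates to one.  The ``delta`` variant is a
    point measure and has no density; asking for it is an error.
    """
    th = np.asarray(theta, dtype=float)
    if np.any(np.abs(th) > math.pi + 1e-12):
        raise ValidationError("theta must lie in [-pi, pi]")
    if bias.variant == "delta":
        raise ValidationError("the delta variant is a point measure with no density")
    if bias.is_isotropic:
        out = np.full_like(th, 1.0 / _TWO_PI)
    elif bias.variant == "model1":
        forward = np.abs(th) <= math.pi / 2
        out = np.where(forward, bias.p / math.pi, (1.0 - bias.p) / math.pi)
    elif bias.variant == "model2":
        out = (1.0 + (2.0 * bias.p - 1.0) * np.cos(th)) / _TWO_PI
    else:  # model3
        q = bias.q
        out = bias.normalization * np.exp(-(q * q) * th * th)
    return out if out.ndim else float(out)


def _scaled_struve_l0(s: np.ndarray) -> np.ndarray:
    """e^{-s} L0(s), stable for arbitrary s >= 0.

    Series head 2s/pi below 1e-6 (relative error O(s^2); scipy's modstruve is
    unreliable for subnormal arguments), the scipy evaluation in the middle,
    and i0e beyond 500 where L0 - I0 ~ -2/(pi s) is drowned by e^{-s}.
    """
    s = np.asarray(s, dtype=float)
    safe = np.clip(s, 1e-6, _STRUVE_EXACT_MAX)
    exact = np.exp(-safe) * special.modstruve(0, safe)
    out = np.where(s > _STRUVE_EXACT_MAX, special.i0e(s), exact)
    return np.where(s < 1e-6, 2.0 * s / math.pi, out)


def _log_mgf_model3(q: float, amplitude: float, s: float) -> float:
    """log of int_{-pi}^{pi} A exp(-q^2 th^2 + s cos th) dth, shifted by s.

    Integrates A exp(-q^2 th^2 + s (cos th - 1)) — bounded by A — so the
    result never overflows.  The integrand peaks sharply at theta = 0 for
    large q or large s; splitting the interval at 0 forces the adaptive rule
    onto the peak.
    """
    if s == 0.0:
        return 0.0  # the density is normalized; avoid quadrature noise

    def f(th):
        return amplitude * math.exp(-(q * q) * th * th + s * (math.cos(th) - 1.0))

    val, _ = integrate.quad(
        f, -math.pi, math.pi, points=[0.0], limit=200, epsabs=1e-12, epsrel=1e-10
    )
    return s + math.log(val)


def angular_log_mgf(bias: AngularBias, s):
    """log B(s) where B(s) = int e^{s cos theta} Phi(theta) dtheta.

    This is the angular factor of the linearized front problem evaluated at
    s = lambda * r.  Working in logs keeps the characteristic equation
    computable for s of several thousand, where e^s overflows.
    """
    s_arr = np.asarray(s, dtype=float)
    if np.any(s_arr < 0):
        raise ValidationError("s must be nonnegative")
    if bias.variant == "delta":
        out = s_arr.astype(float)
    elif bias.is_isotropic:
        out = s_arr + np.log(special.i0e(s_arr))
    elif bias.variant == "model1":
        w = 2.0 * bias.p - 1.0
        out = s_arr + np.log(special.i0e(s_arr) + w * _scaled_struve_l0(s_arr))
    elif bias.variant == "model2":
        w = 2.0 * bias.p - 1.0
        out = s_arr + np.log(special.i0e(s_arr) + w * special.i1e(s_arr))
    else:  # model3, q > 0
        q, amp = bias.q, bias.normalization
        out = np.vectorize(lambda x: _log_mgf_model3(q, amp, x))(s_arr)
    return out if np.ndim(out) else float(out)


def angular_mgf(bias: AngularBias, s):
    """B(s) itself; exact 1 at s = 0, between e^{-s} and e^{s} elsewhere."""
    return np.exp(angular_log_mgf(bias, s))


class Marginal1D(NamedTuple):
    """Discrete distribution of the along-front displacement Delta_x.

    ``cell_offsets`` are signed integer multiples of ``grid_spacing``;
    ``weights`` sum to one.  ``forward_mass`` is the probability of a forward
    displacement (Delta_x > 0) of the underlying continuous law, recorded
    before deposition because cell splitting smears sign information near
    Delta_x = 0.
    """

    cell_offsets: np.ndarray
    weights: np.ndarray
    grid_spacing: float
    forward_mass: float


def _theta_nodes_weights(bias: AngularBias, n_nodes: int):
    """Quadrature nodes/weights for the angular density of one radial bin.

    model1 is piecewise constant with jumps at +-pi/2, so each of the two
    pieces is sampled at midpoints carrying exactly its total mass; the smooth
    variants use a trapezoid rule on [-pi, pi].
    """
    if bias.variant == "model1" and not bias.is_isotropic:
        n_half = max(n_nodes // 2, 8)
        fwd = np.linspace(-math.pi / 2, math.pi / 2, n_half + 1)
        fwd_mid = 0.5 * (fwd[1:] + fwd[:-1])
        bwd = np.linspace(math.pi / 2, 3 * math.pi / 2, n_half + 1)
        bwd_mid = 0.5 * (bwd[1:] + bwd[:-1])  # wraps past pi; only cos matters
        nodes = np.concatenate([fwd_mid, bwd_mid])
        weights = np.concatenate(
            [np.full(n_half, bias.p / n_half), np.full(n_half, (1 - bias.p) / n_half)]
        )
        return nodes, weights
    nodes = np.linspace(-math.pi, math.pi, n_nodes)
    dens = angular_pdf(bias, nodes)
    weights = np.asarray(dens, dtype=float).copy()
    weights[0] *= 0.5
    weights[-1] *= 0.5
    weights *= nodes[1] - nodes[0]
    weights /= weights.sum()
    return nodes, weights


def marginal_forward_kernel(
    kernel: RadialKernel,
    bias: AngularBias,
    grid_spacing: float,
    theta_nodes: int = 721,
) -> Marginal1D:
    """Project the 2-D kernel onto the front axis: law of Delta_x = r cos(theta).

    For planar fronts of the cohabitation equation with a separable kernel the
    2-D dispersal convolution reduces exactly to a 1-D convolution with this
    marginal.  Mass is deposited on the Delta_x grid by linear (cloud-in-cell)
    splitting between the two bracketing nodes, except for the ``delta``
    variant, whose displacement is exactly +r_i and lands in the single cell
    containing it.
    """
    if grid_spacing <= 0:
        raise ValidationError("grid_spacing must be positive")
    if grid_spacing > kernel.r_min / 2:
        raise ValidationError(
            f"grid_spacing {grid_spacing} too coarse for the smallest bin "
            f"r = {kernel.r_min} km (need <= {kernel.r_min / 2})"
        )
    if theta_nodes < 721:
        raise ValidationError("theta_nodes must be at least 721")
    half_width = int(math.ceil(kernel.r_max / grid_spacing)) + 1
    acc = np.zeros(2 * half_width + 1)

    def deposit(dx, mass):
        u = dx / grid_spacing + half_width
        j = np.floor(u).astype(int)
        frac = u - j
        np.add.at(acc, j, mass * (1.0 - frac))
        np.add.at(acc, j + 1, mass * frac)

    if bias.variant == "delta":
        forward = 1.0
        for r_i, p_i in zip(kernel.distances, kernel.probabilities):
            j = int(round(r_i / grid_spacing))
            acc[j + half_width] += p_i
    else:
        nodes, weights = _theta_nodes_weights(bias, theta_nodes)
        cos_nodes = np.cos(nodes)
        forward = float(weights[cos_nodes > 0].sum()
                        + 0.5 * weights[cos_nodes == 0].sum())
        for r_i, p_i in zip(kernel.distances, kernel.probabilities):
            deposit(r_i * cos_nodes, p_i * weights)

    nz = acc > 0
    offsets = np.nonzero(nz)[0] - half_width
    weights_out = acc[nz]
    weights_out = weights_out / weights_out.sum()
    return Marginal1D(offsets, weights_out, float(grid_spacing), forward)


def random_kernel_fixture(
    seed: int, n_bins: int, max_distance: float = 100.0
) -> RadialKernel:
    """Reproducible synthetic radial kernel for property tests."""
    if n_bins < 1:
        raise ValidationError("n_bins must be >= 1")
    rng = np.random.default_rng(seed)
    while True:
        r = np.sort(rng.uniform(0.05 * max_distance, max_distance, size=n_bins))
        if n_bins == 1 or np.all(np.diff(r) > 1e-6 * max_distance):
            break
    p = rng.dirichlet(np.ones(n_bins))
    p = p / p.sum()
    # push residual rounding error into the largest entry so the sum is exact
    p[np.argmax(p)] += 1.0 - p.sum()
    return RadialKernel(tuple(r), tuple(p))
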