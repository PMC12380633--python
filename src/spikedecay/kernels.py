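"""Parametric distance-decay kernel families W(i, j).

Five families map intersomatic distance (mm) to an interaction weight:

- ``exponential``:    W(d) = exp(-lambda * d),  lambda in 1/mm
- ``half_gaussian``:  W(d) = exp(-d^2 / (2 sigma^2)),  sigma in mm
- ``linear``:         W(d) = max(1 - sigma * d, 0),  sigma in 1/mm
- ``inverse_square``: W(d) = 1 / (d^2 + sigma),  sigma in mm^2
- ``lognormal``:      W(d) = 1/(d sigma sqrt(2 pi)) * exp(-(log d^2 - mu)^2 / (2 sigma^2))

The same families serve three roles: connection probabilities for the
generators (clipped to [0, 1] where the family can exceed 1), interaction
weights in the raster-only likelihood, and coupling kernels in the spatial
GLM. The linear form is clipped at zero beyond d = 1/sigma, since a negative
weight is meaningless as a probability or interaction strength. The lognormal
form is implemented exactly as stated (the exponent uses log d^2 while mu is
fixed from the mean of log d); it is undefined at d = 0, where the weight is
taken as 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict

import numpy as np

from .core import Geometry

__all__ = [
    "FAMILIES",
    "DecayKernel",
    "kernel_weight",
    "connection_probability",
    "fix_lognormal_mu",
]

FAMILIES = ("exponential", "half_gaussian", "linear", "inverse_square", "lognormal")

#: Default search bounds for the scale parameter of each family, used by the
#: estimators. Units follow the family definition above.
DEFAULT_BOUNDS: Dict[str, tuple] = {
    "exponential": (0.1, 20.0),
    "half_gaussian": (0.02, 2.0),
    "linear": (0.1, 20.0),
    "inverse_square": (1e-3, 10.0),
    "lognormal": (0.05, 5.0),
}


@dataclass(frozen=True)
class DecayKernel:
    """A decay family plus its (positive) scale parameter.

    ``mu`` is only meaningful for the lognormal family, where it is fixed
    from the geometry (see :func:`fix_lognormal_mu`) rather than estimated.
    """

    family: str
    scale: float
    mu: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown kernel family {self.family!r}")
        if not np.isfinite(self.scale) or self.scale <= 0:
            raise ValueError("kernel scale parameter must be positive and finite")

    def __call__(self, d):
        return kernel_weight(self, d)

    def weight_derivative(self, d):
        """dW/d(scale) evaluated element-wise — used by the spatial GLM."""
        d = np.asarray(d, dtype=float)
        s = self.scale
        if self.family == "exponential":
            return -d * np.exp(-s * d)
        if self.family == "half_gaussian":
            return (d * d / s**3) * np.exp(-(d * d) / (2.0 * s * s))
        if self.family == "linear":
            return np.where(1.0 - s * d > 0, -d, 0.0)
        if self.family == "inverse_square":
            return -1.0 / (d * d + s) ** 2
        # lognormal: W * (-1/sigma + (L - mu)^2 / sigma^3), L = log d^2
        w = kernel_weight(self, d)
        with np.errstate(divide="ignore", invalid="ignore"):
            L = np.log(d * d)
        out = np.where(d > 0, w * (-1.0 / s + (L - self.mu) ** 2 / s**3), 0.0)
        return out


def kernel_weight(kernel: DecayKernel, d) -> np.ndarray:
    """Evaluate the kernel at distance(s) ``d`` (mm); vectorized.

    Returns a nonnegative array (scalar input gives a 0-d array convertible
    with ``float``). Exponential and half-Gaussian return 1 at d = 0; the
    lognormal weight at d = 0 is 0 (with a warning) since the density-style
    prefactor 1/d diverges there.
    """
    d = np.asarray(d, dtype=float)
    if (d < 0).any():
        raise ValueError("distances must be nonnegative")
    s = kernel.scale
    if kernel.family == "exponential":
        return np.exp(-s * d)
    if kernel.family == "half_gaussian":
        return np.exp(-(d * d) / (2.0 * s * s))
    if kernel.family == "linear":
        return np.clip(1.0 - s * d, 0.0, None)
    if kernel.family == "inverse_square":
        return 1.0 / (d * d + s)
    # lognormal (as stated: exponent in log d^2, mu fixed from mean log d)
    if (d == 0).any():
        warnings.warn(
            "lognormal kernel undefined at d = 0; returning weight 0 for coincident pairs",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        L = np.log(d * d)
        w = np.exp(-((L - kernel.mu) ** 2) / (2.0 * s * s)) / (d * s * np.sqrt(2.0 * np.pi))
    return np.where(d > 0, w, 0.0)


def connection_probability(lam: float, d) -> np.ndarray:
    """Exponential wiring rule: P(connected) = exp(-lambda * d).

    ``lam`` is the decay rate in 1/mm; lam = 0 gives all-to-all wiring and
    d = 0 gives probability 1. 1/lam is the characteristic length scale of
    connectivity.
    """
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    d = np.asarray(d, dtype=float)
    if (d < 0).any():
        raise ValueError("distances must be nonnegative")
    return np.exp(-lam * d)


def fix_lognormal_mu(geometry: Geometry) -> float:
    """Fix the lognormal location as the mean of log d over ordered pairs.

    mu = (1 / (N (N-1))) * sum_{i != j} log(d_ij). Any coincident pair makes
    the mean undefined and raises, naming the offending pair.
    """
    n = geometry.n_neurons
    if n < 2:
        raise ValueError("need at least 2 neurons to fix the lognormal mu")
    d = geometry.distances
    off = ~np.eye(n, dtype=bool)
    if (d[off] == 0).any():
        i, j = np.argwhere((d == 0) & off)[0]
        raise ValueError(f"coincident neurons {i} and {j} (d = 0): lognormal mu undefined")
    return float(np.log(d[off]).mean())
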