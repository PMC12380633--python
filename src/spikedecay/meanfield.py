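"""Mean-field predictions linking coupling, noise and spatial decay to
pairwise correlations.

Two neurons at distance d share a fraction K(d) ~ exp(-2 lambda d) of their
presynaptic pool when wiring probability decays as exp(-lambda d). Under weak
coupling the spike-count correlation is then

    C(d) ~ J^2 / (J^2 + sigma^2) * exp(-2 lambda d)

with J the mean synaptic strength and sigma^2 the variance of the private
input noise. A saturating variant keeps the shared-input term in the
denominator:

    C(d) ~ J^2 e^{-2 lambda d} / (J^2 e^{-2 lambda d} + sigma^2)

Both coincide at lambda = 0 (upper bound J^2/(J^2+sigma^2)) and vanish as
lambda d grows; they agree to first order when J^2 e^{-2 lambda d} << sigma^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MeanFieldParams",
    "shared_input_fraction",
    "predicted_correlation",
    "predicted_correlation_saturating",
]


@dataclass(frozen=True)
class MeanFieldParams:
    """J: mean synaptic strength; sigma2: shared-noise variance;
    lambda_decay in 1/mm; r: mean firing rate per bin."""

    J: float
    sigma2: float
    lambda_decay: float
    r: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be nonnegative")
        if self.sigma2 == 0 and self.J == 0:
            raise ValueError("correlation undefined for J = 0 with sigma2 = 0")
        if self.lambda_decay < 0:
            raise ValueError("lambda_decay must be nonnegative")
        if not (0 <= self.r <= 1):
            raise ValueError("r must be a per-bin rate in [0, 1]")


def shared_input_fraction(lam: float, d) -> np.ndarray:
    """Fraction of presynaptic inputs shared by a pair at distance d (mm):
    K(d) = exp(-2 lambda d)."""
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    d = np.asarray(d, dtype=float)
    if (d < 0).any():
        raise ValueError("distances must be nonnegative")
    return np.exp(-2.0 * lam * d)


def predicted_correlation(params: MeanFieldParams, d) -> np.ndarray:
    """Weak-coupling correlation: J^2/(J^2 + sigma^2) * exp(-2 lambda d)."""
    amp = params.J**2 / (params.J**2 + params.sigma2)
    return amp * shared_input_fraction(params.lambda_decay, d)


def predicted_correlation_saturating(params: MeanFieldParams, d) -> np.ndarray:
    """Saturating form: J^2 K / (J^2 K + sigma^2), K = exp(-2 lambda d)."""
    K = shared_input_fraction(params.lambda_decay, d)
    num = params.J**2 * K
    return num / (num + params.sigma2)
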