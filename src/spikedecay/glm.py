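"""Spatial generalized linear model of spiking.

A Bernoulli GLM with logistic link whose interaction term is weighted by a
parametric distance kernel:

    P(S_i(t) = 1) = sigmoid(h_i(t)),
    h_i(t) = r0 + alpha * q_i(t),
    q_i(t) = sum_{j != i} S_j(t - 1) W(i, j; theta)

fitted jointly over the baseline r0, the coupling alpha and the kernel scale
theta (lambda for the exponential family). Unlike the raster-only estimator,
this is a full generative model with lag-1, directional interactions, and its
likelihood is a different object from the substituted raster-only likelihood;
the two are never mixed.

Analytic gradients (validated against finite differences in the test suite):

    dlogL/dr0    = sum (S - P)
    dlogL/dalpha = sum (S - P) * q
    dlogL/dtheta = sum (S - P) * alpha * (dW/dtheta @ S_lag)

Optimization runs in a transformed space — r0 unconstrained, alpha through a
softplus, theta through a log — with a monotone quasi-Newton ascent
(L-BFGS-B on the negative log-likelihood), so positivity holds without
projection and accepted iterates never decrease the likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, sparse
from scipy.special import expit

from .core import Geometry, SpikeRaster
from .kernels import DEFAULT_BOUNDS, DecayKernel, fix_lognormal_mu
from .mle import _as_sparse, _weight_matrix

__all__ = ["GlmFit", "glm_loglik", "glm_gradients", "fit_spatial_glm"]

_CHUNK_ENTRIES = 2_000_000


@dataclass
class GlmFit:
    """Fitted spatial GLM: parameters, likelihood, ascent trace, diagnostics."""

    family: str
    r0: float
    alpha: float
    scale: float
    loglik: float
    trace: list
    converged: bool
    grad_norm: float
    mu: float = 0.0
    n_iter: int = 0
    provenance: dict = field(default_factory=dict)


def _prepare(raster: SpikeRaster, geometry: Geometry):
    if raster.n_neurons != geometry.n_neurons:
        raise ValueError("raster and geometry sizes differ")
    if raster.n_bins < 2:
        raise ValueError("need at least 2 time bins for lag-1 interactions")
    S = _as_sparse(raster)
    return S[:, :-1], S[:, 1:]


def _ll_and_grads(S_src, S_pred, W, Wp, r0: float, alpha: float):
    """One pass over the data: log-likelihood and the three partials.

    W is the kernel weight matrix (zero diagonal), Wp the element-wise
    derivative dW/dtheta (zero diagonal); both symmetric.
    """
    n, t = S_src.shape
    chunk = max(1, _CHUNK_ENTRIES // (2 * max(n, 1)))
    ll = g_r0 = g_alpha = g_scale = 0.0
    for t0 in range(0, t, chunk):
        t1 = min(t0 + chunk, t)
        src = S_src[:, t0:t1]
        q = src.T @ W
        u = src.T @ Wp
        h = r0 + alpha * q
        P = expit(h)
        # softplus(h), overflow-safe without the slow logaddexp path
        sp = np.log1p(np.exp(np.minimum(h, 30.0)))
        big = h > 30.0
        if big.any():
            sp[big] = h[big]
        ll -= float(sp.sum())
        g_r0 -= float(P.sum())
        g_alpha -= float((P * q).sum())
        g_scale -= float((P * u).sum())
        pred = sparse.coo_array(S_pred[:, t0:t1])
        if pred.nnz:
            tt, ii = pred.coords[1], pred.coords[0]
            ll += float(h[tt, ii].sum())
            g_r0 += float(pred.nnz)
            g_alpha += float(q[tt, ii].sum())
            g_scale += float(u[tt, ii].sum())
    return ll, g_r0, g_alpha, alpha * g_scale


def _matrices(family: str, scale: float, mu: float, geometry: Geometry):
    kernel = DecayKernel(family, scale, mu=mu)
    W = _weight_matrix(kernel, geometry)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        Wp = np.asarray(kernel.weight_derivative(geometry.distances), dtype=float)
    np.fill_diagonal(Wp, 0.0)
    return W, Wp


def glm_loglik(raster: SpikeRaster, geometry: Geometry, kernel: DecayKernel,
               r0: float, alpha: float) -> float:
    """Bernoulli log-likelihood of the spatial GLM at the given parameters."""
    S_src, S_pred = _prepare(raster, geometry)
    W, Wp = _matrices(kernel.family, kernel.scale, kernel.mu, geometry)
    return _ll_and_grads(S_src, S_pred, W, Wp, r0, alpha)[0]


def glm_gradients(raster: SpikeRaster, geometry: Geometry, kernel: DecayKernel,
                  r0: float, alpha: float):
    """(dlogL/dr0, dlogL/dalpha, dlogL/dtheta) at the given parameters."""
    S_src, S_pred = _prepare(raster, geometry)
    W, Wp = _matrices(kernel.family, kernel.scale, kernel.mu, geometry)
    _, g0, ga, gs = _ll_and_grads(S_src, S_pred, W, Wp, r0, alpha)
    return g0, ga, gs


def _softplus(x: float) -> float:
    return float(np.logaddexp(0.0, x))


def _softplus_inv(y: float) -> float:
    y = max(y, 1e-12)
    return float(y + np.log1p(-np.exp(-y)))


def fit_spatial_glm(raster: SpikeRaster, geometry: Geometry, family: str = "exponential",
                    init: Optional[tuple] = None, max_iter: int = 200, tol: float = 1e-9,
                    scale_inits: Optional[Sequence[float]] = None,
                    bounds: Optional[tuple] = None) -> GlmFit:
    """Fit (r0, alpha, theta) by monotone quasi-Newton ascent.

    ``init`` is an optional (r0, alpha, theta) triple; by default r0 starts
    at the logit of the mean spike rate, alpha at 0.1 and theta at 2 (1/mm
    for the exponential family). ``scale_inits`` runs a deterministic
    multi-start over kernel-scale initializations and keeps the best
    likelihood — recommended for model-selection runs. Non-convergence
    within ``max_iter`` returns the partial fit flagged, never an exception.

    ``tol`` is the relative decrease of the negative log-likelihood below
    which iteration stops; because the log-likelihood magnitude grows with
    N x T, it must stay far below 1/|logL| (the default 1e-9 resolves
    ~5e-4 nat steps at |logL| ~ 5e5 — a looser value can freeze the kernel
    scale near its initialization on flat likelihood surfaces).
    """
    S_src, S_pred = _prepare(raster, geometry)
    mu = fix_lognormal_mu(geometry) if family == "lognormal" else 0.0
    if bounds is None:
        bounds = DEFAULT_BOUNDS[family]

    rate = float(raster.spikes.mean())
    rate = min(max(rate, 1e-6), 1 - 1e-6)
    if init is not None:
        starts = [init]
    else:
        r0_init = float(np.log(rate / (1 - rate)))
        if scale_inits is None:
            scale_inits = [2.0]
        starts = [(r0_init, 0.1, s) for s in scale_inits]

    best = None
    for r0_0, alpha_0, scale_0 in starts:
        x0 = np.array([r0_0, _softplus_inv(alpha_0), np.log(scale_0)])
        trace: list = []
        last = {"f": None}

        def neg_ll_and_grad(x):
            r0, alpha, scale = float(x[0]), _softplus(x[1]), float(np.exp(x[2]))
            scale = min(max(scale, 1e-8), 1e8)
            W, Wp = _matrices(family, scale, mu, geometry)
            ll, g0, ga, gs = _ll_and_grads(S_src, S_pred, W, Wp, r0, alpha)
            # chain rule through softplus and log transforms
            sig = 1.0 / (1.0 + np.exp(-x[1]))
            grad = np.array([g0, ga * sig, gs * scale])
            last["f"] = ll
            return -ll, -grad

        res = optimize.minimize(
            neg_ll_and_grad, x0, jac=True, method="L-BFGS-B",
            callback=lambda xk: trace.append(last["f"]),
            options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-8},
        )
        ll = -float(res.fun)
        fit = GlmFit(
            family=family,
            r0=float(res.x[0]),
            alpha=_softplus(res.x[1]),
            scale=float(np.exp(res.x[2])),
            loglik=ll,
            trace=trace,
            converged=bool(res.success),
            grad_norm=float(np.linalg.norm(res.jac)),
            mu=mu,
            n_iter=int(res.nit),
            provenance={"init": (r0_0, alpha_0, scale_0), "max_iter": max_iter,
                        "tol": tol, "bounds": tuple(bounds)},
        )
        if best is None or fit.loglik > best.loglik:
            best = fit
    return best
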