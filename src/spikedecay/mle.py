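"""Maximum-likelihood estimation of the spatial decay of functional
connectivity from a spike raster and neuron positions alone.

The estimator needs no knowledge of the baseline rate, the coupling strength
or the wiring: the per-neuron-per-bin spike probability is approximated by

    P(S_i(t) = 1) ~ I_i(t) / N,      I_i(t) = sum_{j != i} S_j(t) W(i, j)

where W is a parametric distance kernel (exponential W = e^{-lambda d} by
default) and N the number of neurons. The Bernoulli log-likelihood

    log L = sum_{t, i} [ S_i(t) log P_i(t) + (1 - S_i(t)) log(1 - P_i(t)) ]

is maximized over the kernel's scale parameter by a deterministic coarse
grid search followed by bounded scalar refinement.

Two conventions matter and both are exposed:

- ``normalize`` (default True): with raw weights the substituted
  probability has mean rate * mean-kernel-weight, so its scale depends on
  the kernel parameter and the profile maximum is dragged toward the
  all-to-all limit on weakly coupled rasters regardless of the generating
  decay. Normalizing each neuron's kernel row to sum to N (equivalently,
  treating the kernel as an interaction distribution p(d) = c e^{-lambda d})
  calibrates E[P] to the firing rate at every decay value, so the profile
  is driven by the spatial coincidence structure alone. ``normalize=False``
  evaluates the raw substitution verbatim.
- ``interaction``: ``"lagged"`` (default) scores bin t against presynaptic
  spikes at t-1, the causal convention of the generative models, which
  carries the directed-coupling signal; ``"same_bin"`` uses simultaneous
  spikes, the raster-as-a-whole summary convention.

Probabilities are clipped to [eps, 1 - eps] (eps = 1e-10) so bins with an
observed spike but zero interaction keep the likelihood finite. The
self-term j = i is excluded: W(i, i) = 1 would let a neuron predict itself
at zero distance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from numba import njit
from scipy import optimize, sparse

from .core import Geometry, SpikeRaster
from .kernels import DEFAULT_BOUNDS, DecayKernel, fix_lognormal_mu, kernel_weight

__all__ = [
    "EstimationResult",
    "raster_loglik",
    "estimate_decay",
    "estimate_decay_known_model",
    "known_model_loglik_and_gradient",
    "stability_curves",
]

EPS_CLIP = 1e-10
#: time-bins per likelihood chunk are sized so a chunk holds ~1e7 entries
_CHUNK_ENTRIES = 2_000_000


@dataclass
class EstimationResult:
    """Fitted kernel scale with its log-likelihood profile and provenance."""

    family: str
    scale: float
    loglik: float
    grid: np.ndarray
    profile: np.ndarray
    bounds: tuple
    boundary: bool
    mu: float = 0.0
    interaction: str = "same_bin"
    n_spikes: int = 0
    provenance: dict = field(default_factory=dict)

    @property
    def lambda_hat(self) -> float:
        """Alias for the fitted scale (decay rate for the exponential family)."""
        return self.scale


def _as_sparse(raster: SpikeRaster) -> sparse.csc_array:
    return sparse.csc_array(raster.spikes)


@njit(cache=True)
def _ll_kernel(W, src_indptr, src_indices, pred_indptr, pred_indices,
               n_cols, n_total, eps):  # pragma: no cover - jitted
    """Exact Bernoulli log-likelihood of the substituted model, bin by bin.

    Spike columns are CSC index arrays; the interaction vector is rebuilt
    per bin from presynaptic spike columns of W. log(1 - P) uses a series
    for small P (relative error < 1e-13 at the 0.01 cut-over) and log1p
    otherwise, so no N x T temporary is ever materialized.
    """
    n = W.shape[0]
    inter = np.empty(n)
    ll = 0.0
    for t in range(n_cols):
        for i in range(n):
            inter[i] = 0.0
        for p in range(src_indptr[t], src_indptr[t + 1]):
            row = W[src_indices[p]]
            for i in range(n):
                inter[i] += row[i]
        for i in range(n):
            x = inter[i] / n_total
            if x < eps:
                x = eps
            elif x > 1.0 - eps:
                x = 1.0 - eps
            if x < 0.01:
                x2 = x * x
                ll -= x + x2 * (0.5 + x * (1.0 / 3.0 + x * (0.25 + 0.2 * x)))
            else:
                ll += math.log1p(-x)
        for p in range(pred_indptr[t], pred_indptr[t + 1]):
            x = inter[pred_indices[p]] / n_total
            if x < eps:
                x = eps
            elif x > 1.0 - eps:
                x = 1.0 - eps
            ll += math.log(x) - math.log1p(-x)
    return ll


def _substituted_loglik(S_src: sparse.csc_array, S_pred: sparse.csc_array,
                        W: np.ndarray, n_total: int, eps: float = EPS_CLIP) -> float:
    """log-likelihood with P = clip((W @ S_src)/N, eps, 1-eps) against S_pred.

    S_src and S_pred are (N, T') column-aligned; W must have a zero diagonal
    and is indexed as W[i, j] = weight of presynaptic j onto i (the kernel
    iterates presynaptic rows of W.T).
    """
    n, t = S_src.shape
    return float(_ll_kernel(
        np.ascontiguousarray(W.T), S_src.indptr, S_src.indices,
        S_pred.indptr, S_pred.indices, t, n_total, eps,
    ))


@njit(cache=True)
def _logistic_ll_kernel(WT, src_indptr, src_indices, pred_indptr, pred_indices,
                        n_cols, r0, alpha):  # pragma: no cover - jitted
    """Logistic-link log-likelihood sum_spk h - sum softplus(h) with
    h = r0 + alpha * (W @ S_src); softplus uses a 6-term exp series for
    h < -3.5 (absolute error < 2e-10 per entry) and log1p(exp(h)) otherwise."""
    n = WT.shape[0]
    q = np.empty(n)
    ll = 0.0
    sp_r0 = math.log1p(math.exp(r0)) if r0 < 30 else r0
    for t in range(n_cols):
        lo, hi = src_indptr[t], src_indptr[t + 1]
        if lo == hi:
            # no presynaptic spikes: h = r0 everywhere in this bin
            ll -= n * sp_r0
            for p in range(pred_indptr[t], pred_indptr[t + 1]):
                ll += r0
            continue
        for i in range(n):
            q[i] = 0.0
        for p in range(lo, hi):
            row = WT[src_indices[p]]
            for i in range(n):
                q[i] += row[i]
        for i in range(n):
            h = r0 + alpha * q[i]
            if h < -3.5:
                e = math.exp(h)
                ll -= e * (1.0 + e * (-0.5 + e * (1.0 / 3.0 + e * (-0.25
                          + e * (0.2 - e / 6.0)))))
            elif h < 30.0:
                ll -= math.log1p(math.exp(h))
            else:
                ll -= h
        for p in range(pred_indptr[t], pred_indptr[t + 1]):
            ll += r0 + alpha * q[pred_indices[p]]
    return ll


@njit(cache=True)
def _linear_offset_ll_kernel(WT, src_indptr, src_indices, pred_indptr, pred_indices,
                             n_cols, r0, eps):  # pragma: no cover - jitted
    """Bernoulli log-likelihood with P = clip(r0 + W @ S_src, eps, 1-eps);
    WT rows are presynaptic (pass alpha-scaled weights transposed)."""
    n = WT.shape[0]
    inter = np.empty(n)
    ll = 0.0
    for t in range(n_cols):
        for i in range(n):
            inter[i] = r0
        for p in range(src_indptr[t], src_indptr[t + 1]):
            row = WT[src_indices[p]]
            for i in range(n):
                inter[i] += row[i]
        for i in range(n):
            x = inter[i]
            if x < eps:
                x = eps
            elif x > 1.0 - eps:
                x = 1.0 - eps
            if x < 0.01:
                x2 = x * x
                ll -= x + x2 * (0.5 + x * (1.0 / 3.0 + x * (0.25 + 0.2 * x)))
            else:
                ll += math.log1p(-x)
        for p in range(pred_indptr[t], pred_indptr[t + 1]):
            x = inter[pred_indices[p]]
            if x < eps:
                x = eps
            elif x > 1.0 - eps:
                x = 1.0 - eps
            ll += math.log(x) - math.log1p(-x)
    return ll


def _weight_matrix(kernel: DecayKernel, geometry: Geometry,
                   normalize: bool = False) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        W = np.asarray(kernel_weight(kernel, geometry.distances), dtype=float)
    np.fill_diagonal(W, 0.0)  # exclude self-interaction
    if normalize:
        # interaction-distribution calibration: each row sums to N so the
        # substituted probability has mean equal to the firing rate
        rows = W.sum(axis=1, keepdims=True)
        rows[rows == 0] = 1.0
        W = W / rows * W.shape[0]
    return W


def raster_loglik(raster: SpikeRaster, geometry: Geometry, kernel: DecayKernel,
                  interaction: str = "same_bin", normalize: bool = False,
                  eps: float = EPS_CLIP) -> float:
    """Raster-only Bernoulli log-likelihood of the kernel (see module docs).

    Defaults evaluate the substitution verbatim (raw weights, same-bin
    interactions); :func:`estimate_decay` defaults to the calibrated
    variant instead — see the module docstring for why.
    """
    if raster.n_neurons != geometry.n_neurons:
        raise ValueError("raster and geometry sizes differ")
    if raster.n_neurons < 2:
        raise ValueError("need at least 2 neurons")
    if interaction not in ("same_bin", "lagged"):
        raise ValueError("interaction must be 'same_bin' or 'lagged'")
    if raster.spikes.sum() == 0:
        warnings.warn("all-zero raster: likelihood is uninformative", RuntimeWarning,
                      stacklevel=2)
    S = _as_sparse(raster)
    W = _weight_matrix(kernel, geometry, normalize=normalize)
    if interaction == "same_bin":
        return _substituted_loglik(S, S, W, raster.n_neurons, eps)
    return _substituted_loglik(S[:, :-1], S[:, 1:], W, raster.n_neurons, eps)


def estimate_decay(raster: SpikeRaster, geometry: Geometry, family: str = "exponential",
                   bounds: Optional[tuple] = None, grid_size: int = 60,
                   interaction: str = "lagged", normalize: bool = True,
                   eps: float = EPS_CLIP,
                   provenance: Optional[dict] = None) -> EstimationResult:
    """Fit the kernel scale by grid search plus bounded refinement.

    The profile is evaluated on ``grid_size`` log-spaced points between the
    bounds, then the maximum is refined with a bounded scalar optimizer on
    the bracketing interval. A maximum on the first or last grid point is
    flagged as a boundary solution rather than silently accepted.

    Defaults use the calibrated likelihood (normalized kernel rows, lagged
    interactions); pass ``normalize=False, interaction="same_bin"`` for the
    verbatim substitution (see module docstring).
    """
    n_spikes = int(raster.spikes.sum())
    if n_spikes == 0:
        raise ValueError("all-silent raster: decay parameter not estimable")
    if raster.n_neurons != geometry.n_neurons:
        raise ValueError("raster and geometry sizes differ")
    if bounds is None:
        bounds = DEFAULT_BOUNDS[family]
    lo, hi = bounds
    if not (0 < lo < hi):
        raise ValueError("bounds must satisfy 0 < lower < upper")
    mu = fix_lognormal_mu(geometry) if family == "lognormal" else 0.0

    S = _as_sparse(raster)
    if interaction == "same_bin":
        S_src, S_pred = S, S
    elif interaction == "lagged":
        S_src, S_pred = S[:, :-1], S[:, 1:]
    else:
        raise ValueError("interaction must be 'same_bin' or 'lagged'")
    n = raster.n_neurons

    def ll(scale: float) -> float:
        W = _weight_matrix(DecayKernel(family, scale, mu=mu), geometry,
                           normalize=normalize)
        return _substituted_loglik(S_src, S_pred, W, n, eps)

    grid = np.geomspace(lo, hi, grid_size)
    profile = np.array([ll(s) for s in grid])
    k = int(np.argmax(profile))
    boundary = k in (0, grid_size - 1)

    lo_r = grid[max(k - 1, 0)]
    hi_r = grid[min(k + 1, grid_size - 1)]
    best_scale, best_ll = grid[k], profile[k]
    if hi_r > lo_r:
        res = optimize.minimize_scalar(
            lambda s: -ll(s), bounds=(lo_r, hi_r), method="bounded",
            options={"xatol": 1e-3 * (hi_r - lo_r)},
        )
        if -res.fun >= best_ll:
            best_scale, best_ll = float(res.x), float(-res.fun)

    # keep the invariant: reported maximum is the maximum of the stored profile
    order = np.argsort(np.append(grid, best_scale))
    full_grid = np.append(grid, best_scale)[order]
    full_profile = np.append(profile, best_ll)[order]

    prov = dict(provenance or {})
    prov.update({"grid_size": grid_size, "bounds": tuple(bounds),
                 "interaction": interaction, "normalize": normalize, "eps": eps})
    return EstimationResult(
        family=family, scale=best_scale, loglik=best_ll, grid=full_grid,
        profile=full_profile, bounds=tuple(bounds), boundary=boundary, mu=mu,
        interaction=interaction, n_spikes=n_spikes, provenance=prov,
    )


def known_model_loglik_and_gradient(raster: SpikeRaster, geometry: Geometry,
                                    r0: float, alpha: float, lam: float):
    """Log-likelihood and d(logL)/d(lambda) of the full generative model.

    Uses the logistic link with lag-1 interactions,
    h_i(t) = r0 + alpha * sum_{j != i} S_j(t-1) e^{-lambda d_ij}, summed over
    t >= 1 (the first bin has no predecessor). The analytic gradient is

        dlogL/dlambda = -alpha * sum_{t, i} (S_i(t) - P_i(t))
                        * sum_{j != i} S_j(t-1) d_ij e^{-lambda d_ij}.
    """
    if raster.n_neurons != geometry.n_neurons:
        raise ValueError("raster and geometry sizes differ")
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    d = geometry.distances
    W = np.exp(-lam * d)
    np.fill_diagonal(W, 0.0)
    Wd = d * np.exp(-lam * d)
    np.fill_diagonal(Wd, 0.0)

    S = _as_sparse(raster)
    S_src, S_pred = S[:, :-1], S[:, 1:]
    n, t = S_src.shape
    chunk = max(1, _CHUNK_ENTRIES // (2 * max(n, 1)))
    ll = 0.0
    grad = 0.0
    for t0 in range(0, t, chunk):
        t1 = min(t0 + chunk, t)
        src = S_src[:, t0:t1]
        q = src.T @ W          # (T_c, N) interaction term
        g = src.T @ Wd         # its distance-weighted counterpart
        h = r0 + alpha * q
        # log L = sum_spikes h - sum softplus(h); S - P enters the gradient
        P = 1.0 / (1.0 + np.exp(-h))
        ll -= float(np.logaddexp(0.0, h).sum())
        grad += float((-P * g).sum())
        pred = sparse.coo_array(S_pred[:, t0:t1])
        if pred.nnz:
            ll += float(h[pred.coords[1], pred.coords[0]].sum())
            grad += float(g[pred.coords[1], pred.coords[0]].sum())
    return ll, -alpha * grad


def estimate_decay_known_model(raster: SpikeRaster, geometry: Geometry,
                               r0: float, alpha: float, link: str = "logistic",
                               bounds: tuple = (0.1, 20.0),
                               grid_size: int = 40) -> EstimationResult:
    """lambda-only MLE of the full generative model with known r0 and alpha.

    Maximizes the lag-1 likelihood over the decay rate alone, holding the
    baseline and coupling at their known values — the estimator appropriate
    when the generative parameters are available, as in simulation
    self-validation. ``link="logistic"`` scores P = sigmoid(r0 + alpha q)
    (r0 in log-odds); ``link="linear"`` scores the wiring-marginalized
    linear rule P = clip(r0 + alpha q, eps, 1-eps) (r0 a probability), where
    q_i(t) = sum_{j != i} S_j(t-1) e^{-lambda d_ij} in both cases. Grid
    search plus bounded refinement, like :func:`estimate_decay`.
    """
    if raster.spikes.sum() == 0:
        raise ValueError("all-silent raster: decay parameter not estimable")
    if link not in ("logistic", "linear"):
        raise ValueError("link must be 'logistic' or 'linear'")
    lo, hi = bounds
    if not (0 < lo < hi):
        raise ValueError("bounds must satisfy 0 < lower < upper")

    S = _as_sparse(raster)
    S_src, S_pred = S[:, :-1], S[:, 1:]
    d = geometry.distances

    def ll(lam: float) -> float:
        W = np.exp(-lam * d)
        np.fill_diagonal(W, 0.0)
        if link == "logistic":
            return float(_logistic_ll_kernel(
                np.ascontiguousarray(W.T), S_src.indptr, S_src.indices,
                S_pred.indptr, S_pred.indices, S_src.shape[1], r0, alpha,
            ))
        return float(_linear_offset_ll_kernel(
            np.ascontiguousarray(alpha * W.T), S_src.indptr, S_src.indices,
            S_pred.indptr, S_pred.indices, S_src.shape[1], r0, EPS_CLIP,
        ))

    grid = np.geomspace(lo, hi, grid_size)
    profile = np.array([ll(s) for s in grid])
    k = int(np.argmax(profile))
    boundary = k in (0, grid_size - 1)
    lo_r, hi_r = grid[max(k - 1, 0)], grid[min(k + 1, grid_size - 1)]
    best_scale, best_ll = grid[k], profile[k]
    if hi_r > lo_r:
        res = optimize.minimize_scalar(lambda s: -ll(s), bounds=(lo_r, hi_r),
                                       method="bounded",
                                       options={"xatol": 1e-3 * (hi_r - lo_r)})
        if -res.fun >= best_ll:
            best_scale, best_ll = float(res.x), float(-res.fun)
    order = np.argsort(np.append(grid, best_scale))
    return EstimationResult(
        family="exponential", scale=best_scale, loglik=best_ll,
        grid=np.append(grid, best_scale)[order],
        profile=np.append(profile, best_ll)[order],
        bounds=tuple(bounds), boundary=boundary, interaction="lagged",
        n_spikes=int(raster.spikes.sum()),
        provenance={"estimator": "known_model", "r0": r0, "alpha": alpha,
                    "link": link, "grid_size": grid_size},
    )


def stability_curves(raster: SpikeRaster, geometry: Geometry,
                     neuron_subset_sizes: Sequence[int] = (),
                     time_prefixes_ms: Sequence[float] = (),
                     n_repeats: int = 5, seed: int = 0,
                     estimator: str = "raster_mle",
                     **estimate_kwargs) -> pd.DataFrame:
    """Re-estimate the decay on random neuron subsets and time prefixes.

    For each subset size, ``n_repeats`` random subsets (without replacement)
    are re-estimated; each time prefix truncates the raster
    deterministically. A ``full`` row holds the whole-data estimate that the
    curves are compared against.

    ``estimator`` selects the engine: ``"raster_mle"`` (the substituted
    likelihood, :func:`estimate_decay`) or ``"spatial_glm"`` (the full
    three-parameter fit). Under neuron subsampling most presynaptic
    partners become unobserved; a refit baseline absorbs their drive, so
    the GLM is the engine whose estimates are stable under subsampling —
    any fixed-baseline estimator must re-explain the hidden drive through
    its kernel and drifts toward broader decay.
    """
    if estimator == "raster_mle":
        def run(r, g):
            est = estimate_decay(r, g, **estimate_kwargs)
            return est.scale, est.boundary
    elif estimator == "spatial_glm":
        from .glm import fit_spatial_glm

        def run(r, g):
            fit = fit_spatial_glm(r, g, **estimate_kwargs)
            return fit.scale, not fit.converged
    else:
        raise ValueError("estimator must be 'raster_mle' or 'spatial_glm'")

    rng = np.random.default_rng(seed)
    rows = []
    scale, flagged = run(raster, geometry)
    rows.append({"kind": "full", "value": float(raster.n_neurons), "repeat": 0,
                 "lambda_hat": scale, "boundary": flagged})
    for size in neuron_subset_sizes:
        if size < 2:
            raise ValueError("subset size must be at least 2")
        if size > raster.n_neurons:
            raise ValueError("subset size exceeds the population")
        for rep in range(n_repeats):
            idx = np.sort(rng.choice(raster.n_neurons, size=size, replace=False))
            sub_raster = SpikeRaster(raster.spikes[idx], bin_ms=raster.bin_ms)
            sub_geom = Geometry(positions=geometry.positions[idx])
            scale, flagged = run(sub_raster, sub_geom)
            rows.append({"kind": "subset", "value": float(size), "repeat": rep,
                         "lambda_hat": scale, "boundary": flagged})
    for prefix in time_prefixes_ms:
        n_bins = int(round(prefix / raster.bin_ms))
        if n_bins > raster.n_bins:
            raise ValueError("time prefix exceeds raster duration")
        sub = SpikeRaster(raster.spikes[:, :n_bins], bin_ms=raster.bin_ms)
        scale, flagged = run(sub, geometry)
        rows.append({"kind": "prefix", "value": float(prefix), "repeat": 0,
                     "lambda_hat": scale, "boundary": flagged})
    return pd.DataFrame(rows)
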