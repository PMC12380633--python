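"""Comparator estimators of spatial decay.

Three pairwise functional-connectivity measures — transfer entropy, Poisson
point-process Granger causality, and binned spike-count correlations — each
reduced to a decay estimate by least-squares fitting of a * exp(-lambda d)
against intersomatic distance. These serve as baselines against the direct
likelihood estimator; all three require O(N^2) pairwise computation, so an
optional pair budget subsamples ordered pairs uniformly at random for large
populations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import optimize

from .core import Geometry, SpikeRaster, bin_counts

__all__ = [
    "PairwiseMeasure",
    "transfer_entropy_matrix",
    "granger_matrix",
    "correlation_matrix",
    "fit_decay_to_pairwise",
    "estimation_error",
]


@dataclass
class PairwiseMeasure:
    """Pairwise functional-connectivity values.

    ``matrix[i, j]`` is the measure for the ordered pair j -> i (source j,
    target i) for directed kinds (TE, GC) and the symmetric value for
    correlations. Unsampled or undefined pairs are NaN; the diagonal is
    always NaN and excluded from decay fits.
    """

    matrix: np.ndarray
    kind: str
    params: dict = field(default_factory=dict)


def _pair_budget(n: int, max_pairs: Optional[int], seed: int):
    """All ordered pairs, or a uniform random subsample of them."""
    ii, jj = np.where(~np.eye(n, dtype=bool))
    if max_pairs is not None and max_pairs < ii.size:
        rng = np.random.default_rng(seed)
        sel = rng.choice(ii.size, size=max_pairs, replace=False)
        ii, jj = ii[sel], jj[sel]
    return ii, jj


def transfer_entropy_matrix(raster: SpikeRaster, delta_t_bins: int = 1,
                            k: int = 1, l: int = 1,
                            max_pairs: Optional[int] = None,
                            seed: int = 0) -> PairwiseMeasure:
    """Plug-in transfer entropy (bits) between all sampled ordered pairs.

    TE_{X->Y} = sum p(y_{t+1}, y_t^(k), x^(l)) log2 p(y_{t+1} | y_t^(k), x^(l))
                / p(y_{t+1} | y_t^(k)),

    estimated from empirical joint frequencies over the 2^(1+k+l) binary
    state combinations; the source history is the l bins ending delta_t
    before the predicted bin. Zero-probability states contribute 0. The
    plug-in estimate is a conditional mutual information of the empirical
    distribution and is therefore nonnegative.
    """
    S = raster.spikes.astype(np.int64)
    n, t = S.shape
    hist = max(k, l + delta_t_bins - 1)
    if t <= hist:
        raise ValueError("raster too short for the requested histories")
    n_t = t - hist  # number of predicted bins

    # bit-encode per-neuron target futures, target pasts and source pasts
    fut = S[:, hist:]
    tgt_past = np.zeros((n, n_t), dtype=np.int64)
    for a in range(k):
        tgt_past = (tgt_past << 1) | S[:, hist - 1 - a: hist - 1 - a + n_t]
    src_past = np.zeros((n, n_t), dtype=np.int64)
    for a in range(l):
        off = hist - delta_t_bins - a
        src_past = (src_past << 1) | S[:, off: off + n_t]

    n_states = 2 ** (1 + k + l)
    ii, jj = _pair_budget(n, max_pairs, seed)
    te = np.full((n, n), np.nan)
    log2 = np.log(2.0)
    for tgt, src in zip(ii, jj):
        code = (fut[tgt] << (k + l)) | (tgt_past[tgt] << l) | src_past[src]
        joint = np.bincount(code, minlength=n_states).astype(float)
        joint /= joint.sum()
        p = joint.reshape(2, 2**k, 2**l)
        p_ypast_x = p.sum(axis=0, keepdims=True)
        p_y_ypast = p.sum(axis=2, keepdims=True)
        p_ypast = p.sum(axis=(0, 2), keepdims=True)
        mask = p > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.log(p * p_ypast / (p_ypast_x * p_y_ypast)) / log2
        te[tgt, src] = max(float((p[mask] * ratio[mask]).sum()), 0.0)
    return PairwiseMeasure(matrix=te, kind="TE",
                           params={"delta_t_bins": delta_t_bins, "k": k, "l": l})


def _poisson_newton(X: np.ndarray, y: np.ndarray, max_iter: int = 50,
                    tol: float = 1e-8, ridge: float = 1e-8):
    """Poisson log-linear fit (log rate = X beta) by Newton with step halving.

    Returns (beta, loglik) with loglik = sum y*eta - exp(eta), i.e. the
    printed point-process likelihood up to the fixed log(y!) term.
    """
    beta = np.zeros(X.shape[1])
    beta[0] = np.log(max(y.mean(), 1e-10))
    eta = X @ beta
    ll = float(y @ eta - np.exp(eta).sum())
    for _ in range(max_iter):
        lam = np.exp(eta)
        grad = X.T @ (y - lam)
        H = (X * lam[:, None]).T @ X + ridge * np.eye(X.shape[1])
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            eta_c = X @ cand
            ll_c = float(y @ eta_c - np.exp(eta_c).sum())
            if np.isfinite(ll_c) and ll_c >= ll:
                break
            scale *= 0.5
        else:
            break
        improved = ll_c - ll
        beta, eta, ll = cand, eta_c, ll_c
        if improved < tol * (abs(ll) + 1.0):
            break
    return beta, ll


def granger_matrix(raster: SpikeRaster, bin_ms: float = 10.0, history_ms: float = 100.0,
                   max_pairs: Optional[int] = None, seed: int = 0) -> PairwiseMeasure:
    """Point-process Granger causality between all sampled ordered pairs.

    Spikes are counted in ``bin_ms`` bins; for each ordered pair a reduced
    Poisson log-linear model (target's own history over ``history_ms``) and
    a full model (own plus source history) are fitted by maximum likelihood,
    and GC_{Y->X} = (L_full - L_reduced) / |L_reduced|. Silent target
    neurons have undefined GC (NaN row entries).
    """
    counts = bin_counts(raster, bin_ms).astype(float)
    n, t = counts.shape
    h = int(round(history_ms / bin_ms))
    if t <= 3 * h:
        raise ValueError("raster too short for the requested history window")
    n_obs = t - h

    lags = np.stack([counts[:, h - 1 - a: h - 1 - a + n_obs] for a in range(h)], axis=2)
    y_all = counts[:, h:]
    ones = np.ones((n_obs, 1))

    ii, jj = _pair_budget(n, max_pairs, seed)
    gc = np.full((n, n), np.nan)
    reduced_cache: dict = {}
    for tgt, src in zip(ii, jj):
        y = y_all[tgt]
        if y.sum() == 0:
            continue  # GC undefined for a silent target
        if tgt not in reduced_cache:
            Xr = np.hstack([ones, lags[tgt]])
            reduced_cache[tgt] = (_poisson_newton(Xr, y)[1], Xr)
        ll_red, Xr = reduced_cache[tgt]
        Xf = np.hstack([Xr, lags[src]])
        _, ll_full = _poisson_newton(Xf, y)
        gc[tgt, src] = (ll_full - ll_red) / abs(ll_red)
    return PairwiseMeasure(matrix=gc, kind="GC",
                           params={"bin_ms": bin_ms, "history_ms": history_ms})


def correlation_matrix(raster: SpikeRaster, bin_ms: float = 10.0) -> PairwiseMeasure:
    """Pearson correlation of spike counts in non-overlapping bins.

    Zero-variance neurons yield NaN rows/columns (flagged, excluded from
    decay fits); a raster shorter than two counting bins is an error.
    """
    counts = bin_counts(raster, bin_ms).astype(float)
    if counts.shape[1] < 2:
        raise ValueError("need at least two counting bins for correlations")
    var = counts.var(axis=1)
    corr = np.full((raster.n_neurons, raster.n_neurons), np.nan)
    keep = var > 0
    if keep.sum() >= 2:
        sub = np.corrcoef(counts[keep])
        corr[np.ix_(keep, keep)] = sub
    np.fill_diagonal(corr, np.nan)
    return PairwiseMeasure(matrix=corr, kind="correlation", params={"bin_ms": bin_ms})


def fit_decay_to_pairwise(measure: PairwiseMeasure, geometry: Geometry,
                          lambda_inits=(0.5, 2.0, 5.0, 10.0)):
    """Least-squares fit of m_ij ~ a * exp(-lambda * d_ij).

    The amplitude a is free because the raw measures have arbitrary scale;
    only lambda is interpreted. Deterministic multi-start over lambda
    initializations; returns ``(lambda_hat, a_hat, rss, identifiable)``.
    An all-constant measure leaves lambda at the lower bound and is flagged
    non-identifiable.
    """
    m = measure.matrix
    d = geometry.distances
    mask = np.isfinite(m) & ~np.eye(m.shape[0], dtype=bool)
    y = m[mask]
    x = d[mask]
    if y.size < 10:
        raise ValueError("need at least 10 valid pairs for the decay fit")
    lo = 1e-6
    if np.ptp(y) == 0:
        return lo, float(y.mean()), 0.0, False

    def residuals(p, xx, yy):
        return p[0] * np.exp(-p[1] * xx) - yy

    best = None
    a0 = max(float(np.abs(y).max()), 1e-12)
    for lam0 in lambda_inits:
        res = optimize.least_squares(
            residuals, x0=[a0, lam0], args=(x, y),
            bounds=([0.0, lo], [np.inf, np.inf]),
        )
        rss = float(2.0 * res.cost)
        if best is None or rss < best[2]:
            best = (float(res.x[1]), float(res.x[0]), rss)
    lam_hat, a_hat, rss = best
    identifiable = lam_hat > 2 * lo
    return lam_hat, a_hat, rss, identifiable


def estimation_error(lambda_true: float, lambda_hat: float) -> float:
    """Absolute difference |lambda_true - lambda_hat| in 1/mm."""
    return abs(float(lambda_true) - float(lambda_hat))
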