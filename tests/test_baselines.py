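"""Comparator estimators: TE, Granger causality, correlations, decay fits."""

import numpy as np
import pytest

import spikedecay as sd
from spikedecay import (PairwiseMeasure, SpikeRaster, correlation_matrix,
                        estimation_error, fit_decay_to_pairwise, granger_matrix,
                        pairwise_distances, transfer_entropy_matrix)


def binary_entropy(p):
    return -(p * np.log2(p) + (1 - p) * np.log2(1 - p))


def lag_copy_raster(p=0.3, t_bins=200_000, seed=0):
    rng = np.random.default_rng(seed)
    x = (rng.random(t_bins) < p).astype(np.uint8)
    y = np.zeros_like(x)
    y[1:] = x[:-1]
    return SpikeRaster(np.vstack([x, y]))


class TestTransferEntropy:
    def test_independent_pair_near_zero(self):
        rng = np.random.default_rng(1)
        raster = SpikeRaster((rng.random((2, 100_000)) < 0.2).astype(np.uint8))
        te = transfer_entropy_matrix(raster).matrix
        # plug-in bias for 8-state estimate is O(states / (2 T ln 2))
        assert te[0, 1] < 1e-3 and te[1, 0] < 1e-3

    def test_lag_copy_equals_binary_entropy(self):
        """Y(t+1) = X(t), X ~ Bernoulli(0.3): TE = H(0.3) = 0.8813 bits."""
        raster = lag_copy_raster(p=0.3)
        te = transfer_entropy_matrix(raster).matrix
        assert te[1, 0] == pytest.approx(binary_entropy(0.3), abs=0.01)
        # reverse direction carries (almost) no information
        assert te[0, 1] < 0.01

    def test_matches_brute_force_enumeration(self):
        """Three-neuron toy raster versus literal summation over all 8 states."""
        rng = np.random.default_rng(2)
        S = (rng.random((3, 500)) < 0.4).astype(np.uint8)
        raster = SpikeRaster(S)
        te = transfer_entropy_matrix(raster).matrix
        for tgt in range(3):
            for src in range(3):
                if tgt == src:
                    continue
                y1, y0, x0 = S[tgt, 1:], S[tgt, :-1], S[src, :-1]
                counts = np.zeros((2, 2, 2))
                for a, b, c in zip(y1, y0, x0):
                    counts[a, b, c] += 1
                p = counts / counts.sum()
                val = 0.0
                for a in (0, 1):
                    for b in (0, 1):
                        for c in (0, 1):
                            if p[a, b, c] == 0:
                                continue
                            num = p[a, b, c] / p[:, b, c].sum()
                            den = p[a, b, :].sum() / p[:, b, :].sum()
                            val += p[a, b, c] * np.log2(num / den)
                assert te[tgt, src] == pytest.approx(val, abs=1e-10)

    def test_nonnegative_and_asymmetric_shape(self):
        rng = np.random.default_rng(3)
        raster = SpikeRaster((rng.random((5, 5000)) < 0.2).astype(np.uint8))
        m = transfer_entropy_matrix(raster)
        off = ~np.eye(5, dtype=bool)
        assert (m.matrix[off] >= 0).all()
        assert np.isnan(np.diag(m.matrix)).all()

    def test_pair_budget_subsampling(self):
        rng = np.random.default_rng(4)
        raster = SpikeRaster((rng.random((10, 2000)) < 0.2).astype(np.uint8))
        m = transfer_entropy_matrix(raster, max_pairs=20, seed=5)
        assert np.isfinite(m.matrix).sum() == 20

    def test_too_short_raster_rejected(self):
        raster = SpikeRaster(np.zeros((2, 1), dtype=np.uint8))
        with pytest.raises(ValueError):
            transfer_entropy_matrix(raster)


class TestGrangerCausality:
    def test_independent_pair_near_zero(self):
        rng = np.random.default_rng(6)
        raster = SpikeRaster((rng.random((2, 60_000)) < 0.02).astype(np.uint8))
        gc = granger_matrix(raster).matrix
        assert abs(gc[0, 1]) < 0.02 and abs(gc[1, 0]) < 0.02

    def test_directed_coupling_detected(self):
        """Y drives X at a 10 ms lag: GC(Y->X) exceeds GC(X->Y) across seeds."""
        wins = 0
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            t_bins = 60_000
            y = (rng.random(t_bins) < 0.02).astype(np.uint8)
            x = np.zeros_like(y)
            drive = np.zeros_like(y)
            drive[10:] = y[:-10]
            x_prob = 0.005 + 0.6 * drive
            x = (rng.random(t_bins) < x_prob).astype(np.uint8)
            raster = SpikeRaster(np.vstack([x, y]))
            gc = granger_matrix(raster).matrix
            # row = target, column = source
            if gc[0, 1] > gc[1, 0]:
                wins += 1
        assert wins >= 4

    def test_silent_target_flagged(self):
        rng = np.random.default_rng(7)
        spikes = np.vstack([np.zeros(40_000, dtype=np.uint8),
                            (rng.random(40_000) < 0.05).astype(np.uint8)])
        gc = granger_matrix(SpikeRaster(spikes)).matrix
        assert np.isnan(gc[0, 1])
        assert np.isfinite(gc[1, 0])


class TestCorrelationMatrix:
    def test_identical_trains_correlate_one(self):
        rng = np.random.default_rng(8)
        x = (rng.random(5000) < 0.1).astype(np.uint8)
        m = correlation_matrix(SpikeRaster(np.vstack([x, x]))).matrix
        assert m[0, 1] == pytest.approx(1.0)

    def test_alternation_and_complement_minus_one(self):
        x = np.tile([1, 0], 500).astype(np.uint8)
        m = correlation_matrix(SpikeRaster(np.vstack([x, 1 - x])), bin_ms=1.0).matrix
        assert m[0, 1] == pytest.approx(-1.0)

    def test_matches_two_pass_pearson(self):
        rng = np.random.default_rng(9)
        S = (rng.random((4, 3000)) < 0.2).astype(np.uint8)
        m = correlation_matrix(SpikeRaster(S), bin_ms=10.0).matrix
        from spikedecay.core import bin_counts
        counts = bin_counts(SpikeRaster(S), 10.0).astype(float)
        for i in range(4):
            for j in range(i + 1, 4):
                xi, xj = counts[i], counts[j]
                num = ((xi - xi.mean()) * (xj - xj.mean())).sum()
                den = np.sqrt(((xi - xi.mean()) ** 2).sum() *
                              ((xj - xj.mean()) ** 2).sum())
                assert m[i, j] == pytest.approx(num / den, rel=1e-10)

    def test_symmetry(self):
        rng = np.random.default_rng(10)
        S = (rng.random((6, 4000)) < 0.1).astype(np.uint8)
        m = correlation_matrix(SpikeRaster(S)).matrix
        np.testing.assert_allclose(m, m.T, equal_nan=True)

    def test_single_bin_rejected(self):
        raster = SpikeRaster(np.ones((3, 10), dtype=np.uint8))
        with pytest.raises(ValueError):
            correlation_matrix(raster, bin_ms=10.0)


class TestFitDecay:
    def test_noiseless_recovery(self):
        rng = np.random.default_rng(11)
        g = pairwise_distances(rng.random((30, 2)))
        m = 1.0 * np.exp(-5.0 * g.distances)
        np.fill_diagonal(m, np.nan)
        lam, a, rss, ok = fit_decay_to_pairwise(
            PairwiseMeasure(m, "correlation"), g)
        assert ok
        assert lam == pytest.approx(5.0, rel=1e-6)
        assert a == pytest.approx(1.0, rel=1e-6)
        assert rss < 1e-12

    def test_noisy_recovery_within_10pct(self):
        rng = np.random.default_rng(12)
        g = pairwise_distances(rng.random((40, 2)))
        m = 0.4 * np.exp(-2.5 * g.distances) + rng.normal(0, 0.01, (40, 40))
        np.fill_diagonal(m, np.nan)
        lam, a, _, ok = fit_decay_to_pairwise(PairwiseMeasure(m, "TE"), g)
        assert ok
        assert lam == pytest.approx(2.5, rel=0.10)

    def test_constant_measure_flagged(self):
        rng = np.random.default_rng(13)
        g = pairwise_distances(rng.random((10, 2)))
        m = np.full((10, 10), 0.3)
        np.fill_diagonal(m, np.nan)
        lam, a, _, ok = fit_decay_to_pairwise(PairwiseMeasure(m, "GC"), g)
        assert not ok
        assert a == pytest.approx(0.3)

    def test_too_few_pairs_rejected(self):
        g = pairwise_distances(np.random.default_rng(14).random((3, 2)))
        m = np.full((3, 3), np.nan)
        with pytest.raises(ValueError):
            fit_decay_to_pairwise(PairwiseMeasure(m, "TE"), g)


def test_estimation_error_is_absolute_difference():
    assert estimation_error(5.0, 5.0) == 0.0
    assert estimation_error(5.0, 3.5) == 1.5
    assert estimation_error(3.5, 5.0) == 1.5


def test_mle_beats_pairwise_baselines_on_poisson_data():
    """Decay-estimate error ordering on a coupled linear Poisson raster:
    the likelihood estimator with known generative parameters outperforms
    the three pairwise reductions (scaled-down comparison)."""
    lam_true = 5.0
    cfg = sd.PoissonNetConfig(n_neurons=400, t_ms=30_000.0, seed=21,
                              alpha=0.0125, r0=0.001)
    raster, geometry, _ = sd.simulate_poisson_network(cfg)
    mle_err = estimation_error(
        lam_true, sd.estimate_decay_known_model(
            raster, geometry, r0=0.001, alpha=0.0125, link="linear",
            grid_size=25).scale)
    errs = {}
    te = transfer_entropy_matrix(raster, max_pairs=4000, seed=1)
    errs["te"] = estimation_error(lam_true, fit_decay_to_pairwise(te, geometry)[0])
    corr = correlation_matrix(raster, bin_ms=10.0)
    errs["corr"] = estimation_error(lam_true, fit_decay_to_pairwise(corr, geometry)[0])
    gc = granger_matrix(raster, max_pairs=150, seed=2)
    errs["gc"] = estimation_error(lam_true, fit_decay_to_pairwise(gc, geometry)[0])
    assert mle_err < min(errs.values()), (mle_err, errs)
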