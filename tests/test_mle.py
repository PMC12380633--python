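"""Raster-only likelihood: brute-force oracles, profiles, gradients."""

import numpy as np
import pytest

from spikedecay import (DecayKernel, SpikeRaster, estimate_decay,
                        estimate_decay_known_model, known_model_loglik_and_gradient,
                        pairwise_distances, raster_loglik, stability_curves)
from spikedecay.mle import EPS_CLIP


def brute_force_loglik(spikes, distances, lam, interaction="same_bin",
                       normalize=False, eps=EPS_CLIP):
    """Literal transcription of the substituted Bernoulli log-likelihood."""
    n, t_bins = spikes.shape
    W = np.exp(-lam * distances)
    np.fill_diagonal(W, 0.0)
    if normalize:
        W = W / W.sum(axis=1, keepdims=True) * n
    ll = 0.0
    t_range = range(t_bins) if interaction == "same_bin" else range(1, t_bins)
    for t in t_range:
        src_t = t if interaction == "same_bin" else t - 1
        for i in range(n):
            I = sum(spikes[j, src_t] * W[i, j] for j in range(n) if j != i)
            P = min(max(I / n, eps), 1 - eps)
            if spikes[i, t]:
                ll += np.log(P)
            else:
                ll += np.log(1 - P)
    return ll


@pytest.fixture()
def toy_instance():
    rng = np.random.default_rng(17)
    spikes = (rng.random((8, 30)) < 0.25).astype(np.uint8)
    geometry = pairwise_distances(rng.random((8, 2)))
    return SpikeRaster(spikes), geometry


class TestRasterLoglik:
    @pytest.mark.parametrize("interaction", ["same_bin", "lagged"])
    @pytest.mark.parametrize("normalize", [False, True])
    @pytest.mark.parametrize("lam", [0.5, 3.0, 9.0])
    def test_matches_brute_force(self, toy_instance, interaction, normalize, lam):
        raster, geometry = toy_instance
        fast = raster_loglik(raster, geometry, DecayKernel("exponential", lam),
                             interaction=interaction, normalize=normalize)
        slow = brute_force_loglik(raster.spikes, geometry.distances, lam,
                                  interaction, normalize)
        assert fast == pytest.approx(slow, rel=1e-10)

    def test_oracle_across_sizes(self):
        rng = np.random.default_rng(23)
        for n, t in [(2, 5), (5, 50), (10, 50)]:
            spikes = (rng.random((n, t)) < 0.3).astype(np.uint8)
            g = pairwise_distances(rng.random((n, 2)))
            fast = raster_loglik(SpikeRaster(spikes), g, DecayKernel("exponential", 2.0))
            slow = brute_force_loglik(spikes, g.distances, 2.0)
            assert fast == pytest.approx(slow, rel=1e-10)

    def test_all_zero_raster_near_zero_loglik(self, toy_instance):
        _, geometry = toy_instance
        raster = SpikeRaster(np.zeros((8, 30), dtype=np.uint8))
        with pytest.warns(RuntimeWarning, match="all-zero"):
            ll = raster_loglik(raster, geometry, DecayKernel("exponential", 2.0))
        # every bin contributes log(1 - eps) ~ -1e-10
        assert ll == pytest.approx(8 * 30 * np.log(1 - EPS_CLIP), abs=1e-12)
        assert abs(ll) < 1e-6

    def test_dimension_mismatch_rejected(self, toy_instance):
        raster, _ = toy_instance
        bad_geom = pairwise_distances(np.random.default_rng(0).random((5, 2)))
        with pytest.raises(ValueError):
            raster_loglik(raster, bad_geom, DecayKernel("exponential", 1.0))


class TestEstimateDecay:
    def test_empty_raster_rejected(self, toy_instance):
        _, geometry = toy_instance
        empty = SpikeRaster(np.zeros((8, 30), dtype=np.uint8))
        with pytest.raises(ValueError):
            estimate_decay(empty, geometry)

    def test_profile_maximum_equals_reported(self, toy_instance):
        raster, geometry = toy_instance
        est = estimate_decay(raster, geometry, grid_size=12)
        assert est.loglik == pytest.approx(est.profile.max())
        assert est.grid.shape == est.profile.shape

    def test_interior_solution_inside_bounds(self, toy_instance):
        raster, geometry = toy_instance
        est = estimate_decay(raster, geometry, bounds=(0.1, 20.0), grid_size=12)
        assert 0.1 <= est.scale <= 20.0

    def test_deterministic(self, toy_instance):
        raster, geometry = toy_instance
        a = estimate_decay(raster, geometry, grid_size=10)
        b = estimate_decay(raster, geometry, grid_size=10)
        assert a.scale == b.scale and a.loglik == b.loglik

    def test_invalid_bounds_rejected(self, toy_instance):
        raster, geometry = toy_instance
        with pytest.raises(ValueError):
            estimate_decay(raster, geometry, bounds=(2.0, 1.0))


class TestKnownModelGradient:
    def test_zero_coupling_zero_gradient(self, toy_instance):
        raster, geometry = toy_instance
        for lam in (0.5, 2.0, 8.0):
            _, grad = known_model_loglik_and_gradient(raster, geometry,
                                                      r0=-4.0, alpha=0.0, lam=lam)
            assert grad == 0.0

    @pytest.mark.parametrize("lam", [0.7, 2.5, 6.0])
    def test_gradient_matches_finite_difference(self, toy_instance, lam):
        raster, geometry = toy_instance
        r0, alpha = -4.0, 1.5
        h = 1e-6
        ll_p, _ = known_model_loglik_and_gradient(raster, geometry, r0, alpha, lam + h)
        ll_m, _ = known_model_loglik_and_gradient(raster, geometry, r0, alpha, lam - h)
        _, grad = known_model_loglik_and_gradient(raster, geometry, r0, alpha, lam)
        fd = (ll_p - ll_m) / (2 * h)
        assert grad == pytest.approx(fd, rel=1e-5)

    def test_stationarity_at_profile_maximum(self):
        """At the likelihood peak of a well-coupled raster the gradient vanishes."""
        import spikedecay as sd
        cfg = sd.PoissonNetConfig(n_neurons=120, t_ms=20_000.0, seed=31,
                                  link="logistic", r0=-5.0, alpha=1.0)
        g = sd.place_neurons(120, seed=31)
        raster = sd.simulate_poisson(np.ones((120, 120), dtype=np.uint8), cfg,
                                     geometry=g)
        est = estimate_decay_known_model(raster, g, r0=-5.0, alpha=1.0,
                                         grid_size=20)
        if not est.boundary:
            _, grad = known_model_loglik_and_gradient(raster, g, -5.0, 1.0, est.scale)
            # normalize by curvature scale: compare to gradient a half-grid away
            _, grad_off = known_model_loglik_and_gradient(raster, g, -5.0, 1.0,
                                                          est.scale * 1.3)
            assert abs(grad) < 0.05 * abs(grad_off)

    def test_known_model_consistency_small_network(self):
        """Logistic generation with all-to-all kernel weights: the lambda-only
        MLE with the generative r0, alpha lands near the true decay."""
        import spikedecay as sd
        lam_true = 5.0
        cfg = sd.PoissonNetConfig(n_neurons=200, t_ms=30_000.0, seed=13,
                                  link="logistic", r0=-5.5, alpha=0.8,
                                  kernel=DecayKernel("exponential", lam_true))
        g = sd.place_neurons(200, seed=13)
        raster = sd.simulate_poisson(np.ones((200, 200), dtype=np.uint8), cfg,
                                     geometry=g)
        est = estimate_decay_known_model(raster, g, r0=-5.5, alpha=0.8,
                                         grid_size=25)
        assert not est.boundary
        assert est.scale == pytest.approx(lam_true, rel=0.3)


@pytest.fixture(scope="module")
def coupled_raster():
    import spikedecay as sd
    cfg = sd.PoissonNetConfig(n_neurons=150, t_ms=20_000.0, seed=8)
    return sd.simulate_poisson_network(cfg)[:2]


def test_recovery_surface_across_decay_rates():
    """Estimated decay tracks the generating value across a grid (scaled
    down): per-point coupling keeps the branching ratio fixed at ~0.7."""
    import spikedecay as sd
    truths, estimates = [2.0, 5.0, 8.0], []
    for lam_true in truths:
        g = sd.place_neurons(250, seed=57)
        wbar = np.exp(-lam_true * g.distances)[~np.eye(250, dtype=bool)].mean()
        alpha = 0.7 / (250 * wbar)
        cfg = sd.PoissonNetConfig(n_neurons=250, t_ms=20_000.0, seed=57,
                                  alpha=alpha, r0=0.001,
                                  kernel=sd.DecayKernel("exponential", lam_true))
        raster, geometry, _ = sd.simulate_poisson_network(cfg)
        est = sd.estimate_decay_known_model(raster, geometry, r0=0.001,
                                            alpha=alpha, link="linear",
                                            grid_size=25)
        estimates.append(est.scale)
    rel_err = [abs(e - t) / t for e, t in zip(estimates, truths)]
    assert np.median(rel_err) < 0.20, list(zip(truths, estimates))
    assert estimates == sorted(estimates), "estimates must preserve ordering"


class TestStabilityCurves:
    def test_full_row_matches_direct_estimate(self, coupled_raster):
        raster, geometry = coupled_raster
        table = stability_curves(raster, geometry, neuron_subset_sizes=[],
                                 time_prefixes_ms=[], grid_size=10)
        direct = estimate_decay(raster, geometry, grid_size=10)
        full = table[table.kind == "full"]
        assert len(full) == 1
        assert full.lambda_hat.iloc[0] == direct.scale

    def test_subset_and_prefix_rows(self, coupled_raster):
        raster, geometry = coupled_raster
        table = stability_curves(raster, geometry, neuron_subset_sizes=[60, 100],
                                 time_prefixes_ms=[10_000.0], n_repeats=2,
                                 seed=1, grid_size=8)
        assert (table.kind == "subset").sum() == 4
        assert (table.kind == "prefix").sum() == 1

    def test_tiny_subset_rejected(self, coupled_raster):
        raster, geometry = coupled_raster
        with pytest.raises(ValueError):
            stability_curves(raster, geometry, neuron_subset_sizes=[1])

    def test_identity_subset_is_full_estimate(self, coupled_raster):
        raster, geometry = coupled_raster
        table = stability_curves(raster, geometry,
                                 neuron_subset_sizes=[raster.n_neurons],
                                 n_repeats=1, seed=0, grid_size=8)
        vals = table[table.kind.isin(["full", "subset"])].lambda_hat
        assert vals.nunique() == 1
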