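# spikedecay

Estimate how functional connectivity between neurons falls off with
distance — a single global decay rate, inferred by maximum likelihood from
a spike raster and neuron coordinates, without reconstructing any pairwise
connections.

Large-scale recordings (two-photon calcium imaging, dense electrode
arrays) deliver spike trains from thousands of neurons whose wiring is
unknown. A recurring empirical rule is that connection probability decays
exponentially with intersomatic distance,

    P(connected) = exp(-λ d),        d in mm, λ in 1/mm,

so 1/λ is the characteristic interaction length. `spikedecay` is for
systems neuroscientists who want λ itself: it fits Bernoulli spiking
models of the form

    P(S_i(t) = 1) = σ( r0 + α Σ_{j≠i} S_j(t-1) e^{-λ d_ij} )

to binary rasters, profiles the likelihood over λ (or over the scale of a
half-Gaussian, linear, inverse-square or lognormal kernel), and compares
kernel families by maximized log-likelihood. The package also contains
everything needed to validate such estimates end-to-end on synthetic data:

- a linear Poisson network generator (distance-dependent wiring, one-step
  coupling) and a spatially embedded Izhikevich network with near-Poisson,
  weakly correlated activity;
- comparator estimators — transfer entropy, point-process Granger
  causality, spike-count correlations — each reduced to a decay estimate
  by least squares against distance;
- closed-form mean-field predictions linking coupling, noise and decay to
  pairwise correlations, including the sharp high→low correlation
  transition as λ grows;
- raster diagnostics (rates, Fano factors, synchrony, correlation
  summaries) and plain-file I/O with a CLI.

## Worked example

Simulate a coupled Poisson network on the unit square at λ = 5 /mm and
re-estimate the decay from its raster:

```python
import spikedecay as sd

cfg = sd.PoissonNetConfig(n_neurons=500, t_ms=30_000.0, seed=5,
                          alpha=0.01, r0=0.00087)   # branching ~0.7, ~3 Hz
raster, geometry, J = sd.simulate_poisson_network(cfg)
print(f"rate {raster.mean_rate_hz().mean():.2f} Hz")

# decay MLE with the generative baseline/coupling known (self-validation)
est = sd.estimate_decay_known_model(raster, geometry, r0=0.00087,
                                    alpha=0.01, link="linear", grid_size=25)
print(f"lambda_hat = {est.scale:.2f} /mm "
      f"(characteristic length {1/est.scale:.3f} mm)")

# raster-only estimate: no knowledge of r0 or alpha
ro = sd.estimate_decay(raster, geometry, grid_size=30)
print(f"raster-only lambda_hat = {ro.scale:.2f} /mm")
```

Output:

```
rate 3.12 Hz
lambda_hat = 4.99 /mm (characteristic length 0.200 mm)
raster-only lambda_hat = 3.52 /mm
```

The known-parameter MLE recovers the generating decay to within a
fraction of a percent; the raster-only estimate, which assumes nothing
about the baseline rate or coupling strength, lands lower because ~30% of
spikes here are baseline-driven and dilute its coincidence profile (see
`docs/methods.md` for the bias analysis and when to prefer the spatial
GLM, `sd.fit_spatial_glm`, which fits r0, α and λ jointly).

The same operations are exposed as a CLI:

```bash
spikedecay simulate-poisson --n-neurons 500 --t-ms 50000 --seed 7 --out-dir run/
spikedecay estimate --raster run/raster.npz --positions run/positions.csv --out est.json
spikedecay select-model --raster run/raster.npz --positions run/positions.csv --out sel.json
```

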