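"""Core data containers and raster diagnostics.

Spike data are represented as dense binary neuron x time-bin matrices with an
explicit bin width in milliseconds; neuron positions live in millimetres in 2-D
or 3-D. Diagnostics (firing rates, Fano factors, pairwise spike-count
correlations, synchrony) are the quantities used throughout to check that a
raster sits in the near-Poisson, weakly correlated regime the decay estimator
assumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpikeRaster",
    "Geometry",
    "RasterDiagnostics",
    "pairwise_distances",
    "raster_diagnostics",
]


@dataclass(frozen=True)
class SpikeRaster:
    """Binary neuron x time-bin spike matrix.

    Parameters
    ----------
    spikes : ndarray of shape (n_neurons, n_bins)
        Binary (0/1) spike indicator per neuron and time bin. Bins are
        half-open ``[t, t + bin_ms)`` and 0-indexed.
    bin_ms : float
        Width of one time bin in milliseconds (default 1 ms: one model
        time-step corresponds to one millisecond).
    """

    spikes: np.ndarray
    bin_ms: float = 1.0

    def __post_init__(self) -> None:
        spikes = np.asarray(self.spikes)
        if spikes.ndim != 2:
            raise ValueError("spikes must be a 2-D neurons x bins matrix")
        if spikes.shape[0] < 1 or spikes.shape[1] < 1:
            raise ValueError("raster needs at least one neuron and one bin")
        if self.bin_ms <= 0:
            raise ValueError("bin_ms must be positive")
        vals = np.unique(spikes)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("raster entries must be binary (0/1)")
        object.__setattr__(self, "spikes", np.ascontiguousarray(spikes, dtype=np.uint8))

    @property
    def n_neurons(self) -> int:
        return self.spikes.shape[0]

    @property
    def n_bins(self) -> int:
        return self.spikes.shape[1]

    @property
    def t_total_ms(self) -> float:
        return self.n_bins * self.bin_ms

    def mean_rate_hz(self) -> np.ndarray:
        """Per-neuron mean firing rate in Hz."""
        return self.spikes.sum(axis=1) / (self.t_total_ms / 1000.0)


@dataclass(frozen=True)
class Geometry:
    """Neuron positions (mm) and the derived Euclidean distance matrix."""

    positions: np.ndarray
    distances: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] not in (2, 3):
            raise ValueError("positions must be (n_neurons, D) with D in {2, 3}")
        if not np.isfinite(pos).all():
            raise ValueError("positions contain non-finite coordinates")
        object.__setattr__(self, "positions", pos)
        if self.distances is None:
            diff = pos[:, None, :] - pos[None, :, :]
            dist = np.sqrt((diff * diff).sum(axis=-1))
            np.fill_diagonal(dist, 0.0)
            object.__setattr__(self, "distances", dist)

    @property
    def n_neurons(self) -> int:
        return self.positions.shape[0]


def pairwise_distances(positions: np.ndarray) -> Geometry:
    """Build a :class:`Geometry` with the symmetric Euclidean distance matrix.

    Distances carry the unit of the coordinates (millimetres throughout the
    package).
    """
    return Geometry(positions=np.asarray(positions, dtype=float))


@dataclass(frozen=True)
class RasterDiagnostics:
    """Summary statistics of a spike raster.

    Fano factors and correlations are computed on spike counts in
    non-overlapping windows of ``count_bin_ms``. Silent neurons have an
    undefined Fano factor; they are flagged in ``silent`` and excluded from
    ``mean_fano``. Pairs with zero count variance are likewise excluded from
    ``mean_pairwise_correlation``.
    """

    rate_hz: np.ndarray
    population_rate_hz: float
    fano_factors: np.ndarray  # NaN for silent neurons
    silent: np.ndarray  # boolean flag per neuron
    mean_fano: float
    mean_pairwise_correlation: float
    synchrony_histogram: np.ndarray
    count_bin_ms: float


def bin_counts(raster: SpikeRaster, count_bin_ms: float) -> np.ndarray:
    """Spike counts in non-overlapping windows of ``count_bin_ms``.

    Trailing bins that do not fill a whole window are dropped.
    """
    if count_bin_ms < raster.bin_ms:
        raise ValueError("count_bin_ms must be >= raster bin_ms")
    factor = count_bin_ms / raster.bin_ms
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError("count_bin_ms must be an integer multiple of bin_ms")
    factor = int(round(factor))
    n_windows = raster.n_bins // factor
    if n_windows < 1:
        raise ValueError("raster shorter than one counting window")
    trimmed = raster.spikes[:, : n_windows * factor]
    return trimmed.reshape(raster.n_neurons, n_windows, factor).sum(axis=2)


def mean_pairwise_correlation(counts: np.ndarray) -> float:
    """Mean Pearson correlation of count vectors over all valid neuron pairs.

    Zero-variance neurons are excluded from the mean rather than counted as
    zero correlation, which would otherwise bias population summaries
    downward in sparse rasters.
    """
    var = counts.var(axis=1)
    keep = var > 0
    if keep.sum() < 2:
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = np.corrcoef(counts[keep].astype(float))
    iu = np.triu_indices(corr.shape[0], k=1)
    vals = corr[iu]
    vals = vals[np.isfinite(vals)]
    return float(vals.mean()) if vals.size else float("nan")


def raster_diagnostics(raster: SpikeRaster, count_bin_ms: float = 10.0) -> RasterDiagnostics:
    """Rates, Fano factors, mean pairwise correlation and synchrony.

    The Fano factor is the ratio of spike-count variance to its mean, per
    neuron, on non-overlapping windows; a mean FF near 1 indicates
    Poisson-like variability. The default 10 ms counting window matches the
    convention used for model diagnostics (100 ms is typical for calcium
    data; pass it explicitly).
    """
    counts = bin_counts(raster, count_bin_ms)
    rate_hz = raster.mean_rate_hz()
    mean_counts = counts.mean(axis=1)
    silent = mean_counts == 0
    fano = np.full(raster.n_neurons, np.nan)
    nz = ~silent
    fano[nz] = counts[nz].var(axis=1) / mean_counts[nz]
    mean_fano = float(fano[nz].mean()) if nz.any() else float("nan")
    sync = raster.spikes.sum(axis=0)
    sync_hist = np.bincount(sync, minlength=raster.n_neurons + 1)
    return RasterDiagnostics(
        rate_hz=rate_hz,
        population_rate_hz=float(rate_hz.mean()),
        fano_factors=fano,
        silent=silent,
        mean_fano=mean_fano,
        mean_pairwise_correlation=mean_pairwise_correlation(counts),
        synchrony_histogram=sync_hist,
        count_bin_ms=float(count_bin_ms),
    )
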