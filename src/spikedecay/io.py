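"""File I/O: rasters, positions, fixtures and provenance records.

Two raster formats are supported and round-trip exactly:

- ``.npz``: compressed dense array with keys ``spikes`` (uint8,
  neurons x bins) and ``bin_ms``;
- ``.csv``: sparse event list with columns ``neuron_id,time_ms`` and header
  comments declaring ``n_neurons``, ``bin_ms`` and ``t_total_ms``. Event
  times are binned half-open at the declared bin width (an event at exactly
  t = bin_ms falls in bin 1, not bin 0).

Positions are CSV with columns ``id,x,y[,z]`` and a mandatory unit
declaration (``# units: mm`` or ``# units: um``) — micrometres are converted
to millimetres on load, and rows are aligned to raster order by id. Units
are never guessed.
"""

from __future__ import annotations

import json
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .core import Geometry, SpikeRaster, pairwise_distances
from .izhikevich import IzhikevichConfig, simulate_izhikevich_network
from .kernels import DecayKernel
from .poisson import PoissonNetConfig, simulate_poisson_network

__all__ = [
    "save_raster",
    "load_raster",
    "save_positions",
    "load_positions",
    "make_fixture",
    "write_provenance",
]


def _package_version() -> str:
    try:
        return version("spikedecay")
    except PackageNotFoundError:  # running from a source tree
        return "unknown"


def save_raster(path, raster: SpikeRaster) -> None:
    """Write a raster as ``.npz`` (dense) or ``.csv`` (event list)."""
    path = Path(path)
    if path.suffix == ".npz":
        np.savez_compressed(path, spikes=raster.spikes, bin_ms=raster.bin_ms)
    elif path.suffix == ".csv":
        nz = np.argwhere(raster.spikes)
        with open(path, "w") as fh:
            fh.write(f"# n_neurons: {raster.n_neurons}\n")
            fh.write(f"# bin_ms: {raster.bin_ms}\n")
            fh.write(f"# t_total_ms: {raster.t_total_ms}\n")
            fh.write("neuron_id,time_ms\n")
            for i, t in nz:
                fh.write(f"{i},{t * raster.bin_ms}\n")
    else:
        raise ValueError(f"unknown raster extension {path.suffix!r} (use .npz or .csv)")


def _read_header_comments(path: Path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if ":" in line:
                key, val = line[1:].split(":", 1)
                meta[key.strip()] = val.strip()
    return meta


def load_raster(path) -> SpikeRaster:
    """Read a raster saved by :func:`save_raster`."""
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path) as data:
            return SpikeRaster(spikes=data["spikes"], bin_ms=float(data["bin_ms"]))
    if path.suffix == ".csv":
        meta = _read_header_comments(path)
        for key in ("n_neurons", "bin_ms", "t_total_ms"):
            if key not in meta:
                raise ValueError(f"event-list raster missing '# {key}:' header")
        n = int(meta["n_neurons"])
        bin_ms = float(meta["bin_ms"])
        t_total = float(meta["t_total_ms"])
        n_bins = int(round(t_total / bin_ms))
        events = pd.read_csv(path, comment="#")
        spikes = np.zeros((n, n_bins), dtype=np.uint8)
        if len(events):
            ids = events["neuron_id"].to_numpy(dtype=int)
            times = events["time_ms"].to_numpy(dtype=float)
            if (times < 0).any():
                raise ValueError("negative event times")
            if (times >= t_total).any():
                raise ValueError("event time beyond declared duration")
            if (ids < 0).any() or (ids >= n).any():
                raise ValueError("neuron_id outside declared population")
            bins = np.floor(times / bin_ms).astype(int)  # half-open [t, t+bin)
            spikes[ids, bins] = 1
        return SpikeRaster(spikes=spikes, bin_ms=bin_ms)
    raise ValueError(f"unknown raster extension {path.suffix!r} (use .npz or .csv)")


def save_positions(path, geometry: Geometry, units: str = "mm") -> None:
    """Write positions as CSV with an explicit unit declaration."""
    if units not in ("mm", "um"):
        raise ValueError("units must be 'mm' or 'um'")
    factor = 1.0 if units == "mm" else 1000.0
    pos = geometry.positions * factor
    cols = ["x", "y", "z"][: pos.shape[1]]
    with open(path, "w") as fh:
        fh.write(f"# units: {units}\n")
        fh.write("id," + ",".join(cols) + "\n")
        for i, row in enumerate(pos):
            fh.write(f"{i}," + ",".join(f"{v:.9g}" for v in row) + "\n")


def load_positions(path) -> Geometry:
    """Read positions CSV; micrometres are converted to millimetres (/1000).

    Rows are sorted by id so that row order matches the raster's neuron
    order; duplicate ids or a missing unit declaration are errors.
    """
    path = Path(path)
    meta = _read_header_comments(path)
    units = meta.get("units")
    if units is None:
        raise ValueError("positions file must declare '# units: mm' or '# units: um'")
    if units not in ("mm", "um"):
        raise ValueError(f"unknown position units {units!r}")
    table = pd.read_csv(path, comment="#")
    if table["id"].duplicated().any():
        dup = table["id"][table["id"].duplicated()].iloc[0]
        raise ValueError(f"duplicate neuron id {dup} in positions file")
    table = table.sort_values("id")
    cols = [c for c in ("x", "y", "z") if c in table.columns]
    pos = table[cols].to_numpy(dtype=float)
    if units == "um":
        pos = pos / 1000.0
    return pairwise_distances(pos)


def write_provenance(path, seed: Optional[int] = None, **settings) -> dict:
    """Record the effective run configuration alongside any output."""
    record = {"package": "spikedecay", "version": _package_version(), "seed": seed}
    record.update(settings)
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2, default=str)
    return record


def _paired_toy_raster(t_bins: int, p: float, lag: int, seed: int) -> SpikeRaster:
    """Two-neuron raster where neuron 1 copies neuron 0 with a fixed lag —
    the closed-form oracle input for transfer entropy / Granger tests."""
    rng = np.random.default_rng(seed)
    x = (rng.random(t_bins) < p).astype(np.uint8)
    y = np.zeros(t_bins, dtype=np.uint8)
    y[lag:] = x[:-lag] if lag > 0 else x
    return SpikeRaster(spikes=np.vstack([x, y]), bin_ms=1.0)


def make_fixture(kind: str, out_dir, params: Optional[dict] = None, seed: int = 0) -> dict:
    """Write a reproducible raster + positions + ground-truth fixture set.

    ``kind`` is ``poisson``, ``izhikevich`` or ``paired_toy``. Returns the
    ground-truth dictionary that was written to ``truth.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = dict(params or {})
    if kind == "poisson":
        family = params.pop("family", "exponential")
        scale = params.pop("scale", 5.0)
        params["kernel"] = DecayKernel(family, float(scale))
        cfg = PoissonNetConfig(**{**params, "seed": seed})
        raster, geometry, _ = simulate_poisson_network(cfg)
        truth = {"kind": kind, "family": cfg.kernel.family, "scale": cfg.kernel.scale,
                 "r0": cfg.r0, "alpha": cfg.alpha, "seed": seed}
    elif kind == "izhikevich":
        cfg = IzhikevichConfig(**{**params, "seed": seed})
        raster, geometry, _ = simulate_izhikevich_network(cfg)
        truth = {"kind": kind, "family": "exponential", "scale": cfg.lambda_decay,
                 "base_sparsity": cfg.base_sparsity, "seed": seed}
    elif kind == "paired_toy":
        raster = _paired_toy_raster(
            t_bins=int(params.get("t_bins", 20000)),
            p=float(params.get("p", 0.3)),
            lag=int(params.get("lag", 1)),
            seed=seed,
        )
        geometry = pairwise_distances(np.array([[0.0, 0.0], [0.1, 0.0]]))
        truth = {"kind": kind, "p": float(params.get("p", 0.3)),
                 "lag": int(params.get("lag", 1)), "seed": seed}
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    save_raster(out / "raster.npz", raster)
    save_positions(out / "positions.csv", geometry, units="mm")
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)
    write_provenance(out / "provenance.json", seed=seed, kind=kind, params=params)
    return truth
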