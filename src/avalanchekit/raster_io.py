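"""Spike-raster data model and I/O.

A raster is a list of timestamped spikes plus a neuron table giving, for every
neuron id, its population label (e.g. ``IT5B``), cortical layer, normalized
cortical depth (NCD, pia = 0, white matter = 1) and excitatory/inhibitory
flag.  Everything downstream — avalanche detection, rhythm-pattern selection,
classification — consumes either the raster itself or its 1-ms binned
population histograms.

On-disk format: a two-column delimited text file (header ``time_ms,neuron_id``)
and a JSON metadata sidecar ``{"schema_version": 1, "t_start": ..,
"t_stop": .., "neurons": [{"id", "population", "layer", "ncd", "ei"}, ...]}``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SpikeRaster",
    "BinnedCounts",
    "RasterParseError",
    "RasterValidationError",
    "read_raster",
    "write_raster",
    "bin_spikes",
    "instantaneous_rate",
]

SCHEMA_VERSION = 1

NEURON_COLUMNS = ("population", "layer", "ncd", "ei")


class RasterParseError(ValueError):
    """A spike or metadata file could not be parsed (carries a line number)."""


class RasterValidationError(ValueError):
    """A raster violates an invariant (unknown neuron, bad NCD, unsorted...)."""


@dataclass
class SpikeRaster:
    """Timestamped spikes plus a neuron table.

    Parameters
    ----------
    times:
        Spike times in ms, non-decreasing, all in ``[t_start, t_stop)``.
    neuron_ids:
        Integer neuron id per spike; every id must appear in ``neurons``.
    neurons:
        DataFrame indexed by neuron id with columns
        ``population, layer, ncd, ei``; ``ei`` is ``"excitatory"`` or
        ``"inhibitory"``; ``0 <= ncd <= 1``.
    t_start, t_stop:
        Recording span in ms.
    """

    times: np.ndarray
    neuron_ids: np.ndarray
    neurons: pd.DataFrame
    t_start: float
    t_stop: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.neuron_ids = np.asarray(self.neuron_ids, dtype=np.int64)
        if self.times.shape != self.neuron_ids.shape:
            raise RasterValidationError("times and neuron_ids differ in length")
        if self.t_stop <= self.t_start:
            raise RasterValidationError(
                f"t_stop ({self.t_stop}) must exceed t_start ({self.t_start})"
            )
        for col in NEURON_COLUMNS:
            if col not in self.neurons.columns:
                raise RasterValidationError(f"neuron table lacks column {col!r}")
        ncd = self.neurons["ncd"].to_numpy(dtype=float)
        if np.any((ncd < 0.0) | (ncd > 1.0)):
            raise RasterValidationError("ncd values must lie in [0, 1]")
        bad_ei = set(self.neurons["ei"]) - {"excitatory", "inhibitory"}
        if bad_ei:
            raise RasterValidationError(f"unknown ei flags: {sorted(bad_ei)}")
        if self.times.size:
            if np.any(np.diff(self.times) < 0):
                raise RasterValidationError("spike times must be non-decreasing")
            if self.times[0] < self.t_start or self.times[-1] >= self.t_stop:
                raise RasterValidationError(
                    "spike times must lie in [t_start, t_stop)"
                )
            unknown = np.setdiff1d(
                np.unique(self.neuron_ids), self.neurons.index.to_numpy()
            )
            if unknown.size:
                raise RasterValidationError(
                    f"spikes reference unknown neuron ids {unknown[:5].tolist()}"
                )

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    @property
    def n_neurons(self) -> int:
        return int(len(self.neurons))

    @property
    def duration_ms(self) -> float:
        return float(self.t_stop - self.t_start)

    def populations(self) -> list[str]:
        """Population labels present in the neuron table, sorted."""
        return sorted(self.neurons["population"].unique())

    def spike_populations(self) -> np.ndarray:
        """Population label of every spike, aligned with ``times``."""
        return (
            self.neurons["population"].reindex(self.neuron_ids).to_numpy()
        )


@dataclass
class BinnedCounts:
    """Per-bin spike counts: total and per population.

    Bin ``i`` covers the half-open interval
    ``[origin + i*bin_width, origin + (i+1)*bin_width)``.
    """

    bin_width: float
    origin: float
    total: np.ndarray
    per_population: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_bins(self) -> int:
        return int(self.total.size)

    def bin_edges(self) -> np.ndarray:
        return self.origin + self.bin_width * np.arange(self.n_bins + 1)


def _parse_spike_file(spike_path) -> tuple[np.ndarray, np.ndarray]:
    try:
        df = pd.read_csv(
            spike_path, dtype={"time_ms": float, "neuron_id": np.int64}
        )
    except (ValueError, pd.errors.ParserError):
        # Re-scan line by line to report where parsing failed.
        with open(spike_path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if lineno == 1:
                    continue
                parts = line.strip().split(",")
                try:
                    float(parts[0])
                    int(parts[1])
                except (ValueError, IndexError):
                    raise RasterParseError(
                        f"{spike_path}: malformed row at line {lineno}: "
                        f"{line.strip()!r}"
                    ) from None
        raise RasterParseError(f"{spike_path}: malformed spike file") from None
    missing = {"time_ms", "neuron_id"} - set(df.columns)
    if missing:
        raise RasterParseError(
            f"{spike_path}: missing columns {sorted(missing)} (line 1)"
        )
    return df["time_ms"].to_numpy(), df["neuron_id"].to_numpy()


def read_raster(spike_path, metadata_path) -> SpikeRaster:
    """Read a spike file and its JSON metadata sidecar into a SpikeRaster.

    Raises
    ------
    RasterParseError
        On a malformed row (message includes the line number).
    RasterValidationError
        If a spike references a neuron id absent from the metadata, or any
        other raster invariant fails.
    """
    times, ids = _parse_spike_file(spike_path)
    with open(metadata_path) as fh:
        meta = json.load(fh)
    neurons = pd.DataFrame(meta["neurons"])
    if neurons.empty:
        neurons = pd.DataFrame(columns=["id", *NEURON_COLUMNS])
    neurons = neurons.set_index("id")
    return SpikeRaster(
        times=times,
        neuron_ids=ids,
        neurons=neurons,
        t_start=float(meta["t_start"]),
        t_stop=float(meta["t_stop"]),
    )


def write_raster(raster: SpikeRaster, spike_path, metadata_path) -> None:
    """Write spikes and metadata; ``read_raster`` round-trips exactly."""
    df = pd.DataFrame({"time_ms": raster.times, "neuron_id": raster.neuron_ids})
    # repr-based float formatting so that read-back is bit-exact
    df.to_csv(spike_path, index=False)
    records = [
        {
            "id": int(idx),
            "population": row["population"],
            "layer": row["layer"],
            "ncd": float(row["ncd"]),
            "ei": row["ei"],
        }
        for idx, row in raster.neurons.iterrows()
    ]
    meta = {
        "schema_version": SCHEMA_VERSION,
        "t_start": raster.t_start,
        "t_stop": raster.t_stop,
        "neurons": records,
    }
    with open(metadata_path, "w") as fh:
        json.dump(meta, fh, indent=1)


def bin_spikes(raster: SpikeRaster, bin_width: float = 1.0) -> BinnedCounts:
    """Bin spikes into half-open bins of ``bin_width`` ms from ``t_start``.

    The sum of ``total`` equals the raw spike count for every bin width, and
    ``total`` is the element-wise sum of the per-population histograms.
    """
    if bin_width <= 0:
        raise ValueError(f"bin_width must be positive, got {bin_width}")
    n_bins = int(np.ceil(raster.duration_ms / bin_width))
    if n_bins == 0:
        n_bins = 1
    idx = np.floor((raster.times - raster.t_start) / bin_width).astype(np.int64)
    total = np.bincount(idx, minlength=n_bins).astype(np.int64)
    per_pop: dict[str, np.ndarray] = {}
    if raster.n_spikes:
        pops = raster.spike_populations()
        for label in raster.populations():
            sel = pops == label
            if sel.any():
                per_pop[label] = np.bincount(
                    idx[sel], minlength=n_bins
                ).astype(np.int64)
            else:
                per_pop[label] = np.zeros(n_bins, dtype=np.int64)
    else:
        for label in raster.populations():
            per_pop[label] = np.zeros(n_bins, dtype=np.int64)
    return BinnedCounts(
        bin_width=float(bin_width),
        origin=float(raster.t_start),
        total=total,
        per_population=per_pop,
    )


def instantaneous_rate(
    raster: SpikeRaster, window: float = 100.0
) -> tuple[np.ndarray, float, float]:
    """Windowed population rate in Hz per neuron, its mean, and its CV.

    Each window's rate is ``count / (window_s * n_neurons)``; the CV is the
    ratio of the standard deviation to the mean across windows.  A raster
    spanning a single window has CV 0 by convention.
    """
    if window <= 0:
        raise ValueError(f"window must be positive, got {window}")
    if raster.duration_ms <= 0:
        raise ValueError("raster has zero duration")
    if raster.n_neurons == 0:
        raise ValueError("raster has no neurons")
    counts = bin_spikes(raster, bin_width=window).total
    rates = counts / (window / 1000.0) / raster.n_neurons
    mean = float(rates.mean())
    if rates.size < 2 or mean == 0.0:
        cv = 0.0
    else:
        cv = float(rates.std() / mean)
    return rates, mean, cv
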