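"""Avalanche detection in binned spike counts.

An avalanche is a maximal run of contiguous non-empty bins (each containing at
least one spike) preceded and followed by at least one empty bin.  Its size is
the total spike count of the run and its duration is the run length times the
bin width (1 ms by default).  Runs touching the first or last bin of the
record lack the bounding empty bin on that side and are kept but flagged
``censored``; power-law fits exclude them by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .raster_io import BinnedCounts, SpikeRaster

__all__ = [
    "Avalanche",
    "detect_avalanches",
    "attach_spikes",
    "inter_avalanche_intervals",
]

LABELS = ("Irregular", "Fragment", "Beta", "Delta+")


@dataclass
class Avalanche:
    """One avalanche: a maximal run of non-empty bins.

    ``size_neurons`` and ``per_population_counts`` are filled by
    :func:`attach_spikes`; ``label`` by :mod:`avalanchekit.classify`.
    """

    start_bin: int
    end_bin: int  # inclusive
    size_spikes: int
    bin_width: float
    origin: float
    censored: bool = False
    size_neurons: int | None = None
    per_population_counts: dict[str, int] = field(default_factory=dict)
    label: str = "unassigned"
    nested_gamma: int = 0  # gamma trains overlapping a Delta+ avalanche
    spike_slice: tuple[int, int] | None = None  # [i0, i1) into the raster

    @property
    def n_bins(self) -> int:
        return self.end_bin - self.start_bin + 1

    @property
    def duration_ms(self) -> float:
        return self.n_bins * self.bin_width

    @property
    def start_ms(self) -> float:
        return self.origin + self.start_bin * self.bin_width

    @property
    def stop_ms(self) -> float:
        """End of the last bin (exclusive)."""
        return self.origin + (self.end_bin + 1) * self.bin_width


def detect_avalanches(binned: BinnedCounts) -> list[Avalanche]:
    """Run-length scan for maximal runs of non-empty bins.

    Every spike belongs to exactly one avalanche; consecutive avalanches are
    separated by at least one empty bin.  Runs at the record boundary are
    flagged ``censored``.
    """
    total = np.asarray(binned.total)
    filled = total > 0
    if not filled.any():
        return []
    # transitions of the filled mask -> run starts/ends
    padded = np.concatenate(([False], filled, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1) - 1
    csum = np.concatenate(([0], np.cumsum(total)))
    out = []
    n = total.size
    for s, e in zip(starts, ends):
        out.append(
            Avalanche(
                start_bin=int(s),
                end_bin=int(e),
                size_spikes=int(csum[e + 1] - csum[s]),
                bin_width=binned.bin_width,
                origin=binned.origin,
                censored=bool(s == 0 or e == n - 1),
            )
        )
    return out


def attach_spikes(
    raster: SpikeRaster, avalanches: list[Avalanche]
) -> list[Avalanche]:
    """Fill neuron membership: distinct-neuron counts and per-population counts.

    The avalanches must come from binning this same raster (same origin and
    bin width); otherwise a consistency error is raised.
    """
    if not avalanches:
        return avalanches
    w = avalanches[0].bin_width
    origin = avalanches[0].origin
    if abs(origin - raster.t_start) > 1e-9:
        raise ValueError(
            "avalanche binning origin does not match the raster t_start"
        )
    spike_bins = np.floor((raster.times - raster.t_start) / w).astype(np.int64)
    pops = raster.spike_populations()
    for av in avalanches:
        i0 = int(np.searchsorted(spike_bins, av.start_bin, side="left"))
        i1 = int(np.searchsorted(spike_bins, av.end_bin, side="right"))
        if i1 - i0 != av.size_spikes:
            raise ValueError(
                "avalanche spike count disagrees with the raster; was it "
                "binned with a different origin or width?"
            )
        av.spike_slice = (i0, i1)
        av.size_neurons = int(np.unique(raster.neuron_ids[i0:i1]).size)
        labels, counts = np.unique(pops[i0:i1], return_counts=True)
        av.per_population_counts = {
            str(k): int(v) for k, v in zip(labels, counts)
        }
    return avalanches


def inter_avalanche_intervals(avalanches: list[Avalanche]) -> np.ndarray:
    """Quiescent gaps (ms) between consecutive avalanches.

    ``gap[i] = (start_bin[i+1] - end_bin[i] - 1) * bin_width``; by the
    avalanche definition every gap is at least one bin.  Fewer than two
    avalanches give an empty result.
    """
    if len(avalanches) < 2:
        return np.empty(0, dtype=float)
    starts = np.array([a.start_bin for a in avalanches[1:]])
    ends = np.array([a.end_bin for a in avalanches[:-1]])
    w = avalanches[0].bin_width
    return (starts - ends - 1).astype(float) * w
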