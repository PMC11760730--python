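"""Avalanche typing: Irregular, Fragment, Beta, Delta+.

Each avalanche is assigned exactly one of four types from its population
composition and its overlap with selected pattern events, with precedence
Delta+ > Beta > Irregular > Fragment:

* Delta+ — the avalanche span overlaps at least one delta event (these
  avalanches typically also carry nested gamma and sometimes beta or
  irregular activity);
* Beta — it overlaps a beta event and is composed essentially entirely of
  beta-pattern activity (>= 90% of its spikes inside beta-event spans by
  default);
* Irregular — all of its spikes are IT5B/IT6 with no inhibitory activity;
* Fragment — anything else (activity beyond IT5B/IT6, often including
  inhibitory neurons, without a delta or full beta composition).

Gamma events never define their own class; gamma trains overlapping a
Delta+ avalanche are recorded as nested annotations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .avalanche import Avalanche
from .patterns import PatternEvent
from .raster_io import SpikeRaster

__all__ = [
    "classify_avalanche",
    "classify_all",
    "summary_table",
    "share_of",
]

IRREGULAR_POPULATIONS = frozenset({"IT5B", "IT6"})
TYPE_ORDER = ("Irregular", "Fragment", "Beta", "Delta+")


def _overlaps(av: Avalanche, ev: PatternEvent) -> bool:
    return av.start_ms < ev.offset and av.stop_ms > ev.onset


def _beta_spike_fraction(
    av: Avalanche, raster: SpikeRaster, beta_events: list[PatternEvent]
) -> float:
    if av.spike_slice is None:
        raise ValueError("avalanche lacks spike membership; run attach_spikes")
    i0, i1 = av.spike_slice
    t = raster.times[i0:i1]
    if t.size == 0:
        return 0.0
    inside = np.zeros(t.size, dtype=bool)
    for ev in beta_events:
        inside |= (t >= ev.onset) & (t < ev.offset)
    return float(inside.mean())


def classify_avalanche(
    av: Avalanche,
    events: list[PatternEvent],
    raster: SpikeRaster | None = None,
    beta_fraction: float = 0.9,
) -> str:
    """Label one avalanche; requires membership from ``attach_spikes``.

    ``raster`` is needed only for the Beta composition check (spike times);
    without it an avalanche overlapping a beta event falls back to the
    span-containment criterion (onset/offset inside beta spans).
    """
    if av.size_neurons is None or not av.per_population_counts:
        raise ValueError(
            "avalanche lacks membership; run attach_spikes first"
        )
    deltas = [e for e in events if e.kind == "delta"]
    if any(_overlaps(av, e) for e in deltas):
        return "Delta+"
    betas = [e for e in events if e.kind == "beta"]
    overlapped = [e for e in betas if _overlaps(av, e)]
    if overlapped:
        if raster is not None:
            frac = _beta_spike_fraction(av, raster, betas)
            if frac >= beta_fraction:
                return "Beta"
        else:
            if any(
                e.onset <= av.start_ms and av.stop_ms <= e.offset
                for e in betas
            ):
                return "Beta"
    pops = set(av.per_population_counts)
    if pops <= IRREGULAR_POPULATIONS:
        # IT5B/IT6 are excitatory, so this also implies zero inhibitory spikes
        return "Irregular"
    return "Fragment"


def classify_all(
    avalanches: list[Avalanche],
    events: list[PatternEvent],
    raster: SpikeRaster | None = None,
    beta_fraction: float = 0.9,
) -> list[Avalanche]:
    """Label every avalanche in place and annotate nested gamma trains."""
    gammas = [e for e in events if e.kind == "gamma"]
    for av in avalanches:
        av.label = classify_avalanche(
            av, events, raster=raster, beta_fraction=beta_fraction
        )
        if av.label == "Delta+":
            av.nested_gamma = sum(_overlaps(av, g) for g in gammas)
    return avalanches


def summary_table(avalanches: list[Avalanche]) -> pd.DataFrame:
    """Per-type summary: counts, shares, size/duration ranges, total durations.

    Columns mirror the usual avalanche-typing report: Number, Percent Total
    Num, Size Range (spikes), Size Range (neurons), Duration Range (ms),
    Total Duration (ms), Percent Total Dur.  Percentages are rounded to one
    decimal and computed from exact counts.
    """
    if not avalanches:
        raise ValueError("no avalanches to summarise")
    unlabeled = [a for a in avalanches if a.label not in TYPE_ORDER]
    if unlabeled:
        raise ValueError(
            f"{len(unlabeled)} avalanches are unlabeled; run classify_all"
        )
    total_n = len(avalanches)
    total_dur = sum(a.duration_ms for a in avalanches)
    rows = []
    for label in TYPE_ORDER:
        group = [a for a in avalanches if a.label == label]
        if group:
            sizes = [a.size_spikes for a in group]
            neurons = [
                a.size_neurons for a in group if a.size_neurons is not None
            ]
            durs = [a.duration_ms for a in group]
            dur_total = sum(durs)
            rows.append(
                {
                    "type": label,
                    "number": len(group),
                    "percent_of_number": round(
                        100.0 * len(group) / total_n, 1
                    ),
                    "size_min_spikes": min(sizes),
                    "size_max_spikes": max(sizes),
                    "size_min_neurons": min(neurons) if neurons else None,
                    "size_max_neurons": max(neurons) if neurons else None,
                    "duration_min_ms": min(durs),
                    "duration_max_ms": max(durs),
                    "total_duration_ms": dur_total,
                    "percent_of_duration": round(
                        100.0 * dur_total / total_dur, 1
                    ),
                }
            )
        else:
            rows.append(
                {
                    "type": label,
                    "number": 0,
                    "percent_of_number": 0.0,
                    "size_min_spikes": None,
                    "size_max_spikes": None,
                    "size_min_neurons": None,
                    "size_max_neurons": None,
                    "duration_min_ms": None,
                    "duration_max_ms": None,
                    "total_duration_ms": 0.0,
                    "percent_of_duration": 0.0,
                }
            )
    return pd.DataFrame(rows).set_index("type")


def share_of(values: dict[str, float], members: set[str] | list[str]) -> float:
    """Percentage share of ``members`` in a mapping of per-type totals.

    ``share_of({"Irregular": 10173, ...}, {"Irregular", "Fragment"})`` gives
    the combined number share, rounded to one decimal.
    """
    members = set(members)
    unknown = members - set(values)
    if unknown:
        raise ValueError(f"unknown labels: {sorted(unknown)}")
    total = float(sum(values.values()))
    if total == 0:
        raise ValueError("empty total")
    return round(100.0 * sum(values[m] for m in members) / total, 1)
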