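"""Time-domain selection of delta, beta, and gamma population patterns.

Pattern events are picked from 1-ms population spike histograms by simple
peak thresholding in the style of SPUD-type time-domain feature selection:

* delta — large IT2/3 peaks (>= 250 spikes per 1-ms bin); peaks <= 50 ms
  apart are collapsed onto the first of the cluster; the event span extends
  to where IT2/3 falls below a floor (10% of the threshold by default).
* beta — IT5B peaks (>= 15 spikes), excluding activity concurrent with
  robust IT2/3 activity (>= 250), i.e. the delta pattern; consecutive kept
  peaks are grouped into trains (~45.5 ms period, ~22 Hz).
* gamma — PT5B peaks (>= 20 spikes), with delta activity removed either by
  excluding whole delta-event spans (default) or only bins of robust
  concurrent IT2/3 activity; trains have ~18.5 ms period (~54 Hz).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .raster_io import BinnedCounts

__all__ = [
    "PatternEvent",
    "UndefinedFrequencyError",
    "threshold_peaks",
    "select_delta",
    "select_beta",
    "select_gamma",
    "select_patterns",
    "event_frequency",
    "event_triggered_average",
    "spectrogram",
]

DELTA_THRESHOLD = 250  # IT2/3 spikes per 1-ms bin
BETA_THRESHOLD = 15  # IT5B spikes per 1-ms bin
GAMMA_THRESHOLD = 20  # PT5B spikes per 1-ms bin
DELTA_MERGE_MS = 50.0  # peaks closer than this collapse onto the first
FLOOR_FRACTION = 0.1  # event span extends to threshold * fraction

DRIVER = {"delta": "IT2/3", "beta": "IT5B", "gamma": "PT5B"}


class UndefinedFrequencyError(ValueError):
    """An event has fewer than two peaks, so no frequency is defined."""


@dataclass
class PatternEvent:
    """A detected delta/beta/gamma episode."""

    kind: str  # {delta, beta, gamma}
    onset: float  # ms
    offset: float  # ms (exclusive)
    peak_times: list[float] = field(default_factory=list)
    driver_population: str = ""

    def __post_init__(self) -> None:
        if not self.driver_population:
            self.driver_population = DRIVER[self.kind]
        if self.offset <= self.onset:
            raise ValueError("event offset must exceed its onset")

    @property
    def duration_ms(self) -> float:
        return self.offset - self.onset

    def contains(self, t: float) -> bool:
        return self.onset <= t < self.offset


def threshold_peaks(
    hist: np.ndarray, min_count: int, smooth_ms: int = 0
) -> np.ndarray:
    """Indices of local maxima with count >= ``min_count``.

    A local maximum is strictly greater than its neighbours over a 3-bin
    neighbourhood; a plateau of equal values counts once, at its leftmost
    bin.  Optional boxcar smoothing (``smooth_ms`` bins, off by default) is
    applied before peak picking.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    h = np.asarray(hist, dtype=float)
    if smooth_ms and smooth_ms > 1:
        kernel = np.ones(smooth_ms) / smooth_ms
        h = np.convolve(h, kernel, mode="same")
    if h.size == 0:
        return np.empty(0, dtype=np.int64)
    # collapse plateaus to their leftmost bin, then compare run values
    change = np.flatnonzero(np.diff(h) != 0)
    run_starts = np.concatenate(([0], change + 1))
    run_vals = h[run_starts]
    left = np.concatenate(([-np.inf], run_vals[:-1]))
    right = np.concatenate((run_vals[1:], [-np.inf]))
    is_peak = (run_vals > left) & (run_vals > right) & (run_vals >= min_count)
    return run_starts[is_peak].astype(np.int64)


def _enforce_min_separation(
    peaks: np.ndarray, hist: np.ndarray, min_bins: int
) -> np.ndarray:
    """Greedily keep the highest peaks at least ``min_bins`` apart.

    Suppresses sub-period noise maxima inside one oscillation bump so that
    inter-peak intervals reflect the rhythm period, not counting noise.
    """
    if min_bins <= 1 or peaks.size < 2:
        return peaks
    order = peaks[np.argsort(hist[peaks], kind="stable")[::-1]]
    kept: list[int] = []
    for p in order:
        if all(abs(p - q) >= min_bins for q in kept):
            kept.append(int(p))
    return np.array(sorted(kept), dtype=np.int64)


def _cluster_first(peaks: np.ndarray, times: np.ndarray, merge_ms: float):
    """Split peaks into chains with consecutive spacing <= merge_ms.

    Returns (kept leader indices, list of member index arrays)."""
    if peaks.size == 0:
        return peaks, []
    gaps = np.diff(times[peaks])
    breaks = np.flatnonzero(gaps > merge_ms) + 1
    groups = np.split(np.arange(peaks.size), breaks)
    leaders = np.array([peaks[g[0]] for g in groups], dtype=np.int64)
    members = [peaks[g] for g in groups]
    return leaders, members


def _bin_times(binned: BinnedCounts) -> np.ndarray:
    # bin centres in ms
    return binned.origin + binned.bin_width * (
        np.arange(binned.n_bins) + 0.5
    )


def _require(binned: BinnedCounts, label: str) -> np.ndarray:
    try:
        return binned.per_population[label]
    except KeyError:
        raise ValueError(
            f"per-population histogram for {label!r} is required"
        ) from None


def _extend_span(
    hist: np.ndarray, peak: int, floor: float
) -> tuple[int, int]:
    """Extend from a peak bin to the nearest bins below ``floor``.

    Returns (first bin of the span, last bin of the span), inclusive."""
    above = hist >= floor
    lo = peak
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = peak
    n = hist.size
    while hi < n - 1 and above[hi + 1]:
        hi += 1
    return lo, hi


def select_delta(
    binned: BinnedCounts,
    threshold: int = DELTA_THRESHOLD,
    merge_ms: float = DELTA_MERGE_MS,
    floor_fraction: float = FLOOR_FRACTION,
    merge_mode: str = "keep-first",
) -> list[PatternEvent]:
    """Delta events from IT2/3 peaks >= ``threshold`` spikes per 1-ms bin.

    Peaks whose consecutive spacing is <= ``merge_ms`` form a cluster; with
    the default ``keep-first`` mode the first peak of each cluster seeds one
    event (``drop-all`` discards whole clusters of more than one peak).  The
    event span extends from the seed peak outwards to the nearest bins where
    IT2/3 falls below ``floor_fraction * threshold``.
    """
    hist = _require(binned, "IT2/3")
    times = _bin_times(binned)
    peaks = threshold_peaks(hist, threshold)
    leaders, members = _cluster_first(peaks, times, merge_ms)
    if merge_mode == "drop-all":
        keep = [i for i, m in enumerate(members) if m.size == 1]
        leaders = leaders[keep]
        members = [members[i] for i in keep]
    elif merge_mode != "keep-first":
        raise ValueError(f"unknown merge_mode {merge_mode!r}")
    floor = floor_fraction * threshold
    events = []
    for lead, group in zip(leaders, members):
        lo, hi = _extend_span(hist, int(lead), floor)
        onset = binned.origin + lo * binned.bin_width
        offset = binned.origin + (hi + 1) * binned.bin_width
        in_span = group[(times[group] >= onset) & (times[group] < offset)]
        events.append(
            PatternEvent(
                kind="delta",
                onset=float(onset),
                offset=float(offset),
                peak_times=[float(t) for t in times[in_span]],
            )
        )
    return events


def _train_events(
    kind: str,
    binned: BinnedCounts,
    hist: np.ndarray,
    peaks: np.ndarray,
    max_gap_ms: float,
    floor: float,
) -> list[PatternEvent]:
    """Group kept peaks into trains; one event per train."""
    times = _bin_times(binned)
    if peaks.size == 0:
        return []
    gaps = np.diff(times[peaks])
    breaks = np.flatnonzero(gaps > max_gap_ms) + 1
    events = []
    for group in np.split(peaks, breaks):
        lo, _ = _extend_span(hist, int(group[0]), floor)
        _, hi = _extend_span(hist, int(group[-1]), floor)
        events.append(
            PatternEvent(
                kind=kind,
                onset=float(binned.origin + lo * binned.bin_width),
                offset=float(binned.origin + (hi + 1) * binned.bin_width),
                peak_times=[float(t) for t in times[group]],
            )
        )
    return events


def select_beta(
    binned: BinnedCounts,
    threshold: int = BETA_THRESHOLD,
    delta_threshold: int = DELTA_THRESHOLD,
    delta_events: list[PatternEvent] | None = None,
    max_gap_ms: float = 100.0,
    floor_fraction: float = FLOOR_FRACTION,
    min_separation_ms: float = 25.0,
) -> list[PatternEvent]:
    """Beta trains from IT5B peaks >= ``threshold``, delta activity removed.

    A peak is excluded if its bin has robust concurrent IT2/3 activity
    (>= ``delta_threshold``) or if it falls inside a selected delta-event
    span (when ``delta_events`` is given; if None they are selected here).
    Peaks closer than ``min_separation_ms`` (about half a beta period) are
    thinned to the highest, and kept peaks with spacing <= ``max_gap_ms``
    form one train event.
    """
    hist = _require(binned, "IT5B")
    it23 = _require(binned, "IT2/3")
    if delta_events is None:
        delta_events = select_delta(binned, threshold=delta_threshold)
    times = _bin_times(binned)
    peaks = threshold_peaks(hist, threshold)
    peaks = _enforce_min_separation(
        peaks, hist, int(round(min_separation_ms / binned.bin_width))
    )
    keep = it23[peaks] < delta_threshold
    for ev in delta_events:
        keep &= ~((times[peaks] >= ev.onset) & (times[peaks] < ev.offset))
    peaks = peaks[keep]
    return _train_events(
        "beta", binned, hist, peaks, max_gap_ms, floor_fraction * threshold
    )


def select_gamma(
    binned: BinnedCounts,
    threshold: int = GAMMA_THRESHOLD,
    robust_threshold: int = 250,
    delta_events: list[PatternEvent] | None = None,
    exclusion: str = "delta-spans",
    max_gap_ms: float = 40.0,
    floor_fraction: float = FLOOR_FRACTION,
    min_separation_ms: float = 9.0,
) -> list[PatternEvent]:
    """Gamma trains from PT5B peaks >= ``threshold``.

    Two exclusion modes remove delta-pattern activity:

    * ``"delta-spans"`` (default) — drop peaks inside any selected
      delta-event span; gamma nested within delta envelopes is then
      annotated on the delta avalanche rather than selected here.
    * ``"robust-concurrent"`` — drop only peaks whose bin has robust
      concurrent IT2/3 activity (>= ``robust_threshold``), which keeps
      gamma bursts nested in the late part of a delta envelope.
    """
    hist = _require(binned, "PT5B")
    times = _bin_times(binned)
    peaks = threshold_peaks(hist, threshold)
    peaks = _enforce_min_separation(
        peaks, hist, int(round(min_separation_ms / binned.bin_width))
    )
    if exclusion == "delta-spans":
        if delta_events is None:
            delta_events = select_delta(binned)
        keep = np.ones(peaks.size, dtype=bool)
        for ev in delta_events:
            keep &= ~(
                (times[peaks] >= ev.onset) & (times[peaks] < ev.offset)
            )
        peaks = peaks[keep]
    elif exclusion == "robust-concurrent":
        it23 = _require(binned, "IT2/3")
        peaks = peaks[it23[peaks] < robust_threshold]
    else:
        raise ValueError(f"unknown exclusion mode {exclusion!r}")
    return _train_events(
        "gamma", binned, hist, peaks, max_gap_ms, floor_fraction * threshold
    )


def select_patterns(
    binned: BinnedCounts, kinds: tuple[str, ...] = ("delta", "beta", "gamma")
) -> list[PatternEvent]:
    """Select all requested pattern kinds with default thresholds.

    A kind whose driver population has no histogram (e.g. a deep-layer-only
    recording with no IT2/3) yields no events of that kind.
    """
    have = binned.per_population
    events: list[PatternEvent] = []
    delta = select_delta(binned) if "IT2/3" in have else []
    if "delta" in kinds:
        events.extend(delta)
    if "beta" in kinds and {"IT5B", "IT2/3"} <= set(have):
        events.extend(select_beta(binned, delta_events=delta))
    if "gamma" in kinds and "PT5B" in have:
        events.extend(select_gamma(binned, delta_events=delta))
    return sorted(events, key=lambda e: e.onset)


def event_frequency(event: PatternEvent) -> float:
    """Dominant frequency in Hz: 1000 / median inter-peak interval (ms)."""
    if len(event.peak_times) < 2:
        raise UndefinedFrequencyError(
            "at least two peaks are needed to define a frequency"
        )
    ipi = np.diff(np.sort(np.asarray(event.peak_times, dtype=float)))
    return float(1000.0 / np.median(ipi))


def event_triggered_average(
    binned: BinnedCounts, events: list[PatternEvent], window: float = 200.0
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Average per-population histograms aligned at each event's first peak.

    Returns (lag axis in ms, mapping population -> mean histogram).  Events
    whose window extends past the record are truncated out with a warning.
    """
    if not events:
        raise ValueError("at least one event is required")
    w = binned.bin_width
    half = int(round(window / w))
    lags = (np.arange(-half, half + 1)) * w
    n = binned.n_bins
    rows: dict[str, list[np.ndarray]] = {
        label: [] for label in binned.per_population
    }
    used = 0
    for ev in events:
        t0 = ev.peak_times[0] if ev.peak_times else ev.onset
        c = int(np.floor((t0 - binned.origin) / w))
        if c - half < 0 or c + half >= n:
            warnings.warn(
                "event window exceeds the record; event truncated out",
                stacklevel=2,
            )
            continue
        used += 1
        for label, hist in binned.per_population.items():
            rows[label].append(hist[c - half : c + half + 1])
    if used == 0:
        raise ValueError("no event fits entirely inside the record")
    avg = {
        label: np.mean(np.stack(stack), axis=0)
        for label, stack in rows.items()
        if stack
    }
    return lags, avg


def spectrogram(
    series: np.ndarray,
    dt_ms: float = 1.0,
    window: float = 1000.0,
    overlap: float = 0.5,
):
    """Short-time Fourier power of a rate/count series.

    Parameters are the sampling step of the series (ms), the STFT window
    length (ms) and the fractional overlap in [0, 1).  Returns
    (frequencies Hz, segment times s, power).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap must lie in [0, 1)")
    fs = 1000.0 / dt_ms
    nperseg = int(round(window / dt_ms))
    series = np.asarray(series, dtype=float)
    if series.size <= nperseg:
        raise ValueError("series must be longer than the window")
    freqs, times, sxx = signal.spectrogram(
        series,
        fs=fs,
        nperseg=nperseg,
        noverlap=int(nperseg * overlap),
        detrend=False,
        scaling="spectrum",
    )
    return freqs, times, sxx
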