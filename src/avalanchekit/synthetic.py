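"""Synthetic spike-raster generator for a layered M1-like cortical column.

The generator emulates the statistical structure of self-sustained activity
in a 10,073-neuron motor-cortex column: an irregular IT5B/IT6 background,
~1 Hz delta envelopes with the layered onset motif (deep lead, concurrent
IT2/3+PT5B peak, IT5A rise at onset, IT4 rise after the peak, ongoing PT5B
tail), ~22 Hz beta trains preceding delta onsets in "beta-rich" blocks,
~54 Hz gamma bursts nested inside delta envelopes, millisecond quiescent
gaps between events, and lognormal per-neuron rate heterogeneity.

Spikes are emitted by an inhomogeneous Poisson process whose population
intensity is a sum of half-cosine (Hann) bump templates on a 1-ms grid;
per-neuron rates are scaled by lognormal multipliers.  Everything is
deterministic under (config, seed).

The module also provides an exact sampler for the zeta-normalised discrete
power law, used to exercise the MLE fitter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import special

from .raster_io import SpikeRaster

__all__ = [
    "SessionConfig",
    "Schedule",
    "DEFAULT_POPULATION_COUNTS",
    "POPULATION_INFO",
    "build_population_table",
    "schedule_session",
    "render_schedule",
    "generate_session",
    "sample_discrete_powerlaw",
]

# Default per-population neuron counts for the full column (sums to 10,073).
# Derived from an ~80:20 E:I balance, a 2:1 PV:SOM ratio per layer, 1:1
# IT:PT in layer 5B and 1:1 IT:CT in layer 6, with layer shares at
# literature scale for mouse agranular cortex.
DEFAULT_POPULATION_COUNTS: dict[str, int] = {
    "IT2/3": 2014,
    "PV2/3": 336,
    "SOM2/3": 168,
    "IT4": 645,
    "IT5A": 967,
    "PV5A": 269,
    "SOM5A": 134,
    "IT5B": 1209,
    "PT5B": 1209,
    "PV5B": 403,
    "SOM5B": 201,
    "IT6": 1007,
    "CT6": 1007,
    "PV6": 336,
    "SOM6": 168,
}

# population -> (layer, (ncd_low, ncd_high), ei). Excitatory bands follow the
# excitatory NCD scheme; interneuron bands the (slightly different)
# interneuron scheme; PV5A/SOM5A span layers 4 + 5A.
POPULATION_INFO: dict[str, tuple[str, tuple[float, float], str]] = {
    "IT2/3": ("L2/3", (0.10, 0.29), "excitatory"),
    "PV2/3": ("L2/3", (0.12, 0.31), "inhibitory"),
    "SOM2/3": ("L2/3", (0.12, 0.31), "inhibitory"),
    "IT4": ("L4", (0.29, 0.37), "excitatory"),
    "IT5A": ("L5A", (0.37, 0.47), "excitatory"),
    "PV5A": ("L4/5A", (0.31, 0.47), "inhibitory"),
    "SOM5A": ("L4/5A", (0.31, 0.47), "inhibitory"),
    "IT5B": ("L5B", (0.47, 0.80), "excitatory"),
    "PT5B": ("L5B", (0.47, 0.80), "excitatory"),
    "PV5B": ("L5B", (0.47, 0.77), "inhibitory"),
    "SOM5B": ("L5B", (0.47, 0.77), "inhibitory"),
    "IT6": ("L6", (0.80, 1.00), "excitatory"),
    "CT6": ("L6", (0.80, 1.00), "excitatory"),
    "PV6": ("L6", (0.77, 1.00), "inhibitory"),
    "SOM6": ("L6", (0.77, 1.00), "inhibitory"),
}

BACKGROUND_POPULATIONS = ("IT5B", "IT6")


@dataclass
class SessionConfig:
    """Parameters of one synthetic session.

    Rates are in Hz or events/s, times in ms.  The defaults reproduce the
    study conditions the analysis assumes: 1 delta envelope/s, 45.5 ms beta
    period (~22 Hz), 18.5 ms gamma period (~54 Hz), 1-40 ms quiescent gaps,
    and lognormal per-neuron rate multipliers (mean 1).
    """

    duration_ms: float = 60_000.0
    seed: int = 0
    population_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_POPULATION_COUNTS)
    )
    include_patterns: tuple[str, ...] = ("delta", "beta", "gamma")

    # delta schedule: jittered-periodic envelopes at delta_rate
    delta_rate: float = 1.0  # envelopes per second
    delta_jitter_ms: float = 40.0
    delta_duration_range_ms: tuple[float, float] = (400.0, 1000.0)

    # onset motif timing
    deep_lead_ms: float = 40.0  # sparse deep-layer lead before the peak
    it5a_lead_ms: float = 30.0
    it4_lag_ms: float = 60.0
    pt5b_tail_ms: float = 120.0

    # rhythm periods
    beta_period_ms: float = 45.5  # ~22 Hz
    gamma_period_ms: float = 18.5  # ~54 Hz
    gamma_jitter_ms: float = 0.8

    # beta-rich / beta-sparse alternation
    beta_block_s: float = 10.0
    beta_rich_k: int = 8  # beta periods preceding each delta in rich blocks

    # irregular background (IT5B / IT6 only)
    background_rate_hz: float = 2.0

    # lognormal per-neuron rate multipliers, mean fixed at 1
    lognormal_sigma: float = 1.0

    # quiescent-gap model: geometric lengths between event-free segments
    gap_mean_ms: float = 2.5
    gap_max_ms: float = 40.0
    segment_mean_ms: float = 35.0

    # template amplitudes: expected population spikes per 1-ms bin at peak
    delta_it23_amp: float = 420.0
    delta_it23_width_ms: float = 60.0
    delta_pt5b_amp: float = 300.0
    delta_it5a_amp: float = 90.0
    delta_it4_amp: float = 90.0
    delta_deep_lead_amp: float = 5.0
    delta_it6_amp: float = 8.0
    delta_pt5b_tail_amp: float = 8.0
    delta_inh_amp: float = 25.0
    beta_it5b_amp: float = 45.0
    beta_width_ms: float = 20.0
    beta_pt5b_amp: float = 15.0
    beta_it5a_amp: float = 12.0
    beta_pv23_amp: float = 15.0
    beta_it6_amp: float = 10.0
    gamma_pt5b_amp: float = 45.0
    gamma_width_ms: float = 8.0
    gamma_it5a_amp: float = 30.0
    gamma_pv5b_amp: float = 12.0
    gamma_it23_amp: float = 8.0  # anti-phase IT2/3 bumps

    def validate(self) -> None:
        if self.duration_ms <= 0:
            raise ValueError("duration must be positive")
        if self.delta_rate <= 0 or self.background_rate_hz < 0:
            raise ValueError("rates must be positive")
        if min(self.beta_period_ms, self.gamma_period_ms) <= 0:
            raise ValueError("periods must be positive")
        if any(c < 0 for c in self.population_counts.values()):
            bad = [k for k, v in self.population_counts.items() if v < 0]
            raise ValueError(f"negative population counts: {bad}")
        delta_interval = 1000.0 / self.delta_rate
        if not (
            self.gamma_period_ms < self.beta_period_ms < delta_interval
        ):
            raise ValueError(
                "require gamma period < beta period < delta inter-event "
                "interval"
            )

    def scaled(self, factor: float) -> "SessionConfig":
        """A copy with every population count scaled (for small test columns)."""
        counts = {
            k: int(round(v * factor)) for k, v in self.population_counts.items()
        }
        return replace(self, population_counts=counts)


@dataclass
class Schedule:
    """Pattern-event timetable for one session (times in ms)."""

    duration_ms: float
    deltas: list[tuple[float, float]]  # (onset, duration)
    betas: list[float]  # beta period centre times
    gammas: list[float]  # gamma burst centre times
    gaps: list[tuple[float, float]]  # quiescent intervals (start, stop)

    def n_events(self) -> int:
        return len(self.deltas) + len(self.betas) + len(self.gammas)


def build_population_table(
    config: SessionConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Neuron table: one row per neuron with population, layer, NCD, E/I flag
    and a lognormal rate multiplier (mean 1).

    NCDs are uniform within each population's configured band.  Population
    order and within-population id order are deterministic; the table is
    reproducible given ``config.seed``.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 0x7AB1E])
        )
    sigma = config.lognormal_sigma
    mu = -0.5 * sigma * sigma  # mean-1 multipliers
    rows = []
    next_id = 0
    for label in sorted(config.population_counts):
        n = config.population_counts[label]
        try:
            layer, (lo, hi), ei = POPULATION_INFO[label]
        except KeyError:
            raise ValueError(f"unknown population label {label!r}") from None
        ncd = rng.uniform(lo, hi, size=n)
        mult = rng.lognormal(mean=mu, sigma=sigma, size=n)
        for k in range(n):
            rows.append(
                (next_id + k, label, layer, ncd[k], ei, mult[k])
            )
        next_id += n
    df = pd.DataFrame(
        rows,
        columns=["id", "population", "layer", "ncd", "ei", "rate_multiplier"],
    )
    return df.set_index("id")


def _rich_block(config: SessionConfig, t_ms: float) -> bool:
    """Beta-rich blocks alternate with beta-sparse blocks; block 0 is rich."""
    return int(t_ms // (config.beta_block_s * 1000.0)) % 2 == 0


def schedule_session(config: SessionConfig, seed: int) -> Schedule:
    """Timetable of delta envelopes, beta trains, gamma bursts and gaps.

    Delta envelopes recur rhythmically at ``delta_rate`` (jittered-periodic
    onsets); in beta-rich blocks each envelope is preceded by
    ``beta_rich_k`` beta periods, in sparse blocks by none.  Gamma bursts
    are nested inside each envelope after the initial cross-layer peak.
    Quiescent gaps (geometric lengths, mean ``gap_mean_ms``, truncated at
    ``gap_max_ms``) are drawn between scheduled events; gaps that would cut
    into an envelope or beta train are discarded.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5C4ED]))
    period = 1000.0 / config.delta_rate
    dur_lo, dur_hi = config.delta_duration_range_ms
    duration = config.duration_ms

    deltas: list[tuple[float, float]] = []
    betas: list[float] = []
    gammas: list[float] = []
    protected: list[tuple[float, float]] = []

    do_delta = "delta" in config.include_patterns
    n_slots = int(np.floor(duration / period)) if do_delta else 0
    beta_extent = (
        config.beta_rich_k * config.beta_period_ms + 90.0
        if "beta" in config.include_patterns
        else 60.0
    )
    for i in range(n_slots):
        base = (i + 0.35) * period
        onset = base + rng.normal(0.0, config.delta_jitter_ms)
        dur = rng.uniform(dur_lo, dur_hi)
        # keep the envelope clear of the next delta's beta train
        cap = (i + 1 + 0.35) * period - beta_extent - onset
        dur = min(dur, cap, duration - 10.0 - onset)
        if dur < 100.0 or onset < 50.0:
            continue
        deltas.append((onset, dur))
        protected.append((onset - 5.0, onset + dur + 5.0))

        if "beta" in config.include_patterns and _rich_block(config, onset):
            for j in range(config.beta_rich_k):
                centre = onset - 30.0 - (j + 1) * config.beta_period_ms
                if centre > 20.0:
                    betas.append(centre)
                    protected.append((centre - 15.0, centre + 15.0))

        if "gamma" in config.include_patterns:
            peak = onset + 0.18 * dur
            t = peak + 80.0
            stop = onset + dur - 40.0
            while t < stop:
                gammas.append(
                    t + rng.normal(0.0, config.gamma_jitter_ms)
                )
                t += config.gamma_period_ms

    # quiescent-gap renewal process over the whole timeline
    gaps: list[tuple[float, float]] = []
    p_geom = min(1.0, 1.0 / config.gap_mean_ms)
    prot = sorted(protected)
    t = 0.0
    while t < duration:
        t += rng.exponential(config.segment_mean_ms)
        glen = float(min(rng.geometric(p_geom), config.gap_max_ms))
        g0, g1 = t, min(t + glen, duration)
        if g1 > g0 and not any(
            g0 < hi and g1 > lo for lo, hi in prot
        ):
            gaps.append((g0, g1))
        t += glen
    betas.sort()
    gammas.sort()
    return Schedule(
        duration_ms=duration,
        deltas=deltas,
        betas=betas,
        gammas=gammas,
        gaps=gaps,
    )


def _add_bump(
    lam: np.ndarray, centre: float, width: float, amp: float
) -> None:
    """Add a Hann (half-cosine) bump of peak ``amp`` to a 1-ms intensity."""
    lo = max(0, int(np.floor(centre - width / 2)))
    hi = min(lam.size, int(np.ceil(centre + width / 2)) + 1)
    if hi <= lo:
        return
    t = np.arange(lo, hi) + 0.5
    x = (t - centre) / width
    mask = np.abs(x) <= 0.5
    lam[lo:hi][mask] += amp * 0.5 * (1.0 + np.cos(2.0 * np.pi * x[mask]))


def _add_plateau(
    lam: np.ndarray, start: float, stop: float, amp: float
) -> None:
    lo = max(0, int(np.floor(start)))
    hi = min(lam.size, int(np.ceil(stop)))
    if hi > lo:
        lam[lo:hi] += amp


def _intensity_grid(
    schedule: Schedule, config: SessionConfig, counts: dict[str, int]
) -> dict[str, np.ndarray]:
    """Population intensity templates (expected spikes per 1-ms bin)."""
    n_bins = int(np.ceil(schedule.duration_ms))
    lam = {p: np.zeros(n_bins) for p in counts if counts[p] > 0}

    def get(label: str) -> np.ndarray | None:
        return lam.get(label)

    # irregular background, IT5B/IT6 only
    for label in BACKGROUND_POPULATIONS:
        arr = get(label)
        if arr is not None:
            arr += config.background_rate_hz * counts[label] / 1000.0

    for onset, dur in schedule.deltas:
        peak = onset + 0.18 * dur
        end = onset + dur
        w = config.delta_it23_width_ms
        for label, amp in (
            ("IT2/3", config.delta_it23_amp),
            ("PT5B", config.delta_pt5b_amp),
            ("PV2/3", config.delta_inh_amp),
        ):
            arr = get(label)
            if arr is not None:
                _add_bump(arr, peak, w, amp)
        arr = get("IT5A")
        if arr is not None:  # rise during onset
            _add_bump(arr, onset + 0.08 * dur + config.it5a_lead_ms,
                      80.0, config.delta_it5a_amp)
        arr = get("IT4")
        if arr is not None:  # rise during the decline of the initial peak
            _add_bump(arr, peak + config.it4_lag_ms, 80.0,
                      config.delta_it4_amp)
        for label in BACKGROUND_POPULATIONS:  # sparse deep-layer lead
            arr = get(label)
            if arr is not None:
                _add_bump(arr, onset + 0.05 * dur, config.deep_lead_ms,
                          config.delta_deep_lead_amp)
        arr = get("IT6")
        if arr is not None:
            _add_plateau(arr, onset, end, config.delta_it6_amp)
        arr = get("PT5B")
        if arr is not None:  # ongoing PT5B tail marks the envelope end
            _add_plateau(arr, onset + 0.3 * dur, end,
                         config.delta_pt5b_tail_amp)
        for label in ("PV5B", "SOM2/3"):
            arr = get(label)
            if arr is not None:
                _add_plateau(arr, onset + 0.05 * dur, end, 4.0)

    for centre in schedule.betas:
        w = config.beta_width_ms
        for label, amp, off in (
            ("IT5B", config.beta_it5b_amp, 0.0),
            ("PT5B", config.beta_pt5b_amp, 5.0),
            ("IT5A", config.beta_it5a_amp, 6.0),
            ("PV2/3", config.beta_pv23_amp, 2.0),  # L2/3 inhibitory, not E
            ("IT6", config.beta_it6_amp, 0.0),
        ):
            arr = get(label)
            if arr is not None:
                _add_bump(arr, centre + off, w, amp)

    for centre in schedule.gammas:
        w = config.gamma_width_ms
        for label, amp, off in (
            ("PT5B", config.gamma_pt5b_amp, 0.0),
            ("IT5A", config.gamma_it5a_amp, 0.0),
            ("PV5B", config.gamma_pv5b_amp, 1.0),
            # IT2/3 participates in anti-phase (half a period later)
            ("IT2/3", config.gamma_it23_amp, config.gamma_period_ms / 2),
        ):
            arr = get(label)
            if arr is not None:
                _add_bump(arr, centre + off, w, amp)

    # quiescent gaps silence every population
    for g0, g1 in schedule.gaps:
        lo, hi = int(np.floor(g0)), int(np.ceil(g1))
        for arr in lam.values():
            arr[lo:hi] = 0.0
    return lam


def render_schedule(
    schedule: Schedule,
    neurons: pd.DataFrame,
    config: SessionConfig,
    seed: int,
) -> SpikeRaster:
    """Emit spikes from the schedule as an inhomogeneous Poisson process.

    Per 1-ms bin and population, a Poisson count is drawn at the template
    intensity; spikes are assigned to neurons with probability proportional
    to their lognormal rate multipliers and placed uniformly within the bin.
    """
    if neurons.empty:
        raise ValueError("neuron table is empty")
    last_event = max(
        [o + d for o, d in schedule.deltas] + schedule.betas + schedule.gammas,
        default=0.0,
    )
    if last_event > schedule.duration_ms:
        raise ValueError("schedule exceeds the session duration")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xF00D]))
    counts = neurons.groupby("population").size().to_dict()
    lam = _intensity_grid(schedule, config, counts)

    all_times = []
    all_ids = []
    mult = neurons["rate_multiplier"] if "rate_multiplier" in neurons else None
    for label in sorted(lam):
        k = rng.poisson(lam[label])
        n_spikes = int(k.sum())
        if n_spikes == 0:
            continue
        times = np.repeat(np.arange(k.size, dtype=float), k)
        times += rng.random(n_spikes)
        ids = neurons.index[neurons["population"] == label].to_numpy()
        if mult is not None:
            w = mult.loc[ids].to_numpy(dtype=float)
            w = w / w.sum()
        else:
            w = None
        chosen = rng.choice(ids, size=n_spikes, p=w)
        all_times.append(times)
        all_ids.append(chosen)
    if all_times:
        times = np.concatenate(all_times)
        ids = np.concatenate(all_ids)
        order = np.argsort(times, kind="stable")
        times = times[order]
        ids = ids[order]
        times = np.minimum(times, np.nextafter(schedule.duration_ms, 0.0))
    else:
        times = np.empty(0)
        ids = np.empty(0, dtype=np.int64)
    return SpikeRaster(
        times=times,
        neuron_ids=ids,
        neurons=neurons,
        t_start=0.0,
        t_stop=float(schedule.duration_ms),
    )


def generate_session(
    config: SessionConfig, seed: int | None = None
) -> tuple[SpikeRaster, Schedule]:
    """Convenience wrapper: table + schedule + rendering from one seed."""
    if seed is None:
        seed = config.seed
    ss = np.random.SeedSequence(seed).spawn(3)
    neurons = build_population_table(
        config, rng=np.random.default_rng(ss[0])
    )
    schedule = schedule_session(config, seed=int(ss[1].generate_state(1)[0] % 2**31))
    raster = render_schedule(
        schedule, neurons, config, seed=int(ss[2].generate_state(1)[0] % 2**31)
    )
    return raster, schedule


def sample_discrete_powerlaw(
    alpha: float, xmin: int, n: int, seed: int
) -> np.ndarray:
    """Exact i.i.d. samples from P(X = x) = x^-alpha / zeta(alpha, xmin).

    Inverse-CDF sampling: the CDF is tabulated exactly up to a large cutoff;
    the rare draws beyond it are resolved by bisection on the zeta survival
    function.  Deterministic under ``seed``.
    """
    if alpha <= 1.0:
        raise ValueError("alpha must exceed 1 (otherwise non-normalisable)")
    if xmin < 1:
        raise ValueError("xmin must be a positive integer")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    u = rng.random(n)

    cutoff = 100_000
    xs = np.arange(xmin, xmin + cutoff, dtype=float)
    z = special.zeta(alpha, xmin)
    pmf = xs ** (-alpha) / z
    cdf = np.cumsum(pmf)
    out = np.empty(n, dtype=np.int64)
    head = u <= cdf[-1]
    out[head] = xmin + np.searchsorted(cdf, u[head], side="left")

    def cdf_at(x: float) -> float:
        return 1.0 - special.zeta(alpha, x + 1.0) / z

    for i in np.flatnonzero(~head):
        lo = xmin + cutoff - 1
        hi = lo * 2
        while cdf_at(hi) < u[i]:
            lo, hi = hi, hi * 2
        while hi - lo > 1:
            mid = (lo + hi) // 2
            if cdf_at(mid) >= u[i]:
                hi = mid
            else:
                lo = mid
        out[i] = hi
    return out
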