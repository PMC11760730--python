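# Methods

This note documents the models, conventions and numerical choices behind
`avalanchekit`, and what the synthetic-data generator does and does not
emulate.

## Avalanche definition and binning

All spikes are placed into half-open bins `[t, t + w)` of width `w = 1 ms`
(configurable), with the bin origin at the recording start.  An avalanche
is a maximal run of contiguous non-empty bins; size is the total spike
count of the run, duration is `(run length) × w`, and the inter-avalanche
interval between consecutive avalanches is the empty-bin gap between them
(always ≥ 1 bin by construction).  The definition requires an empty bin on
*both* sides, which is undecidable at the record edges: runs touching the
first or last bin are kept but flagged `censored`, and power-law fits
exclude censored runs by default.  Detection is a run-length scan and is
verified in tests against a brute-force per-bin enumeration on 1,000 random
count vectors; the partition property (avalanches are disjoint, separated
by ≥ 1 empty bin, and jointly contain every spike) and idempotence under
splitting the record at an empty bin are asserted as property tests.

## Pattern selection

Delta, beta and gamma events are selected from the per-population 1-ms
histograms by peak thresholding in the style of time-domain feature
(SPUD-type) analysis:

* **delta** — IT2/3 local maxima ≥ 250 spikes/bin.  Peaks with consecutive
  spacing ≤ 50 ms form a cluster and only the first is kept (a `drop-all`
  alternative is selectable; the keep-first reading is the default because
  a rhythmic envelope produces one dominant burst that should count once).
  The event span extends from the seed peak outwards to the nearest bins
  where IT2/3 falls below 10% of the threshold.  Peak thresholds define
  peaks only, not extents, so the floor fraction is a package choice;
  10% keeps spans tight around the IT2/3-driven portion of an envelope.
* **beta** — IT5B local maxima ≥ 15 spikes/bin, excluding peaks with
  robust concurrent IT2/3 activity (≥ 250) or inside a selected delta
  span.  Kept peaks within 100 ms of each other are grouped into one train
  event.
* **gamma** — PT5B local maxima ≥ 20 spikes/bin, with delta activity
  removed in one of two modes: excluding whole delta-event spans
  (default), or excluding only bins of robust concurrent IT2/3 activity
  (`robust-concurrent`).  The published description of this exclusion is
  ambiguous about which population the robust filter keys on; both
  readings are implemented.  Under the default mode, gamma trains nested
  inside a delta envelope but outside its IT2/3-driven span are still
  selected; gamma never defines its own avalanche class and is annotated
  on Delta+ avalanches.

A local maximum is strict over a 3-bin neighbourhood, with plateaus
resolved to their leftmost bin; optional 3-ms boxcar smoothing is off by
default.  Because Poisson counting noise produces several spurious local
maxima within a single oscillation bump, the beta and gamma selectors
additionally thin peaks to a minimum separation of about half the
respective period (25 ms and 9 ms), keeping the highest peak of each
conflict — the same `distance` idiom as `scipy.signal.find_peaks`.
Without this, inter-peak intervals measure counting noise instead of the
rhythm.  Event frequency is `1000 / median inter-peak interval (ms)`;
fewer than two peaks raise `UndefinedFrequencyError`.  Event-triggered
averages align windows at each event's first peak and drop (with a
warning) events whose window leaves the record, so averaging is always
within-record.

## Avalanche classification

Each avalanche receives exactly one of four labels with precedence
**Delta+ > Beta > Irregular > Fragment**:

* Delta+ — overlaps ≥ 1 delta event span;
* Beta — overlaps ≥ 1 beta event and ≥ 90% of its spikes lie within beta
  event spans (configurable; "composed entirely of beta patterns" is not
  decidable exactly at edge bins, so a high containment fraction is used);
* Irregular — every spike is IT5B or IT6 (and hence excitatory);
* Fragment — everything else.

The precedence order follows from the composition rules themselves: the
Delta+ class is defined to absorb any avalanche containing a delta
pattern, whatever else it contains.  Single-spike avalanches from
populations other than IT5B/IT6 are Fragments.  Classification is
insensitive to the ordering of the event list.

## Discrete power-law fitting

The model is `P(X = x) = x^(-alpha) / zeta(alpha, xmin)` on integers
`x ≥ xmin`, with the Hurwitz zeta normalisation evaluated by
`scipy.special.zeta`.  The exponent is the maximiser of the exact discrete
log-likelihood, found by bounded scalar minimisation on `alpha ∈ (1, 20]`
to `xatol = 1e-10`; the likelihood is unimodal in alpha (checked by grid
scan in tests).  The closed-form approximation
`alpha ≈ 1 + n / Σ ln(x_i / (xmin − 0.5))` serves as a small-n oracle in
tests.  The reported standard error is `sigma = (alpha − 1) / sqrt(n_tail)`
(the asymptotic form; a bootstrap is not implemented).  Goodness of fit is
the Kolmogorov–Smirnov distance between the empirical and fitted tail
CDFs, evaluated at every observed value and immediately before each (both
candidate suprema of a step/step comparison).  The default is a
full-range fit at `xmin = 1`; a KS scan over observed values
(`select_xmin`) is available by flag.  Exponents are stored positive and
reported with the conventional negative sign.  The sampler used to
exercise the fitter draws exact zeta-normalised variates by inverse CDF
(tabulated to 10^5, with bisection on the zeta survival function for the
rare tail draws), so fitter validation is a genuine round trip through two
independent code paths.

## The synthetic session generator

The generator emulates the raster-level statistics of self-sustained
activity in a 10,073-neuron layered motor-cortex column.  It is an
inhomogeneous Poisson process: per population and 1-ms bin, a count is
drawn at an intensity assembled from half-cosine (Hann) bump templates,
and spikes are assigned to neurons with probabilities proportional to
per-neuron lognormal rate multipliers (sigma = 1, mean fixed at 1).
Defaults define the study conditions:

* **delta** — envelopes recur rhythmically at 1/s (jittered-periodic
  onsets, Gaussian jitter sd 40 ms) with durations drawn uniform in
  [400, 1000] ms (capped so an envelope clears the next envelope's beta
  train).  The onset motif is layered: a sparse deep-layer (IT5B/IT6)
  lead, a concurrent IT2/3 (peak 420 spikes/ms, comfortably above the
  250-spike selector threshold) and PT5B peak, an IT5A rise during onset,
  an IT4 rise after the initial peak, moderate L2/3 and L5B inhibitory
  activity, and an ongoing PT5B tail to the envelope end.
* **beta** — in alternating 10-s "beta-rich" blocks, 8 beta periods
  (45.5 ms, ~22 Hz) of IT5B-dominant bumps precede each delta onset, with
  visible L2/3 inhibitory (PV2/3) but no L2/3 excitatory activity;
  beta-sparse blocks have none.  The number of periods per train is not
  quantitatively constrained by published rasters ("at least 10 bursts"
  in one example is the only hint); 8 is the package default.
* **gamma** — bursts every 18.5 ms (~54 Hz, small timing jitter) nested
  in each envelope after the initial cross-layer peak, driving PT5B and
  IT5A with IT2/3 in anti-phase.
* **irregular background** — 2 Hz per-neuron rate confined to IT5B/IT6.
* **quiescent gaps** — a renewal process (exponential segment lengths,
  mean 35 ms) inserts gaps with geometric lengths (mean 2.5 ms, truncated
  at 40 ms) that silence every population; gaps that would cut into a
  scheduled envelope or beta train are discarded, so gaps fall *between*
  events.  The biophysical origin of the ≤ ~40 ms gap ceiling (sustained
  NMDA-mediated dendritic depolarisation) is not modelled — only its
  raster-level consequence.

The default population counts sum to 10,073 across 15 populations with an
~80:20 E:I balance, PV:SOM = 2:1 per layer, IT:PT = 1:1 in L5B and
IT:CT = 1:1 in L6; NCDs are uniform within per-population bands
(excitatory and interneuron band schemes kept separately).  Everything is
deterministic under `(config, seed)`, to the point of byte-identical
output files.

What the generator does **not** emulate: membrane potentials and synaptic
dynamics, realistic pairwise correlations within populations (spikes are
conditionally independent given the population intensity), the empirical
avalanche type proportions of a biophysical simulation (the synthetic
Beta share by count is far higher than in detailed-model reports), or
power-law avalanche statistics — the synthetic background is not
critical, so fitter validation uses the exact power-law sampler, not
synthetic sessions.  Passing selector-recovery tests therefore shows the
selectors recover what the generator scheduled under realistic Poisson
noise, not that they would perform identically on biophysical data.

## Column network construction

Geometry is a cylinder (default 300 μm diameter, 1350 μm depth;
`π r² h = 95,425,876.85 μm³`).  Cell placement draws per-layer counts as
`round(density × layer volume)` at literature-scale densities
(~1e5 cells/mm³, tuned so the default column totals 10,073 cells) and
apportions them to populations by the largest-remainder method, which
realises the stated ratios exactly where they divide evenly and within one
cell otherwise.  Wiring uses `scon = pcon × vcon`: unitary EPSP amplitudes
are thresholded to [0.3, 1.0] mV, `pcon = clip(scon / vcon, 0, 1)`, and
probability decays exponentially with 3-D inter-somatic distance (length
constant 100 μm).  The published quantitative scon/vcon source grids are
not public, so the defaults are editable placeholders (excitatory
scon 0.05 mV, inhibitory 0.1 mV, vcon 0.5 mV) with the schema documented
in `netbuild.default_rules`.

The border correction multiplies each target cell's connection
probabilities by the ratio of the unbounded planar mass of the lateral
kernel (`2πλ²`) to its mass inside the cylinder cross-section, computed by
polar numerical integration (closed-form in the radial direction, 256
angular nodes, 33-point radial profile interpolated per cell).  No formula
is published for this correction; renormalising the kernel mass is the
package's choice and exactly compensates the expected in-degree deficit of
edge cells.  Class adjustments (CT inputs ×0.62, L2/3→L4 set to ¼ of the
reverse strength, ±50% PV/SOM probability biases, same-layer restriction
of inhibition with L4/5A/5B merged) are applied exactly once behind an
idempotence guard.  Delays are `2 ms + distance / 0.5 m/s`; excitatory
weights split 50/50 AMPA/NMDA, SOM→E 90/10 slow-GABAA/GABAB, PV 100%
fast GABAA, divided over 5 synapses for morphologically detailed targets
(IT5A, PT5B) and 1 otherwise, conserving vcon to 1e-12.  The NMDA
magnesium block is `1 / (1 + 0.28 · Mg · e^(−0.062 V))`.  Compartmental
EPSP normalisation (somatic 0.5 mV target with a 4.0 scale cap) requires
compartment-level simulation and is out of scope; placement classes
(perisomatic / apical / uniform) are carried as edge annotations.  The
GABAB second-messenger (GIRK) cascade is likewise out of scope; the GABAB
entry in the synapse table is a slow double-exponential stand-in at the
GABAB reversal.

## Problem sizes and runtime choices

Tests run full-scale where the analysis is cheap (60-s, 10,073-neuron
sessions with ~3.3M spikes render in ~2 s) and reduced scale where it is
not: selector-recovery tests use 5 seeded full sessions, the lognormal
rate test one 120-s single-population session, network sampling tests toy
columns of tens to hundreds of cells (the Bernoulli edge sampler is
O(n_pre × n_post) per rule).  The fitter's acceptance-scale sample size is
15,578 — the avalanche count of the reference 10-minute column simulation
— at which the MLE recovers exponents to well under ±0.01 typically.

## Known limitations

* Bin-edge handling, event spans and the Beta containment fraction are
  conventions; results at parameter boundaries (e.g. a peak exactly at
  threshold) follow the documented ≥/≤ rules rather than any published
  tie-break.
* `select_xmin` minimises the KS distance over candidate cutoffs without
  a significance test; it is a diagnostic, not a hypothesis test.
* The network builder materialises dense pairwise probability matrices
  per population pair, which is fine for toy and single-column scales but
  not for millions of cells.
* Percentages in summary tables are rounded to one decimal and may sum to
  100 ± 0.1.
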