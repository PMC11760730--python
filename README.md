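# avalanchekit

Neuronal-avalanche analysis for spike rasters of simulated cortical
columns.

Cortical activity, recorded in vitro and in vivo and reproduced by detailed
network simulations, organises into *avalanches*: with all spikes placed
into 1-ms bins, an avalanche is a maximal run of contiguous non-empty bins
bounded by at least one empty bin on each side.  Its size `S` is the total
spike count of the run and its duration `T` the run length.  Near a
critical operating regime the distributions of `S` and `T` are long-tailed
and well described by discrete power laws
`P(x) = x^(-alpha) / zeta(alpha, xmin)`, with size exponents around −1.5.
In layered motor-cortex columns, avalanches are additionally composed of a
small set of cross-population activity patterns — an irregular deep-layer
(IT5B/IT6) background and three rhythmic motifs at delta (~1 Hz), beta
(~22 Hz) and gamma (~54 Hz) frequencies — which partition avalanches into
four types: **Irregular**, **Fragment**, **Beta** and **Delta+**.

`avalanchekit` implements this analysis as a tested, reusable pipeline for
anyone working with spike rasters from large network simulations (or any
point-process population recording with population labels):

* `raster_io` — spike-raster data model, delimited-text + JSON-sidecar I/O,
  1-ms binning, instantaneous-rate summaries;
* `synthetic` — a generator of rasters with the statistical structure the
  analysis assumes (the four patterns, millisecond quiescent gaps,
  lognormal rate heterogeneity) and an exact discrete power-law sampler;
* `avalanche` — avalanche detection, neuron membership, inter-avalanche
  intervals;
* `patterns` — threshold-based (SPUD-style) selection of delta/beta/gamma
  events from population histograms, event frequencies, event-triggered
  averages, spectrograms;
* `classify` — the four-type classification and the per-type summary table;
* `powerlaw_fit` — discrete maximum-likelihood exponent estimation with
  Kolmogorov–Smirnov goodness of fit and an optional xmin scan;
* `netbuild` — construction of a normalized-cortical-depth (NCD) based
  column network description (cell placement, `scon = pcon × vcon` wiring
  rules, exponential lateral decay with border correction, delays, receptor
  splits) exported as portable JSON.

## Worked example

Generate a default 60-s synthetic session of the full 10,073-neuron column,
select patterns, detect and classify avalanches:

```python
import numpy as np
from avalanchekit import (SessionConfig, generate_session, bin_spikes,
                          detect_avalanches, attach_spikes, classify_all,
                          summary_table, select_patterns)

raster, schedule = generate_session(SessionConfig(), seed=1)
binned = bin_spikes(raster, bin_width=1.0)
events = select_patterns(binned)
avalanches = attach_spikes(raster, detect_avalanches(binned))
classify_all(avalanches, events, raster=raster)
print(summary_table(avalanches)[["number", "percent_of_number",
                                 "percent_of_duration"]])
```

prints

```
           number  percent_of_number  percent_of_duration
type
Irregular     555               73.0                 21.1
Fragment       11                1.4                  1.3
Beta          134               17.6                 15.8
Delta+         60                7.9                 61.8
```

The session contains 3,335,329 spikes (mean rate 5.5 Hz per neuron) and
760 avalanches separated by quiescent gaps of 1–21 ms.  The selector finds
60 delta events in 60 s (1.0 Hz), with median beta and gamma event
frequencies of 22.0 Hz and 54.1 Hz — the configured rhythms.  Every delta
envelope becomes a Delta+ avalanche, and Delta+ avalanches dominate the
avalanche-active time while being a minority by count, the hallmark of
this composition analysis.

Fitting the power-law machinery on exact power-law data:

```python
from avalanchekit import sample_discrete_powerlaw, fit_sizes
fit = fit_sizes(sample_discrete_powerlaw(1.52, xmin=1, n=15578, seed=1), xmin=1)
print(f"alpha = {fit.alpha_signed:.3f}, sigma = {fit.sigma:.4f}, D = {fit.D:.4f}")
# alpha = -1.522, sigma = 0.0042, D = 0.0034
```

A command-line interface mirrors the pipeline (`avalanchekit synth
generate`, `raster validate`, `raster bin`, `patterns select`, `aval
detect|classify|report|fit`, `netbuild`); see `avalanchekit --help`.

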