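# Methods

This note documents the analysis definitions, the synthetic-data model,
the defaults and the numerical choices made where the design was open.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Analysis pipeline

### Conventions

All times are seconds (float64); a recording starts at t = 0 unless a file
declares otherwise. Bins and analysis windows are half-open `[a, b)`.
Analyses operate at the electrode level (multi-unit); there is no spike
sorting.

### Spike detection

Spikes are negative threshold crossings at `-k_sd * sigma` with
`k_sd = 6`. The noise SD `sigma` is estimated per channel and per
recording with the scaled median absolute deviation,
`median(|x - median(x)|) / 0.6745`, which is consistent with the SD of
Gaussian noise and nearly insensitive to the spikes themselves; the plain
sample SD (`global_sd`) is available for comparison but is inflated by
spike amplitude. The spike timestamp is the first sample strictly below
threshold — simple and deterministic, at the cost of sitting a fraction of
a waveform rise-time (~0.1 ms at 25 kHz for the synthetic template) before
the trough. A dead time of 1 ms after each detection prevents one waveform
from being counted more than once. Stimulation artifacts are removed by
blanking `[t_stim, t_stim + 2 ms)` rather than by waveform sorting:
artifacts are strictly stimulus-locked, so blanking is deterministic and
testable. A zero-phase 4th-order Butterworth band-pass (150–4000 Hz)
helper is provided for wide-band traces; MEA amplifiers typically apply
this band in hardware.

### Rate correlation (intra-/inter-CC)

Electrodes pass the activity filter when their mean rate is strictly
greater than 0.05 Hz. Rates are binned at 100 ms and smoothed with a
5-bin discrete Gaussian kernel. The kernel sigma is not fixed by the
"five bins" description alone; we use sigma = 1.25 bins so the 5-bin
support covers ±2 sigma, and expose it as a parameter. At the histogram
edges the kernel is renormalized over in-range bins (no zero padding), so
the total spike count is conserved exactly (verified to 1e-9 relative
error). Pearson coefficients are computed between smoothed rate vectors
(smoothing immediately precedes correlation in the pipeline; an
unsmoothed switch exists). Zero-variance channels yield undefined (NaN)
coefficients and are excluded from summary means rather than set to zero,
which would bias inter-CC toward zero. Summaries average unordered
off-diagonal pairs: within-module (intra-CC, per module and pooled),
between-module (inter-CC, per module pair and pooled); pairs involving
control electrodes are reported separately (control-vs-network and
within-control means). Correlations default to the full session; a
sub-window can be selected by slicing the session.

### Bursts, SBEs, SEs

A burst is a maximal run of spikes on one electrode with every
consecutive gap ≤ 200 ms ("within" is inclusive: a gap of exactly 200 ms
stays in the burst). Runs need at least `min_spikes = 3` spikes — the
threshold window alone does not set a floor, and three spikes is the
conventional minimum that keeps isolated spike pairs from seeding events;
it is configurable. The burst window is `[first spike, last spike]`.

SBE detection treats burst windows as closed intervals (touching
endpoints overlap) and merges overlaps transitively: connected components
of the interval-overlap graph whose bursts span ≥ 2 electrodes become
SBEs, with the window equal to the union span. Transitive merging is what
makes a cascade ("chain") of pairwise-overlapping bursts a single event.
An SBE whose participants span ≥ 2 non-control modules is an SE. The
optional single-spike rule (off by default; intended for
two-electrode-per-network layouts) additionally promotes a single-module
SBE when an electrode of another module fires at least one spike inside
the SBE window, adding that electrode to the participants.

Association degree is each electrode's fraction of spikes inside the
union of (merged) SE windows; window membership is closed so the spikes
that define a window's endpoints count. Propagation direction orders the
SE's modules by their first spike time inside the window (minimum over
member electrodes). If the two earliest modules differ by less than
`tie_tolerance = 1 ms` the event is labeled ambiguous and excluded from
direction tallies; 1 ms is far below the tens-of-milliseconds
inter-module delays the analysis is meant to resolve.

### Suppression and influence

A modulation epoch carries a target module, a power density (opaque
metadata — no photothermal dose model), and stimulation window; the
baseline window defaults to a window of the same duration immediately
before the stimulation, the recovery window to the same after. Module
rate pools member electrodes' spikes per window (robust when electrodes
have heterogeneous rates; a per-electrode variant exists). Percent change
is `100 * (rate_during - rate_baseline) / rate_baseline`, undefined
(flagged) for zero baselines. Curves report per-power mean ± SD over
trials for every observed module including the control group; recovery
changes are computed for reversibility checks but are not part of the
influence statistic.

Influence `I[A→B]` is the magnitude of B's mean percent change at A's
highest power level, defined only if A itself reaches at least 90 %
suppression there ("full suppression" criterion, configurable). Trials
are paired by index across observed modules.

Because percent change is a ratio of two finite counts, the estimator
carries a small positive bias of order `CV^2` of the baseline count
(E[D/B] > E[D]/E[B]); with ~30 burst cascades per 60 s window this is a
few percent and visible in the control group's near-zero curve.

### Mann–Whitney test

Group comparisons (network vs. control changes at the highest power) use
a two-sided Mann–Whitney U test computed by exhaustive enumeration for
small samples: ties receive mid-ranks, all `C(n1+n2, n1)` group
assignments of the pooled mid-ranked sample are enumerated, and
`p = P(|U - n1*n2/2| >= |u_obs - n1*n2/2|)`. Under complete separation
with n = 5 per group this gives exactly 2/252 ≈ 0.0079 — the smallest
attainable two-sided value at that sample size. Samples larger than 10
per group fall back to the tie-corrected normal approximation.

### Evoked responses

PSTHs re-reference spikes to the nearest preceding stimulus and count
them over `(blank, window)` with `window = 50 ms`; bins inside the 2 ms
artifact blank are reported as masked, not as zeros. Response probability
is the fraction of trials with ≥ 1 spike in a response window (default
the late 15–35 ms window). The early/late split sums PSTH mass below
10 ms (direct/antidromic activation within the stimulated network) and
in 15–35 ms (inter-network synaptic propagation); bin edges must align
with the window boundaries. Stimulated electrodes are excluded from
recording-side summaries.

## Synthetic generator

The generator produces the statistical structure the analyses assume, at
the event level rather than via biophysics: the analyses only ever see
spike times, and event-level generation gives exact ground truth
(per-burst provenance, per-spike category, realized driven fractions).

* **Modules.** Each module emits population bursts as a Poisson process.
  Within a burst, each electrode participates with probability 0.9 and
  fires `1 + Poisson(9)` spikes uniformly over the 200 ms burst window.
  Keeping the burst duration at (or below) the 200 ms inter-spike
  threshold guarantees a generated burst can never split under burst
  detection. Background activity is an independent 0.1 Hz Poisson train
  per electrode.
* **Coupling.** A directed coupling lets each source burst trigger a
  target burst with probability `p` after a positive Gaussian delay
  (default 30 ± 5 ms — the narrow tens-of-milliseconds inter-module
  delays evoked-response mapping resolves; a truncated Gaussian, not an
  exponential, matches that narrow band). Triggered bursts can trigger
  further bursts, so cyclic couplings produce geometrically decaying
  echo cascades (cycle gain < 1; a depth cap of 60 guards degenerate
  configurations). `ModuleSpec.burst_rate` is the module's intended
  *total* rate; its intrinsic Poisson rate is
  `burst_rate * (1 - driven_fraction)`, and coupling probabilities for
  the standard fixtures are solved from the stationary balance
  `p(src→tgt) = driven_fraction(tgt) * rate(tgt) / rate(src)`.
* **Suppression.** An epoch maps its power density to a rate-scaling
  factor (defaults: 0.9, 0.65, 0.4, 0.15, 0.0 over 30–243 mW/mm²,
  reaching full suppression at the highest level). Every spike of the
  target module inside the epoch survives with that factor (per-spike
  thinning — a burst straddling the epoch onset is cut, not spared), and
  a burst whose onset falls in the epoch fails to trigger its couplings
  with the same probability, so suppressing a source module also removes
  the bursts it would have driven downstream.
* **Evoked responses.** Per stimulation trial the responding module
  fires with a configured probability; each of its electrodes then emits
  one spike at the stimulus time plus an independent positive Gaussian
  delay.
* **Traces.** Spike trains can be rendered into Gaussian-noise voltage
  traces (default 10 µV SD at 25 kHz) with a biphasic 1 ms template
  (0.4 ms negative half-sine of the full amplitude, then a 0.6 ms
  positive half-sine at 30 %) inserted trough-aligned at each spike
  time; overlapping templates add. The injected trough times are exported
  as detection ground truth.

All randomness derives from a single seed through one generator;
identical configurations reproduce byte-identical sessions.

### Standard study conditions

* `asymmetric_pair_config`: driver N2 (30 bursts/min total, 60 % of them
  echoes driven back from N1) and follower N1 (27/min, 100 % driven by
  N2), four electrodes each, plus an equally active but uncoupled
  control module. Rates in the tens of events per minute reflect
  strongly synchronized mature cultures, which show synchronized events
  at sub-second to few-second intervals; they also keep the 60 s
  baseline/stimulation windows of the suppression protocol well sampled
  (the per-trial percent-change noise scales with the inverse square
  root of the burst-cascade count per window).
* `coupled_pair_config(p)`: two intrinsically bursting modules
  (12/min each) with a one-way N2→N1 drive of probability `p`; `p = 0`
  is the uncoupled null, and `ablation_time` severs the coupling
  mid-session to emulate structural disconnection.
* `make_suppression_protocol`: five power-density levels × five trials,
  60 s baseline / stimulation / recovery windows with 10 s gaps —
  mirroring minute-scale pre/during/post raster segments.

### What the generator does not emulate

No biophysical membrane or synapse dynamics, no plasticity or
development (the days-long emergence of synchrony after a new physical
connection is biology, not an algorithm, and is out of scope), no
electrode drift, bursts with uniform rather than ramped intra-burst
structure, and stationary rates outside the scripted epochs. Passing
tests therefore demonstrate correctness of the analysis definitions and
recoverability of event-level structure — not robustness to every
pathology of real MEA data.

## Problem sizes in tests and the acceptance script

Spontaneous sessions are 600 s; suppression protocols are ~4900 s of
scheduled trials; detection runs on 60 s of 25 kHz traces; stochastic
checks aggregate 10 seeds. These sizes put Poisson sampling error well
inside the asserted tolerances while the full suite runs in well under a
minute of compute.

## Known limitations

* Percent-change ratios are biased by `~CV^2` of the baseline count (see
  above); with sparse baselines the influence statistic inherits a
  few-percent bias toward zero suppression.
* The exact Mann–Whitney enumeration is O(C(n1+n2, n1)) and is limited
  to ≤ 10 observations per group before the asymptotic fallback.
* Spike timestamps from threshold detection precede the waveform trough
  by a fraction of the rise time; analyses based on relative timing are
  unaffected, absolute latencies shift by ~0.1 ms.
* The SBE transitive merge can chain long quiet-period-free recordings
  into few large events if burst rates are far above the fixture range;
  the 200 ms threshold assumes clearly separated cascades.
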