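# Methods

This note documents the models, parameters and numerical choices behind
meakit, and what the synthetic-data tests do and do not establish.

## Signal model

A recording is a channels × samples matrix of extracellular voltage in
microvolts at a fixed sampling rate (20 kHz by default — high enough to
capture action potentials of 0.2–4 ms duration). Each electrode sees
Gaussian-like background noise plus transient biphasic deflections
(extracellular action potentials, eAPs): a sharp negative trough followed
by a smaller positive re-polarization peak. A single neuron's spike can
appear on several electrodes of a 100 µm-pitch array: simultaneously-ish
(within ~0.7 ms) along its axon, or 1–10 ms apart in synaptically coupled
partners.

## Filtering

Spikes are isolated with a 2nd-order Butterworth band-pass, 200–4000 Hz.
By default the filter is applied forward and backward (`sosfiltfilt`),
which doubles the effective order and — more importantly — has exactly
zero phase delay, so detected spike times are not systematically shifted;
a causal single pass is available by flag for streaming-like use. Edges
are reflect-padded by roughly the filter's settling length (three time
constants of its slowest pole) to suppress onset transients. Whether the
original workflow filtered causally or zero-phase is not something the
band edges determine; both modes are exposed and the default is the one
that keeps spike alignment unbiased.

## Noise estimation and detection

The detection threshold is 6 × a *robust* noise standard deviation,
σ̂ = median(|x|)/0.6745. For zero-mean Gaussian noise σ̂ equals the true
σ; unlike the sample s.d. it is barely moved by sparse large spikes,
which is the entire point — a spike-inflated threshold would suppress
detections on active channels. The factor 0.6745 is the 75th percentile
of the standard normal.

Detection scans for threshold crossings (default polarity negative;
"both" also fires on large re-polarization peaks, a detector failure mode
kept available deliberately for evaluation work). The event time is the
signal extremum within one dead time (default 1 ms) after the crossing —
extremum alignment is what makes later ensemble averaging sharp — and the
reported amplitude is the signal value at that sample. Consecutive
events are at least one dead time apart.

At 6σ on pure Gaussian noise, the per-sample tail probability is ~1e-9,
so a 20 s, 20 kHz channel is expected to produce essentially zero false
positives; this is asserted across seeds in the tests.

## Waveforms and sorting

3 ms waveforms (61 samples at 20 kHz) are cut symmetrically around each
event; windows crossing the record boundary are dropped and counted. The
split (1.5 ms pre / 1.5 ms post) is a convention; nothing downstream
depends on it.

Sorting projects waveforms onto 3 principal components and clusters with
OPTICS (xi steepness extraction, xi = 0.05). Two size knobs matter:

- minimum cluster size = max(5, 5% of events) — clusters smaller than
  this are not units;
- OPTICS `min_samples` (core-neighborhood size) = max(10, 10% of events).
  This smooths the reachability profile; with a tiny neighborhood a
  single tight cluster fragments into spurious sub-clusters. The 10%
  default was chosen from a seed-robustness sweep on the two-template
  scene before the acceptance outcomes were frozen.

Labels are renumbered by order of first appearance, so sorting is
deterministic for fixed input. Density outliers get −1.

Redundancy tagging flags any spike that has, within 0.7 ms on a
*different* electrode, a partner of larger absolute amplitude (ties:
earlier time, then lexicographically smaller label). The
largest-amplitude member of each coincident group remains primary, and
the outcome is independent of input row order.

## Display transforms

**Min/max decimation.** n samples are split into n_p near-equal bins
(the first n mod n_p bins get one extra sample); each bin emits its
minimum and maximum in order of temporal occurrence — a fixed
min-then-max order would draw phantom zig-zags. Global extrema are
preserved exactly for every n_p, which is the property that keeps sparse
spikes visible at any zoom; with n_p ≥ n the raw samples pass through.

**Pixel resolution.** span/pixels in ms, reported to 2 significant
figures (3 minutes over 1400 px → 130 ms/px), quantifying how badly a
fixed-scale raster undersamples burst activity.

**Raster ordering.** Activity (descending spike count), latency
(ascending first spike at/after t0, silent channels last), or a fixed
list; all ties break lexicographically so orderings are reproducible
permutations.

**Flashing-spike frames.** One display frame at rate f and playback
factor p covers p/f seconds of recording (25 µs at 25 fps, p = 1/1600).
Spikes in [t_start, t_end) increment their electrode's grid cell in the
frame containing their time — total onset intensity always equals the
spike count (conservation). An optional exponential afterglow
(`decay_frames`) is display-only; the undecayed onset counts are always
kept alongside. Frame counts are capped at 2×10⁶ per call; slower
playback over long spans must be requested in pieces.

## Propagation analysis

1. **Coincidence**: for each electrode pair, spike trains are matched
   one-to-one (greedy, in time order) within 0.7 ms; pairs with ≥ 30
   matches count as stereotyped. The repeat floor operationalizes
   "repeated"; it is configurable.
2. **Reference times**: the matched events' timestamps on the
   first-listed channel of the pair, or all (optionally unit-filtered)
   spikes of a single sorted channel.
3. **Aligned extraction**: a 20 ms window (401 samples), centered on each
   reference time, from every channel. If any window crosses the record
   boundary that event is dropped from *all* channels, keeping N equal —
   otherwise per-channel averages would not be comparable.
4. **Averaging**: per-sample mean over events. Peak latency is the
   largest-|value| sample of the mean trace relative to the window
   center. Jitter is the s.d. of per-event peak latencies, with each
   event's peak searched only within ±1 ms of the mean-trace peak and
   with the mean trace's polarity — unrestricted search would measure
   noise excursions at low SNR.
5. **Classification** (per channel, in order):
   - *unlocked* if the mean-trace |peak| < 4·σ_ch/√N — i.e. not
     distinguishable from the residual noise of an N-average. With 401
     samples per window the expected noise maximum is ≈ 3.7·σ/√N, so the
     factor 4 sits just above it; a locked channel must beat that.
   - *propagation* if |latency| ≤ 1 ms and jitter ≤ 0.3 ms — the
     stereotypy of one action potential recorded at different points of
     the same neuron.
   - *coupled* if |latency| falls in 1–10 ms or jitter exceeds 0.3 ms —
     synaptic transmission adds both delay and variance.
   - anything else (locked, but outside both signatures) falls back to
     *unlocked*.
   The jitter and locked-peak cutoffs are package defaults, exposed in
   `PropagationConfig`; the underlying phenomena are qualitative and any
   serious analysis should check sensitivity to them.
   `above_threshold` records whether the *averaged* peak clears the
   detection threshold; a per-event definition would be equally
   defensible, and the averaged one is used because it describes what
   the averaged display actually shows.
6. **Latency map**: propagation-classified electrodes placed at their
   layout coordinates with their mean latency; along an axon this is a
   monotone gradient from the initiation site.

The √N law is what makes sub-threshold recovery work: 400 aligned
windows of a 0.5σ template leave residual noise of σ/√400 = 0.05σ, an
SNR of 10 on a signal a detector could never see. The tests assert both
the correlation with the injected truth and the residual's agreement
with σ/√N.

## Synthetic generator

The generator renders Gaussian noise (default σ = 10 µV) plus linearly
summed biphasic templates at ground-truth times. The template is two
raised-cosine lobes: a trough of width 0.8 ms (FW) with exact amplitude
at the center sample, and a positive after-peak scaled to 30% of the
trough and widened by the inverse fraction so the two phases carry equal
area (approximate charge balance; residual integral is sample-grid
rounding only). Total support stays within the 0.2–4 ms physiological
range and is validated.

Units are `simple` (one electrode), `propagating` (several electrodes
with non-decreasing latencies and per-event Gaussian latency jitter), or
`coupled` (fires after a parent unit with normal delay truncated at
zero, with a follow probability). Firing is Poisson, burst, or an
explicit time list; overlapping events sum linearly, and a configurable
minimum ISI is available (no refractory period is enforced by default).
Everything is driven by one `numpy` PCG64 generator, so a fixed config
and seed reproduce the recording bit for bit across platforms.

Preset scenes (see `preset_config`): a 100-event 8σ detection benchmark,
the −40/−120 µV two-template sorting scene, and the propagation demo
(six-electrode axon, latencies 0–0.75 ms, jitter 0.02 ms, troughs −100
to −40 µV so the last two electrodes sit below the 60 µV threshold;
coupled follower at 3 ± 0.8 ms with follow probability 0.8; 12-electrode
3×4 grid, 30 s — small enough to regenerate in seconds).

What the generator does **not** emulate: electrode-to-electrode noise
correlation, line interference, amplitude drift, overlapping-unit
waveform superposition statistics, bursting adaptation, or realistic
spatial decay of one neuron's waveform across many electrodes. A green
test therefore establishes algorithmic correctness on the stated model,
not performance on real cultures; in particular sorting purity on the
well-separated two-template scene says nothing about near-identical
units, which the pipeline (by design) does not attempt to split.

## Numerical conventions and degenerate inputs

- Times are seconds, latencies/jitter milliseconds, voltages microvolts.
- Spike tables are globally time-sorted with ties broken by electrode
  label; readers restore this regardless of file row order.
- HDF5 analog data is float32 on disk (roundtrip exact to float32
  precision), float64 in memory.
- Empty signals, empty tables, windows outside the record, unknown
  labels and invalid parameter ranges raise typed errors
  (`ParameterError`, `ValidationError`, `FormatError`,
  `ElectrodeLookupError`); empty detection output is a valid empty
  table, not an error.
- The CLI maps usage errors to exit 1 and data/format errors to exit 2,
  and writes output files atomically (temp file + rename) so failures
  leave no partial outputs.
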