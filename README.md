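# meakit

Analysis toolkit for multi-electrode-array (MEA) extracellular recordings:
the computational core behind interactive MEA data exploration. It covers
the full path from raw multichannel voltage to interpreted single-neuron
signals:

- **I/O and geometry** — open interchange formats (HDF5 for analog voltage,
  CSV for spike timestamps) and a `Layout` mapping electrode labels such as
  `F8` to their physical `(column, row)` grid positions, including the
  standard 120-electrode, 100 µm-pitch array (12×12 grid with staircase
  corner exclusions).
- **Conditioning and detection** — 0.2–4 kHz 2nd-order Butterworth
  band-pass (zero-phase by default), robust noise estimation
  σ̂ = median(|x|)/0.6745, and threshold detection at 6σ̂ with dead-time
  enforcement and extremum-aligned timestamps.
- **Sorting** — 3 ms waveform extraction, PCA to a few components, and
  OPTICS density clustering into putative units, plus tagging of redundant
  multi-electrode co-detections (same spike seen on neighboring electrodes
  within 0.7 ms).
- **Display transforms** — extrema-preserving min/max decimation (one
  min/max pair per display pixel, so no spike is ever lost from a plot),
  raster-row ordering schemes, pixel-resolution arithmetic, and
  spatiotemporal frame binning for flashing-spike animation at playback
  factors down to 1/1600 of real time.
- **Propagation analysis** — the centerpiece: when two channels show
  stereotyped coincident spiking (repeated events within 0.7 ms), 20 ms
  windows from *every* channel are aligned on the reference channel's spike
  times and averaged. Averaging N windows shrinks uncorrelated noise by
  √N, revealing the two-dimensional spread of a single neuron's axonal
  action potential — including electrodes whose spikes are below the
  detection threshold — and separating synaptically coupled partner units
  by their longer (1–10 ms) and more jittered delays.
- **Synthetic data** — a seeded generator of ground-truthed recordings
  (Gaussian noise, biphasic spike templates, propagating units with fixed
  inter-electrode latencies, jittered coupled followers) so every stage is
  testable without real recordings.

Intended users: electrophysiologists working with medium-density MEA
cultures and developers of spike-detection/sorting pipelines who need a
scriptable, testable reference implementation of these transforms.

## Worked example

Generate the synthetic propagation scene (one unit propagating over six
electrodes, two of them sub-threshold, plus one coupled follower), detect
spikes, and run the propagation analysis:

```python
import meakit as mk

cfg = mk.preset_config("propagation-demo", seed=7)
rec, truth = mk.generate(cfg)
filtered = mk.bandpass(rec)

sigma = {ch: mk.estimate_noise(filtered.channel(ch))
         for ch in filtered.channel_ids}
table = mk.concat_spike_tables([
    mk.detect_spikes(filtered.channel(ch), filtered.sampling_rate,
                     sigma=sigma[ch], electrode=ch)
    for ch in filtered.channel_ids
])
print(f"{len(table)} spikes detected on {rec.n_channels} channels")

pairs = mk.find_coincident_pairs(table)
print("strongest coincident pair:", pairs[0])

result = mk.analyze_propagation(
    filtered, table, pairs[0][:2],
    sigma=sigma,
    detection_threshold={ch: 6 * s for ch, s in sigma.items()},
)
for ens in result.ensembles:
    if ens.classification != "unlocked":
        print(f"{ens.electrode}: {ens.classification:11s} "
              f"latency {ens.peak_latency:+.2f} ms, "
              f"jitter {ens.jitter:.3f} ms, "
              f"above threshold: {ens.above_threshold}")
```

Output:

```
1099 spikes detected on 12 channels
strongest coincident pair: ('A1', 'B1', 170)
A1: propagation latency +0.00 ms, jitter 0.000 ms, above threshold: True
B1: propagation latency +0.15 ms, jitter 0.053 ms, above threshold: True
D1: coupled     latency +2.80 ms, jitter 0.615 ms, above threshold: False
B2: propagation latency +0.30 ms, jitter 0.057 ms, above threshold: True
C2: propagation latency +0.45 ms, jitter 0.055 ms, above threshold: True
C3: propagation latency +0.60 ms, jitter 0.068 ms, above threshold: True
D3: propagation latency +0.75 ms, jitter 0.077 ms, above threshold: False
```

Reading it: electrodes A1→D3 carry the same neuron's action potential with
a monotone latency gradient of ~0.15 ms per electrode and near-zero jitter
— axonal propagation. D3 never crossed the detection threshold on its own;
signal averaging 170 aligned windows recovered it. D1 fires ~3 ms after
the reference with 0.6 ms jitter: the timing signature of a synaptically
coupled follower, not of the same cell.

The same pipeline is available from the shell:

```sh
meakit --seed 7 synth --preset propagation-demo rec.h5 truth.csv
meakit detect rec.h5 spikes.csv
meakit propagation --reference A1,B1 --layout 3x4 rec.h5 spikes.csv out/
```

which writes per-channel mean traces, a classification table, and the
latency map under `out/`. Other subcommands: `filter`, `sort`,
`downsample`, `raster`, `frames` (see `meakit --help`).

## Acceptance script

`scripts/acceptance.py` re-runs the full pipeline from scratch —
synthetic generation, filtering, per-channel detection, coincidence
search, spike-triggered averaging and classification — and writes its
JSON summary to the path given by `--out`:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout conventions

Coordinates are 0-based `(column, row)` tuples with the origin at the
top-left. The default 120-electrode layout letters its columns A–M
skipping I (to avoid confusion with the digit 1) and numbers rows 1–12;
a 3-2-1 staircase of six positions is excluded at each corner
(144 − 24 = 120). Custom layouts can be registered by name or built with
`grid_layout(rows, columns)`.
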