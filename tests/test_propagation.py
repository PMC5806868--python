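"""Coincidence matching, spike-triggered averaging, channel classification."""

import numpy as np
import pytest

import meakit as mk
from meakit.errors import ElectrodeLookupError, ParameterError
from meakit.propagation import _greedy_match, average_ensembles

FS = 20_000.0


def _pair_table(times_a, times_b, more=None):
    chans = {"A1": times_a, "B1": times_b, **(more or {})}
    electrode, time = [], []
    for ch, ts in chans.items():
        electrode += [ch] * len(ts)
        time += list(ts)
    return mk.spike_table(electrode=electrode, time=time,
                          amplitude=[-80.0] * len(time))


def _coincidence_oracle(a, b, window_s):
    """O(n^2) greedy one-to-one matching oracle."""
    a, b = np.sort(a), np.sort(b)
    used = np.zeros(b.size, dtype=bool)
    count = 0
    for t in a:
        d = np.abs(b - t)
        d[used] = np.inf
        j = int(np.argmin(d)) if b.size else 0
        if b.size and d[j] <= window_s:
            used[j] = True
            count += 1
    return count


class TestCoincidentPairs:
    def test_single_channel_empty(self):
        table = _pair_table(np.linspace(1, 50, 50), [])
        assert mk.find_coincident_pairs(table) == []

    def test_fixed_offset_pair_counted_once_each(self, rng):
        a = np.sort(rng.uniform(1, 50, 50))
        a = a[np.r_[True, np.diff(a) > 0.01]]
        table = _pair_table(a, a + 0.3e-3)
        cfg = mk.PropagationConfig(min_repeats=30)
        pairs = mk.find_coincident_pairs(table, cfg)
        assert ("A1", "B1", a.size) in pairs
        assert ("B1", "A1", a.size) in pairs  # symmetry with equal count

    def test_out_of_window_channel_absent(self, rng):
        a = np.sort(rng.uniform(1, 50, 50))
        a = a[np.r_[True, np.diff(a) > 0.01]]
        table = _pair_table(a, a + 0.3e-3, {"C1": a + 1.5e-3})
        pairs = mk.find_coincident_pairs(table,
                                         mk.PropagationConfig(min_repeats=30))
        assert not any("C1" in p[:2] for p in pairs)

    def test_matching_agrees_with_oracle(self, rng):
        for _ in range(10):
            a = np.sort(rng.uniform(0, 0.5, 40))
            b = np.sort(rng.uniform(0, 0.5, 35))
            got = _greedy_match(a, b, 0.7e-3).size
            assert got == _coincidence_oracle(a, b, 0.7e-3)


class TestReferenceTimes:
    def test_pair_returns_matched_times_of_first_channel(self, rng):
        a = np.sort(rng.uniform(1, 50, 50))
        a = a[np.r_[True, np.diff(a) > 0.01]]
        table = _pair_table(a, a + 0.3e-3)
        times = mk.reference_times(table, ("A1", "B1"))
        np.testing.assert_allclose(times, a)

    def test_single_channel_unit_filter(self):
        table = mk.spike_table(electrode=["A1"] * 4, time=[1, 2, 3, 4],
                               amplitude=[-50] * 4, unit=[2, 1, 2, 1])
        np.testing.assert_array_equal(
            mk.reference_times(table, "A1", unit=2), [1.0, 3.0])

    def test_pair_with_no_matches_warns_empty(self):
        table = _pair_table([1.0, 2.0], [10.0, 20.0])
        with pytest.warns(UserWarning, match="no coincident"):
            times = mk.reference_times(table, ("A1", "B1"))
        assert times.size == 0

    def test_unknown_reference_rejected(self):
        table = _pair_table([1.0], [2.0])
        with pytest.raises(ElectrodeLookupError):
            mk.reference_times(table, "Z9")
        with pytest.raises(ElectrodeLookupError):
            mk.reference_times(table, ("A1", "Z9"))


def _recording_with_template(times, amp=-80.0, duration=10.0, sigma=0.0,
                             seed=0, channels=("A1",)):
    layout = mk.grid_layout(1, len(channels))
    cfg = mk.SyntheticConfig(
        layout=layout, duration=duration, noise_sigma=sigma, seed=seed,
        units=tuple(
            mk.UnitSpec(electrodes=(ch,), amplitudes=(amp,),
                        firing=mk.FiringSpec(kind="times", times=tuple(times)))
            for ch in channels
        ),
    )
    return mk.generate(cfg)


class TestExtractAligned:
    def test_window_sample_count(self):
        rec, truth = _recording_with_template([1.0, 2.0])
        ens = mk.extract_aligned(rec, truth["time"].to_numpy())
        assert ens[0].n_samples == 401  # round(20 ms * 20 kHz) + 1

    def test_noise_free_windows_equal_local_signal(self):
        rec, truth = _recording_with_template([1.0, 2.0, 3.0])
        ens = mk.extract_aligned(rec, truth["time"].to_numpy())[0]
        x = rec.channel("A1")
        for w, t in zip(ens.windows, truth["time"]):
            c = int(round(t * FS))
            np.testing.assert_array_equal(w, x[c - 200:c + 201])

    def test_boundary_event_dropped_everywhere(self):
        rec, truth = _recording_with_template([0.005, 1.0, 2.0],
                                              channels=("A1", "B1"))
        ens = mk.extract_aligned(rec, [0.005, 1.0, 2.0])
        assert all(e.n_events == 2 for e in ens)  # equal-N contract

    def test_no_valid_events_rejected(self):
        rec, _ = _recording_with_template([1.0])
        with pytest.raises(ParameterError):
            mk.extract_aligned(rec, [0.001])


class TestAverageEnsembles:
    def test_identical_windows_mean_is_window(self):
        rec, truth = _recording_with_template([1.0, 2.0, 3.0, 4.0])
        ens = average_ensembles(mk.extract_aligned(rec,
                                                   truth["time"].to_numpy()))
        e = ens[0]
        np.testing.assert_allclose(e.mean_trace, e.windows[0])
        assert e.jitter == 0.0
        assert e.peak_latency == 0.0

    def test_snr_scaling_law(self):
        # residual noise of an N-average shrinks as sigma/sqrt(N)
        sigma = 10.0
        for n in (25, 100, 400):
            times = 0.5 + np.arange(n) * 0.04
            rec, truth = _recording_with_template(
                times, amp=-5.0, duration=times[-1] + 0.5,
                sigma=sigma, seed=n)
            ens = average_ensembles(
                mk.extract_aligned(rec, truth["time"].to_numpy()))[0]
            tmpl = mk.biphasic_template(FS, -5.0)
            half = tmpl.size // 2
            center = ens.n_samples // 2
            truth_trace = np.zeros(ens.n_samples)
            truth_trace[center - half:center + half + 1] = tmpl
            resid = np.std(ens.mean_trace - truth_trace)
            assert abs(resid - sigma / np.sqrt(n)) <= 0.2 * sigma / np.sqrt(n)

    def test_all_noise_peak_below_locked_criterion(self):
        cfg = mk.PropagationConfig()
        n, w = 400, 401
        ok = 0
        for seed in range(20):
            windows = np.random.default_rng(seed).normal(0, 10.0, (n, w))
            ens = average_ensembles(
                [mk.ChannelEnsemble("A1", windows, FS)], cfg)[0]
            criterion = cfg.locked_peak_criterion * 10.0 / np.sqrt(n)
            ok += np.max(np.abs(ens.mean_trace)) < criterion
        assert ok >= 19  # >= 95% of 20 seeds


def _synthetic_ensemble(latency_ms, jitter_ms, amp, n=200, sigma=2.0, seed=0):
    """Construct windows with a template at known latency and jitter."""
    rng = np.random.default_rng(seed)
    tmpl = mk.biphasic_template(FS, amp)
    half = tmpl.size // 2
    w = 401
    center = w // 2
    windows = rng.normal(0, sigma, (n, w))
    for i in range(n):
        lat = latency_ms + rng.normal(0, jitter_ms)
        c = center + int(round(lat * 1e-3 * FS))
        windows[i, c - half:c + half + 1] += tmpl
    return mk.ChannelEnsemble("A1", windows, FS)


class TestClassifyChannels:
    def test_rule_table(self):
        cases = [
            (_synthetic_ensemble(0.4, 0.02, -80.0), "propagation"),
            (_synthetic_ensemble(4.0, 0.8, -80.0), "coupled"),
        ]
        noise = mk.ChannelEnsemble(
            "A1", np.random.default_rng(1).normal(0, 10.0, (200, 401)), FS)
        ensembles = [c[0] for c in cases] + [noise]
        average_ensembles(ensembles)
        mk.classify_channels(ensembles, sigma=10.0, detection_threshold=60.0)
        assert ensembles[0].classification == "propagation"
        assert ensembles[1].classification == "coupled"
        assert ensembles[2].classification == "unlocked"
        assert ensembles[0].above_threshold is True

    def test_requires_averaged_input(self):
        ens = [_synthetic_ensemble(0.0, 0.0, -80.0)]
        with pytest.raises(ParameterError):
            mk.classify_channels(ens, sigma=10.0, detection_threshold=60.0)


class TestLatencyMap:
    def _result(self, ensembles):
        return mk.PropagationResult(reference="A1",
                                    reference_times=np.array([1.0]),
                                    ensembles=ensembles)

    def test_single_propagation_channel(self):
        layout = mk.grid_layout(2, 2)
        e = _synthetic_ensemble(0.0, 0.0, -80.0, n=20, sigma=0.5)
        average_ensembles([e])
        mk.classify_channels([e], sigma=0.5, detection_threshold=3.0)
        grid = mk.latency_map(self._result([e]), layout)
        col, row = layout.coordinates_for_electrode("A1")
        assert grid[row, col] == 0.0
        assert np.isnan(grid).sum() == 3

    def test_axon_gradient_reproduced(self):
        layout = mk.grid_layout(1, 5)
        labels = layout.electrodes
        lats = [0.0, 0.1, 0.2, 0.3, 0.4]
        ensembles = []
        for i, (ch, lat) in enumerate(zip(labels, lats)):
            e = _synthetic_ensemble(lat, 0.0, -80.0, n=20, sigma=0.5, seed=i)
            e.electrode = ch
            ensembles.append(e)
        average_ensembles(ensembles)
        mk.classify_channels(ensembles, sigma=0.5, detection_threshold=3.0)
        grid = mk.latency_map(self._result(ensembles), layout)
        np.testing.assert_allclose(grid[0], lats, atol=1e-9)
        assert np.all(np.diff(grid[0]) > 0)  # monotone along the path

    def test_no_propagation_channels_warns_empty(self):
        layout = mk.grid_layout(2, 2)
        e = mk.ChannelEnsemble(
            "A1", np.random.default_rng(2).normal(0, 10.0, (50, 401)), FS)
        average_ensembles([e])
        mk.classify_channels([e], sigma=10.0, detection_threshold=60.0)
        with pytest.warns(UserWarning, match="no propagation"):
            grid = mk.latency_map(self._result([e]), layout)
        assert np.isnan(grid).all()
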