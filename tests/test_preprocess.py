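"""Conditioning-chain contracts: filter responses checked against the
designed filters' analytic magnitudes, spline resampling against closed
forms, and windowing/splitting/QC bookkeeping against enumeration."""

import numpy as np
import pytest
from scipy import signal as sps

from gaitfuse import (MotionMode, bandpass_emg, cycle_similarity,
                      default_params, generate_recording, iemg, lowpass_imu,
                      qc_report, resample_cubic, segment, split)
from gaitfuse.preprocess import (WindowSet, load_windows, preprocess_bundle,
                                 save_windows, segment_dataset)
from gaitfuse.synthio import RecordingBundle


def sine_gain(filter_fn, freq, rate, duration=2.0, **kw):
    """Measured amplitude of a unit sine after filtering, edge-trimmed."""
    t = np.arange(int(duration * rate)) / rate
    y = filter_fn(np.sin(2 * np.pi * freq * t), **kw)
    trim = int(0.25 * rate)
    return np.max(np.abs(y[trim:-trim]))


def analytic_gain(sos, freq, rate):
    """Zero-phase (forward-backward) magnitude of the designed filter."""
    _, h = sps.sosfreqz(sos, worN=[freq], fs=rate)
    return np.abs(h[0])**2


class TestBandpassEMG:
    def test_dc_rejected(self):
        out = bandpass_emg(np.full(4000, 3.0))
        assert np.max(np.abs(out)) < 1e-6 * 3.0

    def test_100hz_passband_gain(self):
        g = sine_gain(bandpass_emg, 100, 2000)
        assert abs(g - 1.0) < 0.02
        sos = sps.butter(4, [20, 500], btype="bandpass", fs=2000,
                         output="sos")
        assert abs(g - analytic_gain(sos, 100, 2000)) < 0.02

    def test_5hz_stopband(self):
        g = sine_gain(bandpass_emg, 5, 2000)
        sos = sps.butter(4, [20, 500], btype="bandpass", fs=2000,
                         output="sos")
        assert g < 0.1
        assert analytic_gain(sos, 5, 2000) < 0.1  # the bound is the filter's

    def test_passband_idempotence(self):
        t = np.arange(4000) / 2000
        x = np.sin(2 * np.pi * 100 * t)
        once = bandpass_emg(x)
        twice = bandpass_emg(once)
        trim = 500
        a1 = np.max(np.abs(once[trim:-trim]))
        a2 = np.max(np.abs(twice[trim:-trim]))
        assert abs(a2 - a1) / a1 < 0.02

    def test_invalid_band_and_length(self):
        with pytest.raises(ValueError):
            bandpass_emg(np.zeros(4000), low=20, high=1000)
        with pytest.raises(ValueError):
            bandpass_emg(np.zeros(5))


class TestLowpassIMU:
    def test_dc_preserved(self):
        out = lowpass_imu(np.full(800, 2.5))
        assert np.max(np.abs(out - 2.5)) < 1e-6

    def test_2hz_passband(self):
        assert abs(sine_gain(lowpass_imu, 2, 200, duration=4.0) - 1.0) < 0.02

    def test_50hz_stopband(self):
        assert sine_gain(lowpass_imu, 50, 200, duration=4.0) < 0.05

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            lowpass_imu(np.zeros(800), cutoff=150)


class TestResample:
    def test_sample_count_200_to_2000(self):
        out = resample_cubic(np.random.default_rng(0).normal(size=200))
        assert out.shape[-1] == 2000

    def test_knots_reproduced(self):
        x = np.random.default_rng(1).normal(size=50)
        out = resample_cubic(x)
        assert np.max(np.abs(out[::10] - x)) < 1e-9

    def test_sine_error_vs_closed_form(self):
        t_in = np.arange(400) / 200.0
        out = resample_cubic(np.sin(2 * np.pi * 1.0 * t_in))
        t_out = np.arange(4000) / 2000.0
        assert np.max(np.abs(out - np.sin(2 * np.pi * t_out))) < 1e-4

    def test_non_integer_ratio_rejected(self):
        with pytest.raises(ValueError):
            resample_cubic(np.zeros(100), rate_in=200, rate_out=300)
        with pytest.raises(ValueError):
            resample_cubic(np.zeros(3))


def _flat_bundle(T, mode=MotionMode.running):
    """A already-preprocessed-shape bundle with both modalities at T."""
    rng = np.random.default_rng(0)
    return RecordingBundle(emg=rng.normal(size=(4, T)),
                           imu=rng.normal(size=(3, T)), mode=mode,
                           duration=T / 2000.0, meta={})


class TestSegment:
    @pytest.mark.parametrize("T,stride,expected", [
        (6000, 600, 10),
        (6000, 300, 19),  # matches direct enumeration of start offsets
        (600, 600, 1),
    ])
    def test_window_counts(self, T, stride, expected):
        ws = segment(_flat_bundle(T), stride=stride)
        assert len(ws) == expected
        starts = list(range(0, T - 600 + 1, stride))
        assert len(starts) == expected
        assert list(ws.start_index) == starts

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            segment(_flat_bundle(599))

    def test_pairing_alignment(self):
        b = _flat_bundle(3000)
        ws = segment(b, stride=300)
        for i, s in enumerate(ws.start_index):
            assert np.array_equal(ws.emg[i], b.emg[:, s:s + 600])
            assert np.array_equal(ws.imu[i], b.imu[:, s:s + 600])

    def test_preprocess_alignment_end_to_end(self):
        raw = generate_recording(default_params("running"), "running", 4.0,
                                 seed=0)
        pre = preprocess_bundle(raw)
        assert pre.emg.shape[1] == pre.imu.shape[1]
        ws = segment(pre)
        assert np.array_equal(ws.start_index, ws.start_index)  # paired 1:1
        assert ws.emg.shape[0] == ws.imu.shape[0]


def _labeled_windows(n_per_mode, n_modes=4):
    n = n_per_mode * n_modes
    rng = np.random.default_rng(0)
    return WindowSet(
        emg=rng.normal(size=(n, 4, 600)), imu=rng.normal(size=(n, 3, 600)),
        labels=np.repeat(np.arange(n_modes), n_per_mode),
        source_id=np.array([f"r{i % 8}" for i in range(n)], dtype=object),
        start_index=np.arange(n),
    )


class TestSplit:
    def test_712_split_sizes(self):
        ws = split(_labeled_windows(25), seed=0)
        names, counts = np.unique(ws.split, return_counts=True)
        sizes = dict(zip(names, counts))
        assert sizes == {"train": 70, "val": 10, "test": 20}

    def test_deterministic(self):
        a = split(_labeled_windows(25), seed=5)
        b = split(_labeled_windows(25), seed=5)
        assert np.array_equal(a.split, b.split)

    def test_stratified_per_mode(self):
        ws = split(_labeled_windows(50), seed=1)
        for mode in range(4):
            frac = np.mean(ws.split[ws.labels == mode] == "train")
            assert 0.65 <= frac <= 0.75

    def test_every_pair_assigned_exactly_once(self):
        ws = split(_labeled_windows(25), seed=2)
        assert set(np.unique(ws.split)) <= {"train", "val", "test"}
        assert len(ws.split_subset("train", "val", "test")) == len(ws)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            split(_labeled_windows(2, n_modes=2), seed=0)


class TestQCStats:
    def test_iemg_examples_and_oracle(self, rng):
        assert iemg([1, -2, 3]) == 6
        assert iemg(np.zeros(10)) == 0
        x = rng.normal(size=100)
        brute = sum(abs(v) for v in x)
        assert np.isclose(iemg(x), brute)
        with pytest.raises(ValueError):
            iemg([])

    def test_cycle_similarity_trivial_cases(self, rng):
        c = rng.normal(size=50)
        m = cycle_similarity([c, c.copy()])
        assert np.allclose(m, 1.0)
        m = cycle_similarity([c, -c])
        assert np.isclose(m[0, 1], -1.0)

    def test_cycle_similarity_matches_brute_force(self, rng):
        a, b = rng.normal(size=40), rng.normal(size=40)
        m = cycle_similarity([a, b])
        am, bm = a - a.mean(), b - b.mean()
        brute = np.sum(am * bm) / np.sqrt(np.sum(am**2) * np.sum(bm**2))
        assert np.isclose(m[0, 1], brute, atol=1e-12)
        assert np.allclose(m, m.T) and np.allclose(np.diag(m), 1.0)

    def test_constant_cycle_rejected(self):
        with pytest.raises(ValueError):
            cycle_similarity([np.ones(20), np.arange(20.0)])

    @pytest.mark.parametrize("seed", range(5))
    def test_qc_passes_on_defaults(self, seed):
        b = generate_recording(default_params("running"), "running", 12.0,
                               seed=seed)
        rep = qc_report(b, seed=seed)
        assert all(rep.pass_flags.values())
        for mean, sd in rep.iemg_stats.values():
            assert mean > 0 and sd >= 0


def test_hdf5_round_trip(tmp_path, small_windows):
    path = tmp_path / "w.h5"
    save_windows(small_windows, path)
    back = load_windows(path)
    assert np.array_equal(back.emg, small_windows.emg)
    assert np.array_equal(back.labels, small_windows.labels)
    assert np.array_equal(back.split, small_windows.split)
    assert np.array_equal(back.source_id, small_windows.source_id)
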