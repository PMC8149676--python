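"""SO/spindle detection, pairing, and the time-frequency map."""

import numpy as np
import pytest

import sleepreplay as sr
from sleepreplay.core import STAGE_CODES
from sleepreplay.events import moving_rms
from sleepreplay.filters import fir_bandpass_filtfilt


def all_n2_mask(n, sfreq):
    return sr.HypnogramMask(
        np.full(n, STAGE_CODES["N2"], dtype=np.int8), np.zeros(n, bool), sfreq
    )


class TestSODetection:
    def test_constant_zero_signal_no_events(self):
        eeg = sr.ContinuousEEG(np.zeros((1, 12000)), 200.0, ["Cz"])
        assert sr.detect_slow_oscillations(eeg, all_n2_mask(12000, 200.0), "Cz") == []

    def test_sinusoid_count_matches_zero_crossing_oracle(self):
        # 0.75 Hz (period 1.333 s, inside the duration criteria): every full
        # cycle between successive positive-to-negative crossings is an event
        sfreq, dur = 200.0, 60.0
        t = np.arange(int(dur * sfreq)) / sfreq
        x = 60 * np.sin(2 * np.pi * 0.75 * t)
        eeg = sr.ContinuousEEG(x[None, :], sfreq, ["Cz"])
        events = sr.detect_slow_oscillations(eeg, all_n2_mask(t.size, sfreq), "Cz")

        # independent oracle: count p2n crossing pairs on the filtered trace
        xf = fir_bandpass_filtfilt(x, sfreq, 0.3, 1.25)
        pos = xf > 0
        crossings = np.flatnonzero(pos[:-1] & ~pos[1:])
        assert len(events) == len(crossings) - 1
        durations = np.array([e.duration for e in events])
        np.testing.assert_allclose(durations, 1 / 0.75, atol=0.02)

    def test_slow_sinusoid_fails_duration_rule(self):
        # 0.3 Hz: period 3.33 s exceeds the 2-s maximum
        sfreq = 200.0
        t = np.arange(int(60 * sfreq)) / sfreq
        eeg = sr.ContinuousEEG(60 * np.sin(2 * np.pi * 0.3 * t)[None, :], sfreq, ["Cz"])
        assert sr.detect_slow_oscillations(eeg, all_n2_mask(t.size, sfreq), "Cz") == []

    def test_event_structure_invariants(self, nap_cfg):
        eeg, mask, _ = sr.simulate_sleep_recording(nap_cfg, 0)
        eeg = sr.rereference(eeg, "linked-mastoids")
        events = sr.detect_slow_oscillations(eeg, mask, "Cz")
        assert events, "expected SO events on a simulated nap"
        for e in events:
            assert e.start < e.downstate < e.upstate < e.end
            assert 0.8 <= e.duration <= 2.0

    def test_no_nrem_warns_and_returns_empty(self):
        eeg = sr.ContinuousEEG(np.random.default_rng(0).standard_normal((1, 4000)), 200.0, ["Cz"])
        wake = sr.HypnogramMask(
            np.full(4000, STAGE_CODES["W"], dtype=np.int8), np.zeros(4000, bool), 200.0
        )
        with pytest.warns(UserWarning, match="N2/N3"):
            assert sr.detect_slow_oscillations(eeg, wake, "Cz") == []


class TestSpindleDetection:
    def test_single_planted_burst(self, rng):
        sfreq, dur = 200.0, 120.0
        n = int(dur * sfreq)
        x = rng.standard_normal(n) * 2.0
        t_burst = (np.arange(int(1.0 * sfreq)) - sfreq / 2) / sfreq
        burst = 30 * np.hanning(t_burst.size) * np.sin(2 * np.pi * 14 * t_burst)
        center = 60.0
        i0 = int(center * sfreq) - t_burst.size // 2
        x[i0 : i0 + t_burst.size] += burst
        eeg = sr.ContinuousEEG(x[None, :], sfreq, ["Cz"])
        events = sr.detect_spindles(eeg, all_n2_mask(n, sfreq), "Cz", min_peak_factor=2.0)
        assert len(events) == 1
        assert abs(events[0].trough - center) < 0.5
        assert abs(events[0].amplitude_peak_time - center) < 0.05
        assert events[0].onset < events[0].trough < events[0].offset

    def test_run_shorter_than_minimum_rejected(self, rng):
        # the supra-threshold run around a planted burst (length measured by
        # an independent run-length oracle) is accepted under the default
        # bounds but rejected once the minimum duration exceeds it
        sfreq, n = 200.0, int(120 * 200)
        x = rng.standard_normal(n) * 2.0
        tb = (np.arange(int(1.0 * sfreq)) - 0.5 * sfreq) / sfreq
        x[10000 : 10000 + tb.size] += 30 * np.hanning(tb.size) * np.sin(2 * np.pi * 14 * tb)
        eeg = sr.ContinuousEEG(x[None, :], sfreq, ["Cz"])
        mask = all_n2_mask(n, sfreq)

        xf = fir_bandpass_filtfilt(x, sfreq, 12.0, 18.0)
        rms = moving_rms(xf, sfreq, 0.2)
        supra = rms > np.percentile(rms, 75)
        edges = np.flatnonzero(np.diff(np.r_[0, supra.view(np.int8), 0]))
        starts, stops = edges[::2], edges[1::2]
        at_burst = (starts <= 10100) & (stops >= 10100)
        run_len = float((stops[at_burst] - starts[at_burst])[0]) / sfreq

        detected = sr.detect_spindles(eeg, mask, "Cz", min_peak_factor=2.0)
        assert any(abs(e.trough - 50.0) < 1.0 for e in detected)
        rejected = sr.detect_spindles(
            eeg, mask, "Cz", duration_bounds=(run_len + 0.1, 3.0),
            min_peak_factor=2.0,
        )
        assert all(abs(e.trough - 50.0) > 1.0 for e in rejected)

    def test_threshold_is_75th_percentile(self, rng):
        # stationary noise: exactly 25% of valid RMS samples exceed threshold
        sfreq, n = 200.0, int(300 * 200)
        x = rng.standard_normal(n) * 5.0
        eeg = sr.ContinuousEEG(x[None, :], sfreq, ["Cz"])
        mask = all_n2_mask(n, sfreq)
        xf = fir_bandpass_filtfilt(x, sfreq, 12.0, 18.0)
        rms = moving_rms(xf, sfreq, 0.2)
        threshold = np.percentile(rms, 75)
        assert abs((rms > threshold).mean() - 0.25) < 1e-3
        events = sr.detect_spindles(eeg, mask, "Cz")
        # pure noise: the duration rule rejects the vast majority of the
        # supra-threshold runs (run-length oracle)
        runs = np.flatnonzero(np.diff(np.r_[0, (rms > threshold).view(np.int8), 0]))
        n_runs = runs.size // 2
        assert n_runs > 100
        assert len(events) < 0.05 * n_runs

    def test_recall_degrades_as_amplitude_falls(self, small_cfg):
        import dataclasses

        recalls = []
        for amp in (25.0, 10.0, 4.0):
            cfg = dataclasses.replace(small_cfg, spindle_amplitude=amp, seed=21)
            eeg, mask, truth = sr.simulate_sleep_recording(cfg, 0)
            eeg = sr.rereference(eeg, "linked-mastoids")
            det = sr.detect_spindles(eeg, mask, "Cz", min_peak_factor=2.0)
            peaks = np.array([e.amplitude_peak_time for e in det])
            hits = [
                peaks.size and np.abs(peaks - p).min() <= 0.3
                for p in truth.spindle_peak_times
            ]
            recalls.append(np.mean(hits))
        assert recalls[0] >= recalls[1] >= recalls[2]
        assert recalls[0] > 0.9 and recalls[2] < 0.5

    def test_short_valid_span_errors(self):
        eeg = sr.ContinuousEEG(np.zeros((1, 1000)), 200.0, ["Cz"])
        stages = np.full(1000, STAGE_CODES["W"], dtype=np.int8)
        stages[:20] = STAGE_CODES["N2"]  # 0.1 s < one 200-ms RMS window
        mask = sr.HypnogramMask(stages, np.zeros(1000, bool), 200.0)
        with pytest.raises(ValueError, match="RMS window"):
            sr.detect_spindles(eeg, mask, "Cz")


class TestPairing:
    def so_at(self, t):
        return sr.SOEvent(start=t - 0.3, downstate=t, upstate=t + 0.6, end=t + 1.0,
                          duration=1.3, trough_amplitude=-70.0)

    def spindle_at(self, onset):
        return sr.SpindleEvent(onset=onset, offset=onset + 1.0, duration=1.0,
                               trough=onset + 0.5, peak_rms=12.0,
                               amplitude_peak_time=onset + 0.5)

    def test_empty_spindles_all_solitary(self):
        res = sr.pair_so_spindle([self.so_at(10.0)], [])
        assert res.complexes == [] and len(res.solitary_sos) == 1

    def test_lag_arithmetic(self):
        res = sr.pair_so_spindle([self.so_at(10.0)], [self.spindle_at(11.2)])
        assert len(res.complexes) == 1
        assert res.complexes[0].lag == pytest.approx(1.2)

    def test_outside_window_not_paired(self):
        res = sr.pair_so_spindle([self.so_at(10.0)], [self.spindle_at(11.8)])
        assert res.complexes == []
        assert len(res.solitary_spindles) == 1

    def test_earliest_of_multiple_paired(self):
        res = sr.pair_so_spindle(
            [self.so_at(10.0)], [self.spindle_at(11.0), self.spindle_at(10.4)]
        )
        assert res.complexes[0].lag == pytest.approx(0.4)

    def test_complex_count_bounded(self, nap_cfg):
        eeg, mask, _ = sr.simulate_sleep_recording(nap_cfg, 1)
        eeg = sr.rereference(eeg, "linked-mastoids")
        sos = sr.detect_slow_oscillations(eeg, mask, "Cz", amplitude_sd_factor=3.0)
        spd = sr.detect_spindles(eeg, mask, "Cz", min_peak_factor=2.0)
        res = sr.pair_so_spindle(sos, spd)
        assert len(res.complexes) <= min(len(sos), len(spd))
        assert len(res.complexes) + len(res.solitary_sos) == len(sos)
        assert len(res.complexes) + len(res.solitary_spindles) == len(spd)


class TestTFR:
    def make_tone_epochs(self, freq=14.0, sfreq=200.0, n_events=3):
        times = np.arange(-4.0, 4.0 + 1e-9, 1 / sfreq)
        data = np.tile(np.sin(2 * np.pi * freq * times), (n_events, 1, 1))
        return sr.EpochSet(data=data, times=times, lock="SO-downstate",
                           channel_names=["Cz"])

    def test_pure_tone_peaks_at_its_frequency(self):
        tfr = sr.tfr_hanning(self.make_tone_epochs(14.0), zscore=False)
        interior = (tfr.times > -2.0) & (tfr.times < 2.0)
        peak_freqs = tfr.freqs[np.argmax(tfr.power[:, interior], axis=0)]
        assert (peak_freqs == 14.0).all()

    def test_zscore_normalization(self, rng):
        times = np.arange(-4.0, 4.0 + 1e-9, 1 / 200.0)
        eps = sr.EpochSet(data=rng.standard_normal((4, 1, times.size)),
                          times=times, lock="SO-downstate", channel_names=["Cz"])
        tfr = sr.tfr_hanning(eps)
        np.testing.assert_allclose(tfr.power.mean(axis=1), 0, atol=1e-9)
        np.testing.assert_allclose(tfr.power.std(axis=1), 1, atol=1e-9)

    def test_default_grid_is_1_to_30(self):
        tfr = sr.tfr_hanning(self.make_tone_epochs())
        assert tfr.power.shape[0] == 30
        np.testing.assert_array_equal(tfr.freqs, np.arange(1.0, 31.0))

    def test_too_short_epoch_names_limit(self):
        times = np.arange(-1.0, 1.0, 1 / 200.0)
        eps = sr.EpochSet(data=np.zeros((1, 1, times.size)), times=times,
                          lock="SO-downstate", channel_names=["Cz"])
        with pytest.raises(ValueError, match="1 Hz"):
            sr.tfr_hanning(eps)
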