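"""Filter design/application, re-referencing, epoching, baseline and the
artifact screening battery."""

import numpy as np
import pandas as pd
import pytest

from c1readout import preprocess as pp
from c1readout import synth
from c1readout.containers import EpochSet

FS = 512.0


@pytest.fixture(scope="module")
def coeffs():
    return pp.design_lowpass(pp.FilterSpec())


class TestFilterDesign:
    def test_reconstructed_design_matches_published_response(self, coeffs):
        """77 taps at 512 Hz: the recovered design puts ~83.5 dB of
        attenuation at the 50 Hz mains frequency with a -3 dB corner near
        35.5 Hz."""
        att50 = -pp.magnitude_response_db(coeffs, [50.0])[0]
        assert att50 == pytest.approx(83.5, abs=0.5)
        corner = pp.corner_frequency(coeffs)
        assert corner == pytest.approx(35.3, rel=0.02)

    def test_linear_phase_and_unit_dc_gain(self, coeffs):
        assert len(coeffs) == 77
        assert np.allclose(coeffs, coeffs[::-1])          # symmetric
        assert coeffs.sum() == pytest.approx(1.0, abs=1e-12)
        assert pp.magnitude_response_db(coeffs, [0.0])[0] == \
            pytest.approx(0.0, abs=1e-9)

    def test_monotone_through_transition_band(self, coeffs):
        corner = pp.corner_frequency(coeffs)
        freqs = np.linspace(corner, 46.0, 200)
        resp = pp.magnitude_response_db(coeffs, freqs)
        assert np.all(np.diff(resp) <= 1e-9)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            pp.FilterSpec(n_taps=76).validate()
        with pytest.raises(ValueError):
            pp.FilterSpec(nominal_cutoff=300.0).validate()


class TestFilterApplication:
    def test_dc_preserved(self, coeffs):
        x = np.full((2, 1000), 3.7)
        y = pp.apply_filter(x, coeffs)
        assert np.allclose(y[:, 100:-100], 3.7)

    def test_passband_sinusoid_amplitude_preserved(self, coeffs):
        """A 10 Hz sinusoid passes with amplitude matching the designed
        response at 10 Hz to within 1%."""
        t = np.arange(4096) / FS
        x = np.sin(2 * np.pi * 10.0 * t)[None, :]
        y = pp.apply_filter(x, coeffs)[0, 500:-500]
        gain = 10 ** (pp.magnitude_response_db(coeffs, [10.0])[0] / 20.0)
        assert np.max(np.abs(y)) == pytest.approx(gain, rel=0.01)
        assert gain == pytest.approx(1.0, rel=0.01)

    def test_stopband_sinusoid_attenuated_as_designed(self, coeffs):
        t = np.arange(16384) / FS
        x = np.sin(2 * np.pi * 50.0 * t)[None, :]
        y = pp.apply_filter(x, coeffs)[0, 2000:-2000]
        measured_db = 20 * np.log10(np.max(np.abs(y)))
        designed_db = pp.magnitude_response_db(coeffs, [50.0])[0]
        assert measured_db == pytest.approx(designed_db, abs=0.5)

    def test_group_delay_compensated(self, coeffs):
        x = np.zeros((1, 600))
        x[0, 300] = 1.0
        y = pp.apply_filter(x, coeffs)
        assert int(np.argmax(y[0])) == 300

    def test_short_signal_rejected(self, coeffs):
        with pytest.raises(ValueError):
            pp.apply_filter(np.zeros((1, 50)), coeffs)


class TestRereference:
    def test_balanced_pair_unchanged(self):
        x = np.array([[1.0, 1.0], [-1.0, -1.0]])
        assert np.allclose(pp.rereference_average(x), x)

    def test_common_offset_removed_and_scalp_mean_zero(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(6, 100)) + 42.0
        y = pp.rereference_average(x)
        assert np.allclose(y.mean(axis=0), 0.0, atol=1e-12)

    def test_externals_excluded_from_reference(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(5, 50))
        scalp = np.array([True, True, True, False, False])
        y = pp.rereference_average(x, scalp_rows=scalp)
        assert np.allclose(y[scalp].mean(axis=0), 0.0, atol=1e-12)


class TestEpoching:
    def test_target_locked_epoch_is_512_samples(self):
        x = np.zeros((2, 5000))
        ep = pp.extract_epochs(x, [2000, 3000], FS, (-600.0, 400.0))
        assert ep.data.shape == (2, 2, 512)
        # first sample is the grid point nearest -600 ms (event at 0)
        assert abs(ep.time_ms[0] + 600.0) < 1000.0 / FS

    def test_response_locked_epoch_is_358_samples(self):
        x = np.zeros((1, 3000))
        ep = pp.extract_epochs(x, [1500], FS, (-600.0, 100.0))
        assert ep.data.shape[2] == 358

    def test_impulse_lands_at_time_zero(self):
        x = np.zeros((1, 3000))
        x[0, 1500] = 1.0
        ep = pp.extract_epochs(x, [1500], FS, (-600.0, 400.0))
        assert ep.time_ms[np.argmax(ep.data[0, 0])] == pytest.approx(0.0)

    def test_edge_events_dropped_with_log(self):
        x = np.zeros((1, 1000))
        log = []
        ep = pp.extract_epochs(x, [100, 600], FS, (-600.0, 400.0), log=log)
        assert ep.n_trials == 1 and len(log) == 1


class TestBaseline:
    def _epochs(self, data):
        t = (np.arange(data.shape[2]) - 307) * 1000.0 / FS
        return EpochSet(data, t, FS, [f"ch{i}"
                                      for i in range(data.shape[1])])

    def test_constant_epoch_zeroed(self):
        e = self._epochs(np.full((2, 3, 512), 5.0))
        assert np.allclose(pp.baseline_correct(e).data, 0.0)

    def test_idempotent_and_zero_mean(self):
        rng = np.random.default_rng(0)
        e = self._epochs(rng.normal(size=(4, 3, 512)))
        once = pp.baseline_correct(e)
        twice = pp.baseline_correct(once)
        assert np.allclose(once.data, twice.data)
        sel = once.time_window(-50, 30)
        assert np.allclose(once.data[:, :, sel].mean(axis=2), 0.0,
                           atol=1e-12)

    def test_window_outside_epoch_rejected(self):
        e = self._epochs(np.zeros((1, 1, 512)))
        with pytest.raises(ValueError):
            pp.baseline_correct(e, window_ms=(900.0, 950.0))


class TestScreening:
    def _epochs(self, data):
        t = (np.arange(data.shape[2]) - 307) * 1000.0 / FS
        return EpochSet(data, t, FS, [f"ch{i}"
                                      for i in range(data.shape[1])])

    def test_absolute_threshold_flags_channel(self):
        data = np.zeros((1, 2, 512))
        data[0, 1, 100] = 60.0
        rep = pp.screen_artifacts(self._epochs(data),
                                  veog=np.zeros((1, 512)))
        assert not rep.channel_flags["absolute"][0, 0]
        assert rep.channel_flags["absolute"][0, 1]

    def test_blink_segment_padded_50ms(self):
        """A vEOG excursion at 200 ms is flagged with 50 ms padding on
        both sides of the threshold violation."""
        data = np.zeros((1, 1, 512))
        e = self._epochs(data)
        veog = np.zeros((1, 512))
        over = (e.time_ms >= 200) & (e.time_ms <= 260)
        veog[0, over] = 50.0
        rep = pp.screen_artifacts(e, veog=veog)
        (a, b), = rep.blink_segments[0]
        assert a == pytest.approx(150.0, abs=3.0)
        assert b == pytest.approx(310.0, abs=3.0)
        assert not rep.full_reject[0]         # does not overlap stimulus

    def test_blink_over_stimulus_rejects_trial(self):
        data = np.zeros((1, 1, 512))
        e = self._epochs(data)
        veog = np.zeros((1, 512))
        veog[0, (e.time_ms >= 10) & (e.time_ms <= 60)] = 50.0
        rep = pp.screen_artifacts(e, veog=veog)
        assert rep.full_reject[0]
        assert rep.reject_reason[0] == "stim_blink"

    def test_drift_ratio_against_periodogram_oracle(self):
        """1 Hz at 10 µV over 5 Hz at 1 µV gives a (0-3)/(3-7 Hz) power
        ratio of ~50, far over the 5:1 threshold."""
        e = self._epochs(np.zeros((1, 1, 512)))
        t_s = (np.arange(512) / FS)
        trace = 10 * np.sin(2 * np.pi * 1.0 * t_s) + \
            1 * np.sin(2 * np.pi * 5.0 * t_s)
        ratio = pp.band_power(trace, FS, (0, 3)) / \
            pp.band_power(trace, FS, (3, 7))
        assert ratio == pytest.approx(100.0, rel=0.2)
        e.data[0, 0] = trace
        rep = pp.screen_artifacts(e, veog=np.zeros((1, 512)))
        assert rep.channel_flags["drift"][0, 0]

    def test_muscle_ratio_flags_high_band(self):
        e = self._epochs(np.zeros((1, 1, 512)))
        t_s = np.arange(512) / FS
        e.data[0, 0] = 5 * np.sin(2 * np.pi * 30.0 * t_s) + \
            1 * np.sin(2 * np.pi * 5.0 * t_s)
        rep = pp.screen_artifacts(e, veog=np.zeros((1, 512)))
        assert rep.channel_flags["muscle"][0, 0]

    def test_baseline_range_threshold(self):
        data = np.zeros((1, 1, 512))
        e = self._epochs(data)
        sel = e.time_window(-50, 30)
        data[0, 0, np.nonzero(sel)[0][0]] = 45.0
        rep = pp.screen_artifacts(self._epochs(data),
                                  veog=np.zeros((1, 512)))
        assert rep.channel_flags["baseline_range"][0, 0]

    def test_gaze_rules_reject_full_trial(self):
        e = self._epochs(np.zeros((2, 1, 512)))
        gaze = pd.DataFrame({"saccade": [True, False],
                             "gaze_dev_deg": [0.1, 1.5]})
        rep = pp.screen_artifacts(e, veog=np.zeros((2, 512)), gaze=gaze)
        assert rep.full_reject.all()
        assert rep.reject_reason == ["saccade", "gaze"]
        assert rep.trial_loss_fraction == 1.0

    def test_missing_veog_warns_and_skips_blinks(self):
        with pytest.warns(UserWarning, match="vEOG"):
            rep = pp.screen_artifacts(self._epochs(np.zeros((1, 1, 512))))
        assert rep.blink_segments == [[]]

    def test_recovers_injected_artifacts(self, default_observer):
        """Screening finds injected drift/muscle channels with sensitivity
        and specificity both at least 0.95 at default injection
        amplitudes."""
        fm = synth.make_forward_model(16)
        fm.artifact_injection = {"blink_prob": 0.0, "drift_prob": 0.15,
                                 "muscle_prob": 0.15}
        stim = synth.make_session_stimuli(synth.StimulusConfig(), 1, 120,
                                          rng=0)
        trials = synth.simulate_behaviour(default_observer, stim, 600.0,
                                          rng=np.random.default_rng(0))
        ep = synth.simulate_eeg(fm, trials, default_observer,
                                span_ms=(-600.0, 400.0),
                                inject_artifacts=True,
                                rng=np.random.default_rng(1))
        truth = ep.meta["artifact_truth"]
        rep = pp.screen_artifacts(ep, veog=ep.meta["veog"])
        injected = np.zeros((ep.n_trials, ep.n_channels), dtype=bool)
        for _, row in truth.iterrows():
            if row["kind"] in ("drift", "muscle"):
                injected[int(row["trial"]), int(row["channel"])] = True
        detected = rep.channel_flags["drift"] | rep.channel_flags["muscle"]
        sens = detected[injected].mean()
        spec = 1.0 - detected[~injected].mean()
        assert sens >= 0.95
        assert spec >= 0.95


class TestInterpolation:
    def test_inverse_distance_weighted_neighbours(self):
        from c1readout.containers import make_montage

        m = make_montage(16)
        rng = np.random.default_rng(0)
        data = rng.normal(size=(3, 16, 64))
        t = np.arange(64) * 1000.0 / FS
        e = EpochSet(data, t, FS, list(m.labels))
        out = pp.interpolate_channel(e, m, m.labels[5], k=4)
        neigh = m.nearest_neighbours(m.labels[5], 4)
        j = e.channel_index(neigh)
        # interpolated trace is a convex combination of the neighbours
        lo = data[:, j, :].min(axis=1)
        hi = data[:, j, :].max(axis=1)
        assert np.all(out.data[:, 5, :] >= lo - 1e-9)
        assert np.all(out.data[:, 5, :] <= hi + 1e-9)
        assert not np.allclose(out.data[:, 5, :], data[:, 5, :])
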