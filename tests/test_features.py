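"""C1 montage selection and measurement, STFT normalisation, and the
choice-predictive signal search."""

import numpy as np
import pandas as pd
import pytest

from c1readout import features as feat
from c1readout import synth
from c1readout.containers import EpochSet, make_montage

FS = 512.0


def _epochs(data, t0_ms=-600.0, labels=None, mask=None):
    t = t0_ms + np.arange(data.shape[2]) * 1000.0 / FS
    labels = labels or [f"ch{i}" for i in range(data.shape[1])]
    return EpochSet(data, t, FS, labels, mask=mask)


class TestC1Selection:
    def test_poles_match_forward_model_extrema(self, quiet_eeg):
        """On a near-noiseless easy block, the selected poles coincide with
        the extremes of the forward-model difference topography within the
        posterior pool."""
        fm, trials, epochs = quiet_eeg
        m = feat.select_c1_electrodes(epochs, trials, k_per_pole=2,
                                      montage=fm.montage)
        topo = fm.c1_topography_lower - fm.c1_topography_upper
        pool = fm.montage.posterior_pool()
        pool_idx = fm.montage.index(pool)
        order = np.argsort(topo[pool_idx])
        # the montage has exact left/right mirror ties, so demand the
        # unique extremum and containment in the tie-tolerant top set
        top_pos = {pool[i] for i in order[-4:]}      # lower-dominant sites
        top_neg = {pool[i] for i in order[:4]}
        assert pool[order[-1]] in m.pos_electrodes
        assert pool[order[0]] in m.neg_electrodes
        assert set(m.pos_electrodes) <= top_pos
        assert set(m.neg_electrodes) <= top_neg

    def test_identical_responses_raise_no_c1(self):
        data = np.zeros((10, 4, 512))
        trials = pd.DataFrame({"target": [0, 1] * 5})
        with pytest.raises(feat.NoC1Error):
            feat.select_c1_electrodes(_epochs(data), trials)

    def test_k_one_gives_one_electrode_per_pole(self, quiet_eeg):
        fm, trials, epochs = quiet_eeg
        m = feat.select_c1_electrodes(epochs, trials, k_per_pole=1,
                                      montage=fm.montage)
        assert len(m.pos_electrodes) == len(m.neg_electrodes) == 1


class TestMeasureC1:
    def test_bipolar_arithmetic(self):
        data = np.zeros((1, 2, 512))
        data[0, 0] = 2.0    # positive pole
        data[0, 1] = -1.0   # negative pole
        m = feat.C1Montage(["ch0"], ["ch1"])
        assert feat.measure_c1(_epochs(data), m)[0] == pytest.approx(3.0)

    def test_zero_epoch_gives_zero(self):
        m = feat.C1Montage(["ch0"], ["ch1"])
        assert feat.measure_c1(_epochs(np.zeros((2, 2, 512))), m)[0] == 0.0

    def test_linear_in_input(self):
        rng = np.random.default_rng(0)
        data = rng.normal(size=(5, 3, 512))
        m = feat.C1Montage(["ch0", "ch2"], ["ch1"])
        v1 = feat.measure_c1(_epochs(data), m)
        v2 = feat.measure_c1(_epochs(2.5 * data), m)
        assert np.allclose(v2, 2.5 * v1)

    def test_lower_target_is_positive_on_noiseless_synth(self, quiet_eeg):
        fm, trials, epochs = quiet_eeg
        m = feat.select_c1_electrodes(epochs, trials, montage=fm.montage)
        vals = feat.measure_c1(epochs, m)
        assert vals[trials["target"].to_numpy() == 0].mean() > 0
        assert vals[trials["target"].to_numpy() == 1].mean() < 0

    def test_fully_flagged_window_is_missing(self):
        data = np.ones((2, 2, 512))
        mask = np.zeros_like(data, dtype=bool)
        mask[0] = True      # trial 0: everything flagged
        e = _epochs(data, mask=mask)
        m = feat.C1Montage(["ch0"], ["ch1"])
        vals = feat.measure_c1(e, m)
        assert np.isnan(vals[0]) and np.isfinite(vals[1])

    def test_overlapping_poles_rejected(self):
        with pytest.raises(ValueError):
            feat.C1Montage(["ch0"], ["ch0"]).validate()


class TestStft:
    def test_amplitude_normalisation_identity(self):
        """A unit sinusoid at an exact bin frequency reads out magnitude
        1.0 after the divide-by-half-window normalisation."""
        n = 512
        t = np.arange(n) / FS
        n_win = int(round(0.4 * FS))            # 205 samples
        f_bin = 5 * FS / n_win                  # an exact bin, ~12.5 Hz
        data = np.sin(2 * np.pi * f_bin * t)[None, None, :]
        tf = feat.stft(_epochs(data))
        k = int(np.argmin(np.abs(tf.freqs_hz - f_bin)))
        assert tf.magnitudes[0, 0, k, :] == pytest.approx(1.0, abs=0.01)

    def test_twelve_analysis_frequencies_at_512hz(self):
        """400 ms at 512 Hz is a 205-sample window: bin spacing 2.4976 Hz,
        so 12 non-zero analysis frequencies fall at or below 30 Hz."""
        tf = feat.stft(_epochs(np.zeros((1, 1, 512))))
        assert len(tf.freqs_hz) == 12
        assert tf.freqs_hz[0] == pytest.approx(512 / 205, rel=1e-6)
        assert tf.freqs_hz[-1] <= 30.0

    def test_zero_signal_zero_magnitude_and_linearity(self):
        tf0 = feat.stft(_epochs(np.zeros((1, 1, 512))))
        assert np.all(tf0.magnitudes == 0)
        rng = np.random.default_rng(0)
        data = rng.normal(size=(2, 2, 512))
        a = feat.stft(_epochs(data)).magnitudes
        b = feat.stft(_epochs(3.0 * data)).magnitudes
        assert np.allclose(b, 3.0 * a)

    def test_epoch_shorter_than_window_rejected(self):
        with pytest.raises(ValueError):
            feat.stft(_epochs(np.zeros((1, 1, 100))))


class TestSignalSearch:
    def _alpha_dataset(self, alpha_gain, seed=0, n_participants=6,
                       n_trials=60):
        fm = synth.make_forward_model(64, noise_sd=2.0)
        frames, eps = [], []
        for p in range(n_participants):
            params = synth.ObserverParams(seed=seed + p)
            rng = np.random.default_rng(seed + p)
            stim = synth.make_session_stimuli(synth.StimulusConfig(dc=0.006),
                                              1, n_trials, rng=rng)
            tt = synth.simulate_behaviour(params, stim, 600.0, rng=rng)
            tt["participant"] = p
            ep = synth.simulate_eeg(fm, tt, params, span_ms=(-600.0, 400.0),
                                    rng=rng, alpha_gain=alpha_gain)
            frames.append(tt)
            eps.append(ep.data)
        trials = pd.concat(frames, ignore_index=True)
        epochs = EpochSet(np.concatenate(eps), eps and ep.time_ms, ep.fs,
                          list(fm.montage.labels))
        return fm, trials, epochs

    def test_recovers_injected_alpha_lateralisation(self):
        """The TF search finds a pre-target cluster overlapping the alpha
        band and the occipital electrodes where lateralised 10 Hz power
        was injected."""
        fm, trials, epochs = self._alpha_dataset(alpha_gain=1.8, seed=3)
        tf = feat.stft(epochs)
        found = feat.search_choice_signals(trials, tf=tf,
                                           channel_labels=epochs.channel_labels)
        assert found, "no TF signal recovered"
        occ = set(fm.montage.occipital_pool("left")
                  + fm.montage.occipital_pool("right"))
        hits = [s for s in found
                if s.f_lo_hz <= 10.0 <= s.f_hi_hz + 2.5
                and set(s.electrodes) & occ
                and s.t_start_ms < 0]
        assert hits

    def test_zero_noise_zero_effect_is_empty(self):
        trials = pd.DataFrame({"choice": [0, 1] * 20,
                               "participant": [0] * 20 + [1] * 20})
        epochs = _epochs(np.zeros((40, 4, 512)))
        assert feat.search_choice_signals(trials, epochs=epochs) == []

    def test_time_translation_equivariance(self):
        """Shifting the data in time shifts the recovered window by the
        same amount (within sample resolution)."""
        rng = np.random.default_rng(1)
        n_tr, n_ch, n_s = 40, 4, 512
        trials = pd.DataFrame({"choice": [0, 1] * 20,
                               "participant": [0] * 20 + [1] * 20})
        base = rng.normal(size=(n_tr, n_ch, n_s)) * 0.05
        effect = np.zeros((n_tr, n_ch, n_s))
        win = slice(250, 290)
        effect[np.asarray(trials["choice"]) == 1, 0:2, win] = 1.0
        shifted = np.roll(base + effect, 30, axis=2)
        s0 = feat.search_choice_signals(trials, epochs=_epochs(base + effect))
        s1 = feat.search_choice_signals(trials, epochs=_epochs(shifted))
        assert s0 and s1
        delta = 30 * 1000.0 / FS
        assert s1[0].t_start_ms - s0[0].t_start_ms == pytest.approx(
            delta, abs=1000.0 / FS)


class TestExtractCovariates:
    def test_single_point_signal_is_raw_value(self):
        data = np.arange(8, dtype=float).reshape(2, 2, 2)
        e = _epochs(data, t0_ms=0.0)
        s = feat.ChoiceSignal("x", ["ch1"], t_start_ms=0.0, t_end_ms=0.0)
        trials = pd.DataFrame(index=range(2))
        vals = feat.extract_covariates(trials, [s], epochs=e)
        assert vals["x"].tolist() == [2.0, 6.0]

    def test_flagged_window_gives_missing(self):
        data = np.ones((2, 1, 512))
        mask = np.zeros_like(data, dtype=bool)
        mask[1] = True
        e = _epochs(data, mask=mask)
        s = feat.ChoiceSignal("x", ["ch0"], t_start_ms=0.0, t_end_ms=50.0)
        vals = feat.extract_covariates(pd.DataFrame(index=range(2)), [s],
                                       epochs=e)
        assert np.isfinite(vals["x"][0]) and np.isnan(vals["x"][1])

    def test_lateralised_contrast_sign(self):
        m = make_montage(64)
        left = m.occipital_pool("left")
        right = m.occipital_pool("right")
        data = np.zeros((1, 64, 512))
        data[0, m.index(left), :] = 2.0
        data[0, m.index(right), :] = 0.5
        e = _epochs(data, labels=list(m.labels))
        s = feat.ChoiceSignal("lat", left + right, t_start_ms=-100.0,
                              t_end_ms=0.0, contrast="left_minus_right")
        vals = feat.extract_covariates(pd.DataFrame(index=[0]), [s],
                                       epochs=e, montage=m)
        assert vals["lat"][0] == pytest.approx(1.5)
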