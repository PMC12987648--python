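import numpy as np
import pandas as pd
import pytest

from c1readout import synth


@pytest.fixture(scope="session")
def default_observer():
    return synth.ObserverParams(seed=1)


@pytest.fixture(scope="session")
def big_trials(default_observer):
    """20,000 trials from the default observer under the 600 ms deadline
    (used by the conditional-accuracy and behavioural-recovery checks)."""
    stim = synth.make_session_stimuli(synth.StimulusConfig(dc=0.02),
                                      n_blocks=160, trials_per_block=125,
                                      rng=3)
    return synth.simulate_behaviour(default_observer, stim, 600.0,
                                    rng=np.random.default_rng(3))


@pytest.fixture(scope="session")
def both_deadline_trials(default_observer):
    """Default session structure under both deadlines, pooled, with
    participant ids for the mixed models."""
    frames = []
    for p in range(3):
        for deadline in (400.0, 600.0):
            k = 10 * p + int(deadline)
            stim = synth.make_session_stimuli(
                synth.StimulusConfig(dc=0.02), n_blocks=10,
                trials_per_block=120, rng=k)
            tt = synth.simulate_behaviour(default_observer, stim, deadline,
                                          rng=np.random.default_rng(k))
            tt["participant"] = p
            frames.append(tt)
    return pd.concat(frames, ignore_index=True)


@pytest.fixture(scope="session")
def small_forward_model():
    return synth.make_forward_model(64)


@pytest.fixture(scope="session")
def quiet_eeg(small_forward_model, default_observer):
    """Near-noiseless easy-block EEG (both target locations), for
    sign-convention and electrode-selection ground-truth checks."""
    fm = synth.make_forward_model(64, noise_sd=0.05)
    stim = synth.make_session_stimuli(synth.StimulusConfig(dc=0.30), 1, 80,
                                      rng=5)
    trials = synth.simulate_behaviour(default_observer, stim, 600.0,
                                      rng=np.random.default_rng(5))
    trials["participant"] = 0
    epochs = synth.simulate_eeg(fm, trials, default_observer, fs=512.0,
                                span_ms=(-600.0, 400.0), alpha_gain=0.0,
                                alpha_base=0.0,
                                rng=np.random.default_rng(5))
    return fm, trials, epochs
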