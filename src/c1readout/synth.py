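"""Synthetic stimuli, behaviour and EEG with the statistical structure the
analysis assumes.

The task being emulated: two 9x9 arrays of gratings flash briefly in the
upper-left and lower-right visual quadrants; the observer reports which array
had higher mean contrast under a 400 or 600 ms response deadline.  Mean
contrast over both arrays is 60%, with one array incremented and the other
decremented by the differential contrast DC (plus a signed bias term),
titrated so that accuracy sits near 55%.

The observer is a two-stage bounded accumulator: a transient early sensory
sample enters the decision variable at ~80 ms (the latency of the earliest
cortical visual response), sustained evidence-dependent drift begins at
~150 ms, the decision bound collapses under the deadline, and a Gaussian
motor delay separates bound crossing from the button press.  The noise in
the early sample is shared with the simulated C1 amplitude, which is what
creates choice probability by construction: the C1 predicts choice beyond
the physical stimulus exactly insofar as the early sample is read out.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import EpochSet, Montage, make_montage

JITTER_VALUES = np.round(np.arange(-0.20, 0.2001, 0.05), 10)  # 9 values


# ===================================================================== stimuli
@dataclass
class StimulusConfig:
    """Contrast layout of one trial: two 9x9 grating arrays.

    ``dc`` is the differential contrast: the target array mean is
    ``base_contrast + adj`` and the other ``base_contrast - adj`` where
    ``adj = dc + bias`` for upper-field targets and ``dc - bias`` for
    lower-field targets (the bias term is added to DC to make the task
    harder or easier depending on target direction).  Within each array a
    fixed multiset of deviations (+-20% in 5% steps, each value 9 times)
    is spatially shuffled; the deviations sum exactly to zero so the grand
    mean over both arrays is exactly ``base_contrast`` on every trial.
    """

    dc: float = 0.02
    bias: float = 0.0
    base_contrast: float = 0.60
    jitter_values: np.ndarray = field(
        default_factory=lambda: JITTER_VALUES.copy())
    grid: tuple[int, int] = (9, 9)

    def validate(self) -> None:
        vals = np.asarray(self.jitter_values, dtype=float)
        if vals.size != 9 or not np.allclose(np.diff(vals), 0.05):
            raise ValueError("jitter_values must be 9 values in 5% steps")
        if abs(vals.sum()) > 1e-12:
            raise ValueError("jitter values must sum to zero")
        adj = abs(self.dc) + abs(self.bias)
        lo = self.base_contrast - adj + vals.min()
        hi = self.base_contrast + adj + vals.max()
        if lo < 0.0 or hi > 1.0:
            raise ValueError(
                f"contrast range [{lo:.3f}, {hi:.3f}] leaves [0, 1]")

    def adjusted_dc(self, target: int) -> float:
        """Effective differential contrast for a given target location
        (1 = upper, 0 = lower)."""
        return self.dc + self.bias if target == 1 else self.dc - self.bias


def _jitter_grid(cfg: StimulusConfig, rng: np.random.Generator) -> np.ndarray:
    """9x9 deviation grid: each column holds a shuffled copy of the jitter
    values and the columns are presented in random order, so every column is
    a permutation of the full multiset and the grid sums exactly to zero."""
    n_ecc, n_ang = cfg.grid
    cols = [rng.permutation(cfg.jitter_values) for _ in range(n_ang)]
    grid = np.stack(cols, axis=1)
    return grid[:, rng.permutation(n_ang)]


def generate_stimulus_trial(cfg: StimulusConfig, target: int,
                            rng: np.random.Generator | int,
                            ) -> tuple[np.ndarray, np.ndarray]:
    """One trial's contrast matrices ``(upper, lower)``.

    ``target`` is 1 for an upper-field target (upper array is the
    higher-contrast one) and 0 for a lower-field target.
    """
    cfg.validate()
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) \
        else rng
    adj = cfg.adjusted_dc(target)
    sign = 1.0 if target == 1 else -1.0
    upper = cfg.base_contrast + sign * adj + _jitter_grid(cfg, rng)
    lower = cfg.base_contrast - sign * adj + _jitter_grid(cfg, rng)
    if upper.min() < 0 or upper.max() > 1 or lower.min() < 0 or lower.max() > 1:
        raise ValueError("contrast out of [0, 1]; reduce dc/bias/jitter")
    return upper, lower


# ==================================================================== observer
@dataclass
class ObserverParams:
    """Two-stage bounded-accumulator observer.

    Latencies in ms; evidence is the signed mean-contrast difference
    (upper minus lower, positive favouring 'upper' reports).  The bound
    collapses linearly, reaching zero at ``deadline / urgency_slope`` ms so
    that a response is always produced; the shorter deadline therefore
    truncates accumulation earlier, reproducing the speed-accuracy
    trade-off between the two deadline regimes.
    """

    early_latency: float = 80.0
    late_latency: float = 150.0
    early_gain: float = 6.0          # bound units per unit contrast diff
    early_noise_sd: float = 0.5      # sd of the transient early sample
    late_gain: float = 25.0          # drift, bound units / s / contrast diff
    late_noise_sd: float = 0.6       # diffusion sd, bound units / sqrt(s)
    start_sd: float = 0.40           # start-point variability
    bound: float = 1.0
    urgency_slope: float = 1.25      # bound collapses to 0 at deadline/slope
    motor_delay_mean: float = 110.0  # ms
    motor_delay_sd: float = 18.0
    history_bias: float = 0.25       # start-point push toward switching
    c1_gain: float = 5.0             # µV per unit (lower - upper) contrast
    c1_noise_sd: float = 0.8         # µV, C1 noise independent of decision
    shared_noise_gain: float = 1.0   # coupling of early-sample noise into C1
    seed: int = 0

    def validate(self) -> None:
        if min(self.early_latency, self.late_latency) < 0:
            raise ValueError("latencies must be non-negative")
        if min(self.early_noise_sd, self.late_noise_sd) <= 0:
            raise ValueError("noise SDs must be positive")


def simulate_behaviour(params: ObserverParams, stimuli: pd.DataFrame,
                       deadline: float, rng: np.random.Generator | None = None,
                       dt_ms: float = 2.0) -> pd.DataFrame:
    """Simulate choices and RTs for a sequence of trials.

    ``stimuli`` needs columns ``target`` (1 upper / 0 lower) and ``delta_c``
    (signed upper-minus-lower mean-contrast difference).  Returns the trial
    table with choice, RT, correctness, previous choice, plus the latent
    ``early_noise`` sample and single-trial ``c1`` amplitude (µV) whose
    choice covariation is inherited from the shared early noise.
    """
    params.validate()
    if len(stimuli) == 0:
        raise ValueError("empty trial sequence")
    rng = np.random.default_rng(params.seed) if rng is None else rng
    n = len(stimuli)
    delta = stimuli["delta_c"].to_numpy(dtype=float)
    target = stimuli["target"].to_numpy(dtype=int)

    t_collapse = deadline / params.urgency_slope
    n_steps = int(np.ceil(t_collapse / dt_ms)) + 1
    t_grid = np.arange(n_steps) * dt_ms
    bound_t = np.maximum(
        0.0, params.bound * (1.0 - params.urgency_slope * t_grid / deadline))
    dt_s = dt_ms / 1000.0
    i_early = int(np.round(params.early_latency / dt_ms))
    i_late = int(np.round(params.late_latency / dt_ms))

    eps_early = rng.normal(0.0, params.early_noise_sd, size=n)
    start_noise = rng.normal(0.0, params.start_sd, size=n)
    motor = rng.normal(params.motor_delay_mean, params.motor_delay_sd, size=n)
    diffusion = rng.normal(0.0, params.late_noise_sd * np.sqrt(dt_s),
                           size=(n, n_steps))
    c1_noise = rng.normal(0.0, params.c1_noise_sd, size=n)

    choice = np.zeros(n, dtype=int)
    rt = np.zeros(n)
    prev_choice = np.zeros(n, dtype=int)
    prev = int(rng.integers(0, 2))  # unobserved trial before the first

    drift = params.late_gain * delta * dt_s
    for i in range(n):
        inc = diffusion[i].copy()
        inc[i_late:] += drift[i]
        inc[0] = start_noise[i] - params.history_bias * (2 * prev - 1)
        if i_early < n_steps:
            inc[i_early] += params.early_gain * delta[i] + eps_early[i]
        acc = np.cumsum(inc)
        crossed = np.abs(acc) >= bound_t
        idx = int(np.argmax(crossed))  # first True; bound hits 0 so one exists
        choice[i] = 1 if acc[idx] > 0 else 0
        rt[i] = t_grid[idx] + motor[i]
        prev_choice[i] = prev
        prev = choice[i]

    out = stimuli.copy()
    out["deadline_ms"] = float(deadline)
    out["choice"] = choice
    out["rt_ms"] = rt
    out["correct"] = (choice == target).astype(int)
    out["prev_choice"] = prev_choice
    out["early_noise"] = eps_early
    # C1 amplitude: positive pole tracks the lower array, so the stimulus
    # term is -delta; the shared early-sample noise enters congruently
    # (noise pushing the choice toward 'upper' makes the C1 more negative).
    out["c1"] = (-params.c1_gain * delta
                 - params.shared_noise_gain * eps_early + c1_noise)
    out["excluded"] = False
    return out


def make_session_stimuli(cfg: StimulusConfig, n_blocks: int = 10,
                         trials_per_block: int = 120,
                         rng: np.random.Generator | int = 0) -> pd.DataFrame:
    """Balanced trial list for one deadline session: targets alternate in a
    shuffled balanced order within each block (600 trials per target at the
    default 10 x 120 structure)."""
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) \
        else rng
    rows = []
    for b in range(n_blocks):
        targets = np.repeat([0, 1], trials_per_block // 2)
        rng.shuffle(targets)
        for t in targets:
            adj = cfg.adjusted_dc(int(t))
            sign = 1.0 if t == 1 else -1.0
            rows.append((b, int(t), 2 * sign * adj))
    return pd.DataFrame(rows, columns=["block", "target", "delta_c"])


# =================================================================== titration
def block_score(n_correct_timely: int, n_other: int) -> int:
    """Block feedback score: 10 points per correct, timely response and
    -7 for every other trial."""
    return 10 * n_correct_timely - 7 * n_other


@dataclass
class TitrationResult:
    dc: float
    bias: float
    accuracy: float
    converged: bool
    n_blocks: int
    block_scores: list[int]


def titrate_difficulty(params: ObserverParams, target_accuracy: float = 0.55,
                       block_size: int = 120, max_blocks: int = 40,
                       deadline: float = 600.0, tol: float = 0.015,
                       rng: np.random.Generator | None = None,
                       ) -> TitrationResult:
    """Automated stand-in for the experimenter's titration loop.

    Runs ``max_blocks`` short blocks, lowering DC when block accuracy
    overshoots the target and raising it when it undershoots
    (multiplicative Robbins-Monro steps with a decaying rate), while
    nudging the bias term against any choice imbalance.  The returned
    calibration is the Polyak average over the latter half of the
    trajectory — log-DC oscillates around the solution there, and
    averaging removes both the noise of any single block and the upward
    bias a stop-at-first-hit rule would inherit from the one-sided
    approach.  ``converged`` reports whether the averaged accuracy landed
    within ``tol`` of the target.
    """
    if not 0.5 < target_accuracy < 1.0:
        raise ValueError("target accuracy must be in (0.5, 1)")
    rng = np.random.default_rng(params.seed + 101) if rng is None else rng
    dc, bias = 0.05, 0.0
    scores: list[int] = []
    history: list[tuple[float, float, float]] = []    # (dc, bias, acc)
    for b in range(max_blocks):
        cfg = StimulusConfig(dc=dc, bias=bias)
        stim = make_session_stimuli(cfg, n_blocks=1,
                                    trials_per_block=block_size, rng=rng)
        tt = simulate_behaviour(params, stim, deadline, rng=rng)
        acc = tt["correct"].mean()
        timely = tt["rt_ms"] <= deadline
        n_ct = int((tt["correct"].astype(bool) & timely).sum())
        scores.append(block_score(n_ct, len(tt) - n_ct))
        history.append((dc, bias, acc))
        step = 3.0 / np.sqrt(b + 1)
        dc = float(np.clip(dc * np.exp(-step * (acc - target_accuracy)),
                           1e-4, 0.18))
        p_upper = tt["choice"].mean()
        bias = float(np.clip(bias - 0.2 * (p_upper - 0.5) * dc, -0.05, 0.05))
    tail = history[max_blocks // 2:]
    dc_hat = float(np.exp(np.mean([np.log(h[0]) for h in tail])))
    bias_hat = float(np.mean([h[1] for h in tail]))
    acc_hat = float(np.mean([h[2] for h in tail]))
    converged = abs(acc_hat - target_accuracy) <= tol
    if not converged:
        warnings.warn("titration did not converge; returning the averaged "
                      "trajectory anyway")
    return TitrationResult(dc_hat, bias_hat, acc_hat, converged,
                           max_blocks, scores)


# ======================================================== transient readout CP
def simulate_transient_readout(readout_weight_early: float = 1.0,
                               dilution_rate: float = 1.0,
                               n_trials: int = 100_000,
                               seed: int = 0, n_bins: int = 12,
                               ) -> pd.DataFrame:
    """Choice probability versus RT for a decision fed by one transient
    early sensory sample plus ongoing late evidence.

    The stimulus is held ambiguous (zero net evidence) so that any
    association between the early sample and the choice is choice
    probability by construction.  A fraction of trials are fast guesses
    (random choice before the evidence arrives, giving chance CP in the
    fastest bins); in the rest a bounded accumulator receives the early
    sample at 80 ms plus ongoing late evidence whose magnitude is set by
    ``dilution_rate``.  At intermediate RTs the early sample dominates; at
    long RTs accumulated late evidence dilutes it.  Returns CP per RT bin:
    the probability that the choice agrees with the sign of the early
    sample.
    """
    if n_trials < 1000:
        raise ValueError("n_trials must be at least 1000")
    rng = np.random.default_rng(seed)
    dt_ms, t_early, deadline = 2.0, 80.0, 600.0
    params_bound, urgency, guess_prob = 1.0, 1.25, 0.15
    t_collapse = deadline / urgency
    n_steps = int(np.ceil(t_collapse / dt_ms)) + 1
    t_grid = np.arange(n_steps) * dt_ms
    bound_t = np.maximum(0.0, params_bound * (1 - urgency * t_grid / deadline))
    dt_s = dt_ms / 1000.0

    s_early = rng.normal(0.0, 1.0, size=n_trials)
    inc = rng.normal(0.0, dilution_rate * np.sqrt(dt_s),
                     size=(n_trials, n_steps)) if dilution_rate > 0 else \
        np.zeros((n_trials, n_steps))
    inc[:, int(t_early / dt_ms)] += readout_weight_early * s_early
    acc = np.cumsum(inc, axis=1)
    crossed = np.abs(acc) >= bound_t[None, :]
    idx = np.argmax(crossed, axis=1)
    final = np.take_along_axis(acc, idx[:, None], axis=1)[:, 0]
    # ties (zero accumulator at collapse) resolve at random
    choice = np.where(final == 0.0, rng.random(n_trials) < 0.5, final > 0)
    rt = t_grid[idx] + rng.normal(100.0, 18.0, size=n_trials)
    guess = rng.random(n_trials) < guess_prob
    choice = np.where(guess, rng.random(n_trials) < 0.5, choice)
    rt = np.where(guess, rng.uniform(60.0, t_early + 60.0, size=n_trials)
                  + rng.normal(40.0, 10.0, size=n_trials), rt)

    edges = np.quantile(rt, np.linspace(0, 1, n_bins + 1))
    bin_id = np.clip(np.searchsorted(edges, rt, side="right") - 1,
                     0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        m = bin_id == b
        agree = (choice[m] == (s_early[m] > 0)).mean()
        rows.append((0.5 * (edges[b] + edges[b + 1]), float(agree),
                     int(m.sum())))
    return pd.DataFrame(rows, columns=["rt_ms", "cp", "n"])


# =============================================================== forward model
@dataclass
class ForwardModel:
    """Maps latent trial variables onto the scalp.

    Topographies are unit-normalised per-channel weight vectors; the upper-
    and lower-field C1 topographies have a negative inner product (the C1
    polarity inversion across the horizontal meridian).  Background noise is
    1/f with the given spectral exponent.
    """

    montage: Montage
    c1_topography_upper: np.ndarray
    c1_topography_lower: np.ndarray
    cpp_topography: np.ndarray
    alpha_topography_left: np.ndarray
    alpha_topography_right: np.ndarray
    noise_spectrum_exponent: float = 1.0
    noise_sd: float = 8.0            # µV per channel
    cpp_channel: str = ""            # ground-truth CPP site
    artifact_injection: dict = field(default_factory=dict)

    def validate(self) -> None:
        if float(self.c1_topography_upper @ self.c1_topography_lower) >= 0:
            raise ValueError("C1 topographies must have opposite polarity")


def _gauss_topo(montage: Montage, centre: tuple[float, float],
                width: float = 0.35, sign: float = 1.0) -> np.ndarray:
    d2 = np.sum((montage.positions - np.asarray(centre)) ** 2, axis=1)
    w = sign * np.exp(-d2 / (2 * width ** 2))
    return w / np.linalg.norm(w)


def make_forward_model(n_channels: int = 128,
                       noise_sd: float = 8.0) -> ForwardModel:
    """Default forward model on the synthetic cap.

    The upper-field C1 projects negatively and the lower-field C1 positively
    onto overlapping posterior-midline sites (slightly offset so the
    difference topography has two poles); the CPP sits on the centroparietal
    midline, and pre-stimulus alpha generators sit over left/right occipital
    cortex.
    """
    m = make_montage(n_channels)
    # each field's C1 is dipolar on the scalp (main lobe plus an opposite-
    # sign counter-lobe nearer the occipital rim), so the upper-minus-lower
    # difference topography has a positive and a negative posterior pole
    upper = _gauss_topo(m, (0.0, -0.45), 0.28, sign=-1.0) \
        + 0.8 * _gauss_topo(m, (0.0, -0.85), 0.28, sign=+1.0)
    upper /= np.linalg.norm(upper)
    lower = _gauss_topo(m, (0.0, -0.40), 0.28, sign=+1.0) \
        + 0.8 * _gauss_topo(m, (0.0, -0.80), 0.28, sign=-1.0)
    lower /= np.linalg.norm(lower)
    cpp = _gauss_topo(m, (0.0, -0.18), 0.28, sign=+1.0)
    cpp_channel = m.labels[int(np.argmax(cpp))]
    left = _gauss_topo(m, (-0.55, -0.60), 0.30, sign=+1.0)
    right = _gauss_topo(m, (0.55, -0.60), 0.30, sign=+1.0)
    fm = ForwardModel(m, upper, lower, cpp, left, right,
                      noise_spectrum_exponent=1.0, noise_sd=noise_sd,
                      cpp_channel=cpp_channel)
    fm.validate()
    return fm


def _one_over_f(rng: np.random.Generator, shape: tuple[int, ...],
                n_samples: int, fs: float, exponent: float,
                sd: float) -> np.ndarray:
    """EEG-like Gaussian background noise scaled to ``sd`` µV.

    Power falls as 1/f^exponent with a ~1 Hz knee (the spectrum does not
    diverge at DC), carries a broad alpha bump around 10 Hz, and rolls off
    more steeply above ~15 Hz — the gross shape of resting scalp spectra.
    Shaped ``shape + (n_samples,)``."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    scale = np.zeros_like(freqs)
    f = freqs[1:]
    scale[1:] = (f + 1.0) ** (-exponent / 2.0) \
        * (1.0 + 1.5 * np.exp(-(f - 10.0) ** 2 / 8.0))
    hi = freqs > 15.0
    scale[hi] *= (freqs[hi] / 15.0) ** -0.75
    white = rng.normal(size=shape + (n_samples,))
    spec = np.fft.rfft(white, axis=-1) * scale
    x = np.fft.irfft(spec, n=n_samples, axis=-1)
    x *= sd / x.std()
    return x


def simulate_eeg(fm: ForwardModel, trials: pd.DataFrame,
                 params: ObserverParams, fs: float = 512.0,
                 span_ms: tuple[float, float] = (-600.0, 400.0),
                 inject_artifacts: bool = False,
                 rng: np.random.Generator | None = None,
                 alpha_gain: float = 1.5, alpha_base: float = 2.0,
                 cpp_gain: float = 100.0, cpp_base: float = 0.25
                 ) -> EpochSet:
    """Target-locked epochs containing the four structured components.

    * C1: 80-90 ms transient along the differential (lower-minus-upper)
      topography with the trial's single-trial ``c1`` amplitude;
    * CPP: centroparietal ramp whose slope is evidence-magnitude-dependent
      from ``late_latency`` onward, peaking at the response;
    * pre-target 10 Hz alpha, lower over the hemisphere contralateral to the
      upcoming choice (upper-left array -> right hemisphere);
    * 1/f background noise, plus optional blink / drift / muscle artifacts
      with ground-truth labels in ``meta['artifact_truth']`` and a vEOG
      trace in ``meta['veog']``.

    Requires ``trials`` to carry ``c1``, ``delta_c``, ``choice``, ``rt_ms``.
    """
    if fs < 256:
        raise ValueError("fs must be at least 256 Hz")
    fm.validate()
    rng = np.random.default_rng(params.seed + 7) if rng is None else rng
    n = len(trials)
    t0, t1 = span_ms
    n_samples = int(round((t1 - t0) * fs / 1000.0))
    time_ms = t0 + np.arange(n_samples) * 1000.0 / fs
    n_ch = len(fm.montage.labels)

    # background noise: largely spatially structured (volume conduction),
    # so referenced/bipolar derivations cancel much of it, plus an
    # independent per-channel component; per-channel sd ~= noise_sd
    sd = fm.noise_sd
    data = _one_over_f(rng, (n, n_ch), n_samples, fs,
                       fm.noise_spectrum_exponent, sd * np.sqrt(0.4))
    data += _one_over_f(rng, (n,), n_samples, fs,
                        fm.noise_spectrum_exponent,
                        sd * np.sqrt(0.3))[:, None, :]
    for _ in range(3):
        centre = rng.uniform(-0.8, 0.8, size=2)
        width = rng.uniform(0.5, 0.9)
        pattern = np.exp(-np.sum((fm.montage.positions - centre) ** 2,
                                 axis=1) / (2 * width ** 2))
        ts = _one_over_f(rng, (n,), n_samples, fs,
                         fm.noise_spectrum_exponent, sd * np.sqrt(0.1))
        data += pattern[None, :, None] * ts[:, None, :]

    # C1 transient: raised-cosine bump spanning ~70-100 ms, unit peak at 85.
    kern = np.zeros(n_samples)
    in_bump = (time_ms >= 70) & (time_ms <= 100)
    kern[in_bump] = 0.5 * (1 - np.cos(2 * np.pi * (time_ms[in_bump] - 70)
                                      / 30.0))
    topo_diff = fm.c1_topography_lower - fm.c1_topography_upper
    topo_diff = topo_diff / np.linalg.norm(topo_diff)
    c1_amp = trials["c1"].to_numpy(dtype=float)
    data += c1_amp[:, None, None] * topo_diff[None, :, None] * kern[None, None, :]

    # CPP: ramps from late_latency to the response, then decays.  The base
    # slope is evidence-independent (accumulation starts regardless);
    # evidence strength |delta_c| steepens it.
    rt = trials["rt_ms"].to_numpy(dtype=float)
    slope = cpp_gain * (cpp_base + np.abs(trials["delta_c"].to_numpy(float)))
    tt = time_ms[None, :]
    rise = np.clip((tt - params.late_latency) / 1000.0, 0.0, None)
    capped = np.minimum(rise, np.clip((rt[:, None] - params.late_latency),
                                      0, None) / 1000.0)
    decay = np.exp(-np.clip(tt - rt[:, None], 0, None) / 150.0)
    cpp_tc = slope[:, None] * capped * decay  # µV (gain in µV/s per unit)
    data += cpp_tc[:, None, :] * fm.cpp_topography[None, :, None]

    # Pre-target alpha: amplitude lower contralateral to the upcoming choice.
    choice = trials["choice"].to_numpy(dtype=int)
    pre = (time_ms < 0).astype(float)
    fade = np.clip(1.0 - time_ms / 150.0, 0.0, 1.0)
    envelope = np.maximum(pre, (time_ms >= 0) * fade)
    phase = rng.uniform(0, 2 * np.pi, size=n)
    osc = np.sin(2 * np.pi * 10.0 * time_ms[None, :] / 1000.0
                 + phase[:, None]) * envelope[None, :]
    amp_right = alpha_base - alpha_gain * choice   # chose upper -> right low
    amp_left = alpha_base - alpha_gain * (1 - choice)
    data += (amp_right[:, None, None] * fm.alpha_topography_right[None, :, None]
             + amp_left[:, None, None] * fm.alpha_topography_left[None, :, None]
             ) * osc[:, None, :]

    veog = _one_over_f(rng, (n,), n_samples, fs, 1.0, 5.0)
    truth_rows = []
    if inject_artifacts:
        spec = {"blink_prob": 0.10, "blink_amp": 150.0,
                "drift_prob": 0.05, "drift_amp": 60.0,
                "muscle_prob": 0.05, "muscle_amp": 25.0}
        spec.update(fm.artifact_injection)
        frontal = _gauss_topo(fm.montage, (0.0, 0.85), 0.35, +1.0)
        for i in range(n):
            if rng.random() < spec["blink_prob"]:
                onset = rng.uniform(t0 + 100, t1 - 250)
                dur = rng.uniform(120, 200)
                seg = (time_ms >= onset) & (time_ms <= onset + dur)
                pulse = np.sin(np.pi * (time_ms[seg] - onset) / dur) ** 2
                veog[i, seg] += spec["blink_amp"] * pulse
                data[i] += 0.35 * spec["blink_amp"] * frontal[:, None] \
                    * np.where(seg, np.sin(np.pi * np.clip(
                        (time_ms - onset) / dur, 0, 1)) ** 2, 0.0)[None, :]
                truth_rows.append((i, -1, "blink", onset, onset + dur))
            if rng.random() < spec["drift_prob"]:
                ch = int(rng.integers(0, n_ch))
                f_d = rng.uniform(0.5, 1.5)
                data[i, ch] += spec["drift_amp"] * np.sin(
                    2 * np.pi * f_d * (time_ms - t0) / 1000.0
                    + rng.uniform(0, 2 * np.pi))
                truth_rows.append((i, ch, "drift", t0, t1))
            if rng.random() < spec["muscle_prob"]:
                ch = int(rng.integers(0, n_ch))
                f_m = rng.uniform(25, 38)
                data[i, ch] += spec["muscle_amp"] * np.sin(
                    2 * np.pi * f_m * (time_ms - t0) / 1000.0)
                truth_rows.append((i, ch, "muscle", t0, t1))

    truth = pd.DataFrame(truth_rows, columns=["trial", "channel", "kind",
                                              "t_start_ms", "t_end_ms"])
    ep = EpochSet(data=data, time_ms=time_ms, fs=fs,
                  channel_labels=list(fm.montage.labels),
                  meta={"seed": params.seed, "span_ms": list(span_ms)})
    ep.meta["veog"] = veog
    ep.meta["artifact_truth"] = truth
    return ep


def simulate_cpp_divergence_dataset(n_participants: int = 18,
                                    n_per_condition: int = 100,
                                    divergence_ms: float = 150.0,
                                    slope_easy: float = 40.0,
                                    slope_hard: float = 16.0,
                                    rt_mean: float = 330.0,
                                    rt_sd: float = 25.0,
                                    noise_sd: float = 3.0,
                                    fs: float = 256.0,
                                    seed: int = 0
                                    ) -> tuple[EpochSet, pd.DataFrame]:
    """Single-channel ground-truth dataset for the buildup-onset estimator.

    Both conditions share one RT distribution (so the response-locked
    comparison isolates the slope difference): each trial's waveform ramps
    from ``divergence_ms`` post-stimulus to the response at the condition
    slope (µV/s), then decays, on top of 1/f noise.  The stimulus-locked
    divergence time is exactly ``divergence_ms``, giving the estimator a
    known recovery target."""
    rng = np.random.default_rng(seed)
    span = (-600.0, 800.0)
    n_samples = int(round((span[1] - span[0]) * fs / 1000.0))
    time_ms = span[0] + np.arange(n_samples) * 1000.0 / fs
    data, rows = [], []
    for p in range(n_participants):
        for cond, slope in (("easy", slope_easy), ("hard", slope_hard)):
            rt = np.clip(rng.normal(rt_mean, rt_sd, size=n_per_condition),
                         divergence_ms + 60, 580.0)
            noise = _one_over_f(rng, (n_per_condition,), n_samples, fs,
                                1.0, noise_sd)
            rise = np.clip((time_ms[None, :] - divergence_ms) / 1000.0,
                           0.0, None)
            capped = np.minimum(rise, (rt[:, None] - divergence_ms) / 1000.0)
            decay = np.exp(-np.clip(time_ms[None, :] - rt[:, None], 0, None)
                           / 150.0)
            data.append(noise + slope * capped * decay)
            for r in rt:
                rows.append((p, cond, float(r)))
    trials = pd.DataFrame(rows, columns=["participant", "condition",
                                         "rt_ms"])
    ep = EpochSet(np.concatenate(data)[:, None, :], time_ms, fs, ["CPP"],
                  meta={"divergence_ms": divergence_ms, "seed": seed})
    return ep, trials


# =========================================== direct covariate-level injection
def simulate_c1_dataset(n_participants: int = 18, n_trials: int = 1200,
                        coupling: float = 0.5,
                        band_ms: tuple[float, float] | None = (250.0, 380.0),
                        params: ObserverParams | None = None,
                        dc: float = 0.012, seed: int = 0) -> pd.DataFrame:
    """Multi-participant trial table with a C1-choice coupling confined to
    an RT band.

    Behaviour comes from the bounded-accumulator observer (with the shared
    early noise removed from the C1 so the stimulus-driven part stays);
    a controlled choice-congruent C1 component of ``coupling`` (in C1 noise
    SD units, negative-going for upper choices) is then added only on trials
    whose RT falls inside ``band_ms``.  This gives band-limited choice
    probability with known edges for parameter-recovery experiments.
    ``band_ms=None`` injects nothing (a null dataset)."""
    rows = []
    for p in range(n_participants):
        pars = replace(params or ObserverParams(), seed=seed + 1000 * p,
                       shared_noise_gain=0.0)
        rng = np.random.default_rng(seed + 1000 * p)
        cfg = StimulusConfig(dc=dc)
        n_blocks = max(1, n_trials // 120)
        stim = make_session_stimuli(cfg, n_blocks=n_blocks,
                                    trials_per_block=n_trials // n_blocks,
                                    rng=rng)
        deadline = 600.0 if p % 2 else 400.0
        tt = simulate_behaviour(pars, stim, deadline, rng=rng)
        if band_ms is not None and coupling != 0.0:
            in_band = tt["rt_ms"].between(*band_ms)
            tt.loc[in_band, "c1"] -= (coupling * pars.c1_noise_sd
                                      * (2 * tt.loc[in_band, "choice"] - 1))
        tt["participant"] = p
        tt["session"] = p % 2
        rows.append(tt)
    out = pd.concat(rows, ignore_index=True)
    out["excluded"] = out["rt_ms"] > 600.0
    return out
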