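"""Single-trial C1 measurement, time-frequency decomposition and the
comprehensive search for choice-predictive covariate signals.

The C1 is measured as a bipolar scalar: the stimulus layout (one array per
visual hemifield quadrant) makes the earliest cortical response to the two
arrays project with opposite polarity onto posterior midline sites, so the
difference between the strongest electrodes of the two poles of the
upper-minus-lower difference topography in 80-90 ms maximises sensitivity
to differential contrast.  Positive deflections of the measure correspond
to lower-field dominance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import EpochSet, Montage


class NoC1Error(RuntimeError):
    """No sign-opposed C1 poles found (the participant-exclusion case)."""


# ------------------------------------------------------------------ montage
@dataclass
class C1Montage:
    pos_electrodes: list[str]
    neg_electrodes: list[str]
    window_ms: tuple[float, float] = (80.0, 90.0)
    participant: int | str | None = None

    def validate(self) -> None:
        if not self.pos_electrodes or not self.neg_electrodes:
            raise ValueError("both poles need at least one electrode")
        if set(self.pos_electrodes) & set(self.neg_electrodes):
            raise ValueError("pole sets must be disjoint")


def select_c1_electrodes(easy_epochs: EpochSet, trials: pd.DataFrame,
                         k_per_pole: int = 4,
                         montage: Montage | None = None,
                         pool: list[str] | None = None,
                         window_ms: tuple[float, float] = (80.0, 90.0),
                         participant=None) -> C1Montage:
    """Choose measurement electrodes from the easy block.

    Averages the epochs in the C1 window for each target location, forms
    the upper-minus-lower difference topography, and takes the ``k`` most
    positive and ``k`` most negative electrodes within the posterior pool
    as the two poles.  The positive pole of the *measure* is the set where
    lower-field targets dominate (most negative in upper-minus-lower), so
    positive single-trial values mean lower-field-like activity.
    """
    target = trials["target"].to_numpy(dtype=int)
    if len(np.unique(target)) < 2:
        raise ValueError("easy block must contain both target locations")
    sel = easy_epochs.time_window(*window_ms, inclusive=True)
    mean_win = easy_epochs.data[:, :, sel].mean(axis=2)
    diff = mean_win[target == 1].mean(axis=0) - \
        mean_win[target == 0].mean(axis=0)
    labels = easy_epochs.channel_labels
    if pool is None and montage is not None:
        pool = montage.posterior_pool()
    pool_idx = np.arange(len(labels)) if pool is None else \
        easy_epochs.channel_index([lab for lab in pool if lab in labels])
    d = diff[pool_idx]
    if np.all(d == 0) or d.max() <= 0 or d.min() >= 0:
        raise NoC1Error("no sign-opposed poles in the difference topography")
    order = np.argsort(d)
    neg_pole = [labels[pool_idx[i]] for i in order[:k_per_pole]
                if d[i] < 0]                       # lower-dominant sites
    order_desc = order[::-1]
    pos_pole = [labels[pool_idx[i]] for i in order_desc[:k_per_pole]
                if d[i] > 0]                       # upper-dominant sites
    m = C1Montage(pos_electrodes=neg_pole, neg_electrodes=pos_pole,
                  window_ms=window_ms, participant=participant)
    m.validate()
    return m


def measure_c1(e: EpochSet, m: C1Montage) -> np.ndarray:
    """Single-trial bipolar C1 amplitude (µV): mean over the positive-pole
    electrodes minus mean over the negative-pole electrodes within the C1
    window.  Trials whose montage channels are all artifact-flagged in the
    window come back as NaN (missing, not an error)."""
    m.validate()
    sel = e.time_window(*m.window_ms, inclusive=True)
    ip = e.channel_index(m.pos_electrodes)
    im = e.channel_index(m.neg_electrodes)
    if e.mask is None:
        pos = e.data[:, ip][:, :, sel].mean(axis=(1, 2))
        neg = e.data[:, im][:, :, sel].mean(axis=(1, 2))
        return pos - neg

    def masked_mean(idx: np.ndarray) -> np.ndarray:
        d = e.data[:, idx][:, :, sel]
        bad = e.mask[:, idx][:, :, sel]
        w = (~bad).sum(axis=(1, 2)).astype(float)
        s = np.where(bad, 0.0, d).sum(axis=(1, 2))
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(w > 0, s / w, np.nan)

    return masked_mean(ip) - masked_mean(im)


# --------------------------------------------------------------------- STFT
@dataclass
class TFRepresentation:
    magnitudes: np.ndarray     # (trials, channels, freqs, times), µV
    freqs_hz: np.ndarray
    times_ms: np.ndarray       # window centres
    window_ms: float = 400.0
    step_ms: float = 25.0


def stft(e: EpochSet, window_ms: float = 400.0, step_ms: float = 25.0,
         f_max_hz: float = 30.0) -> TFRepresentation:
    """Short-time Fourier magnitude with amplitude normalisation.

    Rectangular taper; magnitudes are divided by half the window length in
    samples so that a sinusoid at an exact bin frequency reads out its
    amplitude.  Analysis frequencies are every non-zero bin up to
    ``f_max_hz`` (at 512 Hz and a 400 ms / 205-sample window the bin
    spacing is 512/205 ≈ 2.4976 Hz, giving 12 analysis frequencies).
    """
    n_win = int(round(window_ms * e.fs / 1000.0))
    if n_win >= e.data.shape[2]:
        raise ValueError("epoch shorter than the STFT window")
    hop = step_ms * e.fs / 1000.0
    starts = np.round(np.arange(0, e.data.shape[2] - n_win + 1e-9, hop)
                      ).astype(int)
    freqs = np.fft.rfftfreq(n_win, d=1.0 / e.fs)
    keep = (freqs > 0) & (freqs <= f_max_hz)
    mags = np.empty(e.data.shape[:2] + (int(keep.sum()), len(starts)))
    for k, s in enumerate(starts):
        seg = e.data[:, :, s:s + n_win]
        spec = np.fft.rfft(seg, axis=2)[:, :, keep]
        mags[:, :, :, k] = np.abs(spec) / (n_win / 2.0)
    centres = e.time_ms[starts] + (n_win - 1) / 2.0 * 1000.0 / e.fs
    return TFRepresentation(mags, freqs[keep], centres, window_ms, step_ms)


# -------------------------------------------------------------- signal search
@dataclass
class ChoiceSignal:
    """A scalar-per-trial covariate: electrodes x time window (x band)."""

    name: str
    electrodes: list[str]
    t_start_ms: float
    t_end_ms: float
    f_lo_hz: float | None = None
    f_hi_hz: float | None = None
    polarity: int = 1           # sign of the upper-minus-lower difference
    contrast: str = "mean"      # or "left_minus_right" for lateralised sets

    def to_dict(self) -> dict:
        return {"name": self.name, "electrodes": self.electrodes,
                "t_start_ms": self.t_start_ms, "t_end_ms": self.t_end_ms,
                "f_lo_hz": self.f_lo_hz, "f_hi_hz": self.f_hi_hz,
                "polarity": self.polarity, "contrast": self.contrast}


@dataclass
class SearchParams:
    alpha: float = 0.05          # per-point threshold, uncorrected
    min_duration_ms: float = 20.0
    min_electrodes: int = 2
    merge_jaccard: float = 0.5   # adjacent-frequency merge criterion


def _participant_choice_diffs(data: np.ndarray, trials: pd.DataFrame
                              ) -> np.ndarray:
    """Per-participant upper-chosen minus lower-chosen averages.

    ``data`` is trials x ... (any trailing shape); returns
    participants x ... stacked differences."""
    choice = trials["choice"].to_numpy(dtype=int)
    pids = trials["participant"].to_numpy() if "participant" in trials \
        else np.zeros(len(trials), dtype=int)
    diffs = []
    for p in np.unique(pids):
        m = pids == p
        if choice[m].min() == choice[m].max():
            continue
        diffs.append(data[m & (choice == 1)].mean(axis=0)
                     - data[m & (choice == 0)].mean(axis=0))
    if not diffs:
        raise ValueError("no participant has both choice outcomes")
    return np.stack(diffs)


def _clusters_2d(sig: np.ndarray, tvals: np.ndarray, time_ms: np.ndarray,
                 labels: list[str], params: SearchParams,
                 min_samples: int) -> list[dict]:
    """Contiguous-in-time candidate clusters from a channels x times
    significance map.

    Positive- and negative-going deflections cluster separately (a
    lateralised effect has opposite signs over the two hemispheres and
    must not cancel within one candidate)."""
    out = []
    for sign in (+1, -1):
        signed = sig & (np.sign(tvals) == sign)
        any_sig = signed.any(axis=0)
        i = 0
        n = any_sig.size
        while i < n:
            if not any_sig[i]:
                i += 1
                continue
            j = i
            while j + 1 < n and any_sig[j + 1]:
                j += 1
            span = slice(i, j + 1)
            ch = np.nonzero(signed[:, span].any(axis=1))[0]
            if (j - i + 1) >= min_samples and \
                    len(ch) >= params.min_electrodes:
                sub = tvals[ch][:, span]
                out.append({"channels": [labels[c] for c in ch],
                            "t_start_ms": float(time_ms[i]),
                            "t_end_ms": float(time_ms[j]),
                            "polarity": sign,
                            "t_mean": float(sub.mean())})
            i = j + 1
    return out


def search_choice_signals(trials: pd.DataFrame,
                          epochs: EpochSet | None = None,
                          tf: TFRepresentation | None = None,
                          channel_labels: list[str] | None = None,
                          params: SearchParams | None = None
                          ) -> list[ChoiceSignal]:
    """Comprehensive (deliberately liberal) search for choice-predictive
    activity.

    Per participant, averages by choice outcome and subtracts
    (upper-chosen minus lower-chosen); group-level t-tests across
    participants identify candidate clusters: contiguous in time, at least
    ``min_duration_ms`` long and ``min_electrodes`` wide at an uncorrected
    threshold.  In the time-frequency domain, clusters at adjacent
    frequencies merge when their time-window and electrode sets mostly
    overlap (Jaccard >= 0.5), and merged candidates are kept if the
    cluster-mean difference passes a group t-test.  False positives are
    acceptable here: these signals become control covariates.
    """
    params = params or SearchParams()
    signals: list[ChoiceSignal] = []
    if epochs is not None:
        diffs = _participant_choice_diffs(epochs.data, trials)  # p x ch x t
        n_p = diffs.shape[0]
        if n_p < 2:
            raise ValueError("group search needs at least 2 participants")
        tvals, pvals = stats.ttest_1samp(diffs, 0.0, axis=0)
        sig = pvals < params.alpha
        min_samp = max(1, int(round(params.min_duration_ms * epochs.fs
                                    / 1000.0)))
        for k, cl in enumerate(_clusters_2d(sig, tvals, epochs.time_ms,
                                            epochs.channel_labels, params,
                                            min_samp)):
            signals.append(ChoiceSignal(
                name=f"td{k + 1}", electrodes=cl["channels"],
                t_start_ms=cl["t_start_ms"], t_end_ms=cl["t_end_ms"],
                polarity=cl["polarity"]))
    if tf is not None:
        labels = channel_labels or [f"ch{i}"
                                    for i in range(tf.magnitudes.shape[1])]
        diffs = _participant_choice_diffs(tf.magnitudes, trials)
        if diffs.shape[0] < 2:
            raise ValueError("group search needs at least 2 participants")
        tvals, pvals = stats.ttest_1samp(diffs, 0.0, axis=0)
        sig = pvals < params.alpha                  # p x f x t -> f x t
        per_freq: list[list[dict]] = []
        step = tf.times_ms[1] - tf.times_ms[0] if len(tf.times_ms) > 1 \
            else tf.step_ms
        min_steps = max(1, int(round(params.min_duration_ms / step)))
        for fi in range(len(tf.freqs_hz)):
            per_freq.append(_clusters_2d(sig[:, fi, :], tvals[:, fi, :],
                                         tf.times_ms, labels, params,
                                         min_steps))
        merged: list[dict] = []
        for fi, clusters in enumerate(per_freq):
            for cl in clusters:
                cl = dict(cl, f_lo=tf.freqs_hz[fi], f_hi=tf.freqs_hz[fi])
                target = None
                for mcl in merged:
                    if mcl["polarity"] != cl["polarity"]:
                        continue
                    if not np.isclose(mcl["f_hi"],
                                      tf.freqs_hz[max(fi - 1, 0)]) \
                            and not np.isclose(mcl["f_hi"], tf.freqs_hz[fi]):
                        continue
                    a0, a1 = mcl["t_start_ms"], mcl["t_end_ms"]
                    b0, b1 = cl["t_start_ms"], cl["t_end_ms"]
                    inter = max(0.0, min(a1, b1) - max(a0, b0))
                    union = max(a1, b1) - min(a0, b0)
                    t_j = inter / union if union > 0 else 1.0
                    sa, sb = set(mcl["channels"]), set(cl["channels"])
                    e_j = len(sa & sb) / len(sa | sb)
                    if t_j >= params.merge_jaccard and \
                            e_j >= params.merge_jaccard:
                        target = mcl
                        break
                if target is None:
                    merged.append(cl)
                else:
                    target["f_hi"] = cl["f_hi"]
                    target["t_start_ms"] = min(target["t_start_ms"],
                                               cl["t_start_ms"])
                    target["t_end_ms"] = max(target["t_end_ms"],
                                             cl["t_end_ms"])
                    target["channels"] = sorted(set(target["channels"])
                                                | set(cl["channels"]))
        # retain merged candidates passing a group-level t-test on the
        # cluster-mean difference
        ch_lookup = {lab: i for i, lab in enumerate(labels)}
        for k, mcl in enumerate(merged):
            fsel = (tf.freqs_hz >= mcl["f_lo"]) & (tf.freqs_hz <= mcl["f_hi"])
            tsel = (tf.times_ms >= mcl["t_start_ms"]) & \
                (tf.times_ms <= mcl["t_end_ms"])
            csel = [ch_lookup[c] for c in mcl["channels"]]
            vals = diffs[:, csel][:, :, fsel][:, :, :, tsel].mean(axis=(1, 2, 3))
            _, p = stats.ttest_1samp(vals, 0.0)
            if p < params.alpha:
                signals.append(ChoiceSignal(
                    name=f"tf{k + 1}", electrodes=list(mcl["channels"]),
                    t_start_ms=mcl["t_start_ms"], t_end_ms=mcl["t_end_ms"],
                    f_lo_hz=float(mcl["f_lo"]), f_hi_hz=float(mcl["f_hi"]),
                    polarity=int(np.sign(vals.mean()) or 1)))
    return signals


def extract_covariates(trials: pd.DataFrame, signals: list[ChoiceSignal],
                       epochs: EpochSet | None = None,
                       tf: TFRepresentation | None = None,
                       channel_labels: list[str] | None = None,
                       montage: Montage | None = None) -> pd.DataFrame:
    """Per-trial scalar covariates for each signal definition.

    Time-domain signals average the epoch over the signal's electrodes and
    window; frequency-banded signals average the STFT magnitude over
    electrodes, band and window.  ``left_minus_right`` contrasts subtract
    right-hemisphere from left-hemisphere electrode means (positions from
    ``montage``).  Fully artifact-flagged windows give NaN.
    """
    out = {}
    for s in signals:
        if s.f_lo_hz is None:
            if epochs is None:
                raise ValueError(f"signal {s.name} needs epochs")
            sel = epochs.time_window(s.t_start_ms, s.t_end_ms)
            idx = epochs.channel_index([c for c in s.electrodes
                                        if c in epochs.channel_labels])
            if s.contrast == "left_minus_right" and montage is not None:
                xs = montage.positions[montage.index(
                    [epochs.channel_labels[i] for i in idx]), 0]
                li, ri = idx[xs < 0], idx[xs >= 0]
                vals = epochs.data[:, li][:, :, sel].mean(axis=(1, 2)) - \
                    epochs.data[:, ri][:, :, sel].mean(axis=(1, 2))
            elif epochs.mask is not None:
                d = epochs.data[:, idx][:, :, sel]
                bad = epochs.mask[:, idx][:, :, sel]
                w = (~bad).sum(axis=(1, 2)).astype(float)
                ssum = np.where(bad, 0.0, d).sum(axis=(1, 2))
                with np.errstate(invalid="ignore", divide="ignore"):
                    vals = np.where(w > 0, ssum / w, np.nan)
            else:
                vals = epochs.data[:, idx][:, :, sel].mean(axis=(1, 2))
        else:
            if tf is None:
                raise ValueError(f"signal {s.name} needs a TF representation")
            labels = channel_labels or [f"ch{i}"
                                        for i in range(tf.magnitudes.shape[1])]
            lookup = {lab: i for i, lab in enumerate(labels)}
            idx = np.array([lookup[c] for c in s.electrodes if c in lookup],
                           dtype=int)
            if idx.size == 0:
                raise ValueError(f"signal {s.name}: no electrodes present")
            fsel = (tf.freqs_hz >= s.f_lo_hz) & (tf.freqs_hz <= s.f_hi_hz)
            tsel = (tf.times_ms >= s.t_start_ms) & \
                (tf.times_ms <= s.t_end_ms)
            if s.contrast == "left_minus_right" and montage is not None:
                xs = montage.positions[montage.index(
                    [labels[i] for i in idx]), 0]
                li, ri = idx[xs < 0], idx[xs >= 0]
                vals = tf.magnitudes[:, li][:, :, fsel][:, :, :, tsel].mean(
                    axis=(1, 2, 3)) - \
                    tf.magnitudes[:, ri][:, :, fsel][:, :, :, tsel].mean(
                    axis=(1, 2, 3))
            else:
                vals = tf.magnitudes[:, idx][:, :, fsel][:, :, :, tsel].mean(
                    axis=(1, 2, 3))
        out[s.name] = vals
    return pd.DataFrame(out, index=trials.index)
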