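"""Response-locked centro-parietal positivity (CPP) analysis.

The CPP indexes the accumulation of sensory evidence toward the decision
bound: it builds up after evidence onset, its buildup rate scales with
evidence strength and it peaks around the response.  The onset of
*evidence-dependent* buildup — the earliest time the slope separates
between easy and hard blocks — estimates when sensory information enters
the accumulator, which is later and more meaningful than the onset of
buildup itself (accumulation can start prematurely on noise).  Response-
locked waveforms are used because stimulus-evoked transients obscure the
CPP in target-locked averages; mean RT converts response-locked latencies
back to delays from stimulus onset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import EpochSet


def select_cpp_electrode(resp_epochs: EpochSet,
                         pool: Sequence[str],
                         window_ms: tuple[float, float] = (-150.0, -50.0)
                         ) -> str:
    """The centroparietal-pool channel with the highest mean amplitude in
    the pre-response window (ties break to the first in the pool, which is
    deterministic and logged in the result)."""
    pool = [p for p in pool if p in resp_epochs.channel_labels]
    if not pool:
        raise ValueError("empty centroparietal pool")
    sel = resp_epochs.time_window(*window_ms, inclusive=True)
    idx = resp_epochs.channel_index(pool)
    amps = resp_epochs.data[:, idx][:, :, sel].mean(axis=(0, 2))
    return pool[int(np.argmax(amps))]


def response_lock(epochs: EpochSet, trials: pd.DataFrame,
                  span_ms: tuple[float, float] = (-600.0, 100.0)
                  ) -> tuple[EpochSet, np.ndarray]:
    """Re-epoch target-locked data around each trial's response.

    Trials whose response-locked span does not fit inside the target-locked
    epoch are dropped; returns the kept-trial selector alongside."""
    t0, t1 = span_ms
    n_samp = int(round((t1 - t0) * epochs.fs / 1000.0))
    rt = trials["rt_ms"].to_numpy(dtype=float)
    out, kept = [], []
    for i in range(epochs.n_trials):
        start_ms = rt[i] + t0
        j0 = int(np.round((start_ms - epochs.time_ms[0]) * epochs.fs
                          / 1000.0))
        if j0 < 0 or j0 + n_samp > epochs.data.shape[2]:
            continue
        out.append(epochs.data[i, :, j0:j0 + n_samp])
        kept.append(i)
    if not out:
        raise ValueError("no trial fits the response-locked span")
    time_ms = t0 + np.arange(n_samp) * 1000.0 / epochs.fs
    keep = np.zeros(epochs.n_trials, dtype=bool)
    keep[kept] = True
    return EpochSet(np.stack(out), time_ms, epochs.fs,
                    list(epochs.channel_labels),
                    meta={"aligned": "response"}), keep


@dataclass
class SlopeSeries:
    """Sliding-window OLS slopes of the condition-average CPP waveform."""

    centers_ms: np.ndarray
    slopes: dict                  # condition -> (participants, windows) µV/ms
    t_stat: np.ndarray | None     # paired easy-vs-hard t per window
    p_one_sided: np.ndarray | None
    peak_window: int | None       # index of the easy-condition peak window
    window_ms: float = 50.0
    step_ms: float = 10.0


def _window_slopes(wave: np.ndarray, time_ms: np.ndarray, fs: float,
                   window_ms: float, step_ms: float
                   ) -> tuple[np.ndarray, np.ndarray]:
    """OLS slope of a waveform in each sliding window (µV/ms)."""
    n_win = int(round(window_ms * fs / 1000.0))
    hop = step_ms * fs / 1000.0
    starts = np.round(np.arange(0, wave.shape[-1] - n_win + 1e-9, hop)
                      ).astype(int)
    centers = time_ms[starts] + (n_win - 1) / 2.0 * 1000.0 / fs
    t = np.arange(n_win) * 1000.0 / fs
    t = t - t.mean()
    denom = (t ** 2).sum()
    slopes = np.stack([(wave[..., s:s + n_win] * t).sum(axis=-1) / denom
                       for s in starts], axis=-1)
    return slopes, centers


def slope_series(resp_epochs: EpochSet, trials: pd.DataFrame,
                 channel: str, condition_col: str = "condition",
                 conditions: tuple[str, str] = ("easy", "hard"),
                 rt_split: str = "all", window_ms: float = 50.0,
                 step_ms: float = 10.0) -> SlopeSeries:
    """Per-participant condition-average CPP slopes with the easy-vs-hard
    paired test per window.

    ``rt_split``: 'all', or 'fast'/'slow' for a per-participant median
    split of RT.  The paired test is one-sided (easy slope greater), per
    the directional hypothesis that stronger evidence steepens buildup.
    """
    ch = resp_epochs.channel_index(channel)[0]
    pids = trials["participant"].to_numpy() if "participant" in trials \
        else np.zeros(len(trials), dtype=int)
    cond = trials[condition_col].to_numpy()
    rt = trials["rt_ms"].to_numpy(dtype=float)
    uniq = np.unique(pids)
    per_cond: dict[str, list[np.ndarray]] = {c: [] for c in conditions}
    keep_p = []
    for p in uniq:
        sel_p = pids == p
        if rt_split != "all":
            med = np.median(rt[sel_p])
            sel_p = sel_p & ((rt < med) if rt_split == "fast"
                             else (rt >= med))
        ok = True
        waves = {}
        for c in conditions:
            m = sel_p & (cond == c)
            if m.sum() < 2:
                ok = False
                break
            waves[c] = resp_epochs.data[m, ch, :].mean(axis=0)
        if ok:
            keep_p.append(p)
            for c in conditions:
                per_cond[c].append(waves[c])
    if not keep_p:
        raise ValueError("no participant has both conditions")
    slopes = {}
    centers = None
    for c in conditions:
        s, centers = _window_slopes(np.stack(per_cond[c]),
                                    resp_epochs.time_ms, resp_epochs.fs,
                                    window_ms, step_ms)
        slopes[c] = s
    easy, hard = slopes[conditions[0]], slopes[conditions[1]]
    if easy.shape[0] >= 2:
        t_stat, p_two = stats.ttest_rel(easy, hard, axis=0)
        p_one = np.where(t_stat > 0, p_two / 2.0, 1.0 - p_two / 2.0)
    else:
        t_stat = p_one = None
    grand_easy = np.stack(per_cond[conditions[0]]).mean(axis=0)
    n_win = int(round(window_ms * resp_epochs.fs / 1000.0))
    hop = step_ms * resp_epochs.fs / 1000.0
    starts = np.round(np.arange(0, grand_easy.size - n_win + 1e-9, hop)
                      ).astype(int)
    win_mean = np.array([grand_easy[s:s + n_win].mean() for s in starts])
    peak = int(np.argmax(win_mean))
    return SlopeSeries(centers_ms=centers, slopes=slopes, t_stat=t_stat,
                       p_one_sided=p_one, peak_window=peak,
                       window_ms=window_ms, step_ms=step_ms)


def onset_window(ss: SlopeSeries, alpha: float = 0.05) -> int | None:
    """First window that is significant and *remains* significant in every
    window up to the easy-condition peak.

    Windows overlapping the peak itself are not required to stay
    significant (the buildup rate passes through zero at the peak by
    definition): continuity is demanded through the last window lying
    wholly before the peak centre."""
    if ss.p_one_sided is None or ss.peak_window is None:
        return None
    sig = ss.p_one_sided < alpha
    peak_ms = ss.centers_ms[ss.peak_window]
    before = np.nonzero(ss.centers_ms <= peak_ms - ss.window_ms / 2.0)[0]
    if before.size == 0:
        return None
    last = int(before[-1])
    qualifying = None
    for i in range(last, -1, -1):
        if sig[i]:
            qualifying = i
        else:
            break
    return qualifying


@dataclass
class CppOnsetEstimate:
    onsets_resp_ms: np.ndarray      # response-locked, negative values
    mean_rt_ms: float
    n_boot: int
    n_empty: int
    seed: int

    @property
    def median_resp_ms(self) -> float:
        return float(np.median(self.onsets_resp_ms)) \
            if self.onsets_resp_ms.size else np.nan

    @property
    def median_stim_ms(self) -> float:
        """Stimulus-locked onset: |response-locked onset| subtracted from
        mean RT."""
        if not self.onsets_resp_ms.size:
            return np.nan
        return float(np.median(self.mean_rt_ms - np.abs(self.onsets_resp_ms)))

    def ci_stim(self) -> tuple[float, float]:
        if not self.onsets_resp_ms.size:
            return (np.nan, np.nan)
        stim = self.mean_rt_ms - np.abs(self.onsets_resp_ms)
        return tuple(np.percentile(stim, [2.5, 97.5]))


def estimate_onset(resp_epochs: EpochSet, trials: pd.DataFrame,
                   channel: str, rt_split: str = "all",
                   n_boot: int = 500, seed: int = 0,
                   alpha: float = 0.05) -> CppOnsetEstimate:
    """Bootstrap (over participants) the onset of evidence-dependent CPP
    buildup; reports response-locked medians and the stimulus-locked
    conversion via mean RT of the analysed trials."""
    pids = np.unique(trials["participant"].to_numpy())
    rng = np.random.default_rng(seed)
    onsets = []
    n_empty = 0
    rt_mask = np.ones(len(trials), dtype=bool)
    if rt_split != "all":
        rt = trials["rt_ms"].to_numpy(float)
        pid_arr = trials["participant"].to_numpy()
        for p in pids:
            m = pid_arr == p
            med = np.median(rt[m])
            rt_mask[m] = (rt[m] < med) if rt_split == "fast" else \
                (rt[m] >= med)
    mean_rt = float(trials.loc[rt_mask, "rt_ms"].mean())
    for _ in range(n_boot):
        draw = rng.choice(pids, size=len(pids), replace=True)
        sel_frames, sel_rows = [], []
        for k, p in enumerate(draw):
            rows = np.nonzero((trials["participant"] == p).to_numpy())[0]
            sel_rows.append(rows)
            f = trials.iloc[rows].copy()
            f["participant"] = k
            sel_frames.append(f)
        idx = np.concatenate(sel_rows)
        sample_tr = pd.concat(sel_frames, ignore_index=True)
        sample_ep = EpochSet(resp_epochs.data[idx], resp_epochs.time_ms,
                             resp_epochs.fs, list(resp_epochs.channel_labels))
        try:
            ss = slope_series(sample_ep, sample_tr, channel,
                              rt_split=rt_split)
        except ValueError:
            n_empty += 1
            continue
        w = onset_window(ss, alpha)
        if w is None:
            n_empty += 1
            continue
        onsets.append(ss.centers_ms[w])
    return CppOnsetEstimate(np.asarray(onsets), mean_rt, n_boot, n_empty,
                            seed)


def pooled_onset(estimates: Sequence[CppOnsetEstimate],
                 c1_latency_ms: float = 80.0) -> dict:
    """Pool the all-trials / fast / slow stimulus-locked onset medians by
    arithmetic mean (flagging any empty estimate) and report the implied
    delay from the C1 latency."""
    meds = [e.median_stim_ms for e in estimates]
    avail = [m for m in meds if np.isfinite(m)]
    if not avail:
        raise ValueError("no onset estimate available")
    pooled = float(np.mean(avail))
    return {"pooled_stim_ms": pooled, "medians_ms": meds,
            "n_missing": len(meds) - len(avail),
            "delay_from_c1_ms": pooled - c1_latency_ms}
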