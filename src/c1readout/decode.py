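"""Time-resolved linear-discriminant decoding of choice from all channels.

Per 10 ms window, a shrinkage-regularised LDA is trained on the per-channel
mean amplitudes and evaluated on the same trials (train = test, matching
the protocol being emulated); overfitting is accounted for empirically by
refitting after shuffling the choice labels, which gives the chance curve
the real curve is compared against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .containers import EpochSet


@dataclass
class DecodingTimecourse:
    centers_ms: np.ndarray
    acc_real: np.ndarray        # (participants, windows)
    acc_shuffled: np.ndarray    # (participants, windows), shuffle mean
    participants: list
    sig: np.ndarray | None      # group real-vs-shuffled paired test

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pi, p in enumerate(self.participants):
            for wi, c in enumerate(self.centers_ms):
                rows.append((c, p, self.acc_real[pi, wi],
                             self.acc_shuffled[pi, wi]))
        return pd.DataFrame(rows, columns=["center_ms", "participant",
                                           "acc_real", "acc_shuffled"])


def _window_features(e: EpochSet, window_ms: float) -> tuple[np.ndarray,
                                                             np.ndarray]:
    n_win = max(1, int(round(window_ms * e.fs / 1000.0)))
    starts = np.arange(0, e.data.shape[2] - n_win + 1, n_win)
    feats = np.stack([e.data[:, :, s:s + n_win].mean(axis=2)
                      for s in starts], axis=0)  # (windows, trials, ch)
    centers = e.time_ms[starts] + (n_win - 1) / 2.0 * 1000.0 / e.fs
    return feats, centers


def lda_timecourse(e: EpochSet, trials: pd.DataFrame,
                   n_shuffles: int = 100, seed: int = 0,
                   window_ms: float = 10.0, shrinkage="auto",
                   log: list | None = None) -> DecodingTimecourse:
    """Train-equals-test LDA decoding accuracy per 10 ms window, per
    participant, with a shuffled-label chance curve (mean over
    ``n_shuffles`` refits on the same features) and a group-level paired
    test of real vs shuffled accuracy per window."""
    rng = np.random.default_rng(seed)
    pids = trials["participant"].to_numpy() if "participant" in trials \
        else np.zeros(len(trials), dtype=int)
    choice = trials["choice"].to_numpy(dtype=int)
    feats, centers = _window_features(e, window_ms)
    n_w = feats.shape[0]
    acc_real, acc_sh, kept = [], [], []
    for p in np.unique(pids):
        m = pids == p
        y = choice[m]
        if len(np.unique(y)) < 2 or min((y == 0).sum(), (y == 1).sum()) < 2:
            if log is not None:
                log.append(f"participant {p} skipped: class missing")
            continue
        real = np.empty(n_w)
        sh = np.empty(n_w)
        shuffles = [rng.permutation(y) for _ in range(n_shuffles)]
        for w in range(n_w):
            X = feats[w][m]
            clf = LinearDiscriminantAnalysis(solver="lsqr",
                                             shrinkage=shrinkage)
            clf.fit(X, y)
            real[w] = clf.score(X, y)
            accs = []
            for ys in shuffles:
                clf = LinearDiscriminantAnalysis(solver="lsqr",
                                                 shrinkage=shrinkage)
                clf.fit(X, ys)
                accs.append(clf.score(X, ys))
            sh[w] = float(np.mean(accs))
        acc_real.append(real)
        acc_sh.append(sh)
        kept.append(p)
    if not kept:
        raise ValueError("no participant had both classes")
    acc_real = np.stack(acc_real)
    acc_sh = np.stack(acc_sh)
    sig = None
    if acc_real.shape[0] >= 2:
        t, p2 = stats.ttest_rel(acc_real, acc_sh, axis=0)
        sig = (t > 0) & (p2 / 2.0 < 0.05)
    return DecodingTimecourse(centers, acc_real, acc_sh, kept, sig)
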