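"""Bootstrap estimation of the RT range over which an effect is expressed.

The per-window test outcomes across the 81 sliding RT windows are modelled
as a single unbroken run of significant windows with non-significant
windows before and after.  The run maximising agreement with the observed
flag sequence (empty run allowed, competing on equal footing) defines the
RT range; its onset and offset latencies are refined by linearly
interpolating the zero crossings of the coefficient series at the run
edges.  Uncertainty comes from resampling participants with replacement
(trials kept intact within a participant), rebuilding the window series in
every bootstrap sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .choice_models import WindowSeries


# ------------------------------------------------------------ run fitting
def fit_significance_run(flags: np.ndarray) -> tuple[int, int] | None:
    """Best-agreement contiguous run ``(start, end)`` (inclusive indices)
    or ``None`` for the empty run.

    Agreement = number of windows where the implied pattern
    (significant inside the run, non-significant outside) matches the
    observed flags.  Ties prefer the longest run, then the earliest start;
    the empty run wins only when strictly better than every non-empty run
    of equal agreement (it has length 0, so the longest-run tie-break
    applies).
    """
    flags = np.asarray(flags, dtype=bool)
    n = flags.size
    if n == 0:
        raise ValueError("empty sequence")
    total_off = int((~flags).sum())  # agreement of the empty run
    # prefix sums for O(1) run agreement
    csum = np.concatenate([[0], np.cumsum(flags)])
    best = (total_off, 0, None)      # (agreement, length, run)
    for i in range(n):
        for j in range(i, n):
            inside = csum[j + 1] - csum[i]          # significant inside
            outside_flags = csum[n] - inside        # significant outside
            outside_len = n - (j - i + 1)
            agreement = inside + (outside_len - outside_flags)
            length = j - i + 1
            if (agreement, length) > (best[0], best[1]):
                best = (agreement, length, (i, j))
            # equal agreement and length: earlier start already kept
    return best[2]


def run_to_latencies(run: tuple[int, int], series: WindowSeries,
                     term: str = "c1") -> tuple[float, float]:
    """Onset/offset latencies (ms) for a fitted run.

    Onset = linearly interpolated zero crossing of the coefficient series
    in the gap just before the run start (offset likewise just after the
    run end); when no crossing exists there, fall back to the run-edge
    window centre."""
    if run is None:
        raise ValueError("empty run has no latencies")
    i, j = run
    beta = series.beta[:, series.term(term)]
    c = series.centers_ms

    def crossing(a: int, b: int) -> float | None:
        if a < 0 or b >= len(beta):
            return None
        b0, b1 = beta[a], beta[b]
        if not (np.isfinite(b0) and np.isfinite(b1)) or b0 * b1 > 0:
            return None
        if b1 == b0:
            return None
        frac = -b0 / (b1 - b0)
        return float(c[a] + frac * (c[b] - c[a]))

    onset = crossing(i - 1, i)
    offset = crossing(j, j + 1)
    return (onset if onset is not None else float(c[i]),
            offset if offset is not None else float(c[j]))


# ------------------------------------------------------------- bootstrapping
@dataclass
class OnsetEstimate:
    onsets_ms: np.ndarray
    offsets_ms: np.ndarray
    n_boot: int
    n_empty: int
    seed: int

    @property
    def median_onset_ms(self) -> float:
        return float(np.median(self.onsets_ms)) if self.onsets_ms.size \
            else np.nan

    @property
    def median_offset_ms(self) -> float:
        return float(np.median(self.offsets_ms)) if self.offsets_ms.size \
            else np.nan

    def ci(self, which: str = "onset") -> tuple[float, float]:
        x = self.onsets_ms if which == "onset" else self.offsets_ms
        if x.size == 0:
            return (np.nan, np.nan)
        return tuple(np.percentile(x, [2.5, 97.5]))

    def to_dict(self) -> dict:
        lo, hi = self.ci("onset")
        olo, ohi = self.ci("offset")
        return {"median_onset_ms": self.median_onset_ms,
                "onset_ci": [lo, hi],
                "median_offset_ms": self.median_offset_ms,
                "offset_ci": [olo, ohi],
                "n_boot": self.n_boot, "n_empty": self.n_empty,
                "seed": self.seed}


def bootstrap_onsets(trials: pd.DataFrame,
                     model_fn: Callable[[pd.DataFrame], WindowSeries],
                     term: str = "c1", n_boot: int = 500,
                     seed: int = 0) -> OnsetEstimate:
    """Participant bootstrap of the RT-range onset and offset.

    ``model_fn`` rebuilds the window series from a (resampled) trial table.
    Each bootstrap sample draws participants with replacement, keeping each
    participant's trials intact; empty-run samples contribute no latencies
    and are counted in ``n_empty``.
    """
    pids = trials["participant"].unique()
    if len(pids) < 2:
        raise ValueError("participant bootstrap needs at least 2 ids")
    if n_boot < 1:
        raise ValueError("n_boot must be positive")
    rng = np.random.default_rng(seed)
    onsets, offsets = [], []
    n_empty = 0
    for _ in range(n_boot):
        draw = rng.choice(pids, size=len(pids), replace=True)
        parts = [trials[trials["participant"] == p].assign(participant=k)
                 for k, p in enumerate(draw)]
        sample = pd.concat(parts, ignore_index=True)
        try:
            series = model_fn(sample)
        except (ValueError, np.linalg.LinAlgError):
            n_empty += 1
            continue
        run = fit_significance_run(series.significance(term))
        if run is None:
            n_empty += 1
            continue
        on, off = run_to_latencies(run, series, term)
        onsets.append(on)
        offsets.append(off)
    return OnsetEstimate(np.asarray(onsets), np.asarray(offsets),
                         n_boot, n_empty, seed)


def paired_bootstrap_difference(trials: pd.DataFrame,
                                model_fn_a: Callable, model_fn_b: Callable,
                                term_a: str = "c1",
                                term_b: str = "intercept",
                                n_boot: int = 500, seed: int = 0
                                ) -> dict:
    """Evaluate two window models on identical bootstrap samples and return
    the onset-difference distribution (a - b) with its 95% CI."""
    pids = trials["participant"].unique()
    rng = np.random.default_rng(seed)
    diffs = []
    for _ in range(n_boot):
        draw = rng.choice(pids, size=len(pids), replace=True)
        parts = [trials[trials["participant"] == p].assign(participant=k)
                 for k, p in enumerate(draw)]
        sample = pd.concat(parts, ignore_index=True)
        vals = []
        for fn, term in ((model_fn_a, term_a), (model_fn_b, term_b)):
            try:
                series = fn(sample)
                run = fit_significance_run(series.significance(term))
            except (ValueError, np.linalg.LinAlgError):
                run = None
            if run is None:
                vals.append(None)
            else:
                vals.append(run_to_latencies(run, series, term)[0])
        if None not in vals:
            diffs.append(vals[0] - vals[1])
    diffs = np.asarray(diffs)
    ci = tuple(np.percentile(diffs, [2.5, 97.5])) if diffs.size else \
        (np.nan, np.nan)
    return {"median_diff_ms": float(np.median(diffs)) if diffs.size
            else np.nan, "ci": ci, "n_used": int(diffs.size),
            "n_boot": n_boot, "seed": seed}
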