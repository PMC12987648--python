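"""In-memory containers and on-disk formats shared by every pipeline stage.

Conventions (enforced here and relied on everywhere else):

* latencies in milliseconds, time 0 at the aligning event;
* sample indices 0-based, epoch windows half-open ``[t0, t1)``;
* EEG amplitudes in microvolts.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

FORMAT_VERSION = 1

#: canonical trial-table columns written by the simulator and consumed by the
#: analysis layers.  ``target``/``choice`` are coded 1 for the upper-field
#: array and 0 for the lower-field array; ``deadline_ms`` is 400 or 600.
TRIAL_COLUMNS = [
    "participant", "session", "block", "deadline_ms", "target", "choice",
    "rt_ms", "correct", "prev_choice", "excluded",
]


class FormatVersionError(RuntimeError):
    """Raised when an on-disk container has an unknown schema version."""


@dataclass
class EpochSet:
    """Epoched multichannel EEG: trials x channels x samples (microvolts).

    ``mask`` is an optional boolean array of the same shape as ``data`` (or
    broadcastable trials x channels) flagging artifact-contaminated samples;
    flagged samples are excluded from any analysis window they overlap.
    """

    data: np.ndarray                # (n_trials, n_channels, n_samples) µV
    time_ms: np.ndarray             # (n_samples,) relative to aligning event
    fs: float                       # Hz
    channel_labels: list[str]
    mask: np.ndarray | None = None  # True where contaminated
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        if self.data.shape[2] != self.time_ms.size:
            raise ValueError("time axis does not match data")
        if len(self.channel_labels) != self.data.shape[1]:
            raise ValueError("channel labels do not match data")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def time_window(self, t0_ms: float, t1_ms: float,
                    inclusive: bool = True) -> np.ndarray:
        """Boolean sample selector for a window; inclusive endpoints by
        default (measurement windows such as the 80-90 ms C1 window), pass
        ``inclusive=False`` for half-open epoch-style windows."""
        if inclusive:
            return (self.time_ms >= t0_ms) & (self.time_ms <= t1_ms)
        return (self.time_ms >= t0_ms) & (self.time_ms < t1_ms)

    def channel_index(self, labels: str | Sequence[str]) -> np.ndarray:
        if isinstance(labels, str):
            labels = [labels]
        lookup = {lab: i for i, lab in enumerate(self.channel_labels)}
        try:
            return np.array([lookup[lab] for lab in labels], dtype=int)
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"unknown channel {exc}") from exc

    def copy(self) -> "EpochSet":
        return EpochSet(self.data.copy(), self.time_ms.copy(), self.fs,
                        list(self.channel_labels),
                        None if self.mask is None else self.mask.copy(),
                        dict(self.meta))

    # ------------------------------------------------------------------ IO
    def save(self, path: str) -> None:
        with h5py.File(path, "w") as f:
            f.attrs["format_version"] = FORMAT_VERSION
            f.attrs["fs"] = float(self.fs)
            for key, val in self.meta.items():
                if isinstance(val, np.ndarray):
                    f.create_dataset(f"meta_arr_{key}", data=val,
                                     compression="gzip")
                elif isinstance(val, (str, int, float, np.integer,
                                      np.floating, list, tuple)):
                    f.attrs[f"meta_{key}"] = val
                # anything else (e.g. DataFrames) has its own format
            f.create_dataset("data", data=self.data, compression="gzip")
            f.create_dataset("time_ms", data=self.time_ms)
            f.create_dataset(
                "channel_labels",
                data=np.array(self.channel_labels, dtype=h5py.string_dtype()))
            if self.mask is not None:
                f.create_dataset("mask", data=self.mask, compression="gzip")

    @classmethod
    def load(cls, path: str) -> "EpochSet":
        with h5py.File(path, "r") as f:
            version = int(f.attrs.get("format_version", -1))
            if version != FORMAT_VERSION:
                raise FormatVersionError(
                    f"unsupported EpochSet container version {version}; "
                    f"this build reads version {FORMAT_VERSION}")
            meta = {k[5:]: f.attrs[k] for k in f.attrs
                    if k.startswith("meta_")}
            for k in f:
                if k.startswith("meta_arr_"):
                    meta[k[9:]] = f[k][()]
            return cls(
                data=f["data"][()],
                time_ms=f["time_ms"][()],
                fs=float(f.attrs["fs"]),
                channel_labels=[s.decode() if isinstance(s, bytes) else s
                                for s in f["channel_labels"][()]],
                mask=f["mask"][()].astype(bool) if "mask" in f else None,
                meta=meta,
            )


# --------------------------------------------------------------- trial table
def write_trial_table(trials: pd.DataFrame, path: str) -> None:
    trials.to_csv(path, index=False)


def read_trial_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("participant", "session", "block", "deadline_ms", "target",
                "choice", "correct"):
        if col in df.columns:
            df[col] = df[col].astype(int)
    if "excluded" in df.columns:
        df["excluded"] = df["excluded"].astype(bool)
    return df


def config_hash(obj) -> str:
    """Stable short hash of a (nested, JSON-serialisable) configuration."""
    import json

    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha1(blob).hexdigest()[:12]


# -------------------------------------------------------------------- montage
@dataclass
class Montage:
    """Simplified 128-channel layout: labels plus 2-D positions on the unit
    disc (nose along +y).  Real electrode geometry is not required by any
    stage; positions only define 'posterior', 'centroparietal' and lateral
    occipital pools and nearest-neighbour interpolation."""

    labels: list[str]
    positions: np.ndarray  # (n, 2)

    def index(self, labels: str | Sequence[str]) -> np.ndarray:
        if isinstance(labels, str):
            labels = [labels]
        lookup = {lab: i for i, lab in enumerate(self.labels)}
        return np.array([lookup[lab] for lab in labels], dtype=int)

    def posterior_pool(self) -> list[str]:
        """Electrodes below the horizontal midline (candidate C1 sites)."""
        return [lab for lab, (x, y) in zip(self.labels, self.positions)
                if y < 0]

    def centroparietal_pool(self, radius: float = 0.30) -> list[str]:
        """Electrodes near the midline just behind the vertex (CPP sites)."""
        centre = np.array([0.0, -0.20])
        d = np.linalg.norm(self.positions - centre, axis=1)
        return [lab for lab, dist in zip(self.labels, d) if dist < radius]

    def occipital_pool(self, side: str) -> list[str]:
        sign = -1.0 if side == "left" else 1.0
        return [lab for lab, (x, y) in zip(self.labels, self.positions)
                if y < -0.45 and sign * x > 0.12]

    def nearest_neighbours(self, label: str, k: int = 4) -> list[str]:
        i = self.index(label)[0]
        d = np.linalg.norm(self.positions - self.positions[i], axis=1)
        order = np.argsort(d)
        return [self.labels[j] for j in order if j != i][:k]


def make_montage(n_channels: int = 128) -> Montage:
    """Deterministic concentric-ring layout labelled A1..D32 (128 channels)
    in the style of a Biosemi ABC cap.  Smaller counts take the first rings
    (used in reduced-scale simulations)."""
    ring_sizes = [1, 6, 10, 14, 18, 22, 26, 31]
    positions = []
    total = sum(ring_sizes)
    radii = np.linspace(0.0, 1.0, len(ring_sizes))
    for r, size in zip(radii, ring_sizes):
        if size == 1:
            positions.append((0.0, 0.0))
            continue
        # fill each ring from the back (-y) alternating left/right so a
        # truncated montage keeps symmetric posterior coverage
        step = 2 * np.pi / size
        offsets = [0.0]
        for k in range(1, size // 2 + 1):
            offsets.extend([k * step, -k * step])
        angles = -np.pi / 2 + np.array(offsets[:size])
        for a in angles:
            positions.append((r * np.cos(a), r * np.sin(a)))
    positions = np.array(positions[:n_channels])
    banks = "ABCD"
    labels = [f"{banks[i // 32]}{i % 32 + 1}" for i in range(n_channels)]
    if n_channels > total:
        raise ValueError(f"montage supports at most {total} channels")
    return Montage(labels=labels, positions=positions)
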