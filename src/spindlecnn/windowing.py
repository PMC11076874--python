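"""Balanced window extraction: 3 s positives centred on spindle midpoints,
equal-count 3 s negatives from unannotated stretches of the same channel.

For every annotated spindle the midpoint ``onset + duration/2`` is extended
1.5 s to each side, giving a 300-sample window at 100 Hz. Negatives are
drawn uniformly (seeded) from the same subject and channel, at least
``guard_s`` away from every annotated event — spindle tails just outside the
annotation must not leak into the negative class — and without overlapping
one another, so no training sample is duplicated. Balance therefore holds
per (subject, channel) and hence globally, which is what makes accuracy on
the balanced set interpretable.

Windows carry their subject id so cross-validation can split by subject.
"""

from __future__ import annotations

import json
import warnings
import zlib
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from .types import Recording

__all__ = [
    "WindowingConfig", "Window", "WindowSet",
    "extract_positives", "sample_negatives", "build_window_set",
    "save_window_set", "load_window_set",
]


@dataclass(frozen=True)
class WindowingConfig:
    window_s: float = 3.0
    guard_s: float = 0.5
    seed: int = 0
    per_window_zscore: bool = False


@dataclass
class Window:
    """One labelled 1-D segment with provenance."""

    samples: np.ndarray
    label: int  # 1 = spindle, 0 = non-spindle
    subject_id: str
    channel: str
    start_s: float


class WindowSet:
    """Columnar container for labelled windows.

    Attributes ``X`` (n × window_len float32), ``y`` (n int8), and parallel
    ``subject_id`` / ``channel`` / ``start_s`` arrays; ``provenance`` records
    the windowing config and seed.
    """

    def __init__(self, windows: list[Window], provenance: dict | None = None):
        if windows:
            self.X = np.stack([w.samples for w in windows]).astype(np.float32)
        else:
            self.X = np.empty((0, 0), dtype=np.float32)
        self.y = np.array([w.label for w in windows], dtype=np.int8)
        self.subject_id = np.array([w.subject_id for w in windows])
        self.channel = np.array([w.channel for w in windows])
        self.start_s = np.array([w.start_s for w in windows], dtype=np.float64)
        self.provenance = provenance or {}

    def __len__(self) -> int:
        return len(self.y)

    @property
    def class_counts(self) -> dict[int, int]:
        return {c: int((self.y == c).sum()) for c in (0, 1)}

    def check_balanced(self) -> None:
        """Assert per-(subject, channel) class balance."""
        df = pd.DataFrame(
            {"s": self.subject_id, "c": self.channel, "y": self.y}
        )
        counts = df.groupby(["s", "c"])["y"].agg(
            pos=lambda v: int((v == 1).sum()), neg=lambda v: int((v == 0).sum())
        )
        bad = counts[counts["pos"] != counts["neg"]]
        if len(bad):
            raise AssertionError(f"unbalanced subject/channel groups:\n{bad}")

    def subset(self, idx: np.ndarray) -> "WindowSet":
        ws = WindowSet.__new__(WindowSet)
        ws.X = self.X[idx]
        ws.y = self.y[idx]
        ws.subject_id = self.subject_id[idx]
        ws.channel = self.channel[idx]
        ws.start_s = self.start_s[idx]
        ws.provenance = dict(self.provenance)
        return ws


def _window_len(window_s: float, fs_hz: float) -> int:
    return int(round(window_s * fs_hz))


def extract_positives(
    recording: Recording,
    annotations: pd.DataFrame,
    window_s: float = 3.0,
) -> tuple[list[Window], int]:
    """One window per annotation, centred on the event midpoint.

    Returns (windows, n_dropped); annotations whose window would cross a
    recording boundary are dropped with a warning (padding would fabricate
    signal).
    """
    fs = recording.fs_hz
    n_win = _window_len(window_s, fs)
    out: list[Window] = []
    dropped = 0
    for row in annotations.itertuples(index=False):
        if row.channel not in recording.channel_names:
            continue
        ci = recording.channel_names.index(row.channel)
        midpoint = row.onset_s + row.duration_s / 2.0
        start = int(round(midpoint * fs)) - n_win // 2
        if start < 0 or start + n_win > recording.n_samples:
            dropped += 1
            continue
        out.append(
            Window(
                samples=recording.signal[ci, start : start + n_win].copy(),
                label=1,
                subject_id=recording.subject_id,
                channel=row.channel,
                start_s=start / fs,
            )
        )
    if dropped:
        warnings.warn(
            f"dropped {dropped} boundary-crossing positive window(s) for "
            f"subject {recording.subject_id}",
            stacklevel=2,
        )
    return out, dropped


def sample_negatives(
    recording: Recording,
    annotations: pd.DataFrame,
    channel: str,
    n: int,
    window_s: float = 3.0,
    guard_s: float = 0.5,
    seed: int = 0,
) -> list[Window]:
    """``n`` non-spindle windows from one channel, uniformly sampled.

    Candidate start samples exclude any window that comes within ``guard_s``
    of an annotated event on that channel; accepted windows may not overlap
    each other (sampling without replacement). Raises when fewer than ``n``
    placements are feasible, reporting how many were achieved.
    """
    if channel not in recording.channel_names:
        raise KeyError(f"channel {channel!r} not in recording")
    ci = recording.channel_names.index(channel)
    fs = recording.fs_hz
    n_win = _window_len(window_s, fs)
    max_start = recording.n_samples - n_win
    if max_start < 0:
        raise ValueError("recording shorter than one window")
    feasible = np.ones(max_start + 1, dtype=bool)
    ev = annotations[annotations["channel"] == channel]
    for row in ev.itertuples(index=False):
        lo = int(np.floor((row.onset_s - guard_s) * fs)) - n_win + 1
        hi = int(np.ceil((row.onset_s + row.duration_s + guard_s) * fs)) - 1
        feasible[max(lo, 0) : min(hi, max_start) + 1] = False
    rng = np.random.default_rng(seed)
    out: list[Window] = []
    for k in range(n):
        candidates = np.flatnonzero(feasible)
        if candidates.size == 0:
            raise ValueError(
                f"could only place {k} of {n} negative windows on channel "
                f"{channel!r} of subject {recording.subject_id}; reduce n or "
                f"the guard margin"
            )
        start = int(rng.choice(candidates))
        feasible[max(start - n_win + 1, 0) : min(start + n_win, max_start + 1)] = False
        out.append(
            Window(
                samples=recording.signal[ci, start : start + n_win].copy(),
                label=0,
                subject_id=recording.subject_id,
                channel=channel,
                start_s=start / fs,
            )
        )
    return out


def _group_seed(base_seed: int, subject_id: str, channel: str) -> int:
    """Stable per-(subject, channel) seed, independent of cohort order."""
    ss = np.random.SeedSequence(
        [int(base_seed), zlib.crc32(subject_id.encode()), zlib.crc32(channel.encode())]
    )
    return int(ss.generate_state(1)[0] % (2**31))


def build_window_set(
    cohort: list[tuple[Recording, pd.DataFrame]],
    config: WindowingConfig = WindowingConfig(),
) -> WindowSet:
    """Positives plus matched negatives over all subjects and channels.

    Deterministic under ``config.seed``; per-(subject, channel) seeds are
    derived from stable hashes, so the resulting multiset of windows does not
    depend on cohort ordering. With ``per_window_zscore`` each window is
    normalized to zero mean / unit variance individually.
    """
    windows: list[Window] = []
    total_dropped = 0
    for recording, annotations in cohort:
        for channel in recording.channel_names:
            ann = annotations[annotations["channel"] == channel]
            pos, dropped = extract_positives(recording, ann, config.window_s)
            total_dropped += dropped
            neg = sample_negatives(
                recording, ann, channel, n=len(pos),
                window_s=config.window_s, guard_s=config.guard_s,
                seed=_group_seed(config.seed, recording.subject_id, channel),
            )
            windows.extend(pos)
            windows.extend(neg)
    if config.per_window_zscore:
        for w in windows:
            std = w.samples.std()
            if std == 0:
                raise ValueError("zero-variance window cannot be z-scored")
            w.samples = (w.samples - w.samples.mean()) / std
    ws = WindowSet(
        windows,
        provenance={
            "window_s": config.window_s,
            "guard_s": config.guard_s,
            "seed": config.seed,
            "per_window_zscore": config.per_window_zscore,
            "n_boundary_dropped": total_dropped,
        },
    )
    return ws


def save_window_set(ws: WindowSet, path) -> None:
    """HDF5 layout: datasets X, y, subject_id, channel, start_s; provenance
    in a JSON attribute."""
    with h5py.File(path, "w") as f:
        f.create_dataset("X", data=ws.X)
        f.create_dataset("y", data=ws.y)
        str_dt = h5py.string_dtype()
        f.create_dataset("subject_id", data=ws.subject_id.astype(object), dtype=str_dt)
        f.create_dataset("channel", data=ws.channel.astype(object), dtype=str_dt)
        f.create_dataset("start_s", data=ws.start_s)
        f.attrs["provenance"] = json.dumps(ws.provenance)


def load_window_set(path) -> WindowSet:
    with h5py.File(path, "r") as f:
        ws = WindowSet.__new__(WindowSet)
        ws.X = f["X"][()]
        ws.y = f["y"][()]
        ws.subject_id = f["subject_id"].asstr()[()]
        ws.channel = f["channel"].asstr()[()]
        ws.start_s = f["start_s"][()]
        ws.provenance = json.loads(f.attrs["provenance"])
    return ws
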