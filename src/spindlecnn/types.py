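"""Core in-memory containers shared across the pipeline.

A :class:`Recording` is a channels-by-samples matrix in microvolts with its
sampling rate and provenance. Spindle annotations travel as a plain pandas
DataFrame with the columns in :data:`ANNOTATION_COLUMNS`; onsets are seconds
from recording start (0-based) and an event occupies the half-open interval
``[onset_s, onset_s + duration_s)``. Keeping annotation times in seconds
rather than sample indices means they survive resampling unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Required column order for annotation tables (CSV header matches).
ANNOTATION_COLUMNS = ["subject_id", "channel", "onset_s", "duration_s"]


@dataclass
class Recording:
    """Multichannel EEG signal in microvolts.

    Parameters
    ----------
    signal : ndarray, shape (n_channels, n_samples)
        Signal matrix in μV.
    fs_hz : float
        Sampling rate in Hz.
    channel_names : list of str
        Ordered channel labels, one per signal row.
    subject_id : str
        Identifier used to group windows into cross-validation folds.
    meta : dict
        Free-form provenance (generator / preprocessing parameters).
    """

    signal: np.ndarray
    fs_hz: float
    channel_names: list[str]
    subject_id: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D (channels x samples)")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if len(self.channel_names) != self.signal.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.signal.shape[0]} signal rows"
            )

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def pick(self, channels: list[str]) -> "Recording":
        """Return a copy restricted to ``channels`` (in the given order)."""
        missing = [c for c in channels if c not in self.channel_names]
        if missing:
            raise KeyError(
                f"channel(s) {missing} not present in recording "
                f"(has {self.channel_names})"
            )
        idx = [self.channel_names.index(c) for c in channels]
        return Recording(
            signal=self.signal[idx].copy(),
            fs_hz=self.fs_hz,
            channel_names=list(channels),
            subject_id=self.subject_id,
            meta=dict(self.meta),
        )


def empty_annotations() -> pd.DataFrame:
    """An annotation table with the required schema and zero rows."""
    return pd.DataFrame(
        {
            "subject_id": pd.Series(dtype=str),
            "channel": pd.Series(dtype=str),
            "onset_s": pd.Series(dtype=float),
            "duration_s": pd.Series(dtype=float),
        }
    )


def validate_annotations(
    annotations: pd.DataFrame, recording: Recording | None = None
) -> pd.DataFrame:
    """Validate an annotation table, optionally against a recording.

    Checks schema, non-negative onsets and positive durations; when a
    recording is given, also that every event interval fits inside it and
    every referenced channel exists.

    Returns the table (unchanged) for chaining; raises ``ValueError`` on the
    first violation.
    """
    missing_cols = [c for c in ANNOTATION_COLUMNS if c not in annotations.columns]
    if missing_cols:
        raise ValueError(f"annotation table missing columns {missing_cols}")
    if len(annotations) == 0:
        return annotations
    if (annotations["onset_s"] < 0).any():
        raise ValueError("annotation with negative onset_s")
    if (annotations["duration_s"] <= 0).any():
        raise ValueError("annotation with non-positive duration_s")
    if recording is not None:
        ends = annotations["onset_s"] + annotations["duration_s"]
        if (ends > recording.duration_s + 1e-9).any():
            raise ValueError("annotation extends beyond recording end")
        bad = set(annotations["channel"]) - set(recording.channel_names)
        if bad:
            raise ValueError(f"annotation references unknown channel(s) {sorted(bad)}")
    return annotations
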