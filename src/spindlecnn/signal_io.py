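"""Recording and annotation I/O: EDF, HDF5, CSV matrix, annotation CSV.

All readers return signals in μV regardless of on-disk scaling metadata.

The EDF path is asymmetric by design: writing uses a self-contained 16-bit
EDF encoder (1 s data records, physical range ±200 μV by default, which
covers observed spindle excursions of ±50 μV with headroom and fixes the
quantization step at 400/65535 ≈ 0.0061 μV), while reading is delegated to
``mne.io.read_raw_edf``. Round-tripping through an independent reader is a
continuous check that the encoder emits standard-conforming files.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .types import ANNOTATION_COLUMNS, Recording, empty_annotations, validate_annotations

__all__ = [
    "RecordingSource",
    "read_recording",
    "write_edf",
    "read_edf",
    "write_hdf5",
    "read_hdf5",
    "write_csv_matrix",
    "read_csv_matrix",
    "write_annotations",
    "read_annotations",
    "edf_quantization_step_uv",
]

EDF_PHYSICAL_RANGE_UV = (-200.0, 200.0)
_DIG_MIN, _DIG_MAX = -32768, 32767


@dataclass
class RecordingSource:
    """Where and how to read a recording.

    ``format`` is inferred from the suffix when None (.edf, .h5/.hdf5, .csv).
    ``channel_filter`` keeps the listed channels in the given order; None
    keeps everything.
    """

    path: str | Path
    format: str | None = None
    channel_filter: list[str] | None = field(default_factory=lambda: ["C3", "C4"])

    def resolved_format(self) -> str:
        if self.format is not None:
            return self.format.lower()
        suffix = Path(self.path).suffix.lower()
        mapping = {".edf": "edf", ".h5": "hdf5", ".hdf5": "hdf5", ".csv": "csv"}
        if suffix not in mapping:
            raise ValueError(f"cannot infer format from suffix {suffix!r}")
        return mapping[suffix]


def read_recording(source: RecordingSource) -> Recording:
    """Dispatch to the format-specific reader, then apply the channel filter."""
    fmt = source.resolved_format()
    readers = {"edf": read_edf, "hdf5": read_hdf5, "csv": read_csv_matrix}
    if fmt not in readers:
        raise ValueError(f"unsupported format {fmt!r}")
    rec = readers[fmt](source.path)
    if source.channel_filter is not None:
        rec = rec.pick(source.channel_filter)
    return rec


def edf_quantization_step_uv(
    physical_range: tuple[float, float] = EDF_PHYSICAL_RANGE_UV
) -> float:
    """μV per digital step of the 16-bit EDF encoding."""
    return (physical_range[1] - physical_range[0]) / (_DIG_MAX - _DIG_MIN)


def _edf_field(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(
    recording: Recording,
    path: str | Path,
    physical_range_uv: tuple[float, float] = EDF_PHYSICAL_RANGE_UV,
) -> Path:
    """Write a recording as 16-bit EDF with 1 s data records.

    Requires an integer sampling rate. The last partial second, if any, is
    zero-padded to a whole record (EDF stores whole records only). Samples
    outside ``physical_range_uv`` are clipped.
    """
    path = Path(path)
    fs = recording.fs_hz
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    pmin, pmax = physical_range_uv
    n_ch = recording.n_channels
    n_records = int(np.ceil(recording.n_samples / fs))
    padded = np.zeros((n_ch, n_records * fs))
    padded[:, : recording.n_samples] = recording.signal

    scale = (_DIG_MAX - _DIG_MIN) / (pmax - pmin)
    digital = np.round((np.clip(padded, pmin, pmax) - pmin) * scale + _DIG_MIN)
    digital = digital.astype("<i2")

    header_bytes = 256 * (1 + n_ch)
    with open(path, "wb") as f:
        f.write(_edf_field("0", 8))
        f.write(_edf_field(recording.subject_id or "X", 80))
        f.write(_edf_field("Startdate 01-JAN-2000", 80))
        f.write(_edf_field("01.01.00", 8))
        f.write(_edf_field("00.00.00", 8))
        f.write(_edf_field(str(header_bytes), 8))
        f.write(_edf_field("", 44))
        f.write(_edf_field(str(n_records), 8))
        f.write(_edf_field("1", 8))  # record duration, seconds
        f.write(_edf_field(str(n_ch), 4))
        for name in recording.channel_names:
            f.write(_edf_field(f"EEG {name}", 16))
        for _ in range(n_ch):
            f.write(_edf_field("AgAgCl electrode", 80))
        for _ in range(n_ch):
            f.write(_edf_field("uV", 8))
        for _ in range(n_ch):
            f.write(_edf_field(f"{pmin:g}", 8))
        for _ in range(n_ch):
            f.write(_edf_field(f"{pmax:g}", 8))
        for _ in range(n_ch):
            f.write(_edf_field(str(_DIG_MIN), 8))
        for _ in range(n_ch):
            f.write(_edf_field(str(_DIG_MAX), 8))
        for _ in range(n_ch):
            f.write(_edf_field("", 80))
        for _ in range(n_ch):
            f.write(_edf_field(str(fs), 8))
        for _ in range(n_ch):
            f.write(_edf_field("", 32))
        # data: record-major, channel blocks within each record
        for r in range(n_records):
            block = digital[:, r * fs : (r + 1) * fs]
            f.write(block.tobytes())
    return path


def _edf_samples_per_record(path: Path) -> list[int]:
    """Per-signal samples-per-record fields from the EDF header."""
    with open(path, "rb") as f:
        header = f.read(256)
        n_sig = int(header[252:256].decode("ascii").strip())
        f.seek(256 + n_sig * 216)  # skip labels..prefiltering blocks
        raw = f.read(n_sig * 8).decode("ascii")
    return [int(raw[i * 8 : (i + 1) * 8].strip()) for i in range(n_sig)]


def read_edf(path: str | Path) -> Recording:
    """Read an EDF file via MNE; returns μV with EDF channel prefixes stripped.

    Files whose signals are sampled at different rates are rejected up front
    (a resampling decision belongs to preprocessing, not to the reader).
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if len(set(_edf_samples_per_record(path))) > 1:
        raise ValueError(
            f"inconsistent per-channel sampling rates in EDF file {path}"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    signal_uv = raw.get_data() * 1e6  # MNE loads EEG in volts
    names = [n.removeprefix("EEG ").strip() for n in raw.ch_names]
    return Recording(
        signal=signal_uv,
        fs_hz=float(raw.info["sfreq"]),
        channel_names=names,
        subject_id=_edf_patient_id(path),
    )


def _edf_patient_id(path: Path) -> str:
    with open(path, "rb") as f:
        f.seek(8)
        return f.read(80).decode("ascii", errors="replace").strip()


def write_hdf5(recording: Recording, path: str | Path) -> Path:
    """HDF5 layout: dataset ``signal`` [channels x samples] (float64 μV) with
    attributes ``fs_hz``, ``channel_names``, ``subject_id``. Lossless."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("signal", data=recording.signal)
        ds.attrs["units"] = "uV"
        f.attrs["fs_hz"] = recording.fs_hz
        f.attrs["channel_names"] = [str(c) for c in recording.channel_names]
        f.attrs["subject_id"] = recording.subject_id
    return path


def read_hdf5(path: str | Path) -> Recording:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as f:
        return Recording(
            signal=f["signal"][()],
            fs_hz=float(f.attrs["fs_hz"]),
            channel_names=[str(c) for c in f.attrs["channel_names"]],
            subject_id=str(f.attrs["subject_id"]),
        )


def write_csv_matrix(recording: Recording, path: str | Path) -> Path:
    """Plain-text matrix: comment line with metadata, then one column per
    channel. Convenient for eyeballing; lossy only through float formatting."""
    path = Path(path)
    with open(path, "w") as f:
        f.write(
            f"# fs_hz={recording.fs_hz:g} subject_id={recording.subject_id}\n"
        )
        pd.DataFrame(recording.signal.T, columns=recording.channel_names).to_csv(
            f, index=False, float_format="%.6f"
        )
    return path


def read_csv_matrix(path: str | Path) -> Recording:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as f:
        meta_line = f.readline()
        if not meta_line.startswith("#"):
            raise ValueError("CSV matrix must start with a '# fs_hz=...' line")
        meta = dict(
            kv.split("=", 1) for kv in meta_line.lstrip("#").split() if "=" in kv
        )
        df = pd.read_csv(f)
    return Recording(
        signal=df.to_numpy().T,
        fs_hz=float(meta["fs_hz"]),
        channel_names=list(df.columns),
        subject_id=meta.get("subject_id", "unknown"),
    )


def write_annotations(annotations: pd.DataFrame, path: str | Path) -> Path:
    """Annotation CSV with header ``subject_id,channel,onset_s,duration_s``."""
    path = Path(path)
    validate_annotations(annotations)
    annotations.loc[:, ANNOTATION_COLUMNS].to_csv(path, index=False)
    return path


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read and validate an annotation CSV.

    Rows with non-positive duration are dropped with a warning reporting the
    count; malformed numeric fields raise with the offending row number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"subject_id": str, "channel": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation CSV missing columns {missing}")
    if len(df) == 0:
        return empty_annotations()
    for col in ("onset_s", "duration_s"):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"malformed numeric value in column {col!r} at data row {row}"
            )
        df[col] = converted
    nonpos = df["duration_s"] <= 0
    if nonpos.any():
        warnings.warn(
            f"dropped {int(nonpos.sum())} annotation(s) with non-positive duration",
            stacklevel=2,
        )
        df = df.loc[~nonpos].reset_index(drop=True)
    if (df["onset_s"] < 0).any():
        raise ValueError("annotation with negative onset_s")
    return df.loc[:, ANNOTATION_COLUMNS]
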