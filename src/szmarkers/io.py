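"""Domain containers and on-disk formats for seizure recordings and marker tables.

A seizure is handled as three contiguous segments of a multichannel intracranial
EEG recording: a preictal baseline (target 120 s), the ictal period between the
annotated electrographic onset and offset, and a postictal window (target 120 s).
Recordings are read either from EDF/EDF+ files (via :mod:`mne`) or from a plain
delimited channels-by-samples text matrix with a sampling-rate header; seizure
boundaries come from a JSON or CSV annotation sidecar.

Sample-index annotations are 0-based, half-open ``[onset, offset)``.
"""

from __future__ import annotations

import csv
import datetime as _dt
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SignalSegment",
    "SeizureRecord",
    "SEIZURE_TYPES",
    "MARKER_COLUMNS",
    "METADATA_COLUMNS",
    "read_recording",
    "read_annotation",
    "write_matrix_recording",
    "read_matrix_recording",
    "write_annotation",
    "ictal_duration_marker",
    "write_marker_table",
    "read_marker_table",
    "clock_time_to_seconds",
]

SEIZURE_TYPES = (
    "focal",
    "focal_aware",
    "focal_impaired_awareness",
    "subclinical",
    "FTBTC",
    "unknown",
)

#: The 16 severity markers, in stable table order. Peak markers and the
#: suppression durations are stored log-transformed (natural log; durations as
#: ln(seconds + 1)); proportions and ictal duration are stored raw.
MARKER_COLUMNS = (
    "peak_line_length",
    "peak_energy",
    "peak_power_delta",
    "peak_power_theta",
    "peak_power_alpha",
    "peak_power_beta",
    "peak_power_lowgamma",
    "peak_power_highgamma",
    "prop_channels_ever_recruited",
    "prop_channels_max_recruitment",
    "time_to_max_recruitment",
    "prop_duration_to_max_recruitment",
    "majority_suppression_duration",
    "partial_suppression_duration",
    "suppression_strength",
    "ictal_duration",
)

METADATA_COLUMNS = (
    "patient_id",
    "seizure_id",
    "onset_clock_time",
    "type_label",
    "onset_epoch_time",
    "short_preictal",
    "short_postictal",
    "flags",
)


def clock_time_to_seconds(clock_time: str) -> float:
    """Convert an ISO 8601 time or datetime string to seconds past midnight."""
    s = str(clock_time).strip()
    if "T" in s or " " in s and "-" in s:
        t = _dt.datetime.fromisoformat(s).time()
    else:
        t = _dt.time.fromisoformat(s)
    return t.hour * 3600.0 + t.minute * 60.0 + t.second + t.microsecond / 1e6


@dataclass
class SignalSegment:
    """A contiguous multichannel iEEG segment.

    Parameters
    ----------
    data : ndarray, shape (C, N)
        Channel time series in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_ids : sequence of str
        Unique channel labels, one per row of ``data``.
    t0_offset : float
        Start time of the segment in seconds relative to the electrographic
        seizure onset (negative for a preictal segment).
    """

    data: np.ndarray
    fs: float
    channel_ids: tuple[str, ...]
    t0_offset: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (channels x samples) array")
        if self.data.shape[0] < 1 or self.data.shape[1] < 1:
            raise ValueError("segment needs at least one channel and one sample")
        if not np.isfinite(self.data).all():
            raise ValueError("segment contains NaN/inf samples")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        self.channel_ids = tuple(str(c) for c in self.channel_ids)
        if len(self.channel_ids) != self.data.shape[0]:
            raise ValueError("channel_ids length must equal number of channels")
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise ValueError("duplicate channel labels")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Segment length in seconds."""
        return self.n_samples / self.fs

    def select_channels(self, keep: Sequence[str]) -> "SignalSegment":
        """Return a copy restricted to ``keep`` (order follows this segment)."""
        keep_set = set(keep)
        idx = [i for i, c in enumerate(self.channel_ids) if c in keep_set]
        if not idx:
            raise ValueError("no channels left after selection")
        return SignalSegment(
            self.data[idx].copy(),
            self.fs,
            tuple(self.channel_ids[i] for i in idx),
            self.t0_offset,
        )

    def copy(self) -> "SignalSegment":
        return SignalSegment(self.data.copy(), self.fs, self.channel_ids, self.t0_offset)


@dataclass
class SeizureRecord:
    """One seizure: preictal/ictal/postictal segments plus annotations."""

    patient_id: str
    seizure_id: str
    preictal: SignalSegment
    ictal: SignalSegment
    postictal: SignalSegment | None
    onset_clock_time: str = "00:00:00"
    type_label: str = "unknown"
    onset_epoch_time: float = 0.0
    short_preictal: bool = False
    short_postictal: bool = False

    def __post_init__(self) -> None:
        if self.type_label not in SEIZURE_TYPES:
            raise ValueError(
                f"type_label {self.type_label!r} not one of {SEIZURE_TYPES}"
            )
        segs = [self.preictal, self.ictal]
        if self.postictal is not None:
            segs.append(self.postictal)
        fs = {s.fs for s in segs}
        if len(fs) != 1:
            raise ValueError("segments must share a sampling rate")
        chans = {s.channel_ids for s in segs}
        if len(chans) != 1:
            raise ValueError("segments must share channel labels")
        if self.ictal.n_samples < 1:
            raise ValueError("ictal segment is empty")

    @property
    def fs(self) -> float:
        return self.ictal.fs

    @property
    def channel_ids(self) -> tuple[str, ...]:
        return self.ictal.channel_ids

    @property
    def ictal_duration(self) -> float:
        return self.ictal.n_samples / self.fs

    @property
    def clock_seconds(self) -> float:
        """Seizure onset time of day in seconds past midnight."""
        return clock_time_to_seconds(self.onset_clock_time)

    def select_channels(self, keep: Sequence[str]) -> "SeizureRecord":
        return replace(
            self,
            preictal=self.preictal.select_channels(keep),
            ictal=self.ictal.select_channels(keep),
            postictal=None if self.postictal is None else self.postictal.select_channels(keep),
        )


def ictal_duration_marker(record: SeizureRecord) -> float:
    """Ictal duration in seconds (``N_ictal / fs``), itself a severity marker."""
    return record.ictal_duration


# ---------------------------------------------------------------------------
# Recording files


def write_matrix_recording(
    path: str | Path, data: np.ndarray, fs: float, channel_ids: Sequence[str]
) -> None:
    """Write a channels-by-samples matrix as delimited text with an fs header."""
    data = np.asarray(data, dtype=np.float64)
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# fs: {fs:g}\n")
        fh.write("# channels: " + ",".join(str(c) for c in channel_ids) + "\n")
        np.savetxt(fh, data, delimiter=",", fmt="%.10g")


def read_matrix_recording(path: str | Path) -> tuple[np.ndarray, float, tuple[str, ...]]:
    """Read the delimited-matrix recording dialect written by the simulator."""
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        line1 = fh.readline().strip()
        line2 = fh.readline().strip()
        if not line1.startswith("# fs:"):
            raise ValueError(f"{path}: missing '# fs:' header")
        fs = float(line1.split(":", 1)[1])
        if not line2.startswith("# channels:"):
            raise ValueError(f"{path}: missing '# channels:' header")
        channels = tuple(c.strip() for c in line2.split(":", 1)[1].split(","))
        data = np.loadtxt(fh, delimiter=",", ndmin=2)
    if data.shape[0] != len(channels):
        raise ValueError(f"{path}: {data.shape[0]} rows but {len(channels)} channel labels")
    return data, fs, channels


def _read_edf(path: Path) -> tuple[np.ndarray, float, tuple[str, ...]]:
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    return data, float(raw.info["sfreq"]), tuple(raw.ch_names)


def read_annotation(path: str | Path) -> dict:
    """Read a JSON or CSV annotation sidecar.

    Required fields: ``seizure_id, onset_sample, offset_sample, clock_time,
    type_label``; optional: ``patient_id, epoch_time``.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        ann = json.loads(path.read_text(encoding="utf-8"))
    else:
        with path.open("r", encoding="utf-8", newline="") as fh:
            rows = list(csv.DictReader(fh))
        if len(rows) != 1:
            raise ValueError(f"{path}: expected exactly one annotation row, got {len(rows)}")
        ann = rows[0]
    required = {"seizure_id", "onset_sample", "offset_sample", "clock_time", "type_label"}
    missing = required - set(ann)
    if missing:
        raise ValueError(f"{path}: annotation missing fields {sorted(missing)}")
    ann["onset_sample"] = int(ann["onset_sample"])
    ann["offset_sample"] = int(ann["offset_sample"])
    ann["epoch_time"] = float(ann.get("epoch_time", 0.0) or 0.0)
    ann.setdefault("patient_id", "unknown")
    return ann


def write_annotation(path: str | Path, ann: dict) -> None:
    Path(path).write_text(json.dumps(ann, indent=1), encoding="utf-8")


def read_recording(
    path: str | Path,
    annotation_path: str | Path,
    *,
    context_len: float = 120.0,
) -> SeizureRecord:
    """Read one seizure from a recording file plus its annotation sidecar.

    The recording file holds the full extract (preictal + ictal + postictal);
    the annotation gives the electrographic onset/offset as 0-based, half-open
    sample indices into it. Up to ``context_len`` seconds before onset and
    after offset are kept as the pre-/postictal segments; shorter context is
    kept and flagged, never padded.
    """
    path = Path(path)
    if path.suffix.lower() in {".edf", ".edf+", ".bdf"}:
        data, fs, channels = _read_edf(path)
    else:
        data, fs, channels = read_matrix_recording(path)
    if len(set(channels)) != len(channels):
        raise ValueError("duplicate channel labels in recording")
    ann = read_annotation(annotation_path)
    onset, offset = ann["onset_sample"], ann["offset_sample"]
    n = data.shape[1]
    if not (0 <= onset < offset <= n):
        raise ValueError(
            f"annotation interval [{onset}, {offset}) out of range for {n} samples"
        )
    ctx = int(round(context_len * fs))
    pre_start = max(0, onset - ctx)
    post_end = min(n, offset + ctx)
    if pre_start == onset:
        raise ValueError("no preictal context before the annotated onset")
    pre = SignalSegment(data[:, pre_start:onset], fs, channels, (pre_start - onset) / fs)
    ict = SignalSegment(data[:, onset:offset], fs, channels, 0.0)
    post = None
    if post_end > offset:
        post = SignalSegment(data[:, offset:post_end], fs, channels, (offset - onset) / fs)
    return SeizureRecord(
        patient_id=str(ann["patient_id"]),
        seizure_id=str(ann["seizure_id"]),
        preictal=pre,
        ictal=ict,
        postictal=post,
        onset_clock_time=str(ann["clock_time"]),
        type_label=str(ann["type_label"]),
        onset_epoch_time=ann["epoch_time"],
        short_preictal=(onset - pre_start) < ctx,
        short_postictal=post is None or (post_end - offset) < ctx,
    )


# ---------------------------------------------------------------------------
# Marker tables


def write_marker_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a marker table as UTF-8 CSV with stable column order.

    Missing markers are serialized as empty cells (NA), never as 0.
    """
    if len(table) == 0:
        raise ValueError("marker table is empty")
    cols = [c for c in METADATA_COLUMNS if c in table.columns]
    cols += [c for c in MARKER_COLUMNS if c in table.columns]
    cols += [c for c in table.columns if c not in cols]
    table[cols].to_csv(path, index=False, na_rep="", encoding="utf-8")


def read_marker_table(path: str | Path) -> pd.DataFrame:
    """Read a marker table CSV written by :func:`write_marker_table`."""
    df = pd.read_csv(path, encoding="utf-8")
    for col in ("patient_id", "seizure_id"):
        if col in df.columns:
            df[col] = df[col].astype(str)
    return df
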