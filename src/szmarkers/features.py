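"""Epoching and the eight base iEEG features.

Each segment is divided into 1-s non-overlapping epochs; per epoch and channel
we compute line length (sum of absolute first differences), energy (sum of
squared samples), and band power in six canonical bands (delta 1-4, theta 4-8,
alpha 8-13, beta 13-30, low-gamma 30-60, high-gamma 60-100 Hz). Band edges are
half-open ``[low, high)`` except high-gamma, which closes at the 100 Hz global
band-pass edge.

Band power is the total power (Hann-tapered periodogram, ``scaling='spectrum'``)
summed over the frequency bins of the band; with a rectangular taper the six
bands plus the out-of-band remainder partition the signal's mean-square power
(Parseval), which is what the rectangular mode exists to verify.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as _signal

from .io import SignalSegment

__all__ = [
    "BandDefinition",
    "BANDS",
    "FEATURE_NAMES",
    "FeatureMatrix",
    "epoch",
    "line_length",
    "energy",
    "band_power",
    "compute_feature_matrices",
]


@dataclass(frozen=True)
class BandDefinition:
    name: str
    low: float
    high: float
    closed_high: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.low < self.high):
            raise ValueError("band must satisfy 0 < low < high")

    def mask(self, freqs: np.ndarray) -> np.ndarray:
        if self.closed_high:
            return (freqs >= self.low) & (freqs <= self.high)
        return (freqs >= self.low) & (freqs < self.high)


BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
    BandDefinition("lowgamma", 30.0, 60.0),
    BandDefinition("highgamma", 60.0, 100.0, closed_high=True),
)

FEATURE_NAMES: tuple[str, ...] = ("line_length", "energy") + tuple(
    f"power_{b.name}" for b in BANDS
)


@dataclass
class FeatureMatrix:
    """A T x C matrix of one base feature over 1-s epochs."""

    values: np.ndarray
    feature_name: str
    channel_ids: tuple[str, ...]
    epoch_len: float = 1.0
    epoch_starts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be T x C")
        if (self.values < 0).any():
            raise ValueError("feature values must be non-negative")
        if self.epoch_starts is None:
            self.epoch_starts = np.arange(self.values.shape[0]) * self.epoch_len
        self.epoch_starts = np.asarray(self.epoch_starts, dtype=np.float64)

    @property
    def n_epochs(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]


def epoch(segment: SignalSegment, win: float = 1.0) -> np.ndarray:
    """Split a segment into non-overlapping windows.

    Returns an array of shape (T, C, L) where ``L = round(fs * win)``; a
    trailing partial window is discarded.
    """
    L = int(round(segment.fs * win))
    T = segment.n_samples // L
    if T < 1:
        raise ValueError(f"segment of {segment.duration:.3f} s shorter than one {win} s window")
    x = segment.data[:, : T * L]
    return np.transpose(x.reshape(segment.n_channels, T, L), (1, 0, 2))


def line_length(window: np.ndarray) -> float:
    """Sum of absolute sample-to-sample differences of one window."""
    window = np.asarray(window, dtype=np.float64)
    if window.shape[-1] < 2:
        raise ValueError("line length needs at least 2 samples")
    return float(np.sum(np.abs(np.diff(window))))

def energy(window: np.ndarray) -> float:
    """Sum of squared samples of one window."""
    return float(np.sum(np.square(np.asarray(window, dtype=np.float64))))


def _periodogram(windows: np.ndarray, fs: float, taper: str) -> tuple[np.ndarray, np.ndarray]:
    win = "hann" if taper == "hann" else "boxcar"
    freqs, pxx = _signal.periodogram(windows, fs=fs, window=win, scaling="spectrum", axis=-1)
    # undo the taper's noise-power gain (N * sum(w^2) / sum(w)^2; 1.5 for Hann,
    # 1 for boxcar) so summed bins estimate true power under either taper
    n = windows.shape[-1]
    w = _signal.get_window(win, n)
    pxx = pxx / (n * np.sum(w**2) / np.sum(w) ** 2)
    return freqs, pxx


def band_power(
    window: np.ndarray, band: BandDefinition, fs: float, *, taper: str = "hann"
) -> float:
    """Power of one window inside ``band`` (periodogram spectrum summed over bins)."""
    window = np.asarray(window, dtype=np.float64)
    if band.low >= fs / 2:
        raise ValueError(f"band {band.name} lies outside Nyquist ({fs / 2} Hz)")
    freqs, pxx = _periodogram(window, fs, taper)
    return float(pxx[..., band.mask(freqs)].sum())


def compute_feature_matrices(
    segment: SignalSegment, *, taper: str = "hann", win: float = 1.0
) -> dict[str, FeatureMatrix]:
    """Compute all eight T x C feature matrices for a preprocessed segment."""
    wins = epoch(segment, win)  # (T, C, L)
    starts = np.arange(wins.shape[0]) * win + segment.t0_offset
    out: dict[str, FeatureMatrix] = {}

    ll = np.abs(np.diff(wins, axis=-1)).sum(axis=-1)
    out["line_length"] = FeatureMatrix(ll, "line_length", segment.channel_ids, win, starts)
    en = np.square(wins).sum(axis=-1)
    out["energy"] = FeatureMatrix(en, "energy", segment.channel_ids, win, starts)

    freqs, pxx = _periodogram(wins, segment.fs, taper)
    for band in BANDS:
        bp = pxx[..., band.mask(freqs)].sum(axis=-1)
        out[f"power_{band.name}"] = FeatureMatrix(
            bp, f"power_{band.name}", segment.channel_ids, win, starts
        )
    return out
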