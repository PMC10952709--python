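"""Postictal suppression markers: majority/partial durations and strength.

Signal range (max minus min) is computed per channel in 0.5-s non-overlapping
windows. A postictal window on a channel counts as suppressed when its range
falls below the 5th percentile of that channel's preictal ranges. The
proportion of suppressed channels per window, starting 1 s after seizure
offset and followed for up to 120 s, is the suppression profile.

Durations: the profile is thresholded (majority 0.5, partial 0.1) into a
binary state, a centered 2.5-s moving sum bridges short spikes of activity
(state counts as active while at least 3 of the 5 surrounding windows are
above threshold), and the duration runs from the first active window within
the 5-s grace period after the buffer until the first inactive window
thereafter. Durations are capped at the 120-s horizon and a capped value
means "at least 120 s". Suppression strength is the median proportion of
suppressed channels over the whole postictal horizon.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import SignalSegment

__all__ = [
    "SuppressionConfig",
    "SuppressionProfile",
    "SuppressionMarkerSet",
    "range_windows",
    "suppression_map",
    "build_suppression_profile",
    "suppression_durations",
    "suppression_strength",
    "log_duration",
]


@dataclass
class SuppressionConfig:
    window_len: float = 0.5
    majority_threshold: float = 0.5
    partial_threshold: float = 0.1
    buffer: float = 1.0
    horizon: float = 120.0
    moving_sum_len: int = 5
    moving_sum_min: int = 3
    grace_window: float = 5.0
    preictal_percentile: float = 5.0

    def __post_init__(self) -> None:
        for thr in (self.majority_threshold, self.partial_threshold):
            if not (0 < thr <= 1):
                raise ValueError("state thresholds must lie in (0, 1]")
        if self.partial_threshold > self.majority_threshold:
            raise ValueError("partial threshold must not exceed majority threshold")
        if self.moving_sum_min > self.moving_sum_len:
            raise ValueError("moving_sum_min cannot exceed moving_sum_len")


@dataclass
class SuppressionProfile:
    """Suppression map and proportion-suppressed series over the postictal period."""

    suppressed: np.ndarray  # (T, C) bool, windows after the buffer
    p: np.ndarray  # (T,) proportion of suppressed channels
    window_len: float
    start_time: float  # s after seizure offset (buffer end)
    channel_ids: tuple[str, ...] = ()


@dataclass
class SuppressionMarkerSet:
    majority_duration: float
    partial_duration: float
    strength: float


def range_windows(segment: SignalSegment, win: float = 0.5) -> np.ndarray:
    """Per-channel max-minus-min in non-overlapping windows; shape (T, C)."""
    L = int(round(segment.fs * win))
    T = segment.n_samples // L
    if T < 1:
        raise ValueError("segment shorter than one range window")
    x = segment.data[:, : T * L].reshape(segment.n_channels, T, L)
    return (x.max(axis=2) - x.min(axis=2)).T


def suppression_map(
    post_ranges: np.ndarray,
    pre_ranges: np.ndarray,
    *,
    percentile: float = 5.0,
) -> np.ndarray:
    """Boolean (T_post, C): postictal range below the preictal 5th percentile."""
    post_ranges = np.asarray(post_ranges, dtype=np.float64)
    pre_ranges = np.asarray(pre_ranges, dtype=np.float64)
    if post_ranges.shape[1] != pre_ranges.shape[1]:
        raise ValueError("channel mismatch between pre- and postictal ranges")
    if pre_ranges.shape[0] < 20:
        warnings.warn(
            f"only {pre_ranges.shape[0]} preictal range windows per channel; "
            "suppression thresholds may be unstable"
        )
    thresholds = np.percentile(pre_ranges, percentile, axis=0)
    return post_ranges < thresholds


def build_suppression_profile(
    postictal: SignalSegment,
    preictal: SignalSegment,
    config: SuppressionConfig | None = None,
) -> SuppressionProfile:
    """Suppression profile of a seizure from its preprocessed segments.

    The postictal series starts ``buffer`` seconds after seizure offset (the
    segment is assumed to start at the offset) and is truncated at the
    ``horizon``.
    """
    config = config or SuppressionConfig()
    pre_r = range_windows(preictal, config.window_len)
    post_r = range_windows(postictal, config.window_len)
    supp = suppression_map(post_r, pre_r, percentile=config.preictal_percentile)
    skip = int(round(config.buffer / config.window_len))
    n_max = int(round(config.horizon / config.window_len))
    supp = supp[skip : skip + n_max]
    if supp.shape[0] == 0:
        raise ValueError("postictal segment shorter than the buffer")
    return SuppressionProfile(
        suppressed=supp,
        p=supp.mean(axis=1),
        window_len=config.window_len,
        start_time=config.buffer,
        channel_ids=postictal.channel_ids,
    )


def _threshold_duration(p: np.ndarray, threshold: float, config: SuppressionConfig) -> float:
    s = (p >= threshold).astype(int)
    kernel = np.ones(config.moving_sum_len, dtype=int)
    moving = np.convolve(s, kernel, mode="same")  # centered, zero-padded ends
    active = moving >= config.moving_sum_min
    n_grace = max(1, int(round(config.grace_window / config.window_len)))
    head = np.flatnonzero(active[:n_grace])
    if head.size == 0:
        return 0.0
    i0 = int(head[0])
    later_inactive = np.flatnonzero(~active[i0:])
    j = i0 + int(later_inactive[0]) if later_inactive.size else len(active)
    duration = (j - i0) * config.window_len
    return float(min(duration, config.horizon))


def suppression_durations(
    profile: SuppressionProfile, config: SuppressionConfig | None = None
) -> tuple[float, float]:
    """(majority_duration, partial_duration) in seconds, each capped at the horizon."""
    config = config or SuppressionConfig()
    maj = _threshold_duration(profile.p, config.majority_threshold, config)
    part = _threshold_duration(profile.p, config.partial_threshold, config)
    return maj, part


def suppression_strength(profile: SuppressionProfile) -> float:
    """Median proportion of suppressed channels over the postictal horizon."""
    if profile.p.size == 0:
        raise ValueError("empty suppression profile")
    return float(np.median(profile.p))


def log_duration(duration_s: float, *, offset: float = 1.0) -> float:
    """``ln(duration + offset)`` transform keeping zero durations finite."""
    return float(np.log(duration_s + offset))
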