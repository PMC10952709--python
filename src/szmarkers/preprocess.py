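"""iEEG preprocessing: downsampling, noisy-channel removal, re-referencing, filtering.

Pipeline order is fixed: downsample to 256 Hz, detect noisy channels on the
preictal baseline (in cohort mode the union of flagged channels across a
patient's seizures is removed from all of that patient's seizures), re-reference
to the common average, then notch filter at 50 and 100 Hz (2-Hz stop bands) and
band-pass 0.5-100 Hz, all fourth-order zero-phase Butterworth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .io import SeizureRecord, SignalSegment

__all__ = [
    "PreprocessConfig",
    "downsample",
    "detect_noisy_channels",
    "common_average_reference",
    "filter_pipeline",
    "preprocess_record",
]


@dataclass
class PreprocessConfig:
    """Parameters of the preprocessing chain.

    The band-pass upper edge is clipped to ``0.99 * target_fs / 2`` so the
    nominal 100 Hz edge stays legal at a 128 Hz Nyquist.
    """

    target_fs: float = 256.0
    notch_centers: tuple[float, ...] = (50.0, 100.0)
    notch_halfwidth: float = 1.0
    bandpass: tuple[float, float] = (0.5, 100.0)
    filter_order: int = 4
    noise_mad_threshold: float = 5.0
    max_noise_fraction: float = 0.2
    flat_range_fraction: float = 1e-6
    manual_exclude: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.target_fs <= 0:
            raise ValueError("target_fs must be positive")
        lo, hi = self.bandpass
        if not (0 < lo < hi):
            raise ValueError("bandpass must satisfy 0 < low < high")
        if self.noise_mad_threshold <= 0 or not (0 < self.max_noise_fraction < 1):
            raise ValueError("noise thresholds must be positive")

    @property
    def bandpass_hz(self) -> tuple[float, float]:
        lo, hi = self.bandpass
        return lo, min(hi, 0.99 * self.target_fs / 2)


def downsample(segment: SignalSegment, target_fs: float = 256.0) -> SignalSegment:
    """Resample a segment down to ``target_fs`` with polyphase anti-aliasing.

    A segment already at the target rate is returned unchanged; upsampling is
    refused.
    """
    if segment.fs < target_fs:
        raise ValueError(f"refusing to upsample from {segment.fs} to {target_fs} Hz")
    if segment.fs == target_fs:
        return segment
    from fractions import Fraction

    frac = Fraction(target_fs / segment.fs).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    data = signal.resample_poly(segment.data, up, down, axis=1, window=("kaiser", 5.0))
    n_out = int(np.floor(segment.n_samples * target_fs / segment.fs))
    data = data[:, :n_out] if data.shape[1] > n_out else data
    return SignalSegment(data, target_fs, segment.channel_ids, segment.t0_offset)


def _mad(x: np.ndarray, axis=None):
    med = np.median(x, axis=axis, keepdims=True)
    return np.median(np.abs(x - med), axis=axis)


def detect_noisy_channels(
    preictal: SignalSegment, config: PreprocessConfig | None = None
) -> np.ndarray:
    """Flag noisy and flat channels from the preictal baseline.

    Iteratively computes the log of each channel's 95th percentile absolute
    amplitude and removes channels whose robust z-score across channels
    (deviation from the median over the normal-consistent MAD, i.e. MAD x
    1.4826) exceeds ``noise_mad_threshold``, recomputing until stable or until
    ``max_noise_fraction`` of channels has been removed. The consistency
    factor matters here: the statistic is computed across a few dozen
    channels, and an unscaled small-sample MAD denominator fires on ordinary
    sampling variation. Channels with a near-zero amplitude range (relative
    to the median channel range) are removed as flat.

    Returns a boolean keep-mask over channels. Raises if every channel is
    flagged (the recording is uninterpretable).
    """
    config = config or PreprocessConfig()
    if preictal.duration < 10.0:
        warnings.warn("preictal baseline shorter than 10 s; noise detection may be unreliable")
    x = preictal.data
    n_ch = x.shape[0]
    keep = np.ones(n_ch, dtype=bool)

    # flat channels first: range tiny relative to the cohort (here: recording) median
    ranges = x.max(axis=1) - x.min(axis=1)
    med_range = np.median(ranges)
    if med_range > 0:
        keep &= ranges >= config.flat_range_fraction * med_range
    else:
        raise ValueError("all channels flat; uninterpretable recording")

    amp95 = np.percentile(np.abs(x), 95, axis=1)
    log_amp = np.log(np.maximum(amp95, 1e-30))
    max_remove = int(np.floor(config.max_noise_fraction * n_ch))
    removed_by_iter = 0
    while True:
        vals = log_amp[keep]
        if vals.size < 3:
            break
        med = np.median(vals)
        mad = 1.4826 * _mad(vals)  # normal-consistent robust scale
        if mad <= 0:
            break
        scores = np.abs(log_amp - med) / mad
        candidates = keep & (scores > config.noise_mad_threshold)
        if not candidates.any() or removed_by_iter >= max_remove:
            break
        # remove the single worst channel per iteration, then re-estimate
        worst = np.argmax(np.where(candidates, scores, -np.inf))
        keep[worst] = False
        removed_by_iter += 1

    for idx, cid in enumerate(preictal.channel_ids):
        if cid in config.manual_exclude:
            keep[idx] = False
    if not keep.any():
        raise ValueError("all channels flagged as noisy; uninterpretable recording")
    return keep


def common_average_reference(segment: SignalSegment) -> SignalSegment:
    """Subtract the instantaneous mean across channels from every channel."""
    if segment.n_channels < 2:
        raise ValueError("common average reference needs at least 2 channels")
    data = segment.data - segment.data.mean(axis=0, keepdims=True)
    return SignalSegment(data, segment.fs, segment.channel_ids, segment.t0_offset)


def _sos_bandstop(center: float, halfwidth: float, order: int, fs: float):
    return signal.butter(
        order, [center - halfwidth, center + halfwidth], btype="bandstop", fs=fs, output="sos"
    )


def filter_pipeline(
    segment: SignalSegment, config: PreprocessConfig | None = None
) -> SignalSegment:
    """Zero-phase notch (50, 100 Hz) and 0.5-100 Hz band-pass filtering.

    All filters are Butterworth of ``config.filter_order`` applied
    forward-backward (``sosfiltfilt``), so the output has no phase shift and
    the same length as the input.
    """
    config = config or PreprocessConfig()
    fs = segment.fs
    nyq = fs / 2
    sos_list = []
    for center in config.notch_centers:
        hi = center + config.notch_halfwidth
        if hi >= nyq:
            # a stop band touching Nyquist degenerates into a low-pass
            sos_list.append(
                signal.butter(
                    config.filter_order,
                    center - config.notch_halfwidth,
                    btype="lowpass",
                    fs=fs,
                    output="sos",
                )
            )
        else:
            sos_list.append(_sos_bandstop(center, config.notch_halfwidth, config.filter_order, fs))
    lo, hi = config.bandpass_hz
    sos_list.append(
        signal.butter(config.filter_order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    )

    padlen = 3 * (2 * config.filter_order + 1)
    if segment.n_samples <= 3 * padlen:
        raise ValueError(
            f"segment of {segment.n_samples} samples too short for stable zero-phase filtering"
        )
    data = segment.data
    for sos in sos_list:
        data = signal.sosfiltfilt(sos, data, axis=1)
    return SignalSegment(data, fs, segment.channel_ids, segment.t0_offset)


def preprocess_record(
    record: SeizureRecord,
    config: PreprocessConfig | None = None,
    *,
    exclude_channels: tuple[str, ...] = (),
) -> tuple[SeizureRecord, tuple[str, ...]]:
    """Run the full preprocessing chain on one seizure.

    ``exclude_channels`` carries cohort-level removals (the union of channels
    flagged on any of the patient's seizures); channels flagged on this
    seizure's own preictal baseline are removed as well.

    Returns the preprocessed record and the tuple of removed channel labels.
    """
    config = config or PreprocessConfig()
    pre = downsample(record.preictal, config.target_fs)
    ict = downsample(record.ictal, config.target_fs)
    post = None if record.postictal is None else downsample(record.postictal, config.target_fs)

    keep_mask = detect_noisy_channels(pre, config)
    removed = {c for c, k in zip(pre.channel_ids, keep_mask) if not k}
    removed |= set(exclude_channels) & set(pre.channel_ids)
    keep = [c for c in pre.channel_ids if c not in removed]
    if len(keep) < 2:
        raise ValueError("fewer than 2 channels survive noise removal")

    def chain(seg: SignalSegment) -> SignalSegment:
        seg = seg.select_channels(keep)
        seg = common_average_reference(seg)
        return filter_pipeline(seg, config)

    out = replace(
        record,
        preictal=chain(pre),
        ictal=chain(ict),
        postictal=None if post is None else chain(post),
    )
    return out, tuple(sorted(removed))
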