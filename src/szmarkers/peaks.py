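"""Peak severity markers: collapse each ictal feature matrix to one scalar.

For every feature matrix the 95th percentile over time is taken per channel
(linear interpolation between order statistics), the maximum of those
percentiles across channels is the peak activity of the seizure, and the
result is natural-log transformed to normalize its distribution.
"""

from __future__ import annotations

import warnings

import numpy as np

from .features import FEATURE_NAMES, FeatureMatrix

__all__ = ["peak_marker", "peak_marker_set", "PEAK_EPSILON"]

#: Floor substituted for a pathological all-zero feature before the log, so the
#: marker stays finite and ordered below any physical value.
PEAK_EPSILON = 1e-12


def peak_marker(matrix: FeatureMatrix, *, percentile: float = 95.0) -> float:
    """``ln(max over channels of the per-channel 95th percentile over time)``."""
    if matrix.n_epochs < 1 or matrix.n_channels < 1:
        raise ValueError("empty feature matrix")
    per_channel = np.percentile(matrix.values, percentile, axis=0)
    peak = float(per_channel.max())
    if peak <= 0.0:
        warnings.warn(
            f"all-zero {matrix.feature_name} matrix; peak marker floored at ln({PEAK_EPSILON})"
        )
        peak = PEAK_EPSILON
    return float(np.log(peak))


def peak_marker_set(
    matrices: dict[str, FeatureMatrix], *, percentile: float = 95.0
) -> dict[str, float]:
    """The eight log-scale peak markers, keyed ``peak_<feature>``."""
    missing = set(FEATURE_NAMES) - set(matrices)
    if missing:
        raise ValueError(f"missing feature matrices: {sorted(missing)}")
    return {
        f"peak_{name}": peak_marker(matrices[name], percentile=percentile)
        for name in FEATURE_NAMES
    }
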