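"""End-to-end marker computation: one seizure record in, 16 markers out.

Ties the preprocessing chain, the base features, and the three marker
families together and assembles the per-seizure marker table row. Peak
markers and suppression durations are stored log-transformed (natural log;
durations as ``ln(s + 1)``); proportions, recruitment timing, and ictal
duration are stored raw. A marker that cannot be computed (e.g., no
postictal segment, or an empty imprint's recruitment time) is a missing
value, never zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import compute_feature_matrices
from .imprint import ImprintConfig, baseline_stats, imprint, mad_scores, spatial_markers
from .io import MARKER_COLUMNS, SeizureRecord
from .peaks import peak_marker_set
from .preprocess import PreprocessConfig, detect_noisy_channels, downsample, preprocess_record
from .suppression import (
    SuppressionConfig,
    build_suppression_profile,
    log_duration,
    suppression_durations,
    suppression_strength,
)

__all__ = ["MarkerPipelineConfig", "compute_markers", "compute_marker_table"]


@dataclass
class MarkerPipelineConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    imprint: ImprintConfig = field(default_factory=ImprintConfig)
    suppression: SuppressionConfig = field(default_factory=SuppressionConfig)
    log_ictal_duration: bool = False


def compute_markers(
    record: SeizureRecord,
    config: MarkerPipelineConfig | None = None,
    *,
    exclude_channels: tuple[str, ...] = (),
) -> dict:
    """Compute all 16 severity markers for one seizure.

    Returns a flat dict: metadata, the 16 marker values (NaN where a marker is
    undefined for this record), and a semicolon-joined ``flags`` field noting
    removed channels and degenerate conditions.
    """
    config = config or MarkerPipelineConfig()
    flags: list[str] = []
    proc, removed = preprocess_record(
        record, config.preprocess, exclude_channels=exclude_channels
    )
    if removed:
        flags.append("removed_channels:" + "|".join(removed))

    row: dict = {
        "patient_id": record.patient_id,
        "seizure_id": record.seizure_id,
        "onset_clock_time": record.onset_clock_time,
        "type_label": record.type_label,
        "onset_epoch_time": record.onset_epoch_time,
        "short_preictal": record.short_preictal,
        "short_postictal": record.short_postictal or record.postictal is None,
    }

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        ictal_fm = compute_feature_matrices(proc.ictal)
        row.update(peak_marker_set(ictal_fm))

        pre_fm = compute_feature_matrices(proc.preictal)
        base = baseline_stats(pre_fm)
        if base.zero_mad_flagged:
            flags.append("zero_mad_baseline")
        scores = mad_scores(ictal_fm, base, one_sided=config.imprint.one_sided)
        imp = imprint(scores, config.imprint)
        sm = spatial_markers(imp, record.ictal_duration)
        row["prop_channels_ever_recruited"] = sm.prop_channels_ever
        row["prop_channels_max_recruitment"] = sm.prop_channels_max
        row["time_to_max_recruitment"] = sm.time_to_max
        row["prop_duration_to_max_recruitment"] = sm.prop_duration_to_max
        if np.isnan(sm.time_to_max):
            flags.append("empty_imprint")

        scfg = config.suppression
        if proc.postictal is not None and proc.postictal.duration > scfg.buffer + scfg.window_len:
            profile = build_suppression_profile(proc.postictal, proc.preictal, scfg)
            maj, part = suppression_durations(profile, scfg)
            row["majority_suppression_duration"] = log_duration(maj)
            row["partial_suppression_duration"] = log_duration(part)
            row["suppression_strength"] = suppression_strength(profile)
        else:
            flags.append("no_postictal")
            row["majority_suppression_duration"] = np.nan
            row["partial_suppression_duration"] = np.nan
            row["suppression_strength"] = np.nan

    for w in caught:
        if "all-zero" in str(w.message):
            flags.append("zero_peak_feature")

    dur = record.ictal_duration
    row["ictal_duration"] = float(np.log(dur)) if config.log_ictal_duration else dur
    row["flags"] = ";".join(flags)
    return row


def compute_marker_table(
    records: list[SeizureRecord],
    config: MarkerPipelineConfig | None = None,
    *,
    cohort_noise_union: bool = True,
    on_error: str = "raise",
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Marker table for a list of seizures (one row each).

    With ``cohort_noise_union`` (the default), channels flagged as noisy on
    any of a patient's seizures are removed from all of that patient's
    seizures. ``on_error='collect'`` keeps processing after a per-seizure
    failure and returns ``(seizure_id, message)`` pairs for the failures.

    Rows are ordered by (patient_id, onset_epoch_time).
    """
    config = config or MarkerPipelineConfig()
    exclude: dict[str, set[str]] = {}
    if cohort_noise_union:
        for rec in records:
            try:
                pre = downsample(rec.preictal, config.preprocess.target_fs)
                keep = detect_noisy_channels(pre, config.preprocess)
                bad = {c for c, k in zip(pre.channel_ids, keep) if not k}
            except ValueError:
                bad = set()
            exclude.setdefault(rec.patient_id, set()).update(bad)

    rows, failures = [], []
    for rec in records:
        try:
            rows.append(
                compute_markers(
                    rec,
                    config,
                    exclude_channels=tuple(sorted(exclude.get(rec.patient_id, set()))),
                )
            )
        except Exception as exc:  # noqa: BLE001 - cohort robustness
            if on_error == "raise":
                raise
            failures.append((rec.seizure_id, str(exc)))
    table = pd.DataFrame(rows)
    if len(table):
        table = table.sort_values(["patient_id", "onset_epoch_time"], kind="stable")
        table = table.reset_index(drop=True)
    return table, failures
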