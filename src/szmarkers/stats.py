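"""Marker-evaluation statistics.

Within-patient seizure-type contrasts use the two-tailed Wilcoxon rank-sum
test with the effect size ``r = |Z| / sqrt(N)`` (Z the tie- and
continuity-corrected normal-approximation statistic, N the total sample size),
categorized as negligible/small/moderate/large at 0.1/0.3/0.5. Classifier
performance is summarized by the ROC area under the curve evaluated over 100
evenly spaced decision thresholds (acceptable > 0.7, excellent > 0.8,
outstanding > 0.9). Circadian modulation is measured by a rank circular-linear
correlation (circular ranks of time of day against linear ranks of the marker,
via the multiple correlation of the rank on the sine and cosine of the
circular rank) with a 1000-permutation test; longer-term drift by the Spearman
rank correlation against time since the first recorded seizure.

Hierarchical mixed-effects logistic regression fits are deliberately left to
external statistical tooling; :func:`long_format_table` emits a tidy table
ready for such fits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .io import MARKER_COLUMNS

__all__ = [
    "EffectSizeResult",
    "CircadianResult",
    "effect_size_r",
    "effect_category",
    "auc_category",
    "ranksum_effect",
    "roc_auc",
    "circular_linear_rank_corr",
    "longitudinal_corr",
    "long_format_table",
    "evaluate_type_contrast",
    "evaluate_circadian",
    "evaluate_longitudinal",
]


def effect_size_r(z: float, n_total: int) -> float:
    """Rank-sum effect size ``r = |Z| / sqrt(N)``, bounded in [0, 1]."""
    if n_total < 1:
        raise ValueError("N must be positive")
    return min(1.0, abs(z) / np.sqrt(n_total))


def effect_category(r: float) -> str:
    """Conventional effect-size bins: 0.1 (small), 0.3 (moderate), 0.5 (large)."""
    if r < 0.1:
        return "negligible"
    if r < 0.3:
        return "small"
    if r < 0.5:
        return "moderate"
    return "large"


def auc_category(auc: float) -> str:
    if auc > 0.9:
        return "outstanding"
    if auc > 0.8:
        return "excellent"
    if auc > 0.7:
        return "acceptable"
    return "unacceptable"


@dataclass
class EffectSizeResult:
    Z: float
    p: float
    r: float
    n1: int
    n2: int
    category: str


@dataclass
class CircadianResult:
    rho: float
    p_perm: float
    n_perm: int
    n: int


def ranksum_effect(
    group_a: np.ndarray, group_b: np.ndarray, *, continuity: bool = True
) -> EffectSizeResult:
    """Two-tailed Wilcoxon rank-sum test with effect size ``r = |Z|/sqrt(N)``.

    Z uses the normal approximation to the Mann-Whitney U statistic with tie
    correction and (by default) a 0.5 continuity correction toward the mean.
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need at least 2 observations")
    n1, n2 = a.size, b.size
    n = n1 + n2
    ranks = _stats.rankdata(np.concatenate([a, b]))
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    _, counts = np.unique(np.concatenate([a, b]), return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1))
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var <= 0:
        z = 0.0
    else:
        d = u1 - mu
        if continuity and d != 0:
            d -= 0.5 * np.sign(d)
        z = d / np.sqrt(var)
    p = 2.0 * _stats.norm.sf(abs(z))
    r = effect_size_r(z, n)
    return EffectSizeResult(float(z), float(min(p, 1.0)), float(r), n1, n2, effect_category(r))


def roc_auc(
    scores: np.ndarray, labels: np.ndarray, n_thresholds: int = 100
) -> float:
    """Trapezoidal ROC AUC over evenly spaced decision thresholds.

    Scores outside [0, 1] are min-max scaled first; a score at or above a
    threshold predicts the positive class.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(bool)
    if labels.all() or (~labels).all():
        raise ValueError("both classes must be present")
    lo, hi = scores.min(), scores.max()
    if lo < 0 or hi > 1:
        scores = (scores - lo) / (hi - lo) if hi > lo else np.full_like(scores, 0.5)
    thresholds = np.linspace(0.0, 1.0, n_thresholds)
    pred = scores[None, :] >= thresholds[:, None]
    tpr = (pred & labels[None, :]).sum(axis=1) / labels.sum()
    fpr = (pred & ~labels[None, :]).sum(axis=1) / (~labels).sum()
    fpr = np.concatenate([[0.0], fpr, [1.0]])
    tpr = np.concatenate([[0.0], tpr, [1.0]])
    order = np.lexsort((tpr, fpr))  # ties in FPR ordered by TPR (vertical segments)
    return float(np.trapezoid(tpr[order], fpr[order]))


def _circ_linear_rho(u: np.ndarray, cos_t: np.ndarray, sin_t: np.ndarray) -> float:
    """sqrt(R^2) of the multiple correlation of u on (cos, sin)."""
    r_uc = np.corrcoef(u, cos_t)[0, 1]
    r_us = np.corrcoef(u, sin_t)[0, 1]
    r_cs = np.corrcoef(cos_t, sin_t)[0, 1]
    denom = 1.0 - r_cs**2
    if denom <= 0:
        return 0.0
    r2 = (r_uc**2 + r_us**2 - 2 * r_uc * r_us * r_cs) / denom
    return float(np.sqrt(max(0.0, min(1.0, r2))))


def circular_linear_rank_corr(
    clock_times: np.ndarray,
    values: np.ndarray,
    *,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
    period: float = 86400.0,
) -> CircadianResult:
    """Rank circular-linear correlation with a permutation test.

    Times of day (seconds past midnight, period 24 h) are converted to
    circular ranks ``theta_i = 2 pi rank(t_i) / n``; marker values to linear
    ranks. rho is the multiple correlation of the linear ranks on
    ``(cos theta, sin theta)`` and lies in [0, 1]. The permutation p-value
    uses the add-one estimator, so its smallest attainable value is
    ``1 / (n_perm + 1)``.
    """
    t = np.asarray(clock_times, dtype=np.float64) % period
    v = np.asarray(values, dtype=np.float64)
    n = t.size
    if n != v.size:
        raise ValueError("times and values must have equal length")
    if n < 20:
        import warnings

        warnings.warn(f"only {n} seizures; circadian correlation is unreliable below 20")
    if np.unique(v).size < 2:
        return CircadianResult(float("nan"), float("nan"), n_perm, n)
    theta = 2 * np.pi * _stats.rankdata(t) / n
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    u = _stats.rankdata(v)
    rho = _circ_linear_rho(u, cos_t, sin_t)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perms = rng.permuted(np.tile(u, (n_perm, 1)), axis=1)
    # vectorized correlations of each permuted rank vector with cos/sin
    uc = perms - perms.mean(axis=1, keepdims=True)
    su = np.sqrt((uc**2).sum(axis=1))
    cc = cos_t - cos_t.mean()
    sc = sin_t - sin_t.mean()
    r_uc = uc @ cc / (su * np.sqrt((cc**2).sum()))
    r_us = uc @ sc / (su * np.sqrt((sc**2).sum()))
    r_cs = np.corrcoef(cos_t, sin_t)[0, 1]
    denom = 1.0 - r_cs**2
    r2 = (r_uc**2 + r_us**2 - 2 * r_uc * r_us * r_cs) / denom
    rho_perm = np.sqrt(np.clip(r2, 0.0, 1.0))
    p_perm = (1.0 + np.sum(rho_perm >= rho)) / (1.0 + n_perm)
    return CircadianResult(rho, float(p_perm), n_perm, n)


def longitudinal_corr(
    times_since_first: np.ndarray, values: np.ndarray
) -> tuple[float, float]:
    """Spearman rank correlation of a marker against time since first seizure."""
    t = np.asarray(times_since_first, dtype=np.float64)
    v = np.asarray(values, dtype=np.float64)
    if t.size < 3:
        raise ValueError("need at least 3 seizures")
    if np.unique(v).size < 2 or np.unique(t).size < 2:
        raise ValueError("constant input; Spearman correlation undefined")
    res = _stats.spearmanr(t, v)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Cohort-level evaluation on marker tables


def long_format_table(table: pd.DataFrame) -> pd.DataFrame:
    """Tidy long-format export for external (e.g., mixed-model) tooling."""
    meta = ["patient_id", "seizure_id", "type_label", "onset_clock_time", "onset_epoch_time"]
    meta = [c for c in meta if c in table.columns]
    markers = [c for c in MARKER_COLUMNS if c in table.columns]
    long = table.melt(id_vars=meta, value_vars=markers, var_name="marker", value_name="value")
    if "onset_epoch_time" in long.columns:
        first = long.groupby("patient_id")["onset_epoch_time"].transform("min")
        long["time_since_first"] = long["onset_epoch_time"] - first
    return long


def evaluate_type_contrast(
    table: pd.DataFrame,
    type_a: str = "focal",
    type_b: str = "subclinical",
    *,
    min_seizures: int = 5,
    min_per_type: int = 2,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-patient, per-marker rank-sum effect sizes between two seizure types.

    Patients with fewer than ``min_seizures`` seizures overall or fewer than
    ``min_per_type`` of either type are excluded and listed.
    """
    rows, excluded = [], []
    for patient, sub in table.groupby("patient_id"):
        a = sub[sub["type_label"] == type_a]
        b = sub[sub["type_label"] == type_b]
        if len(sub) < min_seizures or len(a) < min_per_type or len(b) < min_per_type:
            excluded.append(str(patient))
            continue
        for marker in MARKER_COLUMNS:
            if marker not in sub.columns:
                continue
            va = a[marker].dropna().to_numpy()
            vb = b[marker].dropna().to_numpy()
            if va.size < min_per_type or vb.size < min_per_type:
                continue
            res = ranksum_effect(va, vb)
            rows.append(
                dict(patient_id=patient, marker=marker, r=res.r, Z=res.Z, p=res.p,
                     n_a=res.n1, n_b=res.n2, category=res.category)
            )
    return pd.DataFrame(rows), excluded


def evaluate_circadian(
    table: pd.DataFrame,
    *,
    min_seizures: int = 20,
    n_perm: int = 1000,
    seed: int | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-patient, per-marker circular-linear correlation with time of day."""
    from .io import clock_time_to_seconds

    rng = np.random.default_rng(seed)
    rows, excluded = [], []
    for patient, sub in table.groupby("patient_id"):
        if len(sub) < min_seizures:
            excluded.append(str(patient))
            continue
        times = sub["onset_clock_time"].map(clock_time_to_seconds).to_numpy()
        for marker in MARKER_COLUMNS:
            if marker not in sub.columns:
                continue
            mask = sub[marker].notna().to_numpy()
            if mask.sum() < min_seizures:
                continue
            res = circular_linear_rank_corr(
                times[mask], sub[marker].to_numpy()[mask], n_perm=n_perm, seed=rng
            )
            rows.append(
                dict(patient_id=patient, marker=marker, rho=res.rho,
                     p_perm=res.p_perm, n=res.n)
            )
    return pd.DataFrame(rows), excluded


def evaluate_longitudinal(
    table: pd.DataFrame, *, min_seizures: int = 20
) -> tuple[pd.DataFrame, list[str]]:
    """Per-patient, per-marker Spearman correlation with time since first seizure."""
    rows, excluded = [], []
    for patient, sub in table.groupby("patient_id"):
        if len(sub) < min_seizures:
            excluded.append(str(patient))
            continue
        t = sub["onset_epoch_time"].to_numpy(dtype=float)
        t = t - t.min()
        for marker in MARKER_COLUMNS:
            if marker not in sub.columns:
                continue
            mask = sub[marker].notna().to_numpy()
            v = sub[marker].to_numpy()[mask]
            if v.size < 3 or np.unique(v).size < 2:
                continue
            rho, p = longitudinal_corr(t[mask], v)
            rows.append(
                dict(patient_id=patient, marker=marker, rho=rho, abs_rho=abs(rho),
                     p=p, n=int(mask.sum()))
            )
    return pd.DataFrame(rows), excluded
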