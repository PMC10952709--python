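"""Baseline statistics, MAD scores, imprint cleanup, and spatial markers."""

import numpy as np
import pytest

import szmarkers as sz
from szmarkers.features import FEATURE_NAMES, FeatureMatrix
from szmarkers.imprint import (
    ImprintConfig,
    baseline_stats,
    imprint,
    mad_scores,
    spatial_markers,
)

# cleanup semantics tests use the minimal persistence rule so single-epoch
# arithmetic is visible; the package default is stricter (null-calibrated)
LOOSE = ImprintConfig(min_run=2, min_channel_total=2)


def feature_dict(col, n_channels=1):
    """All eight features share one T-vector per channel (enough for stats tests)."""
    col = np.asarray(col, dtype=float)[:, None] * np.ones((1, n_channels))
    return {
        name: FeatureMatrix(col, name, tuple(f"c{i}" for i in range(n_channels)))
        for name in FEATURE_NAMES
    }


class TestBaselineStats:
    def test_median_and_mad_example(self):
        with pytest.warns(UserWarning, match="preictal epochs"):
            stats = baseline_stats(feature_dict([1, 2, 3, 4, 5]))
        assert stats.medians[0, 0] == 3.0
        assert stats.mads[0, 0] == 1.0

    def test_constant_column_epsilon_substitution(self):
        with pytest.warns(UserWarning):
            stats = baseline_stats(feature_dict([7.0] * 10))
        assert stats.zero_mad_flagged
        assert stats.mads[0, 0] == pytest.approx(7e-6)

    def test_agreement_with_sort_based_oracle(self, rng):
        cols = rng.gamma(2.0, 1.0, size=(50, 3))
        fms = {
            name: FeatureMatrix(cols, name, ("a", "b", "c")) for name in FEATURE_NAMES
        }
        stats = baseline_stats(fms)
        for c in range(3):
            v = np.sort(cols[:, c])
            med = (v[24] + v[25]) / 2
            mad = np.median(np.abs(cols[:, c] - med))
            assert stats.medians[c, 0] == pytest.approx(med, rel=1e-12)
            assert stats.mads[c, 0] == pytest.approx(mad, rel=1e-12)


class TestMadScores:
    def test_hand_example(self):
        with pytest.warns(UserWarning):
            stats = baseline_stats(feature_dict([1.0, 3.0, 5.0, 7.0, 9.0]))
        # median 5, MAD 2 -> value 15 scores 5.0, value == median scores 0
        ict = feature_dict([15.0, 5.0])
        scores = mad_scores(ict, stats)
        assert scores[0, 0, 0] == pytest.approx(5.0)
        assert scores[1, 0, 0] == 0.0

    def test_tensor_matches_loop_oracle(self, rng):
        pre = rng.gamma(3.0, 2.0, size=(40, 3))
        ict = rng.gamma(3.0, 2.0, size=(5, 3))
        pre_fms = {n: FeatureMatrix(pre, n, ("a", "b", "c")) for n in FEATURE_NAMES}
        ict_fms = {n: FeatureMatrix(ict, n, ("a", "b", "c")) for n in FEATURE_NAMES}
        stats = baseline_stats(pre_fms)
        scores = mad_scores(ict_fms, stats)
        assert scores.shape == (5, 3, 8)
        for t in range(5):
            for c in range(3):
                med = np.median(pre[:, c])
                mad = np.median(np.abs(pre[:, c] - med))
                assert scores[t, c, 0] == pytest.approx(abs(ict[t, c] - med) / mad, rel=1e-12)

    def test_channel_mismatch_rejected(self, rng):
        pre = {n: FeatureMatrix(rng.random((30, 2)), n, ("a", "b")) for n in FEATURE_NAMES}
        ict = {n: FeatureMatrix(rng.random((5, 2)), n, ("x", "y")) for n in FEATURE_NAMES}
        stats = baseline_stats(pre)
        with pytest.raises(ValueError, match="mismatch"):
            mad_scores(ict, stats)


class TestImprintCleanup:
    def _scores(self, flags):
        """Build a score tensor whose any-feature exceedance equals `flags`."""
        flags = np.asarray(flags, dtype=bool)
        scores = np.ones(flags.shape + (8,))
        scores[flags, 0] = 10.0
        return scores

    def test_all_below_threshold(self):
        assert not imprint(np.ones((10, 4, 8)), LOOSE).any()

    def test_isolated_epoch_removed(self):
        flags = np.zeros((10, 3), dtype=bool)
        flags[4, 1] = True
        assert not imprint(self._scores(flags), LOOSE).any()

    def test_consecutive_run_survives(self):
        flags = np.zeros((10, 10), dtype=bool)
        flags[2:5, 3] = True
        flags[2:5, 7] = True
        out = imprint(self._scores(flags), LOOSE)
        assert out.sum() == 6
        np.testing.assert_array_equal(out, flags)

    def test_channel_total_rule(self):
        # two isolated 2-runs on one channel pass min_run but can fail the total
        flags = np.zeros((20, 2), dtype=bool)
        flags[2:4, 0] = True
        flags[10:12, 0] = True
        cfg = ImprintConfig(min_run=2, min_channel_total=5)
        assert not imprint(self._scores(flags), cfg).any()
        assert imprint(self._scores(flags), LOOSE).sum() == 4

    def test_threshold_anti_monotone(self, rng):
        scores = rng.gamma(2.0, 2.0, size=(30, 6, 8))
        low = imprint(scores, ImprintConfig(mad_threshold=4, min_run=2, min_channel_total=2))
        high = imprint(scores, ImprintConfig(mad_threshold=6, min_run=2, min_channel_total=2))
        assert not (high & ~low).any()

    def test_nonfinite_scores_rejected(self):
        scores = np.ones((5, 2, 8))
        scores[0, 0, 0] = np.inf
        with pytest.raises(ValueError, match="finite"):
            imprint(scores)


class TestSpatialMarkers:
    def test_hand_example(self):
        imp = np.zeros((20, 10), dtype=bool)
        imp[7:10, 0] = True  # channels 1 & 2 recruited, simultaneous max at t=7
        imp[7:10, 1] = True
        sm = spatial_markers(imp, 20.0)
        assert sm.prop_channels_ever == pytest.approx(0.2)
        assert sm.prop_channels_max == pytest.approx(0.2)
        assert sm.time_to_max == 7.0
        assert sm.prop_duration_to_max == pytest.approx(0.35)

    def test_full_imprint(self):
        sm = spatial_markers(np.ones((15, 4), dtype=bool), 15.0)
        assert (sm.prop_channels_ever, sm.prop_channels_max) == (1.0, 1.0)
        assert sm.time_to_max == 0.0 and sm.prop_duration_to_max == 0.0

    def test_empty_imprint_missing_not_zero(self):
        sm = spatial_markers(np.zeros((15, 4), dtype=bool), 15.0)
        assert sm.prop_channels_ever == 0.0 and sm.prop_channels_max == 0.0
        assert np.isnan(sm.time_to_max) and np.isnan(sm.prop_duration_to_max)

    def test_earliest_epoch_wins_ties(self):
        imp = np.zeros((10, 4), dtype=bool)
        imp[3, :2] = True
        imp[8, 2:] = True  # same count later
        assert spatial_markers(imp, 10.0).time_to_max == 3.0

    def test_max_leq_ever(self, rng):
        for _ in range(20):
            imp = rng.random((12, 8)) < 0.3
            sm = spatial_markers(imp, 12.0)
            assert sm.prop_channels_max <= sm.prop_channels_ever + 1e-12

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError, match="duration"):
            spatial_markers(np.ones((2, 2), dtype=bool), 0.0)


def test_recruited_channel_recovery(preprocessed_standard):
    """Planted recruitment is recovered through the full feature/imprint chain."""
    proc, truth, _ = preprocessed_standard
    pre_fm = sz.compute_feature_matrices(proc.preictal)
    ict_fm = sz.compute_feature_matrices(proc.ictal)
    scores = mad_scores(ict_fm, baseline_stats(pre_fm))
    imp = imprint(scores)
    detected = set(np.array(proc.ictal.channel_ids)[imp.any(axis=0)])
    assert detected == set(truth.recruited_channels)
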