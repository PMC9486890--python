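"""Time-thresholded ROC profiles, Youden cut-offs, window comparison."""

import numpy as np
import pandas as pd
import pytest

from seroclone import (CohortConfig, compare_windows, roc_auc,
                       simulate_serology_cohort, time_thresholded_auc,
                       windowed_auc, youden_optimal)


def pairwise_auc(scores, labels):
    """Oracle: direct pairwise Mann–Whitney counting."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos, neg = scores[labels == 1], scores[labels == 0]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def enumerate_youden(scores, labels):
    """Oracle: J over every candidate cut-off (>= rule)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    best = 0.0
    cutoffs = []
    for c in np.unique(scores):
        tpr = (scores[labels == 1] >= c).mean()
        fpr = (scores[labels == 0] >= c).mean()
        j = tpr - fpr
        if j > best + 1e-12:
            best, cutoffs = j, [c]
        elif abs(j - best) <= 1e-12:
            cutoffs.append(c)
    return best, cutoffs


class TestRocAuc:
    @pytest.mark.parametrize("scores, labels, expected", [
        ([4, 3, 2, 1], [1, 1, 0, 0], 1.0),     # perfect separation
        ([7, 7, 7, 7], [1, 0, 1, 0], 0.5),     # ties only
        ([3, 1, 2], [1, 1, 0], 0.5),           # 1 win, 1 loss of 2 pairs
    ])
    def test_examples(self, scores, labels, expected):
        assert roc_auc(scores, labels) == pytest.approx(expected)

    def test_single_class_error(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], [1, 1, 1])

    def test_matches_pairwise_counting_oracle(self, rng):
        for _ in range(300):
            n = int(rng.integers(4, 200))
            scores = rng.choice([0, 20, 40, 80, 160, 320], size=n).astype(float)
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            assert roc_auc(scores, labels) == pytest.approx(
                pairwise_auc(scores, labels), abs=1e-12)

    def test_score_negation_complements_auc(self, rng):
        for _ in range(50):
            scores = rng.normal(size=30)
            labels = np.r_[np.ones(15, int), np.zeros(15, int)]
            assert roc_auc(scores, labels) + roc_auc(-scores, labels) == \
                pytest.approx(1.0)


class TestYouden:
    def test_perfect_separation(self):
        assert youden_optimal([4, 3, 2, 1], [1, 1, 0, 0])["J"] == pytest.approx(1.0)

    def test_constant_score_j_zero(self):
        assert youden_optimal([5, 5, 5, 5], [1, 0, 1, 0])["J"] == pytest.approx(0.0)

    def test_tied_maximum_example(self):
        """pos {40,80} vs neg {20,40}: enumeration gives max J = 0.5,
        attained at more than one cut-off; the returned cut-off attains it."""
        scores, labels = [40, 80, 20, 40], [1, 1, 0, 0]
        res = youden_optimal(scores, labels)
        best, cutoffs = enumerate_youden(scores, labels)
        assert best == pytest.approx(0.5)
        assert res["J"] == pytest.approx(best)
        assert res["cutoff"] in cutoffs

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 60))
            scores = rng.choice([0, 20, 40, 80, 160], size=n).astype(float)
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            best, cutoffs = enumerate_youden(scores, labels)
            res = youden_optimal(scores, labels)
            assert res["J"] == pytest.approx(best, abs=1e-12)
            assert any(np.isclose(res["cutoff"], c) for c in cutoffs)

    def test_binary_scores_j_equals_2auc_minus_1(self, rng):
        for _ in range(50):
            scores = rng.integers(0, 2, size=40).astype(float)
            labels = rng.integers(0, 2, size=40)
            if labels.min() == labels.max() or scores.min() == scores.max():
                continue
            j = youden_optimal(scores, labels)["J"]
            # for a positively oriented binary score J = 2*AUC - 1; when the
            # score is anti-discriminating the best >= rule is "call all" (J=0)
            assert j == pytest.approx(max(2 * roc_auc(scores, labels) - 1, 0.0),
                                      abs=1e-12)


def _profile_frame(days, ot, titres):
    return pd.DataFrame({
        "patient_id": [f"p{i}" for i in range(len(days))],
        "days_from_onset": days,
        "ot_status": ["OT" if o else "non-OT" for o in ot],
        "titre_IgA": titres,
    })


class TestTimeThresholdedProfile:
    def test_constant_inclusion_set(self):
        """All samples on day 5: every threshold sees the same data."""
        frame = _profile_frame([5] * 8, [1, 1, 1, 1, 0, 0, 0, 0],
                               [80, 40, 160, 20, 0, 20, 0, 40])
        profile = time_thresholded_auc(frame, "IgA")
        aucs = profile.auc
        assert np.all(aucs == aucs[0])
        assert profile.table["n_included"].is_monotonic_increasing

    def test_single_class_threshold_flagged_missing(self):
        frame = _profile_frame([5, 5, 100, 100], [1, 1, 0, 0], [80, 40, 0, 0])
        profile = time_thresholded_auc(frame, "IgA")
        assert np.isnan(profile.auc[profile.thresholds < 100]).all()
        assert not np.isnan(profile.auc[profile.thresholds >= 100]).any()

    def test_empty_table_error(self):
        with pytest.raises(ValueError):
            time_thresholded_auc(_profile_frame([], [], []).iloc[:0], "IgA")

    def test_permuted_outcomes_auc_near_half(self, cohort, rng):
        """Destroying the outcome-titre link pulls every AUC toward 0.5."""
        samples, _ = cohort
        aucs = []
        for _ in range(40):
            shuffled = samples.copy()
            shuffled["ot_status"] = rng.permutation(shuffled["ot_status"].to_numpy())
            profile = time_thresholded_auc(shuffled, "IgA")
            aucs.append(np.nanmean(profile.auc))
        assert abs(np.mean(aucs) - 0.5) < 0.03

    def test_profile_reproducible(self, cohort):
        samples, _ = cohort
        a = time_thresholded_auc(samples, "IgA").table
        b = time_thresholded_auc(samples, "IgA").table
        pd.testing.assert_frame_equal(a, b)


class TestCompareWindows:
    def _make_profile(self, aucs):
        table = pd.DataFrame({
            "threshold": np.arange(10, 10 * len(aucs) + 1, 10),
            "auc": aucs, "n_included": 50, "youden_j": 0.0, "youden_cutoff": 20.0})
        from seroclone.temporal_roc import TimeRocProfile
        return TimeRocProfile(table, "IgA", 10, int(table["threshold"].max()))

    def test_identical_windows_p_one(self):
        profile = self._make_profile([0.7] * 6)
        assert compare_windows(profile, split_day=30)["p"] == pytest.approx(1.0)

    def test_separated_windows_exact_p(self):
        # {1,1,1} vs {0.5,0.5,0.5}: 2/20 arrangements as extreme
        profile = self._make_profile([1.0, 1.0, 1.0, 0.5, 0.5, 0.5])
        assert compare_windows(profile, split_day=30)["p"] == pytest.approx(0.1)

    def test_insufficient_thresholds_error(self):
        profile = self._make_profile([0.7, 0.8])
        with pytest.raises(ValueError):
            compare_windows(profile, split_day=10)

    def test_null_p_uniformity_on_independent_aucs(self, rng):
        """With per-threshold AUCs drawn independently under the null the
        rank-sum p is approximately uniform."""
        from scipy.stats import kstest
        ps = []
        for _ in range(300):
            profile = self._make_profile(rng.normal(0.5, 0.05, size=37))
            ps.append(compare_windows(profile, split_day=30)["p"])
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_cohort_early_exceeds_late(self, cohort):
        """The programmed pre-resection IgA effect shows as a higher early
        cumulative AUC than the 40-370 complement-window AUC."""
        samples, _ = cohort
        profile = time_thresholded_auc(samples, "IgA")
        late = time_thresholded_auc(samples, "IgA", min_day=30)
        res = compare_windows(profile, late_profile=late)
        assert res["mean_auc_early"] > res["mean_auc_late"]
        assert windowed_auc(samples, "IgA", 30, 370) < res["mean_auc_early"]
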