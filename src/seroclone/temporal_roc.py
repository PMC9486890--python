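"""Sliding time-thresholded ROC discrimination of tumour status.

For each time threshold t on a 10-day grid, samples drawn within t days of
symptom onset are pooled and the ROC AUC of an isotype titre against
ovarian-teratoma (OT) status is computed, together with the Youden-optimal
titre cut-off.  The resulting AUC-versus-threshold profile captures how the
discriminatory value of an isotype decays with time from onset; an early
window can then be compared against a late window with a rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = [
    "TimeRocProfile",
    "roc_auc",
    "youden_optimal",
    "time_thresholded_auc",
    "windowed_auc",
    "compare_windows",
]


def _validate_binary(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D and of equal length")
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary (0/1)")
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    return scores, labels


def roc_auc(scores, labels) -> float:
    """AUC in its Mann–Whitney form: P(score+ > score-) + 0.5 P(tie)."""
    scores, labels = _validate_binary(scores, labels)
    return float(roc_auc_score(labels, scores))


def youden_optimal(scores, labels) -> dict[str, float]:
    """Maximal Youden J = sensitivity + specificity - 1 over titre cut-offs.

    A cut-off calls a sample positive when score >= cutoff; candidate
    cut-offs are the observed score values.  Ties in J are broken toward
    the lower cut-off (the more sensitive rule).
    """
    scores, labels = _validate_binary(scores, labels)
    fpr, tpr, thresholds = roc_curve(labels, scores, drop_intermediate=False)
    j = tpr - fpr
    # roc_curve thresholds are decreasing; argmax on the reversed array
    # returns the lowest threshold among ties.
    idx = len(j) - 1 - int(np.argmax(j[::-1]))
    cutoff = float(thresholds[idx])
    if np.isinf(cutoff):  # the "predict nothing positive" pseudo-threshold
        cutoff = float(scores.max())
    return {"J": float(j[idx]), "cutoff": cutoff}


@dataclass(frozen=True)
class TimeRocProfile:
    """AUC/Youden values over cumulative time thresholds (days from onset)."""

    table: pd.DataFrame  # columns: threshold, auc, n_included, youden_j, youden_cutoff
    isotype: str
    grid_step: int = 10
    max_day: int = 370

    @property
    def thresholds(self) -> np.ndarray:
        return self.table["threshold"].to_numpy()

    @property
    def auc(self) -> np.ndarray:
        return self.table["auc"].to_numpy()

    def window_auc(self, lo: float, hi: float) -> np.ndarray:
        """Per-threshold AUC values with lo <= threshold <= hi (NaN dropped)."""
        mask = (self.thresholds >= lo) & (self.thresholds <= hi)
        vals = self.auc[mask]
        return vals[~np.isnan(vals)]


def time_thresholded_auc(samples: pd.DataFrame, isotype: str,
                         grid_step: int = 10, max_day: int = 370,
                         min_day: int = 0,
                         first_sample_only: bool = False) -> TimeRocProfile:
    """AUC of an isotype titre against OT status for sliding time thresholds.

    For each threshold t in {grid_step, 2*grid_step, ..., max_day}, all
    samples with ``days_from_onset <= t`` are included (cumulative windows).
    Thresholds whose inclusion set contains a single outcome class are
    recorded with NaN AUC rather than raising.

    ``min_day > 0`` builds the complement-window style instead: each
    threshold includes samples with ``min_day < days_from_onset <= t``
    (thresholds at or below ``min_day`` are skipped), so a late-window
    profile can exclude the early samples entirely.

    ``first_sample_only`` optionally de-duplicates to each patient's first
    sample within the threshold (default off: every sample enters).
    """
    if samples.empty:
        raise ValueError("empty sample table")
    col = f"titre_{isotype}"
    cases = samples[samples["ot_status"].isin(["OT", "non-OT"])]
    rows = []
    start = grid_step * (min_day // grid_step + 1) if min_day else grid_step
    for t in range(start, max_day + 1, grid_step):
        sub = cases[(cases["days_from_onset"] <= t)
                    & (cases["days_from_onset"] > min_day)]
        if first_sample_only and not sub.empty:
            sub = sub.sort_values("days_from_onset").groupby("patient_id", sort=False).head(1)
        labels = (sub["ot_status"] == "OT").to_numpy(dtype=int)
        if sub.empty or labels.min() == labels.max():
            rows.append((t, np.nan, len(sub), np.nan, np.nan))
            continue
        scores = sub[col].to_numpy(dtype=float)
        res = youden_optimal(scores, labels)
        rows.append((t, roc_auc(scores, labels), len(sub), res["J"], res["cutoff"]))
    table = pd.DataFrame(rows, columns=["threshold", "auc", "n_included",
                                        "youden_j", "youden_cutoff"])
    return TimeRocProfile(table, isotype, grid_step, max_day)


def windowed_auc(samples: pd.DataFrame, isotype: str,
                 lo: float, hi: float) -> float:
    """Single AUC over the non-cumulative window lo < days_from_onset <= hi."""
    col = f"titre_{isotype}"
    cases = samples[samples["ot_status"].isin(["OT", "non-OT"])]
    sub = cases[(cases["days_from_onset"] > lo) & (cases["days_from_onset"] <= hi)]
    labels = (sub["ot_status"] == "OT").to_numpy(dtype=int)
    if sub.empty or labels.min() == labels.max():
        return float("nan")
    return roc_auc(sub[col].to_numpy(dtype=float), labels)


def compare_windows(profile: TimeRocProfile, split_day: int = 30,
                    late_start: int | None = None,
                    late_profile: TimeRocProfile | None = None) -> dict[str, float]:
    """Early-versus-late comparison of per-threshold AUC values.

    Two-sided Wilcoxon rank-sum (Mann–Whitney) test between the AUC values
    at thresholds <= ``split_day`` and those at thresholds in
    [``late_start``, max_day]; ``late_start`` defaults to the next grid
    point after ``split_day``.  When ``late_profile`` is given (typically a
    complement-window profile built with ``min_day=split_day``, so the late
    side excludes the early samples), the late values are taken from it.
    The exact null distribution is used for small windows, the normal
    approximation otherwise.
    """
    if late_start is None:
        late_start = split_day + profile.grid_step
    early = profile.window_auc(0, split_day)
    late = (late_profile or profile).window_auc(late_start, profile.max_day)
    if len(early) < 2 or len(late) < 2:
        raise ValueError("need >= 2 non-missing AUC values per window")
    method = "exact" if max(len(early), len(late)) <= 12 else "asymptotic"
    res = stats.mannwhitneyu(early, late, alternative="two-sided", method=method)
    return {
        "p": float(res.pvalue),
        "statistic": float(res.statistic),
        "mean_auc_early": float(np.mean(early)),
        "mean_auc_late": float(np.mean(late)),
    }
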