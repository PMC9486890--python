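"""IgA:IgM end-point-titre ratio trajectories.

Negative titres (coded 0) are replaced with 0.1 before forming the
IgA/IgM ratio, so ratios are strictly positive and a fully negative pair
gives ratio 1.  Ratios are summarised per time window from onset by the
geometric mean, the median and Tukey box-plot fences; a pseudo-log
transform is provided for display only — all statistics are computed on
the raw ratios.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "NEGATIVE_REPLACEMENT",
    "iga_igm_ratio",
    "pseudo_log",
    "assign_stratum",
    "ratio_trajectories",
    "window_summary",
]

NEGATIVE_REPLACEMENT = 0.1
DEFAULT_WINDOW_EDGES = (0, 30, 90, 180, 365, 920)


def iga_igm_ratio(titre_iga: float, titre_igm: float) -> float:
    """IgA/IgM end-point ratio with negatives (0) replaced by 0.1."""
    if titre_iga < 0 or titre_igm < 0:
        raise ValueError("titres must be non-negative")
    iga = titre_iga if titre_iga > 0 else NEGATIVE_REPLACEMENT
    igm = titre_igm if titre_igm > 0 else NEGATIVE_REPLACEMENT
    return iga / igm


def pseudo_log(x, base: float = 10.0):
    """Pseudo-log display transform asinh(x/2)/ln(base); linear near 0."""
    return np.arcsinh(np.asarray(x, dtype=float) / 2.0) / np.log(base)


def assign_stratum(row: pd.Series) -> str:
    """Stratum for a sample: OT-pre/post-resection or non-OT.

    OT samples lacking a resection date cannot be placed on either side of
    resection and are flagged ``OT-unknown-resection`` (excluded from the
    pre/post strata by downstream summaries).
    """
    if row["ot_status"] != "OT":
        return "non-OT"
    resection = row.get("resection_day")
    if resection is None or (isinstance(resection, float) and np.isnan(resection)):
        return "OT-unknown-resection"
    return "OT-pre-resection" if row["days_from_onset"] <= resection else "OT-post-resection"


def ratio_trajectories(samples: pd.DataFrame, max_day: int = 920) -> pd.DataFrame:
    """Per-sample IgA:IgM ratios with stratum labels, restricted to max_day."""
    cases = samples[samples["ot_status"].isin(["OT", "non-OT"])].copy()
    cases = cases[cases["days_from_onset"] <= max_day]
    cases["ratio"] = [iga_igm_ratio(a, m) for a, m in
                      zip(cases["titre_IgA"], cases["titre_IgM"])]
    cases["stratum"] = cases.apply(assign_stratum, axis=1)
    return cases[["sample_id", "patient_id", "days_from_onset",
                  "stratum", "ratio"]].reset_index(drop=True)


def _tukey(values: np.ndarray) -> dict[str, float | int]:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = values[(values >= lo_fence) & (values <= hi_fence)]
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_low": float(inside.min()),
        "whisker_high": float(inside.max()),
        "n_outliers": int(values.size - inside.size),
    }


def window_summary(trajectories: pd.DataFrame,
                   window_edges=DEFAULT_WINDOW_EDGES,
                   max_day: int = 920,
                   by_stratum: bool = False) -> pd.DataFrame:
    """Per-window summaries of ratio trajectories.

    Windows are (lo, hi] intervals from consecutive ``window_edges`` (the
    first window also includes day lo); edges must be strictly increasing.
    Each window reports n, geometric mean exp(mean(ln ratio)), and Tukey
    box statistics; empty windows yield a row flagged missing (NaN
    summaries) rather than an error.
    """
    edges = list(window_edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("window edges must be strictly increasing")
    traj = trajectories[trajectories["days_from_onset"] <= max_day]
    strata = sorted(traj["stratum"].unique()) if by_stratum else [None]
    rows = []
    for stratum in strata:
        sub = traj if stratum is None else traj[traj["stratum"] == stratum]
        for lo, hi in zip(edges[:-1], edges[1:]):
            if lo == edges[0]:
                mask = (sub["days_from_onset"] >= lo) & (sub["days_from_onset"] <= hi)
            else:
                mask = (sub["days_from_onset"] > lo) & (sub["days_from_onset"] <= hi)
            vals = sub.loc[mask, "ratio"].to_numpy(dtype=float)
            row = {"stratum": stratum or "all", "window_lo": lo, "window_hi": hi,
                   "n": vals.size}
            if vals.size == 0:
                row.update(geometric_mean=np.nan, median=np.nan, q1=np.nan,
                           q3=np.nan, whisker_low=np.nan, whisker_high=np.nan,
                           n_outliers=0, missing=True)
            else:
                row["geometric_mean"] = float(np.exp(np.mean(np.log(vals))))
                row.update(_tukey(vals))
                row["missing"] = False
            rows.append(row)
    return pd.DataFrame(rows)
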