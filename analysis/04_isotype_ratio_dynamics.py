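#!/usr/bin/env python
"""IgA:IgM end-point-ratio trajectories by resection stratum.

Forms per-sample IgA:IgM ratios (negatives -> 0.1), stratifies OT samples
by pre/post resection, and summarises each time window (to 920 days) with
geometric means and Tukey box statistics.
"""

from pathlib import Path

from seroclone import io, ratio_trajectories, window_summary

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    samples = io.read_serology(RESULTS / "data" / "serology_samples.csv")
    traj = ratio_trajectories(samples)
    traj.to_csv(RESULTS / "ratio_trajectories.csv", index=False)
    summary = window_summary(traj, by_stratum=True)
    summary.to_csv(RESULTS / "ratio_window_summary.csv", index=False)

    first = summary[(summary.window_lo == 0) & ~summary.missing]
    print("geometric-mean IgA:IgM ratio, window 0-30 days:")
    for _, row in first.iterrows():
        print(f"  {row.stratum:22s} gm = {row.geometric_mean:8.2f} (n = {row.n})")
    late = summary[(summary.window_lo == 365) & ~summary.missing]
    print("window 365-920 days:")
    for _, row in late.iterrows():
        print(f"  {row.stratum:22s} gm = {row.geometric_mean:8.2f} (n = {row.n})")
    pre = summary[(summary.stratum == "OT-pre-resection") & (summary.window_lo == 0)]
    non = summary[(summary.stratum == "non-OT") & (summary.window_lo == 0)]
    if not pre.empty and not non.empty:
        fold = pre.iloc[0].geometric_mean / non.iloc[0].geometric_mean
        print(f"early IgA:IgM polarization: OT pre-resection gm is {fold:.0f}x "
              f"the non-OT gm in the first window; at late windows IgM waning "
              f"drives all strata upward.")


if __name__ == "__main__":
    main()
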