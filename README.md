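# seroclone

Statistical toolkit for studying germinal-centre activity in
autoantibody-mediated disease — specifically the serological and B-cell
receptor (BCR) repertoire signatures that distinguish tumour-associated
from non-tumour disease in NMDA-receptor (NR1) antibody encephalitis.
It is written for biostatisticians and computational immunologists who
need the bespoke statistics of such studies as tested, reusable code:

- **Serology** — assay positivity cut-offs (median + raw MAD of control
  sera), end-point titres on a doubling dilution ladder from 1:20, 2×2
  contingency tables with two-sided Fisher exact tests (conditional-MLE
  odds ratios and exact CIs), Benjamini–Hochberg correction.
- **Temporal ROC** — AUC of an isotype titre against ovarian-teratoma
  (OT) status for sliding 10-day time thresholds to 370 days, Youden's
  J = max(sensitivity + specificity − 1) optimal cut-offs, and an
  early-versus-late window Wilcoxon contrast.
- **Isotype dynamics** — IgA:IgM end-point-ratio trajectories (negatives
  replaced with 0.1), stratified by tumour resection, summarised per time
  window by geometric means and Tukey box statistics.
- **Repertoire** — per-cell dominant constant-region calls, V-region
  mutations per kilobase, Hodges–Lehmann rank-sum contrasts between
  isotypes, clonal-expansion odds ratios from repeated downsampling to a
  common cell number (median + percentile CI over 1000 rounds), Wilson
  CIs for constant-region usage.
- **Enrichment** — permutation tests for attribute enrichment within a
  cluster (empirical p = (1 + #{null ≥ obs})/(n_perm + 1)), k-nearest-
  neighbour tissue scores in an embedding, and label-transfer confidence
  filtering (top quartile of max − second-max prediction score).
- **Synthetic data** — seeded generators for a serology cohort (latent
  class-switch processes with a tumour-driven IgA component that decays
  after resection) and paired tumour/blood repertoires (power-law clone
  sizes, isotype-dependent mutation loads, cluster-structured
  embeddings), so every stage is testable without patient data.

Patient-level data from such studies are controlled-access; the package
therefore ships generators that emulate the published cohort structure
(108 patients, ~285 serum samples, 27% tumour prevalence, 508 control
sera) and all analyses run end-to-end on synthetic data.

## Worked example

```python
from seroclone import (CohortConfig, simulate_serology_cohort,
                       contingency_from_calls, fisher_exact,
                       time_thresholded_auc, compare_windows)

samples, controls = simulate_serology_cohort(CohortConfig(seed=2026))
table = contingency_from_calls(samples, "IgA")        # OT vs non-OT
res = fisher_exact(table)
print(f"OR = {res.odds_ratio:.2f} ({res.ci95_low:.2f}-{res.ci95_high:.2f}), "
      f"p = {res.p_two_sided:.2e}")

profile = time_thresholded_auc(samples, "IgA")
late = time_thresholded_auc(samples, "IgA", min_day=30)
c = compare_windows(profile, split_day=30, late_profile=late)
print(f"mean AUC <=30 d: {c['mean_auc_early']:.2f} vs "
      f"40-370 d: {c['mean_auc_late']:.2f}, Wilcoxon p = {c['p']:.3g}")
```

prints

```
OR = 5.39 (2.87-10.30), p = 1.89e-08
mean AUC <=30 d: 0.91 vs 40-370 d: 0.66, Wilcoxon p = 0.00696
```

i.e. in this synthetic cohort IgA positivity is associated with tumour
status (odds ratio ≈ 5), and the association is concentrated in samples
drawn within 30 days of onset: the AUC profile decays once the
post-resection loss of tumour-driven IgA sets in.

The full analysis is organised as numbered drivers:

```bash
python analysis/01_simulate.py              # cohort + repertoire -> results/data/
python analysis/02_serology_contingency.py  # cut-off, Fisher tables, BH
python analysis/03_time_thresholded_roc.py  # AUC profiles, Youden, early/late
python analysis/04_isotype_ratio_dynamics.py
python analysis/05_repertoire_expansion.py  # proportions, mutations, expansion OR
python analysis/06_cluster_enrichment.py    # permutation folds, k-NN, filtering
```

A thin CLI mirrors the same stages (`seroclone run --seed 1 --out out/`;
see `seroclone --help`).

## Layout

```
src/seroclone/     library (serology, temporal_roc, ratios, repertoire,
                   enrichment, synthetic, io, pipeline, cli)
analysis/          numbered narrative drivers writing to results/
tests/             pytest suite incl. statistical acceptance checks
docs/methods.md    models, assumptions, calibration choices
```
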