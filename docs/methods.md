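# Methods

This note documents the statistical procedures the package implements,
the generative models behind its synthetic data, the numerical choices
made where conventions differ, and what the test suite does and does not
establish about real data.

## Serology statistics

**Cut-off.** The assay positivity cut-off is `median + MAD` of control
signals, with the *raw* median absolute deviation — no 1.4826 scaling.
The scaling factor exists only to make the MAD a consistent estimator of
a normal σ; the rule here is a direct robust offset, and assay signal
distributions are not normal. With the default control-signal model
(exponential, median 10) the cut-off lands in (10, 20], so the first
ladder dilution (1:20) becomes the operational positivity threshold.

**End-point titre.** The titre is the last dilution of the *initial
consecutive* positive run of a doubling series from 1:20. Serial
dilution occasionally produces non-monotone runs (prozone effects,
plate noise); the consecutive-run rule is the standard conservative
convention and makes the titre monotone under the addition of higher
positive dilutions. Negative samples are coded 0.

**Fisher exact test.** The two-sided p-value follows the
minimum-likelihood rule: all tables with the observed margins whose
hypergeometric probability does not exceed the observed table's are
summed. The implementation works in exact integer arithmetic
(numerators of the hypergeometric mass over a common denominator), so
probability ties are decided exactly and no floating-point tolerance is
involved; the p is converted to float only on return. The odds ratio is
reported in two flavours, because published studies rarely state which
they used: the conditional maximum-likelihood estimate with an exact
conditional 95% CI (the default, computed by the exact machinery), and
the sample cross-product ad/bc. Zero cells need no continuity
correction for the p-value; CI bounds may be 0 or ∞.

**Multiplicity.** Benjamini–Hochberg step-up adjustment, capped at 1.

## Time-thresholded ROC

For thresholds t ∈ {10, 20, …, 370} days, all case samples with
`days_from_onset ≤ t` are pooled and the AUC of the isotype titre
against OT status computed in Mann–Whitney form (ties count ½). The
grid starts at 10 because a "≤ 0 days" window admits only day-0
samples; both the step and the maximum are configurable. Thresholds
whose window contains one outcome class yield a missing AUC, not an
error. Continuous titres are used as scores (binary positivity loses
information); repeat samples per patient all enter by default, with an
optional first-sample-per-patient de-duplication.

Youden's J is maximised over observed score cut-offs with the "positive
if score ≥ c" rule; ties in J are broken toward the lower (more
sensitive) cut-off. For anti-discriminating scores the best rule is
"call everything positive", so J is never negative.

**Early/late contrast.** The early window takes the per-threshold AUCs
at t ≤ 30 from the cumulative profile. The late comparator (40–370
days) is built as a *complement-window* profile (`min_day = 30`), whose
thresholds include only samples later than day 30 — otherwise the early
samples dominate every late threshold and the contrast is diluted. The
two sets of per-threshold AUCs are compared with a two-sided Wilcoxon
rank-sum test (exact null for ≤ 12 values per side). Per-threshold
AUCs from nested windows are serially dependent, so this p-value is a
descriptive summary rather than a calibrated test — the study design it
mirrors shares this property, and the unit of comparison (thresholds,
not samples) is flagged here deliberately. The machinery itself is
calibrated: on independently drawn per-threshold AUCs the p-values are
uniform (tested).

## Isotype-ratio dynamics

IgA:IgM end-point ratios replace negative (0) titres with 0.1, so
ratios are strictly positive and a doubly negative pair gives 1.
Statistics are computed on raw ratios; the pseudo-log transform
asinh(x/2)/ln 10 is display-only. Windows (default edges 0, 30, 90,
180, 365, 920 days — the published binning is unstated, so these are
package defaults) are summarised by the geometric mean exp(mean(ln r)),
the median, and Tukey fences (whiskers at the last point within
1.5·IQR). OT samples split into pre-/post-resection strata by sampling
day versus resection day; OT samples without a resection date are
flagged and excluded from those strata.

## Repertoire statistics

**Dominant isotype.** Argmax of the constant-region expression vector;
ties break by genomic gene order (IGHM, IGHD, IGHG3, IGHG1, IGHA1,
IGHG2, IGHG4, IGHE, IGHA2); all-zero vectors are "unassigned".

**Mutation load.** Mutations per kilobase of V region,
`count/(length/1000)`. The log10 display value floors the rate at the
equivalent of 0.5 mutations over the cell's own V length so unmutated
cells plot finitely. Pairwise isotype contrasts use the two-sided
Mann–Whitney test with the Hodges–Lehmann shift (median of pairwise
differences) and its Moses rank-sum-inversion 95% CI; BH across pairs.

**Clonal expansion.** The tumour-versus-blood comparison is confounded
by sample size: a larger sample mechanically contains more cells in
multi-cell clones. Both tissues are therefore repeatedly downsampled
without replacement to the smaller tissue's cell count (1000 rounds by
default); within each round a clonotype is *expanded* when ≥ 2 sampled
cells share it (the threshold is configurable — no published definition
exists), the 2×2 table of cells in expanded/non-expanded clonotypes by
tissue is formed, and the OR recorded. The point estimate is the median
over rounds and the 95% CI the 2.5/97.5 nearest-rank percentiles. Table
units are cells by default (a clonotype-weighted variant is provided).
Exact per-round ORs may be 0 or ∞; a Haldane–Anscombe (+0.5) corrected
OR of the full table is retained for finite summaries, as is the full
table's exact Fisher result. Because only the larger tissue is
resampled, the percentile CI omits the smaller tissue's sampling noise
and is mildly anti-conservative; measured null coverage with the
default size imbalance is ~94% (see calibration below).

**Usage proportions.** Wilson score 95% intervals per constant region
over all cells (including "unassigned", so proportions sum to 1). The
Wilson interval behaves well at the boundary proportions these data
produce; a logit-normal alternative was considered and rejected as it
degenerates at 0 and 1.

## Enrichment statistics

**Permutation test.** Observed statistic: proportion of cells in the
target cluster carrying the attribute. Null: shuffle the per-cell
attribute labels (`permute_unit="cell"`, the default — this is the
shuffle of per-cell sample labels when the attribute is the sample) or
permute the sample→attribute assignment keeping samples intact
(`"sample"`). Empirical one-sided p = (1 + #{null ≥ obs})/(n_perm + 1),
never 0; a two-sided variant doubles it. The enrichment fold divides
the observed proportion by the permutation-mean proportion, which is
robust to cluster-size imbalance.

**k-NN tissue score.** Fraction of a cell's k = 200 Euclidean nearest
neighbours (self excluded; coordinate ties by index) carrying the
reference tissue label, in the embedding *as provided* — embeddings are
inputs, never recomputed. The scaled display variant maps the global
tissue fraction to 0.5 piecewise-linearly.

**Label transfer.** Confidence = top − second prediction score; the
top-quartile filter keeps cells at or above the 75th percentile (ties
kept). Label transfer itself is out of scope; a nearest-centroid
softmax classifier exists solely to produce score vectors for testing.

## Synthetic-data generators

**Serology cohort.** Defaults mirror the published cohort scale: 108
patients, ≈ 2.6 samples each (first sample at lognormal median 26 days,
follow-ups at lognormal gaps), 27% OT prevalence, 508 control sera with
1.7% positivity. Each patient carries exponential-waiting-time switch
processes: IgM present from onset with probability 0.55, waning with a
300-day half-life; baseline IgA switching at 0.0018/day in everyone;
and in OT patients a tumour-driven IgA process with hazard multiplier 6
running from 120 days before onset (the tumour predates symptoms) until
resection (lognormal median 30 days), whose antibody output then decays
with a 20-day half-life while baseline output persists. The observed
titre is the larger component snapped *down* to the doubling ladder —
titres exist only on the ladder, negatives are 0. Setting the
multiplier to 1 removes the tumour component entirely, making OT status
exactly independent of serology (the calibration null). Effect sizes
were fixed once to reproduce the published serological pattern — early
AUC ≈ 0.8–0.9 decaying to ≈ 0.6–0.65 in the 40–370-day window, and an
OT–IgA odds ratio of a few — and are not re-fit anywhere.

The exponential-hazard form is a modelling convenience: the true
temporal shape of the tumour-linked class-switch effect is unknown, and
nothing downstream depends on that choice beyond the qualitative
early-effect/late-decay structure.

**Repertoire.** One patient's paired tissues, default 350 tumour and
4500 blood cells (sorted B cells are far scarcer from dissociated
tumour than from blood; two patients at these defaults total ≈ 10k
cells, the scale of a two-patient 10x experiment). Clones share
power-law base sizes (zeta, exponent 2.5, capped at 500); in tumour
tissue the sizes of multi-cell clones are multiplied by 2.2, which
raises the expanded-clone fraction without changing singleton
composition; a multiplier of 1 restores exchangeability. Cells draw a
cluster (8 by default, the last one tumour-biased 1.7×), a latent
isotype from cluster-specific usage (naive-like clusters IGHM/IGHD
heavy, memory-like switched, the last cluster IgA-skewed), an
expression vector dominated by that isotype, a negative-binomial
mutation count (dispersion 2) with isotype-dependent means per kb (IgA1
45, IgA2 48 > IgG1 30 > IgM 12 > IgD 5 — the switched/unswitched
hierarchy), a V length ~ N(330, 25) nt, Gaussian 2-D coordinates around
its cluster centre, and a prediction-score row (softmax of negative
centroid distances) summing to 1.

**What the generators do not emulate:** within-patient serological
autocorrelation beyond a static latent state, CSF/serum titre coupling,
transcriptome counts, sequence-level BCRs, shared clones between
patients, or embedding geometry beyond Gaussian blobs. Passing
calibration on these generators therefore demonstrates that the
*statistics* are correct and calibrated under a faithful null, not that
the biological effect sizes of any real cohort are recovered.

## Calibration and test design

- The exact-test p is verified against exhaustive exact-rational
  enumeration for every 2×2 table with total ≤ 60, and against an
  independent implementation on random larger tables.
- The AUC is verified against direct pairwise Mann–Whitney counting on
  1000 random tied instances (n ≤ 200).
- Permutation-enrichment p-values are checked for uniformity (KS at
  α = 0.01) over 500 null repertoires (isotype independent of cluster;
  300 permutations each — small enough to run routinely, fine enough
  for the KS resolution).
- Expansion-OR null coverage is measured over 300 null repertoires at a
  scaled-down 120/1540 cell split (the default 350/4500 imbalance at
  lower cost); the acceptance bound (≥ 90.5%) is the nominal 95% minus
  binomial Monte-Carlo tolerance and the documented subsampling
  anti-conservatism.
- Serology-null Fisher CI coverage is assessed at *patient* level (one
  sample per patient): repeat samples from one patient are correlated,
  so sample-level tables under-cover by construction, which is a
  property of the unit of analysis rather than of the test.
- The early-versus-late AUC recovery uses 200 replicate cohorts; the
  programmed odds ratio is recovered by comparing the replicate
  distribution against the same generator at n = 20,000 patients.

## Known limitations

- The conditional-MLE OR and exact CI come from the exact
  non-central-hypergeometric machinery; for very large unbalanced
  tables the CI root-finding is the slow path (`compute_ci=False`
  skips it).
- The downsampling CI is a subsampling interval, not a bootstrap of
  both tissues; its mild anti-conservatism is documented above.
- The Wilcoxon early/late p inherits the serial dependence of nested
  windows (descriptive, as discussed).
- The Hodges–Lehmann CI uses the normal approximation for the order
  index; for group sizes beyond ~2000² the pairwise-difference matrix
  is subsampled.
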