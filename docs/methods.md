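# Methods

This note documents the models, conventions and numerical choices
behind `methyloutlier`, and what the synthetic-data tests do and do
not demonstrate about real data.

## Outlier marker selection

A marker (CpG probe) is summarized per sample by its β value, the
methylated-allele intensity fraction, in [0, 1]. Selection applies
three rules in a fixed order, and every marker's report carries the
first rule it failed:

1. **Missingness.** A marker is removed when its missing fraction is
   *strictly greater* than `max_missing_fraction` (default 0.05).
   Exactly 5% missing is retained. Missing values are never imputed
   in the threshold rules; they are simply skipped, and the report
   records how many observations each decision used.
2. **All-cases rule.** Every observed case β must be *strictly*
   greater than `case_min_beta` (default 0.20). A marker whose case
   values are all missing is excluded — absence of evidence is not
   treated as methylation.
3. **Controls rule.** A violation is an observed control β *strictly*
   above `control_max_beta` (default 0.15); the marker is kept when
   the violation fraction is ≤ `control_violation_tolerance` (default
   0.05; 0.0 gives the strict all-controls rule). Because the default
   reading makes "above the threshold" the violation, a control
   exactly at the threshold is tolerated even in strict mode; the
   alternative reading — every control strictly *below* the
   threshold — is available as `control_strict_less=True`.

Survivors are ranked by the odds ratio of the 2×2 table a = cases
above the case threshold, b = cases at/below it, c = controls above
the control threshold, d = controls at/below it, with the
Haldane–Anscombe correction: OR = ((a+½)(d+½))/((b+½)(c+½)). Clean
outlier markers have b = c = 0, so the uncorrected ratio is infinite
and uninformative; the correction maps a perfect 4-case/6-control
marker to 117.0 and keeps the ranking finite and monotone in the
evidence. The correction is isolated in `marker_odds_ratio` so an
alternative definition can be swapped in. Ties in the corrected OR
(common among perfect markers) are broken by the per-marker ROC AUC,
then lexicographically by marker id, making output order
deterministic.

## Panel evaluation

The cumulative methylation value of a two-marker panel is the plain
sum of the two β values (range [0, 2]); for qPCR panels the analogous
sum of percent methylation is used. If exactly one member is missing
the observed value is kept and flagged partial; if both are missing
the sample is excluded from the ROC. This matters little on arrays
filtered at ≤ 5% missingness but keeps the behavior defined.

AUC is computed by midrank: AUC = (R₁ − n₁(n₁+1)/2)/(n₁n₂), which
equals the Mann–Whitney U for the case group divided by n₁n₂ with
ties counting ½ — an identity asserted exactly in the tests.
P-values delegate to `scipy.stats.mannwhitneyu`: the exact null
distribution when n₁+n₂ ≤ 20 and the pooled scores are tie-free,
otherwise the normal approximation with tie and continuity
correction. When every pooled score is identical the test is
degenerate and p = 1 is returned directly. A separate full-enumeration
routine (`mann_whitney_exact_p`, all C(n₁+n₂, n₁) label assignments,
two-sided via |U − n₁n₂/2|, valid under ties because the permutation
null of U is symmetric) is used for the small limit-of-detection
groups, where ties at zero MAF are the norm.

Confidence intervals default to the DeLong placement-variance method.
At perfect separation the DeLong variance is identically zero, so the
lower bound substitutes the simulated bound described below at a true
AUC of 1 − 1/(n₁+n₂), i.e. one misclassified sample; with one case
and one control no finite-precision statement is possible and the
interval is [0, 1]. A stratified percentile bootstrap (seeded,
n ≥ 100 resamples) is the alternative. Heatmap ordering uses
Euclidean distance with complete (or average) linkage after
within-marker mean imputation; it is cosmetic and deterministic.

## qPCR quantification

The quantification model is one template doubling per cycle at 100%
efficiency, anchored on fully methylated control DNA:

* **Percent methylation (ΔΔCt).**
  `100 · 2^[(Ct_marker^ctl − Ct_ACTB^ctl) − (Ct_marker^s − Ct_ACTB^s)]`.
  Values above 100% (sample amplifying earlier than the fully
  methylated control) are reported with a flag, never clipped: the
  formula permits them and clipping would bias panel sums.
* **Copies.** `copies = reference_copies · 2^(reference_ct − Ct)`,
  with the reference 2 ng ↔ 606 haploid genome equivalents (3.3 pg
  per haploid genome; 6.6 pg per diploid cell reproduces
  63 pg ≈ 10 cells). For markers the reference Ct is offset by the
  marker's fully-methylated-control ΔCt, which makes
  MAF = 100·copies_marker/copies_ACTB algebraically identical to
  percent methylation in the noiseless model — consistent with how
  plasma tables report marker/ACTB copy pairs alongside MAF.
* **CMI / total MAF.** Sums over panel markers of the unrounded
  per-marker values; a two-marker CMI can exceed 100 by construction
  and is left uncapped. Rounding (copies to integers, MAF/CMI to two
  decimals) is applied only at reporting. Published plasma tables
  that print rounded copies are internally inconsistent at the second
  decimal for exactly this reason; this package always computes from
  unrounded values.
* **Replicates and dropout.** Numeric replicate Cts are averaged
  arithmetically; an all-NO_AMP replicate set is a dropout (0 copies,
  0%, flag set) and a mixed set uses the numeric replicates with a
  partial-dropout flag. Limit-of-detection analysis instead works per
  replicate, since dropout frequency is itself the signal there.
  A numeric Ct at/above the 40-cycle run limit is coerced to NO_AMP
  with a warning; NO_AMP is a distinct state end to end, never a
  sentinel number.
* **Standard curves.** Mean ΔCt is regressed on log₂(nominal
  methylated fraction); perfect doubling chemistry gives slope −1 and
  R² = 1. Inter-assay CV is sd/mean of the replicate ΔCts per level
  (defined as 0 when the replicates are identical, including the
  all-zero ΔCt at 100%).

## Design bounds

`binomial_lower_bound` is the exact one-sided Clopper–Pearson bound,
`Beta(s, n−s+1).ppf(alpha)`, equal to `alpha^(1/n)` at full success:
25/25 at α = 0.05 → 0.887, the "within 11 percentage points" bound
for a perfect 25-sample group. `auc_lower_bound_sim` draws control
scores from N(0, 1) and case scores from N(√2·Φ⁻¹(AUC), 1) — the
equal-variance binormal ROC model, under which the population AUC is
exactly the requested value — computes the empirical AUC of each
replicate, and returns the α-quantile. At (0.98, 25, 25, 10 000 reps)
the 5th percentile is ≈ 0.949, within 0.01 of the Hanley–McNeil
normal-theory bound 0.946, and rounds to the reported 0.95. A true
AUC of 1 means complete separation; every simulated AUC is 1 and the
bound is 1.0. Whether one simulates fresh datasets (as here) or
bootstraps one fixed perfect dataset makes no difference at this
size; the fresh-dataset reading was chosen as the cleaner generative
statement.

## Synthetic data

The β-matrix generator plants `n_planted` markers whose case values
come from a Beta(20, 5) rescaled to [0.25, 1] and whose control
values come from a Beta(2, 40) rescaled to [0, 0.10], among `n_noise`
markers drawn from one background Beta(0.8, 3) for all samples. The
default cohort is 48 cases vs 656 controls with 8 planted among 992
noise markers. The rescaling is what makes the fixture *clean*: case
mass sits entirely above the 0.20 threshold (checked by
`case_mass_above`, ≥ 99.9% by construction) and control mass entirely
below 0.15, so detector precision and recall are 1.0 almost surely at
any sample size — an unrescaled Beta(2, 40) leaves ≈ 1% of control
mass above 0.15, which at small control counts would make "exact
recovery" a coin flip rather than a property. Missingness defaults to
0 for the same reason and is opt-in.

The qPCR generator computes Ct = reference_ct(target) −
log₂(T/reference_copies)/log₂(1 + efficiency) + N(0, σ), with the
template count T Poisson-sampled from the expected copies; T = 0 is a
non-amplifying well. Poisson sampling is the entire dropout model —
it reproduces the qualitative spike-in pattern (occasional failures
even at 40 copies, frequent at 5, e⁻⁵ ≈ 0.7% fully-zero wells per
marker) without simulating per-cycle PCR stochasticity. The spike-in
layout gives markers the spiked copies plus a configurable healthy
background (default 0) and ACTB a constant 1500-copy background so
the loading control always amplifies; the dilution layout fixes total
DNA (default 606 copies ≈ 2 ng) and scales marker copies by the
nominal percent. Default Ct noise is σ = 0.2 cycles, a typical
well-replicate spread for a tuned TaqMan assay.

### What the synthetic tests do and do not show

Passing tests demonstrate that the algorithms are implemented
correctly and behave as specified under their own assumptions:
planted markers are recovered exactly, quantification round-trips are
exact in the noiseless model, simulated dilution series stay linear
(R² > 0.90 at σ = 0.2), and a 5-copy spike-in separates from a clean
blank at the exact-test floor p = 2/924. They do not show that the
selection thresholds are optimal for any particular cancer contrast,
that real 450K noise is Beta-distributed or independent across
samples and probes (it is not: probes are correlated along the
genome, batches and tumor purity shift whole distributions), or that
real blank plasma is methylation-free — published healthy plasma
shows low-level positives, which is why the background rate is a
parameter rather than an assumption.

## Problem sizes and defaults used in tests

Detector oracle checks run on random matrices up to 50 markers × 20
samples; recovery checks on 20 seeded matrices of 1000 markers × 100
samples (25 cases / 75 controls, the generator's clean
distributions); exact-p enumeration up to combined n = 12 against an
independent brute-force oracle; the AUC-bound simulation at 10 000
replicates. These sizes make the full suite run in about a minute on
one CPU while keeping every enumeration exact.

## Known limitations

* Case/control only; no multi-class selection and no covariate
  adjustment in the ROC machinery.
* The odds ratio is threshold-based by design; markers that separate
  groups without crossing the fixed thresholds are invisible to it.
* DeLong intervals are asymptotic; for very small panels prefer the
  bootstrap or the exact enumeration p-values.
* The qPCR simulator models template sampling and Ct noise only — no
  amplification-efficiency drift, inhibition, probe cross-talk, or
  bisulfite-conversion failure.
* IDAT parsing, normalization, probe QC and genomic annotation are
  out of scope; inputs are assumed to be level-3-style β matrices.
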