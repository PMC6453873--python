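# Methods

## The procedure

`modytree` builds and evaluates sequential one-vs-rest decision trees over
four diagnostic groups: HNF1A MODY, GCK MODY, type 1 diabetes (T1D) and
type 2 diabetes (T2D). The candidate marker pool is fasting serum C-peptide
(ng/ml), BMI (kg/m²), 1,5-anhydroglucitol (μg/ml), hsCRP (mg/l) and fasting
glucose (mmol/l); all markers enter untransformed, in raw units.

**Forward selection (per group).** For a target group against the pooled
rest, each marker's single-marker C-statistic is computed and
orientation-corrected (flipped so AUC ≥ 0.5). Starting from the best single
marker, each unused marker is tried as an addition by refitting the
logistic model; the addition with the largest AUC gain is retained only if
DeLong's paired test against the current model gives p < α (two-sided;
default α = 0.05). Selection stops when no addition qualifies. A candidate
fit that hits separation is skipped with a warning rather than aborting the
search. The choice of DeLong's test as the significance gate is ours: it is
the standard test for nested, correlated ROC comparisons.

**Group peeling.** At each tree step, forward selection is run for every
remaining group; the group with the highest selected-set AUC becomes the
step's target. Its composite index and threshold are frozen and its records
removed; the loop repeats until two groups remain, whose split is the last
step. Exact AUC ties are broken toward the smaller marker set, then a fixed
group order (T1D, T2D, HNF1A, GCK). Steps require at least 10 records per
remaining group, and a best AUC ≤ 0.5 + 10⁻⁶ aborts with a degeneracy
error. Record order is canonicalized (sort by patient id) before fitting,
so permuting rows reproduces the tree bit-for-bit.

**Composite index.** A fitted model `β₀ + β₁m₁ + … + βₖmₖ` is reduced to
the index `m₁ + (β₂/β₁)m₂ + … + (βₖ/β₁)mₖ`. Dividing by the lead
coefficient fixes the lead weight at 1 (the form in which such indices are
reported clinically); the sign of β₁ sets the direction
(higher- vs lower-is-positive) and the intercept is absorbed into the
threshold. The index is a strictly monotone function of the linear
predictor, so its ROC properties are identical — a property the tests
assert exactly. Re-derived trees keep full coefficient precision; the
published indices carry their printed weights (0.16, 1.56).

**Thresholds.** Build-time thresholds maximize the Youden index
J = sensitivity + specificity − 1 over all observed cutpoints, breaking
ties toward the smallest threshold (the selection rule behind the published
thresholds is not stated; Youden is our default, and fixed thresholds can be
imposed instead). A score exactly at a threshold follows the tree's
`boundary` convention: `"strict"` (the shipped published tree — boundary
scores take the non-target branch) or `"inclusive"` (rebuilt trees, under
which build-time Youden sensitivity/specificity are exact on the training
data).

**Evaluation.** A tree is applied to a cohort retaining misclassified
records at each step, exactly as a clinic would run the cascade. Reports
contain the 4×4 confusion matrix, per-group correct counts and percentages
(one decimal, rounded half-up, matching clinical reporting style) and
per-step branch tallies (per true group: how many records reached the step
and how many took the target branch).

## ROC machinery

The C-statistic is the tie-aware Mann–Whitney probability; its variance and
the paired test use DeLong structural components computed via midranks
(O((m+n) log(m+n))). Confidence intervals are Wald on the AUC scale with the
DeLong standard error, clipped to [0, 1] — chosen because the symmetric
intervals match how such CIs are usually printed; no exact small-sample or
bootstrap CI is attempted, and published CI widths are not expected to be
reproduced exactly. Classes with a single member contribute zero variance
(their component covariance is not estimable). ROC curves are stepwise over
all unique cutpoints with a +inf sentinel, so the trapezoidal area equals
the pairwise AUC to 10⁻¹²; this equivalence is asserted in the tests.

## Logistic regression

IRLS with the deviance as convergence criterion (change < 10⁻⁸, at most 100
iterations) and step-halving, which makes the deviance monotone
non-increasing — an invariant the tests check. Wald standard errors come
from the inverse observed information at convergence. Complete separation
(deviance collapsing to zero with perfect prediction) and quasi-complete
separation (coefficient·scale exceeding 10⁴) raise an explicit error naming
the markers; no penalization or Firth correction is applied, keeping the
fits plain maximum likelihood. Models contain an intercept plus the chosen
markers only.

## Synthetic cohorts

The simulator's defaults are the study conditions: group sizes 77 (HNF1A),
88 (GCK), 99 (T1D), 92 (T2D), and per-group marker distributions anchored
to the published group summaries.

* **Median/quartile biomarkers** (hsCRP, 1,5-AG, C-peptide) are drawn from a
  split lognormal, `exp(μ + σ_lo·Z)` for standard-normal Z < 0 and
  `exp(μ + σ_hi·Z)` otherwise, with μ = ln(median) and each σ set from its
  quartile: the law reproduces the printed median and both quartiles
  exactly. A single-σ lognormal (also provided, via
  `fit_lognormal_from_quantiles`) can match only the median and the
  log-scale IQR, and the printed quartiles are visibly asymmetric on the
  log scale, which is why the simulator uses the split form. The skewed-law
  choice itself mirrors the reporting convention: variables summarized by
  quartiles are skewed.
* **Mean ± SD variables** (age, duration, age at diagnosis, BMI, creatinine,
  HbA1c, fasting glucose) are truncated normals with per-variable
  plausibility bounds (e.g. BMI in (10, 80) kg/m², HbA1c in (3, 20) %).
  Truncation slightly shifts means for variables with mean ≈ SD (e.g. GCK
  age at diagnosis); the affected variables are not tree inputs.
* **T1D C-peptide** is a detection-floor mixture: with probability
  `floor_prob` (default 0.50) the value is the floor (default 0.01 ng/ml),
  otherwise a lognormal tail clipped at the floor. The printed median and
  Q1 both equal 0.01, forcing at least half the mass onto the floor, and the
  tail is anchored so the group's overall 75th percentile is 0.10 ng/ml.
  The tail's log-scale spread is not identified by any printed summary; the
  default 0.8 places the detectable tail over ~0.02–0.5 ng/ml, consistent
  with C-peptide being undetectable in most but not all such patients. Both
  floor value and floor probability are exposed because the assay's
  detection limit and the exact undetectable fraction are not published.
* **Sex and treatment** are drawn from the published group percentages;
  they are carried on records but unused by the tree.

Markers are independent within patient (no joint structure is published);
one root seed feeds deterministic per-(group, variable) substreams, so
adding a variable never perturbs the others' draws.

**What passing tests show — and do not.** On these synthetic cohorts the
builder recovers the published tree structure (T1D first on C-peptide
alone, T2D second on C-peptide + BMI, then the MODY split) in essentially
every seed, and cascade accuracy shows the published qualitative ordering
(T1D best, the MODY pair worst). Exact published AUCs, thresholds and rates
are *not* reproduced: real patients' markers are correlated (obesity with
C-peptide, glycemia with 1,5-AG), tails need not be lognormal, and the
independence assumption typically makes synthetic discrimination slightly
easier at step 1 and different in the MODY split (where the rebuilt
hsCRP weight can differ substantially from 1.56). Matching the printed
marginals therefore validates the algorithmic machinery, not the clinical
performance estimates.

## Numerical choices and problem sizes

* Percentages are rounded half-up to one decimal via exact decimal
  arithmetic (92/99 → 92.9), never via binary-float rounding.
* Cohort CSVs round-trip floats exactly (shortest-repr writing,
  round-trip parsing).
* Youden ties break toward the smallest threshold; marker-pool order is
  canonicalized so pool reordering cannot change a tree.
* Monte-Carlo checks use moderate, fixed sizes chosen to keep the suite
  fast while leaving comfortable statistical margins: 1,000 replicates at
  n = 100 for the DeLong null calibration, 25 seeds at the study-group
  sizes for structure recovery, and 10⁵ draws per group for simulator
  quantile fidelity (2% relative tolerance, dominated by sampling error of
  ~0.5%).

## Known limitations

* Apparent (training) performance only: no cross-validation or optimism
  correction of step AUCs, matching the evaluated design.
* No within-patient marker correlation by default; a Gaussian-copula
  extension would slot into the sampler but is not implemented.
* No probabilistic class membership, cost-weighted thresholds, partial AUC
  or exact small-sample CIs.
* Age, diabetes duration and age at diagnosis are drawn independently, so a
  simulated patient's three values need not be mutually consistent; none is
  a tree input.
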