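# Methods

## Overview

`cogclust` screens medications for association with cognitive status in a
dementia-registry cohort by (i) clustering patients at each follow-up in the
(MMSE score, MMSE decline) plane with k-means, (ii) testing every drug's usage
proportion between every cluster pair, and (iii) repeating the whole step over
Monte-Carlo simulations, declaring only stable associations. This note records
the model, its assumptions, the tunable parameters, and the design choices
made where more than one reasonable construction exists.

## Cohort preparation

**Eligibility.** A patient enters the analysis with a baseline diagnosis of
Alzheimer's disease (AD) or mixed dementia (MD), a non-missing baseline MMSE,
and at least one follow-up with MMSE (a decline needs two measurements).
Exclusions are counted flowchart-style against the first rule that removes a
patient, so the counts always conserve the input total.

**MMSE decline.** At follow-up *f*, decline = MMSE(f) − most recent prior
non-missing MMSE. Negative values mean deterioration. When an intermediate
visit lacks MMSE, the difference is taken against the last measured value
rather than dropping the row; rows with no prior measurement get a missing
decline and are excluded from clustering.

**Exposure window.** A drug (identified by its full ATC code) is a current
exposure at a visit iff a dispensation falls in the **closed** interval
[visit − 100 days, visit]. The closed boundary is a deliberate convention — a
same-day or an exactly-100-days-old dispensation counts — fixed so that the
window rule is bit-exactly testable. `window_days` is configurable;
exposure is monotone in it by construction.

**Prevalence filter.** Drugs used in strictly more than 5% of *all* cohort
observations (baseline + follow-ups of eligible patients) are kept. Strict
inequality and the all-observations denominator are conventions of this
package; the threshold is configurable in (0, 1).

## Clustering

k-means (k-means++ initialization, 10 restarts, tolerance 1e-4 on centroid
movement, max 300 iterations) is run per follow-up on **standardized**
coordinates: each axis is centered and scaled to unit variance within the
follow-up table. MMSE spans 0–30 while declines span roughly ±15, so raw
Euclidean distance would be dominated by the score axis; standardization can
be disabled (`scale=False` / `--no-scaling`) for sensitivity analysis.
Centroids are always reported in original units.

**Choosing k.** Three diagnostics are computed over a candidate range
(default 1–8): the inertia curve (elbow), the mean silhouette (k ≥ 2, on a
5,000-point subsample when n is larger), and the gap statistic in the
Tibshirani construction — B = 10 reference datasets drawn uniformly over the
bounding box of the scaled data, gap(k) = mean_b log W*_kb − log W_k, with
SE = sd_b(log W*)·sqrt(1 + 1/B). The combined rule: take the smallest k
satisfying the gap 1-SE criterion (gap(k) ≥ gap(k+1) − SE(k+1)); if that k
is 1, report "no structure" and stop; otherwise require it to lie within ±1
of the elbow knee (the point of maximum chord distance on the normalized
inertia curve), preferring the silhouette-maximizing k when several k satisfy
both. If no k satisfies the joint rule the gap candidate is returned with a
warning. The special-casing of k = 1 reflects that the gap statistic is the
only one of the three diagnostics able to diagnose the absence of cluster
structure — an elbow always exists numerically. k can also be fixed directly
(default 4), which is how the screen is normally run.

**Canonical labels.** With k = 4 the raw clusters are mapped to the four
cognitive archetypes by z-scoring the four centroids among themselves per
axis and solving a minimum-cost perfect matching (Hungarian algorithm)
against four fixed reference points in that normalized space:
(+1, +1) high score/no decline, (+1, −1) high score/decline,
(−1, +0.5) low score/little decline, (−1, −1.5) high decliners. Matching on
self-normalized centroids makes the labeling invariant to units, to row
order, and to permutations of the raw cluster indices, and requires no
external calibration data. This matching is what allows Z-scores to be
averaged across simulations: without it, cluster-index permutations between
runs would corrupt every aggregate.

## The association screen

**Test.** For clusters a < b (canonical labels) and drug d: pooled two-sided
two-proportion Z-test without continuity correction. Positive z ⇒ higher
usage in the lower-numbered (better-cognition) cluster. A pooled proportion
of exactly 0 or 1 carries no information and returns (z, p) = (0, 1).

**Multiplicity.** BH step-up at q = 0.05 is applied within each family of m =
(number of included drugs) tests defined by one (cluster pair, follow-up)
combination — six families per follow-up. Families are not pooled; this
mirrors a pairwise-cluster analysis in which each comparison is corrected on
its own.

**Monte-Carlo stability.** Between simulations only the k-means seed varies
by default (`bootstrap=True` additionally resamples patients with
replacement, a strictly harder stability requirement). Each simulation's
clusters are canonicalized before aggregation. Per (drug, pair, follow-up)
the package reports the mean z, the fraction of simulations with BH
rejection, and the verdict `final_significant = fraction ≥ 0.80`. The
threshold is configurable; raising it can only remove verdicts.

**Simulation count.** Either fixed (100 at published scale) or `auto`: a
20-simulation pilot estimates the per-drug standard deviation σ of the
Z-scores, and N = ceil((CL·σ_max/∅)²) with CL = 2.576 (99% normal quantile)
and precision ∅ = 0.1, floored at 1 and capped at 1,000.

**Odds ratios.** For declared associations the 2×2 table
[[users_a, n_a−users_a], [users_b, n_b−users_b]] from the best-inertia
(reference) simulation yields a conditional maximum-likelihood odds ratio
with an exact conditional (Cornfield-type) 95% CI and Fisher's exact
two-sided p. The conditional-MLE/exact-CI pair was chosen because it is the
exact-test-consistent estimator for small strata; the cross-product sample OR
is within a few percent on the table sizes seen here. A zero margin leaves
the OR undefined (reported missing, not continuity-corrected); a single zero
cell keeps its finite exact bound. By default ORs are computed only for
declared associations (`or_policy="significant"`), since they are the
reporting payload, not part of the decision rule; `"all"` and `"none"` are
available.

## Synthetic registry generator

The generator emulates the relevant structure of a national dementia registry
linked to dispensation records, with full ground truth:

- **Cognition mixture.** Each (patient, follow-up) draws a true archetype
  component from fixed weights (defaults 0.39/0.29/0.195/0.125, shaped like
  observed first-follow-up cluster sizes) and a (score, decline) pair from
  that component's Gaussian. Default means (25, +1), (23, −5.5), (15, −0.5),
  (12, −10) with axis-aligned covariances; these are deliberately
  well-separated archetypes chosen from the qualitative cluster description,
  not fitted values — no per-cluster centroid values are publicly available.
- **MMSE construction.** Visit MMSE values are the drawn scores rounded and
  clipped to the integer range 0–30; the baseline is score − decline of the
  follow-up-1 draw. Realized declines are therefore *exactly* consistent with
  consecutive table values. Two consequences are intentional: (i) the 0–30
  ceiling censors large implied baselines, attenuating the realized decline
  of the high-score/declining archetype (a real feature of a bounded scale;
  the tests account for it with the censored-normal closed form), and
  (ii) at follow-ups ≥ 2 the realized decline reflects component
  *transitions* (current score minus the previous visit's score), so the
  drawn decline component is honored exactly only at follow-up 1.
  Recovery-style tests are anchored at follow-up 1 for this reason.
- **Drugs.** 26 medications: 16 named drugs with real ATC codes and injected
  per-component log-odds offsets consistent with their reported directions,
  plus 10 null placeholders; all marginal prevalences exceed 5%. Exposure at
  a visit is Bernoulli with logit = logit(baseline prevalence) + offset of
  the current true component (the baseline visit shares the follow-up-1
  component). Exposed visits get a dispensation dated uniformly within the
  100-day window; unexposed visits get either none or (with probability 0.3)
  a stale one 101–200 days back. Minimum inter-visit gaps of 210 days
  guarantee windows never overlap, so the visit-level exposure bit
  round-trips exactly through the dated events and the window logic in
  preparation is genuinely exercised.
- **Attrition and noise.** Dropout probabilities per interval (default 0.10,
  0.65, 0.60, chosen to echo the observed cohort-size profile across
  baseline and three follow-ups — the observed attrition is not geometric,
  so a vector rather than a scalar), independent of cluster membership; 2%
  missing MMSE per follow-up visit; ~1% non-AD/MD diagnoses to exercise the
  eligibility rules.
- **Randomness.** One global seed expands through named `SeedSequence`
  substreams (demographics, trajectories, attrition, dates, one per drug),
  so adding a drug never perturbs the trajectories. Identical config + seed
  gives byte-identical tables.

**What the generator does not emulate** — and hence what passing tests do not
show about real data: informative dropout (attrition independent of
cognition by default), measurement error and practice effects in MMSE,
within-patient autocorrelation of exposure beyond the visit level,
confounding by indication, co-prescription correlation between drugs, and
mortality as a distinct process. Results on synthetic data validate the
*machinery* (recovery, FDR control, stability), not clinical conclusions.

## Operating characteristics (computed by the test suite / acceptance script)

- **Null FDR study.** 200 replicate cohorts with every drug independent of
  cognition (offsets 0, n = 3,000, 26 drugs, prevalences 0.05–0.40), each
  screened with 20 simulations. The false-discovery proportion is computed
  per BH family — one (cluster pair, follow-up), the unit at which the
  correction is applied and the unit carrying its guarantee — as
  V/max(R, 1), and averaged over the 18 families and 200 replicates. Note
  that under a *global* null any procedure applying BH per family will show
  a much larger probability (~1 − 0.95^18) that *some* family somewhere
  makes a false call; that pooled quantity is not controlled by per-family
  BH and is not the reported measure.
- **Planted-effect study.** One drug with a +0.8 log-odds offset in the
  high-decliner archetype at 15% baseline prevalence, equal component
  weights, n = 5,000 (≥ 1,000 patients per cluster at follow-up 1); the
  study reports the fraction of replicate screens declaring that drug in a
  pair involving that cluster.

Problem sizes in the routine suite (10,000-patient fixtures, 200×3,000-patient
null replicates, 20-simulation screens) are the package's chosen desk-scale
defaults; every size is a parameter and can be raised to published scale
(15,428 patients, 100 simulations) without code changes.

## Known limitations

- Semantic archetype labels are defined only for k = 4; other k values fall
  back to arbitrary-but-deterministic raw labels.
- The two-proportion Z-test is a normal approximation; in very small clusters
  (late follow-ups under heavy attrition) its p-values are discrete and the
  empirical FDR bound relies on the BH correction absorbing that.
- The exact-CI construction for the odds ratio is one of several in
  legitimate use; sample (cross-product) ORs can differ slightly from the
  conditional MLE on small tables.
- Monte-Carlo variation spans k-means initialization (optionally bootstrap),
  not data re-collection; stability claims are relative to that source of
  variation.
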