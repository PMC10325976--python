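# Methods

## Score stratification model

Each deleteriousness score (CADD, phred-scaled and unbounded above; VIPUR, a
probability-like score in [0, 1]) is modeled marginally as a two-component
univariate Gaussian mixture with unequal variances,

    f(x) = w_lo N(x; mu_lo, s2_lo) + w_hi N(x; mu_hi, s2_hi),

the low component standing for tolerated missense changes and the high
component for functionally damaging ones. Two components are fixed a priori
(no model selection): the question the model answers is binary — does the
variant sit in the damaging score regime or not.

**Fitting.** Plain EM. Initialization is deterministic: component means at
the 25th/75th percentiles of the data (falling back to min/max when the
percentiles coincide under heavy ties), both variances at the overall sample
variance (ddof = 1), weights 0.5/0.5. No random restarts — reproducibility of
the derived cutpoints matters more here than escaping rare bad local optima,
and the intended inputs (clearly bimodal score sets) are benign for EM.
Convergence is declared when the relative log-likelihood change per iteration
falls below `tol = 1e-8` (default cap 500 iterations). The log-likelihood
sequence is retained on the fit object so the EM ascent property is checkable
per fit. Variances are floored at `1e-6 ×` the overall sample variance to
prevent singular collapse onto a single point; fits that touch the floor are
flagged (`variance_floor_hit`). Inputs with fewer than 4 finite values, or
with zero range, are rejected.

**Cutpoint.** The operational threshold is data-anchored rather than
analytic: among observed scores at or above the low-component mean whose
posterior probability of the high component exceeds 1/2, the minimum is the
cutpoint. This matches how such thresholds are reported clinically ("24 or
higher"): as the smallest observed score in the high cluster, not as the
posterior-0.5 crossing of two fitted densities. A warning is emitted when the
MAP assignment is non-monotone over the observed score range (possible when
the high component has much larger variance) and when no observation maps to
the high component (cutpoint undefined).

**Tier rule.** Flags are boundary-inclusive (score ≥ cutpoint → high). Both
flags high → deleterious; exactly one high → possibly deleterious; otherwise
benign. A missing VIPUR score (no structural model available) leaves the call
to CADD alone: high CADD → possibly deleterious, low CADD → benign. A missing
CADD is an error since CADD is defined for every variant in scope.

**Group comparison and ellipses.** Score distributions across phenotype
groups (variants reported with MMA, aortic disease, other arteriopathy, or
from the study cohort) are compared pairwise with the exact Mann–Whitney
kernel below; variants lacking the score are dropped with a warning. Group
clouds are summarized by normal-theory confidence ellipses: sample mean,
sample covariance (n−1), semi-axes `sqrt(lambda_i * chi2.ppf(level, 2))`
along the covariance eigenvectors (level defaults to 0.95, quantile 5.9915).

## Exact tests

**Mann–Whitney.** The p-value is exact under the permutation null conditional
on the observed pooled multiset, with ties handled by midranks: midranks are
doubled to integers and a shift-algorithm dynamic program counts, for every
attainable doubled rank sum s, the number of size-n subsets attaining s. The
two-tailed p is `min(1, 2·min(lower tail, upper tail))`, both tails inclusive
of the observed value. Counts are accumulated in float64: exact for the small
problems where enumeration is feasible, and at cohort sizes (counts up to
~1e19) correct to ~1e-16 relative error, far below reporting precision. The
asymptotic normal approximation is deliberately not used anywhere.

**Fisher's exact test.** Two-sided p by the probability-mass rule (sum of
point probabilities ≤ the observed one, compared with relative tolerance
1e-7 to absorb floating-point ties). The odds ratio is the conditional MLE —
the root in ψ of E[a | margins, ψ] = a under Fisher's noncentral
hypergeometric distribution, solved by bracketed root-finding in log ψ
(xtol 1e-12) — not the sample cross-product ratio, matching the convention of
the exact-test implementations whose output cohort papers report (for the
carrier table 17/38/3/30 the cross-product ratio is 4.47 while the CMLE is
4.41, which is what rounds to the published 4.4). The 95% CI inverts
one-sided exact tests at 0.025 per side. Boundary tables (a at the edge of
its support) give OR 0 or ∞ with a one-sided CI; an empty margin yields p = 1
with undefined OR/CI.

**Multiplicity.** Bonferroni, `min(1, m·p)`, with m = the number of
structures tested in one battery family (3 arteries + 10 stroke
compartment/depth classes = 13); laterality tests are reported separately and
uncorrected, mirroring how such batteries are corrected "without taking
laterality into account". Raw and adjusted p-values are always both reported.

## Cohort model and eligibility

"Involved" means stenosis/occlusion on at least one side; "bilateral" means
both sides. The stroke map has 20 slots: {ACA, MCA, PCA territorial;
ACA–MCA, MCA–PCA watershed} × {cortical, subcortical} × {left, right};
ischemic burden is the count of affected slots. Age-at-onset analyses exclude
incidentally diagnosed patients (no attributable symptom onset; their onset
is missing and never imputed) and, in carrier-vs-rest or NF1-vs-rest
contexts, symptomatic NF1 patients who also carry a (possibly) deleterious
RNF213 variant (ambiguous group membership). The same double carriers are
excluded from involvement/stroke comparisons. The under-5 subset uses strict
onset < 60 months. Inheritance is summarized at the occurrence level
(variant × carrier): a variant carried by two patients contributes two
occurrences; "established" is any state other than `not_established` (a de
novo call requires both parents, so de novo occurrences are established);
the de novo percentage is rounded half away from zero.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, at the
published subgroup parameters, so that every stage is testable without
patient-level data.

* **Variant scores**: one latent low/high component per variant drives both
  scores (which is what makes CADD and VIPUR correlated in the cloud); scores
  are conditionally normal, VIPUR clamped to [0, 1], a configured fraction
  (default 11/90) missing VIPUR. Default component locations (CADD 15/29,
  SD 4/3; VIPUR 0.25/0.70, SD 0.10/0.15, equal weights) put the derived
  cutpoints near the published 24 / 0.46 region; the aortic-disease group is
  shifted upward (+4 CADD, +0.15 VIPUR) and other arteriopathies slightly
  (+1, +0.05), reproducing the published ordering of group means. These
  shifts are package defaults chosen once, not published values.
* **Cohort**: 88 patients; diagnosis Bernoulli(55/88); exactly 20 carriers
  allocated by count, preferentially to MMD (fraction 17/20), so the expected
  carrier-by-diagnosis split is the published 17/3. MMS patients get an NF1
  label with probability 15/33. Exactly round(8/88 × n) incidental diagnoses
  are assigned among non-carriers (onset missing). Onset is drawn per
  carrier stratum from a normal truncated at 0 (carriers 35.2 ± 35.5 months,
  non-carriers 65.1 ± 46.5); truncation is necessary because the SDs exceed
  half the means, and it raises the realized means above the configured
  pre-truncation values (to ≈ 45.7 and ≈ 73.3 at large n) — reported moments
  are post-truncation. The published MMD/MMS stratum means (50.7/75.7) are
  stored in the config for reference; the MMD-vs-MMS onset contrast emerges
  through the carrier allocation rather than being forced directly.
  Artery involvement is Bernoulli per artery and stratum (PCA 0.615 carriers
  / 0.225 non-carriers — published; ACA 0.815 and MCA 0.83 in both strata —
  the published cohort-wide rates, since the strata were reported not to
  differ anteriorly), with P(bilateral | involved) = 0.50 / 0.16 applied to
  all arteries (published for PCA). Each stroke slot is Bernoulli with
  probability mean_burden/20 (carriers 5.2, non-carriers 2.5, NF1
  non-carriers 1.2): the simplest mechanism matching the published means.
  Its binomial variance (SD ≈ 2.0 at the carrier rate) understates the
  published SDs (≈ 4.5), i.e. real burdens are more overdispersed; tests
  that depend on burden spread are therefore conservative about that aspect
  of real data.
* **Reproducibility**: one 64-bit seed, split into per-component child
  streams (`SeedSequence.spawn`), so adding a generator does not perturb the
  others; identical seed and config give bit-identical tables.

**What passing tests show.** The generator produces the configured group
differences with independent-across-patients sampling, no covariate
structure (no age–severity correlation beyond the strata, no site effects,
no correlated laterality across arteries) and exact carrier counts.
Passing the battery on synthetic cohorts therefore validates the plumbing and
the exact statistics under the published effect sizes — detection of the
onset difference at α = 0.05 in ~80% of replicate cohorts at n = 20 vs ~60 —
not the clinical claims themselves, and not robustness to confounding that
the generator does not model.

## Problem sizes and numerical choices

The test suite and the acceptance script run the exact Mann–Whitney at cohort
scale (n + m ≈ 80, where the DP is exact and takes milliseconds), enumerate
oracle comparisons at n + m ≤ 10 and 2×2 tables up to N = 40, fit 50
simulated mixtures of n = 500 at 4-SD separation, and use 200–400 replicate
cohorts for detection-rate estimates — sizes chosen so each suite documents
the behavior it claims in seconds. EM tolerance 1e-8 relative; CMLE/CI
root-finding tolerance 1e-12 in log ψ; probability-mass comparisons at 1e-7
relative. Ties in MAP assignment (posterior exactly 1/2) resolve to the low
component.

## Known limitations

* The cutpoint definition is data-anchored; on sparse data near the decision
  boundary it can differ from the posterior-0.5 crossing by one observation.
* The published 24 (CADD) and 0.46 (VIPUR) thresholds themselves cannot be
  recomputed without the study's per-variant score table, which is not
  publicly deposited; cutpoint derivation is validated through recovery on
  synthetic mixtures instead.
* Fisher-exact CI coverage is conservative (exact tests over a discrete
  support), so intervals are wide on small tables — a property, not a bug.
* The bundled gene panel is a documented stand-in, not a curated 87-gene
  clinical panel; supply your own panel file for real analyses.
* No multivariable adjustment or survival modeling: the battery consists of
  the univariate exact tests only.
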