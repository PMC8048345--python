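# Methods

This note documents the models, algorithms, parameter defaults and numerical
choices behind `trajsurv`, and what the synthetic cohorts it is tested on do
and do not emulate.

## Survival primitives

All survival statistics are implemented directly on right-censored
(time, event) pairs, with *discharge* as the event — a "good" event, so a
higher risk score means earlier expected discharge.

- **Kaplan-Meier.** Product-limit estimator; steps only at observed event
  times, censored-only times shrink the risk set.
- **Log-rank.** k-sample observed-minus-expected statistic with the
  hypergeometric covariance, chi-square with k−1 df. No small-sample
  correction is applied.
- **Harrell's c-index.** A pair (i, j) is comparable when patient i has an
  observed event strictly earlier than patient j's time; score ties count
  0.5. Pairs tied on time — including two tied events — are non-comparable.
- **Cox partial likelihood.** Breslow convention for tied event times
  throughout (likelihood, gradient, Hessian, baseline hazard). The Breslow
  baseline increment at an event time is d/Σ_{R(t)} exp(xᵀβ); with distinct
  event times this reduces to the classical 1/Σ form.
- **Proportional-hazards check.** Grambsch-Therneau score test of drift in
  the Schoenfeld residuals against the identity time transform g(t) = t.
  The information matrix uses the exact profiled form
  Σg²V − (ΣgV)(ΣV)⁻¹(ΣgV) over per-event risk-set covariances V rather than
  the classical averaged-V approximation: with the identity transform, late
  event times pair large (g−ḡ)² with small risk sets, and the averaged
  approximation overstates the information so badly that the test's size
  drops to well under 1%. The exact form reproduces R's `cox.zph`
  (survival ≥ 3) to print precision and holds its nominal level in
  simulation once n is in the asymptotic regime (a few hundred events).

## Elastic-net Cox solver

The solver minimizes −l(β)/n + λΨ(β) with Ψ(β) = α‖β‖₁ + (1−α)‖β‖₂².
Note the ℓ2 term carries no ½, so KKT stationarity at a nonzero coordinate is
g_j + λα·sign(β_j) + 2λ(1−α)β_j = 0 (g = ∇(−l/n)); the glmnet convention is
recovered by λ' = λ(2−α), α' = α/(2−α), which is how the solver is
cross-checked against scikit-survival's coxnet in the tests.

Implementation is the standard glmnet recipe: an outer IRLS loop forms a
diagonal quadratic approximation of the partial likelihood (working weights
and responses from the per-subject gradient and Hessian diagonal), an inner
cyclical coordinate descent solves the penalized weighted least squares,
with active-set iteration (full sweeps only to admit coordinates, cheap
active-only sweeps in between). The outer loop terminates on the *exact*
KKT residual, not the subproblem's, so converged fits satisfy the optimality
conditions of the true objective (default tolerance 1e-8; coefficient-change
tolerance 1e-7; sweep budget 1e5). The inner loops are numba-compiled.

Genes are standardized to unit variance internally (the penalty acts on the
standardized scale, the convention of the software family this follows);
returned coefficients are back-transformed. Zero-variance columns are
excluded with a warning.

- **Lambda path.** λ_max = max_j |g_j(0)|/α (closed form; for α = 0 a large
  documented start of 1000·max|g_j(0)|), geometric path of 30 values down to
  λ_max·0.05 (p ≫ n default), warm starts, sequential strong-rule screening
  with full KKT verification on all predictors.
- **Cross-validated λ.** Verweij-van Houwelingen deviance: per fold,
  2·[nll_all(β_fold) − nll_train(β_fold)], summed over folds (10 by
  default), minimized over the full-data path. Fold fits run at a looser
  tolerance (1e-4) — λ selection is insensitive to the last decimals — and
  the returned model is a warm-started strict-tolerance refit at λ_opt.
  `rule="1se"` instead takes the sparsest λ within one standard error of the
  minimum.

## Stability selection and the gene signature

Per selection day (defaults 0, 1, 4), patients with a draw that day form the
snapshot; missing patients are excluded, not imputed. α is tuned on a seeded
70/30 split (held-out c-index of the linear predictor, λ by CV on the
training part); one shared α maximizes the mean c-index across days, ties
going to the larger (sparser) α. The per-day stable set is the intersection
of the supports of all n leave-one-out refits, λ re-chosen by CV inside
every refit with the **one-standard-error rule**: stability selection wants
the sparsest defensible model, and the deviance minimum demonstrably
overselects (at n ≈ 110, p = 500 it keeps 15–25 genes, so the same chance
correlates survive every leave-one-out refit and the intersection cannot
prune them; with the 1-SE rule the intersection is clean). The union of the
per-day sets, with per-gene day provenance, is the signature.

High/low-risk stratification splits a test set at the median linear
predictor (balanced by construction; an all-tied score vector is an error)
and compares the two Kaplan-Meier curves by log-rank.

## Mixed imputation

The reduced grid T keeps the days whose missingness — computed over patients
still under follow-up at that day, the documented default (a denominator
switch allows "all patients") — is *strictly* below 50%. For each required
(patient, day ∈ T): keep an observed draw; otherwise carry the nearest draw
within 2 days (past = LOCF before future = NOCB on ties, configurable);
otherwise interpolate linearly between the closest bracketing draws at any
distance. Carrying moves whole per-day draw vectors, since missingness is
draw-level (one blood draw per day). No extrapolation beyond the last draw:
trailing cells stay missing and are resolved solely by the complete-case
horizon split (horizons 7 and 28 by default), mirroring a design where
expression follow-up ends at discharge. Every cell carries a provenance tag
(observed / carried_forward / carried_backward / interpolated), which the
tests assert on. Log-transformation, when requested, is base 2 (configurable).

An unbounded-LOCF imputer is included purely as the comparison baseline for
the accuracy contract (mixed RMSE ≤ LOCF RMSE on smooth truth).

## GAK distance and clustering

The local kernel between two per-day gene vectors a, b is
κ = w(q,r)·exp(−φ_σ), φ_σ = ‖a−b‖²/(2σ²) + log(2 − exp(−‖a−b‖²/(2σ²))) —
the Gaussian kernel with the 2−k normalization that keeps the alignment sum
positive definite — times a triangular integer window
w = max(0, 1 − |q−r|/order) (order 0 = unconstrained, the default: with only
7 grid points a band constraint is unnecessary). The kernel sums κ-products
over all monotone alignments via the DP
M(q,r) = κ(q,r)[M(q−1,r) + M(q,r−1) + M(q−1,r−1)], run in log space because
kernel values decay exponentially with series length. A window so tight that
no alignment exists raises a distinct `NoAlignmentError`. The dissimilarity
1 − exp(logk_ij − ½(logk_ii + logk_jj)) lies in [0,1] and is 0 on identical
series; it is *not* a metric (no triangle inequality), which PAM does not
require. σ defaults to Cuturi's rule: median pairwise observation distance ×
√(median series length), over a seeded subsample.

PAM is Lloyd-style alternation on the precomputed distance matrix (assign to
nearest medoid; move each medoid to the member minimizing the within-cluster
distance sum), from 5 seeded random initializations (best objective wins);
an emptied cluster is re-seeded with a random non-medoid point. k is chosen
over a range (all clusters ≥ 2 members to be admissible) by the smallest
log-rank p-value across cluster survival curves; a Wald companion p-value
from an unpenalized Cox fit on cluster indicator dummies is reported
alongside. When a clustering perfectly separates early from late discharges
the dummy Cox likelihood is monotone (infinite coefficient); the Wald
statistic then collapses toward 0 — the same behaviour as R's `coxph` — so
k selection never uses it.

## Synthetic cohorts

The generator emulates a 28-day prospective trauma transcriptomics design:
sampling days S = {0,1,…,29} (22 scheduled days), draw-level missingness
(defaults: 25% on the canonical low-missingness days {0,1,4,7,14,21,28},
70% elsewhere, so grid selection recovers that subset), log-scale expression,
a small active-gene set driving a Weibull proportional-hazards discharge
time from day-0 expression, loss of expression follow-up after discharge,
and administrative censoring of the outcome at day 60 — after the sampling
window, because the emulated design observes discharge days beyond the last
blood draw.

Cluster mean curves are baseline + amplitude·exp(−decay·t). The defaults
encode a shared acute phase that diverges during recovery: day-0 value =
0.2×baseline (all clusters nearly alike at admission), recovery baselines
spread over ±1.5 log₂ units, decay 0.15/day, observation noise 0.35. This
parameterization was calibrated to the design facts of the cohort being
emulated — roughly 65% of patients with complete series to day 7 and
20–40% to day 28, day-snapshot test c-indexes in the 0.7–0.9 range, and
moderate hazard ratios — rather than to any test threshold. (Putting the
full cluster separation at day 0 instead makes the linear predictor span
±25, i.e. a near-deterministic discharge order and horizon datasets with no
events at all.) Weibull baseline shape 1.6 and scale 21 days come from
matching the two complete-case fractions analytically. Active-gene loadings
are ±Uniform(0.6, 1.4) with alternating signs, matched to alternating ±1
effect sizes.

Randomness: one root seed, split into named per-stage streams
(`SeedSequence(seed, spawn_key=...)` for loadings, cluster assignment,
expression noise, event times, missingness), so identical seeds give
byte-identical cohorts. Derived stage seeds elsewhere in the pipeline hash
stage names through SHA-256, never Python's randomized `hash`.

What the generator does **not** emulate: probe-level microarray artefacts,
batch effects, competing risks (death vs discharge; non-discharge is
right-censoring only), gene-gene correlation beyond the planted cluster
structure, and informative (non-MCAR) missingness. Passing tests therefore
demonstrate correctness of the machinery and recoverability of planted
structure under this idealized design, not performance on real microarray
data.

## Problem sizes and numerical choices

The test suite exercises the pipeline at desk scale, chosen as the package's
own test design: cohorts of 40–170 patients, 20–500 genes, leave-one-out
stability selection at n ≈ 110 with 5-fold inner CV and 30-point λ paths;
log-rank calibration with 1000 null replicates at 200/arm; the
proportional-hazards size check with 500 replicates at n = 400 (the score
test needs the asymptotic regime); kernel-oracle equivalence on all series
pairs of length ≤ 4 against exhaustive alignment enumeration (tolerance
1e-10); solver-oracle agreement at λ = 1e-8 against an independent
Newton-Raphson fit (1e-4). Degenerate inputs (no events, all-tied scores,
zero-variance genes, all-identical series, windows admitting no alignment,
emptied PAM clusters) raise or are handled as documented above.

## Known limitations

- The per-day snapshot models ignore within-patient correlation across
  selection days; the union signature treats days symmetrically.
- LOOCV-intersection stability is conservative by construction: correlated
  true predictors can evict each other at sparse λ, so recovery of *all*
  redundant actives is not guaranteed.
- PAM is a local optimizer; multiple seeded restarts mitigate but do not
  eliminate local optima.
- The GAK dissimilarity is not a metric; methods requiring a metric
  embedding should not consume it.
- With heavy censoring inside a cluster the Wald companion test is
  uninformative (monotone likelihood); interpret only the log-rank column.
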