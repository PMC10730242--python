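# Methods

This note documents the models, defaults, and design decisions behind
`endotyper`, and what the synthetic study conditions do and do not show.

## Synthetic cohort model

One row per subject, n = 3121 by default, with four latent severity classes
allocated by largest-remainder rounding of the proportions
(1277, 783, 502, 559)/3121 — counts are exact functions of (n, proportions),
independent of the seed, which makes class-size assertions deterministic.

**Biomarkers.** The 92-protein panel follows a block factor model
`x_j = s_{c,m(j)} + sqrt(rho) f_m(j) + sqrt(1-rho) e_j` with 17 modules
(7 of 6 proteins, 10 of 5), within-module correlation `rho = 0.6`, and
class/module mean shifts `s` in SD units. Anchored modules carry named
signatures — low renin / high RAGE+leptin in class 1 (mirrored in class 3),
an HSP27-block elevation in class 2, and a class-4-specific up-shift of the
OPG/GDF15/MMP12/CHI3L1 block with a mirrored down-shift of the soluble IL-6
receptor block. The twelve remaining modules carry balanced ±0.8 SD contrast
patterns so that every pair of classes differs by a broad signature.

The signature breadth is a deliberate calibration: the generator's contract
is that the planted classes are *recoverable* (they stand in for endotypes
that, in real data, replicate across cohorts via a supervised classifier).
With the default matrix, a supervised linear discriminant reaches ~99%
accuracy at n = 3121; sparser signatures (4–7 active modules per class)
leave the classes irrecoverable by any outcome-guided representation, which
would make every downstream stage untestable. Magnitudes are kept at 0.8 SD
throughout. A consequence worth noting: real endotype signatures concentrate
in a handful of modules, so the synthetic panel is *more* broadly informative
than a real one — passing tests show the pipeline works when separable
structure exists, not that any given cohort contains it.

**Ultrasound.** A subject-level c-IMT value is drawn as
`class mean + covariate effects + noise`, with the covariate contributions
(age 0.004 mm/y, male sex +0.04 mm, SBP 0.0015 mm/mmHg) centred — within
class for the class-shifted SBP — so the derived c-IMT_mean-max matches the
configured class means (1.10/1.23/1.39/1.50 mm) and SDs (0.20/0.24/0.30/0.33)
exactly in expectation; the noise SD absorbs the remainder. Per-segment
maxima are the subject value plus mean-zero segment deviations (SD 0.25 mm),
so mean-max is exact by construction. Segment-level 30-month progressions
are normal with class means chosen so the expected fastest-progressing
segment (max of four) hits 0.14/0.16/0.19/0.22 mm/y via the order-statistic
offset 1.029·SD; draws are floored at −0.099 mm/y to keep log10(x + 0.1)
defined. Plaque counts are Poisson with the class rates; centre membership
(5 centres) adds small zero-mean c-IMT offsets standing in for latitude.

**Survival.** Exponential event times with hazard
`0.01176 · exp(log HR_class)` per year (log HRs 0, ln 0.97, ln 2.43,
ln 2.85) and administrative censoring at 3 years. The baseline hazard solves
`sum_c pi_c (1 − exp(−3 λ0 HR_c)) = 0.053` analytically, so ~5.3% of
subjects experience an event. Event types are multinomial
(cardiac/cerebrovascular/peripheral ≈ 0.62/0.34/0.04). No competing risks —
the 3-year composite-endpoint analysis does not resolve them.

## Representation learning

The encoder maps standardized variables through a linear layer into a
bottleneck of 10 units — 8 gated by a softmax (a mixture-of-experts form)
plus 2 linear units — feeding a linear regression head trained by MSE on
standardized c-IMT_mean-max.

Why this architecture: when the outcome's conditional mean is driven by a
small number of latent classes with Gaussian, equal-covariance signatures,
the Bayes predictor is exactly `sum_c mu_c softmax(Ax + b)_c` — a softmax
gate over linear logits. A conventional deep ReLU encoder with a linear head
collapses its bottleneck onto the fitted conditional mean (one smooth
severity axis), which merges endotypes whose outcome means are close and
lets the random-outcome control pick up folding artifacts; we observed both
failure modes and they motivated the gate design. The two linear units carry
continuous effects (covariates, or a purely linear outcome) that a gate
staircase would quantize.

Training choices that matter (all defaults in `EncoderHParams`):

* **Sliced inverse regression initialization** of the gating layer
  (10 slices, 8 directions, eigen-scaled, gain 0.5). Gradient descent alone
  recovers directions that influence the outcome only through higher-order
  structure too slowly (the first-order gradient vanishes by the normal
  equations once the linear fit converges); SIR estimates the
  outcome-sufficient subspace by inverse regression, where those directions
  appear at first order. SIR also inherits outcome dependence: with a random
  outcome its spectrum is flat noise, which keeps the null control clean.
* **Regularized information maximization on the gates**: an entropy penalty
  (weight 0.3) sharpens each subject's gate distribution toward a vertex
  while a usage-diversity reward (weight 0.2) keeps experts from dying
  (mixture collapse was the dominant failure without it).
* **Adam** (lr 1e-3, batch 128), weight decay 3e-4, Polyak weight averaging
  (decay 0.998), plateau learning-rate halving, early stopping on a 20%
  validation split (patience 80, min-delta 0.02).
* **Selection against the intercept model**: if the best validation MSE
  never beats predicting the training mean by more than min-delta, the
  fitted encoder is the null model — zero weights, constant embedding. This
  is ordinary model selection, and it is what makes the random-outcome
  control robust: without it the returned network is either an uninformative
  random projection (which still leaks input correlation structure into the
  silhouette) or a noise-memorizing overfit, both of which can fake
  clusters.

`embed` returns bottleneck activations; gates of outcome-equivalent experts
(head coefficients closer than `merge_tol`) can be merged, but the default
leaves this off. An embedding whose per-dimension variation falls below
1e-3 (against unit-variance inputs) is treated as collapsed — numerically
meaningful variation, not structure.

## Endotyping

Ward/Euclidean agglomeration of the embedding; k is the silhouette argmax
over 2..8 with a no-structure guard at mean silhouette 0.15. Because
gate-mixture training is restart-sensitive, the pipeline wrapper
(`discover_endotypes`) trains five restarts and takes the modal silhouette
argmax (ties toward fewer clusters), reporting the first restart that agrees
with the vote. Labels are renumbered so mean baseline c-IMT_mean-max is
non-decreasing (ties broken toward the larger cluster): endotype 1 mildest.

## Stacking, attribution, modules

The stacking ensemble uses heterogeneous base learners (histogram
gradient-boosted trees, 200-tree random forest, multinomial logistic) fitted
per stratified fold; the multinomial-logistic meta-learner sees only
out-of-fold class probabilities. New cohorts must be standardized with the
training statistics; prediction refuses missing values. For external cohorts
with fewer variables, refit on the shared-variable subset.

Shapley attributions use Monte-Carlo permutation sampling (64 permutations,
100 background subjects by default) against the model's per-endotype
predicted probability; all permutations advance in lock-step so the model is
called only p+1 times. Estimates are additively efficiency-normalized, so
`sum_v phi = f(x) − mean f(background)` holds exactly; individual phi retain
Monte-Carlo noise of order sd/sqrt(permutations). Rankings use mean |phi|
(global and per endotype), ties alphabetical.

The correlation-network stage is the standard construction: unsigned
adjacency `|cor|^beta`, the smallest beta whose scale-free fit R² ≥ 0.8
(binned log10 p(k) on log10 k regression) with a flagged max-R² fallback —
designed panels of equal blocks are not scale-free, so the fallback is the
expected path; topological overlap
`TOM_ij = (l_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij)`; average linkage on
1 − TOM with a fixed-height cut scan (grid = midpoints of merge heights)
maximizing the number of clusters that satisfy both the size guard
(≥3 members) and a cohesion guard — mean within-module |correlation| above
five times sqrt(2/(pi n)), the null expectation for independent variables —
which keeps pure-noise panels module-free. Modules are numbered by
descending size, 0 = unassigned.

## Outcome models and reclassification

Linear models are OLS with endotype dummies (endotype 1 reference) under
three adjustment sets: Model 1 centre only (latitude/batch surrogate);
Model 2 adds smoking, BMI, LDL, diabetes and the matching baseline
ultrasound measure for progression outcomes; Model 3 adds the three
treatment indicators. Age, sex, and SBP stay out of the adjustment sets by
default because they are constituents of every endotype; pass
`extra_covariates` to override. No multiplicity correction is applied across
the correlated ultrasound outcomes.

Cox models use Efron tie handling. At the cohort's event counts (~40–55 per
endotype) the maximum partial-likelihood estimate is biased away from zero
and Wald intervals undercover slightly, so the default estimate is Firth's
penalized partial likelihood (penalty 0.5 log det I(β), analytic
gradient/Hessian) with profile-penalized-likelihood CIs for the endotype
terms; `estimate="ml"`/`ci_method="wald"` recover the classical fit, and the
ML path is validated against a brute-force Efron partial-likelihood grid in
the tests. Proportionality is checked by the rank-transform scaled
Schoenfeld residual test; collinearity by VIF = 1/(1 − R²_j).

Risk scores are config-driven (YAML): LP = Σ coefficient·(x − centre)/scale,
uncalibrated risk `1 − S0^exp(LP)`, and the two-parameter recalibration
`1 − exp(−exp(scale1 + scale2 ln(−ln(1 − r))))`. The shipped coefficients
are synthetic placeholders that preserve structure and monotone directions;
they are explicitly non-clinical. Categories: <5/5–10/≥10% (standard scheme)
or <7.5/7.5–15/≥15% (older-person scheme), boundaries upward.

The categorical NRI at a horizon estimates event probabilities inside the
up-/down-/un-reclassified groups by Kaplan-Meier, so
`NRI+ = P(up|event) − P(down|event)` and
`NRI− = P(down|non-event) − P(up|non-event)`; with no censoring before the
horizon this reduces exactly to cell counting. Confidence intervals are
subject-level percentile bootstrap (B = 1000 by default), seeded; resamples
on which the statistic fails are skipped, more than 10% failures is an
error. Model comparison for reclassification fits Cox models with and
without endotype dummies and categorizes predicted risk at the horizon.

## Problem sizes used by the test suite

The suite exercises the full pipeline at the design scale (n = 3121) across
10 seeds for endotype-count recovery and the null control, 100 replicate
cohorts for hazard-ratio CI coverage, B = 1000 for the bootstrap check, and
smaller fixtures (n ≤ 8 Cox oracles, 3-variable TOM closed forms, planted
blocks) for estimator identities. Simulation-based checks (Schoenfeld
calibration/power) use 200/40 replicates at n = 150/400.

## Known limitations

* The generator's class-conditional distributions are Gaussian blocks with
  equal covariances; real panels have skewed, heteroscedastic, and
  platform-batch structure the pipeline never sees here.
* Broad balanced signatures make the synthetic classes more separable than
  real endotypes concentrated in a few modules.
* Survival is exponential with administrative censoring only — no competing
  risks, no covariate-dependent censoring.
* The SCORE2-style coefficients are placeholders; any clinical use requires
  externally sourced coefficients and recalibration.
* Silhouette-based k selection inherits silhouette's bias toward compact,
  balanced clusters; strongly elongated structure tends toward k = 2.
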