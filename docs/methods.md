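# Methods

This note documents the models, parameter choices and numerical decisions
behind the package, and what its validation does and does not establish.

## The segmentation-agreement statistic

A press log `p_1 < … < p_k` is smoothed into a boundary-likelihood profile
on the uniform grid `t_j = j / rate`, `j = 0 … floor(duration · rate)`:

    b(t) = min(1, Σ_i 1{|t − p_i| < Rσ} · exp(−(t − p_i)² / 2σ²))

with bandwidth σ = 1 s and truncation radius R = 3 SDs by default.

Numerical/definitional choices, all configurable:

* **Bandwidth convention.** "A one-second Gaussian kernel" is read as
  SD = 1 s, not FWHM. With FWHM = 1 s the profile would be ~2.35× narrower;
  the statistic's ordering behavior is unchanged, only its scale of
  temporal tolerance.
* **Truncation.** Kernel terms are exactly zero at and beyond Rσ from a
  press (strict support on the open interval). At R = 3 the truncated mass
  is < 1% of σ√(2π), verified by quadrature in the tests. The truncation is
  part of the kernel definition, so the brute-force oracle applies the same
  rule; what the oracle foregoes is the windowed evaluation.
* **Overlap rule.** Overlapping kernels *sum* and the curve is clipped at 1,
  preserving the stated 0–1 likelihood scale while letting press clusters
  widen (not heighten) evidence for a boundary. A pointwise-max variant is
  available (`overlap="max"`) for sensitivity analysis; correlations under
  the two rules differ negligibly at realistic press spacings.
* **Grid density.** 10 samples/s. With σ = 1 s the profile is heavily
  oversampled at this rate; correlations are stable above ~5 samples/s.
* **Correlation.** Pearson, with Spearman behind a flag. Zero-variance
  profiles (no presses, or a constant curve) make r undefined; such scores
  carry `undefined_owner` / `undefined_reference` statuses and are excluded
  from the agreement model rather than imputed.
* **Leave-one-out scope.** A reference-group member's own post-test profile
  is excluded from the norm for *both* their pre- and post-test comparisons.
  The conventional description covers only the post-test case; extending it
  to pre-test avoids self-correlation leakage through a participant's
  stable pressing style, at the cost of reference norms differing between
  members and non-members at pre-test by one profile in ~40.
* **Counts.** Segmentation count is the raw press count; no debouncing.
  Accidental double-presses are a property of the (simulated) presser, not
  the scorer.

## Scoring

Binomial outcomes are stored as successes out of trials, with trials doubling
as the model weight: survey 17 (gyoza) / 16 (Tai chi) scored items,
recognition 20, order memory 66. The recall composite is the mean of the A1
and A2 recalled proportions; its weight is the full coded inventory
(86 + 16 = 102 gyoza, 159 + 19 = 178 Tai chi) with successes reconstructed
by rounding composite × weight. This preserves all coded information and
keeps the successes/trials representation exact across CSV round-trips; the
rounding perturbs the composite by at most 1/(2·weight) ≈ 0.005. Novice
eligibility is ≤ 10 correct on each activity's survey (strictly-greater-than
cutoff). Cohen's κ uses marginal-product chance agreement; the degenerate
case (both raters constant and identical, chance agreement 1) raises rather
than returning 0. Fluency unique-item counting case-folds and trims
whitespace only — no stemming or spelling normalization, the minimal
defensible reading of "unique items".

## Multilevel models

All six outcome analyses share Group × Time × Activity fixed effects with
sum-to-zero ±1 contrasts (first levels gyoza / pre / gyoza coded +1, the R
`contr.sum` convention). Under this coding, equal-weight marginalization
zeroes every term containing a non-focal factor, making lower-order
coefficients interpretable as main effects alongside interactions. Dummy
coding is not offered; the contrast enters only through the design matrix,
which callers can replace.

Families: weighted binomial-logit (survey, recall, recognition, order),
Poisson-log (segmentation count), gaussian-identity (agreement, with raw —
uncentered — segmentation count as covariate and the random structure fixed
to a participant intercept). The other models select between a participant
intercept and an intercept + random Time slope by lowest AIC, ties to the
simpler structure.

Estimation is Laplace-approximate maximum likelihood, written in
numpy/scipy: per-participant random-effect modes by vectorized Newton
solves, marginal likelihood via the per-group curvature correction, outer
optimization by L-BFGS-B over fixed effects and the log-Cholesky-
parametrized covariance jointly. The gaussian model is fitted by ML, not
REML, so AICs are comparable across random structures and families. The
binomial likelihood includes the binomial normalizing constant, so
log-likelihood and AIC agree with lme4's conventions; the test suite pins
all three families to lme4 reference fits (coefficients to ~1e−4) and the
gaussian family to statsmodels MixedLM at runtime. Standard errors come
from the inverse numerical Hessian of the Laplace log-likelihood, which
(unlike lme4's conditional SEs) absorbs variance-parameter uncertainty —
differences are ~1e−3 at this design size. Wald z tests for the GLMM
families; t with residual degrees of freedom n − p for the gaussian model
(at 320 rows the choice of df approximation is immaterial). With
`random=None` the same machinery fits the ordinary weighted GLM — the exact
zero-variance limit used for oracle equivalence. Non-convergence raises;
stationary points that L-BFGS-B mislabels (zero-iteration line-search
failures at an optimum) are accepted on a gradient-norm check.

Marginal means average design rows over non-focal factors on the link scale
(covariates at their data means), then apply the inverse link, with
delta-method SEs from the fixed-effect covariance block. Contrasts are
link-scale Wald tests.

## The synthetic-study generator

The generator emulates the structure the analysis assumes, not any real
stimulus:

* **Press logs** are a latent point process: each latent boundary is
  detected independently (coarse/fine detection probabilities per activity),
  detected presses get Gaussian motor jitter (SD 1 s) clipped — not redrawn,
  which would bias edge-adjacent detections inward — to the video, and a
  homogeneous Poisson process (0.005 presses/s) adds false alarms. Latent
  boundary layouts place the coarse (A2-grain) boundaries at duration
  quantiles and fine (A1-grain) boundaries proportionally between them; no
  real boundary timestamps exist to copy, so layouts are injectable.
  Detection defaults (gyoza 0.60 coarse / 0.02 fine; Tai chi 0.75 / 0.05)
  put mean counts near 13 and 22–24 for the two videos. The ≥ 3-press
  practice gate is modelled as resample-until-satisfied and defaults to off
  for experimental videos.
* **Graded outcomes** are Bernoulli/binomial with logits combining an
  activity baseline (set at the design's pre-test marginal means: e.g.
  recognition 0.75/0.81, order 0.92/0.55, survey 0.07/0.22), a practice
  effect at post-test, an extra trained-activity post-test increment — the
  intervention effect, concentrated in survey (hitting trained post-test
  means ≈ 0.70/0.82 after attenuation by the random effects) and
  recognition — plus a participant random intercept and time slope.
  Simulation studies can instead inject exactly coded contrast coefficients
  (`coded_effects`), which is how the parameter-recovery and type-I runs
  set a known Group × Time × Activity logit effect.
* **Recall** draws A1 and A2 counts binomially around one shared latent
  propensity per participant × session × activity with small grain-specific
  noise (SD 0.15), reproducing a pooled cross-participant A1/A2 correlation
  near 0.8.
* **Reproducibility.** Every participant uses counter-based substreams
  keyed `(master seed, participant index, stage)`, so datasets are
  bit-identical under a fixed seed and growing the cohort never reshuffles
  existing participants' draws.

What the generator does *not* emulate: real boundary placements and their
semantic structure, item-level difficulty heterogeneity within instruments,
serial dependence between presses (refractory periods), dropout, or
session-order effects beyond counterbalancing. Passing calibration tests
therefore shows the *inference machinery* behaves correctly under the
design's statistical structure — not that real data would show these
effects.

## Validation design

* Segmentation statistics are pinned to naive full-evaluation oracles
  (1e−9) on randomized small cohorts, plus closed-form kernel values.
* Agreement degrades strictly monotonically across generator jitter SDs
  {0.25, 0.5, 1, 2, 4} s (50 participants/level, fixed seed).
* Mixed fits reproduce ordinary weighted GLMs in the zero-variance limit
  (1e−3), lme4 reference fits on a frozen fixture, and statsmodels MixedLM.
* At the full 80-participant design: a true three-way logit effect of 0.5
  on recognition is recovered with mean bias < 0.15 and 95% CI coverage in
  [0.90, 0.98] over 200 replications; the null three-way Wald test rejects
  at 2–9% over 300 replications; AIC picks the generating random structure
  in ≥ 80/100 replications in separated regimes (slope SD 0 vs 1.0).
  Replication counts were chosen to make these Monte-Carlo bands reliable
  while keeping the default suite desk-scale.

## Known limitations

* The Laplace approximation (like glmer's default) can bias variance
  components with few observations per cluster; with 4–8 weighted
  observations per participant here, the lme4 cross-checks bound the error.
* Profiles are dense float arrays (~3–4k samples per video); cohort-scale
  agreement uses a running-sum leave-one-out trick, but memory is O(cohort ×
  grid) per activity.
* `ingest_external` validates the package's documented CSV schemas and
  offers a column-mapping layer; mappings for any particular external
  deposit must be supplied by the caller.
* p-values for the gaussian agreement model use a simple residual-df t; no
  Satterthwaite/Kenward-Roger correction.
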