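# Methods

## The paradigm, as modeled

Each participant rates `n_items` items twice on a closed integer scale
(default 1–6). Between the two ratings of an item, the experimental
group sees an ostensible group judgment equal to their own rating plus a
scheduled deviation; the control group's deviation is drawn and logged
identically but never displayed. The deviation schedule is a uniformly
random permutation of a fixed multiset — 30 each of −2, −1, +1, +2 and
60 zeros per 180-item session (rescaled proportionally for other item
counts). When rating + deviation would leave the scale, the deviation's
sign is flipped before presentation (*boundary reflection*). On a 1–6
scale with |deviation| ≤ 2 the flipped judgment is always in bounds, so
the rule is a pure sign flip with no fallback; the package asserts this
rather than handling a case that cannot occur. A zero deviation never
reflects. The on-screen magnitude cue of the original display is
cosmetic and not modeled, nor are stimulus timing or response
collection.

## Generative model of the simulator

For participant *k* and item *i*:

- latent value `v_ik ~ N(latent_mean, latent_sd²)`, drawn per
  participant. Items within a participant are exchangeable in every
  downstream analysis, and per-participant draws keep the item-level
  residuals independent; a `shared_items` flag draws one latent vector
  for all participants for sensitivity analyses.
- session-1 rating: `v_ik + e1`, `e1 ~ N(0, noise_sd²)`;
- the deviation schedule is drawn and reflected against the session-1
  rating *as recorded* (discretized when Likert rounding is on);
- session-2 rating: `v_ik + e2 + w_k · d_ik · 1[experimental]`, with
  `e2 ~ N(0, noise_sd²)`, conformity weight
  `w_k ~ N(conformity_weight_mean, conformity_weight_sd²)` and `d_ik`
  the presented deviation.

With Likert rounding on, ratings are rounded half-away-from-zero and
clamped to the scale; clamping deliberately produces the floor/ceiling
effects of real rating data. In continuous mode ratings stay real-valued
and may fall outside the nominal scale; the reflection rule is still
applied as a pure sign flip there, so closed-form identities hold
exactly.

Because both sessions share `v` but not the occasion noise, the
population regression slope of rating change on the centered first
rating is `−noise_sd² / (latent_sd² + noise_sd²)` in continuous mode —
the RTM rate, tunable independently of the conformity effect.

### Defaults and why

| parameter | default | rationale |
|---|---|---|
| `n_per_group` | 27 | two groups of 27 female raters, the design scale of the paradigm's control-group studies |
| `n_items` | 180 | one full deviation schedule |
| `latent_mean` | 3.5 | scale midpoint of the 1–6 scale |
| `latent_sd` | 1.0 (rating units) | spreads items over the scale's interior with mild edge mass |
| `noise_sd` | ≈ 0.7729 | sets the continuous-mode RTM slope to −0.374, the magnitude reported for this paradigm's control condition |
| `conformity_weight_mean` | 0.15 /deviation unit | small positive shift: an effect clearly present yet well below the RTM share, matching the field's finding that RTM inflates raw conformity severalfold |
| `conformity_weight_sd` | 0.05 | real between-person spread without sign flips for almost all participants |
| `discretize` | on | Likert data are the paradigm's reality; continuous mode exists for analytic checks |
| `seed` | 0 | master seed; one substream per (group, participant) via `SeedSequence` spawn keys, so enlarging a group never reshuffles existing participants |

These defaults are simulator calibrations, not estimates of any
particular dataset.

### What the generator does and does not emulate

It reproduces the design constants, natural RTM, floor/ceiling
censoring, and an additive, participant-varying conformity shift. It
does **not** model rater drift or fatigue, item-level agreement across
participants (unless `shared_items`), heavy-tailed or bimodal scale use,
attention lapses, or any dependence of conformity on the initial
rating's extremity. Tests passing on these simulations therefore
validate the statistical machinery and the correction logic under a
well-specified generative model — they do not certify behavior on human
data, where the linearity of RTM in the centered first rating is an
approximation.

## Preprocessing

Ratings are centered per participant × session (session mean
subtracted); the rating change `c` is the centered second minus the
centered first rating. Each participant's mean `r` and mean `c` are then
zero by construction (asserted to 1e−9 rating units), which is what
licenses the model's fixed zero intercept. The 5-level presented
deviation collapses to the 3-level Deviation factor (lower / equal /
higher), using the *presented* (post-reflection) value in both groups —
in the control group that is the determined-but-suppressed value. No
outlier trimming is performed anywhere: discarding extreme initial
ratings is exactly the kind of ad-hoc fix the control-group design makes
unnecessary.

## The RTM model and its estimation

`RTMModel` fits `c_ik = β1k r_ik + ε_ik`, `β1k = γ10 + δ1k`, with
`ε ~ N(0, σ²_ε)` and `δ ~ N(0, σ²_δ)`, intercept hard-constrained to
zero (no intercept parameter exists in the design matrix). The marginal
covariance per participant is `V_k = σ²_δ r_k r_kᵀ + σ²_ε I`.

Numerical strategy:

- the REML criterion is profiled down to the variance ratio
  `λ = σ²_δ/σ²_ε`. For fixed λ, `V_k⁻¹` follows from the
  Sherman–Morrison rank-one identity, and both the GLS slope and σ̂²_ε
  are closed-form in three per-participant sufficient statistics
  (Σr², Σrc, Σc²). The entire fit is O(participants) per criterion
  evaluation.
- λ is minimized by bounded scalar search on log(λ + 1e−8) over
  λ ∈ [0, 1e3]; the λ = 0 boundary (no slope heterogeneity) is compared
  explicitly and reported as σ²_δ = 0 when it wins. A `lambda_` argument
  fixes the ratio instead (0 reduces the fit to the pooled
  through-origin OLS slope).
- REML is the default criterion, matching standard mixed-model software;
  full ML is available via `fit(reml=False)`.
- Satterthwaite denominator df: `df = 2·Var(γ̂)² / (gᵀ A g)` with `g`
  the finite-difference gradient of Var(γ̂) in (σ²_ε, σ²_δ) (central
  differences, relative step 1e−5; one-sided at the σ²_δ = 0 boundary)
  and `A` twice the inverse finite-difference Hessian of the −2
  restricted log-likelihood. If the curvature is unusable (degenerate
  boundary), the residual df N−1 is the fallback.
- degenerate inputs: fewer than 2 participants, any participant with
  fewer than 2 items, or zero variance in `r` raise immediately; data a
  single common slope fits exactly (zero residual) short-circuit to that
  slope with both variance components 0.

The fit is validated in the test suite against two independent oracles:
a dense-matrix restricted likelihood maximized by a generic optimizer,
and `lme4::lmer(c ~ 0 + r + (0 + r | participant))` with `lmerTest`
Satterthwaite df.

## Correction and scoring

`ŝ = c − γ̂10 r` uses only the fixed average slope from the control fit —
never experimental-group information and never per-participant BLUPs
(the BLUPs are exposed for diagnostics only). Since `r` is centered,
per-participant means of `ŝ` remain zero. The built-in falsification
check applies the correction to the control group itself: under the
null generator the corrected Deviation ANOVA rejects at the nominal
rate, i.e. the correction removes everything the control group's design
can produce.

Conformity scores correlate the presented deviation — all five raw
levels, not the binned factor — with `c` (uncorrected) or `ŝ`
(corrected) across a participant's items, then apply Fisher's
z = arctanh(r). |r| = 1 is clamped to 1 − 1e−12 before the transform
(z ≈ 14.2) rather than dropping the participant, keeping score counts
stable; zero-variance inputs yield an undefined score, flagged and
excluded from aggregates with a warning. Control-group scores are
computed against the suppressed deviation, mirroring the falsification
logic.

## ANOVA conventions

The mixed repeated-measures ANOVA uses the classical balanced
decomposition (every participant supplies every condition mean; group
sizes may differ). Generalized η² divides each effect's SS by the
effect SS plus *all* subject-related error strata (between-subjects
error and the within-error stratum), making the value comparable across
designs. Sphericity is assessed with Mauchly's W on orthonormalized
contrasts of the pooled within-group covariance (error df N − G);
when the chi-square test rejects at α = 0.05 the Huynh–Feldt ε
(computed from the Greenhouse–Geisser ε with the same pooled df, capped
at 1) multiplies both df for the corrected p — uncorrected df and ε are
what the summary reports, following the field's reporting convention.
Both ε values are always exposed. With a single group the routine
reduces exactly to the one-way repeated-measures ANOVA and matches
`pingouin` on F, η²_G, W and both ε (tested).

t-tests: one-sample and paired via scipy with Cohen's d = mean/sd
(difference-score d for paired); the two-sample test is pooled-variance
(df = n₁+n₂−2) with d on the pooled sd. A paired comparison of two
identical vectors returns t = 0, p = 1 (no evidence either way), while a
constant nonzero offset — zero difference variance with nonzero mean —
raises a degenerate-data error. Holm's step-down adjustment handles the
three pairwise condition comparisons.

## Problem sizes in the validation suite

Simulation-based checks run at the design scale of 27 participants per
group × 180 items: 200 continuous-mode replicates for slope recovery
(γ̂10 within 3 SE of the calibrated −0.374 in ≥ 99%), 500 null
replicates for the falsification type-I rate (within a 3σ binomial band
of 0.05, p-values approximately uniform), and 100 Likert-mode replicates
for the directional pattern (experimental Deviation effect exceeds
control; corrected scores positive yet below uncorrected; each ≥ 95%).

## Known limitations

- The correction assumes RTM is linear in the centered first rating and
  independent of the manipulation; with Likert censoring the linear
  model is an approximation (the falsification check on discretized
  control data is how that approximation should be judged on real data).
- γ̂10 is estimated, not known; its sampling error propagates into every
  corrected score, and the type-I rate of the falsification ANOVA is
  accordingly very slightly conservative in simulation.
- The ANOVA requires a balanced within-factor (all three condition
  means per participant); designs losing a whole condition to
  reflection would need cell-size-aware extensions.
- Crossed item random effects, random intercepts and covariates are out
  of scope of the RTM model by design.
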