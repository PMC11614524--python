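# Methods

## The generative model

Visual foraging — sequentially collecting every target from a display of
targets and distractors — is modelled as *weighted sampling without
replacement* over the remaining targets.  Targets belong to two classes, A
and B (distractors are neglected by the model).  After every selection the
probability of each remaining target is recomputed from four parameters:

| parameter   | meaning                                             | units |
| ----------- | --------------------------------------------------- | ----- |
| `b_A`       | class bias: log-odds of preferring class A          | log-odds; `p_A = logit⁻¹(b_A)` |
| `b_S`       | stickiness: log-odds of repeating the last class    | log-odds; `p_S = logit⁻¹(b_S)` |
| `σ_ρ`       | proximity tuning on diagonal-normalised distance    | dimensionless |
| `σ_d`       | direction tuning on the cosine of the turn angle    | dimensionless |

The unnormalised weight of remaining target *i* is the product of

* a class term — `p_A` for class-A items, `1 − p_A` for class-B (the two
  class log-odds are redundant with two classes, so a single free
  parameter with `b_B ≡ −b_A` is used);
* a stick term — `p_S` if *i*'s class equals the class of the last
  selection, else `1 − p_S` (applied once a last selection exists);
* a proximity kernel `exp(−σ_ρ · d)`, where `d` is the Euclidean distance
  from the last selection divided by the display diagonal
  `√(width² + height²)` — normalising by the diagonal keeps distances
  comparable for non-square displays without distorting angles;
* a direction kernel `exp(σ_d · cos φ)`, where `φ` is the angle between
  the movement vector (previous → last selection) and the candidate vector
  (last selection → *i*); applied once two selections exist.  `σ_d > 0`
  prefers items ahead of the current movement, `σ_d < 0` items behind.

Weights are renormalised over the remaining targets after every pick; with
`σ_ρ = σ_d = 0` the model reduces to non-spatial biased sampling without
replacement, and with all parameters zero to uniform sampling without
replacement.

Exact functional forms for the two spatial kernels are a design choice of
this package: the exponential-in-distance and exponential-in-cosine (von
Mises-style) kernels satisfy the qualitative requirements (monotone
strengthening with `σ_ρ`; sign-symmetric ahead/behind preference in
`σ_d`; neutrality at zero) and give sensible weight ratios at the
magnitudes typical of fitted data (`σ_ρ` ≈ 10–20 on diagonal-normalised
distance, `σ_d` ≈ −1).  Everything downstream (fitting, contrasts,
recovery) is self-consistent for any fixed choice.

Conventions for degenerate cases: the first selection uses the class term
only; the second adds stick and proximity; coincident positions make the
direction term neutral (`cos φ = 0`).  The first selection contributes to
the likelihood like every other.

In log space the per-item weight is **linear** in `(b_A, b_S, σ_ρ, σ_d)`
with data-only features `(1[A], 1[same-class], −d, cos φ)`, i.e. each
selection is a conditional-logit observation.  `forage.likelihood`
precomputes these feature tensors per trial so the sampler evaluates
likelihoods as batched matrix products (a numba kernel; a pure-numpy
twin is kept and the two are cross-checked in the tests).  A brute-force
enumeration oracle (`enumerate_trial_probs`, ≤ 7 targets) provides exact
ordering probabilities for testing the simulator and the likelihood.

## Hierarchical inference

The four parameters are fitted per experimental condition *k* (2
difficulties × 3 target-ratio levels) with participant random effects:

    θ_p(j, k) = μ_p(k) + sd_p · z_p(j, k),   z ~ N(0, 1)

One independent offset per participant × condition × parameter (random-
effect correlations are deliberately not modelled), with one scale per
parameter shared across conditions.  Priors: `b_A, b_S ~ N(0, 1)`,
`σ_ρ ~ N(15, 5)`, `σ_d ~ N(0, 1)` on the group means; half-normal(1) on
the log-odds random-effect scales and half-normal(5) on the tuning
scales.  The proximity prior is deliberately informative about scale
(fitted values near 10–20) while the rest are weakly informative.  `σ_ρ`
is left real-valued; its prior does the regularising rather than a
positivity constraint.

Sampling is by a blocked adaptive random-walk Metropolis
(Metropolis-within-Gibbs) scheme, chosen because the conditional-logit
likelihood is cheap to evaluate in batch and no automatic-differentiation
backend is required.  Per iteration:

1. per-condition joint update of the four group means (conditions are
   conditionally independent given offsets, so all blocks share one
   batched likelihood evaluation);
2. coordinate-wise updates of the log random-effect scales holding the
   offsets fixed — this rescales all residuals together and is the move
   that traverses the "funnel" of the hierarchy;
3. coordinate-wise random-walk updates of every cell's offsets (batched
   across cells), plus prior-independence refresh proposals (the prior
   cancels against the proposal, leaving a pure likelihood ratio) that
   de-correlate weakly identified offsets;
4. exact Gibbs recentering of each group mean along the non-centred ridge
   (effective parameters held fixed; the conditional is Gaussian);
5. an exact slice-sampling draw of each log-scale from its conditional
   given the effective parameters (the interweaving counterpart of 2).

Moves 4–5 need no likelihood evaluations and remove the classic slow
modes of non-centred hierarchies.  Proposal scales adapt during warmup
only (Robbins–Monro on acceptance rates toward 0.25 for joint blocks and
0.44 for coordinate moves; component scales from running variance
estimates) and are frozen for sampling, so the kept draws come from a
fixed Markov kernel.

Convergence is summarised by split-chain R̂ (own implementation,
cross-checked against arviz) and bulk effective sample size (arviz); a
fit with any R̂ ≥ 1.01 is flagged, not rejected.  Defaults: 4 chains ×
1000 warmup × 1000 kept draws; the recovery analyses below use thinning
(keep every 2nd of 2000) to push worst-parameter ESS near 1000, which the
strict 1.01 threshold over hundreds of offset parameters requires.
Posterior intervals are central (equal-tailed) quantile intervals — at
53% and 97% where interval pairs are reported — rather than HPD
intervals; for the near-symmetric marginals here the difference is
negligible and quantile intervals are deterministic.

The empty dataset is legal and yields prior-only sampling (the Gibbs
recentering then draws group means i.i.d. from their priors), which the
tests use for prior-recovery checks.

## Hypothesis criteria

Decisions are posterior contrasts at threshold 0.99 (configurable):

* **Scarcity (H1)** — both `Pr(b_A(scarceA) − b_A(equal) > 0)` and
  `Pr(b_A(equal) − b_A(scarceB) > 0)` must exceed the threshold,
  marginalising over the two difficulties by averaging their group-mean
  draws draw-by-draw; per-difficulty variants are reported alongside.
  Ties count against the hypothesis (strict inequality).
* **Stickiness (H2)** — `b_S(conjunction) > b_S(feature)`.
* **Proximity (H3)** — `σ_ρ(feature) > σ_ρ(conjunction)`, plus
  `Pr(σ_ρ > 10)` within each difficulty.
* **Direction (H4)** — `Pr(σ_d < 0)` marginalised over conditions.
* **Per-participant effects** — the H1 contrast pair applied to
  `μ + u` (group mean plus offset) per participant, per difficulty and
  marginalised, with reversed contrasts screening for anti-scarcity
  participants, and a Spearman screen of participant scarcity effects
  against the other random effects.

## Synthetic experiments

`forage.synth` generates the study design: 40-item displays (20 targets
in a 5:15 / 10:10 / 15:5 class split + 20 distractors) on a jittered grid
inside 1000 × 1000 px.  Default geometry: 7 × 6 grid (40 of 42 cells
used), Gaussian jitter with sd 12 px, re-drawn wholesale if any pair
falls within 60 px (twice the 25 px item radius); jitter magnitude and
separation are package choices that produce visible irregularity without
overlap.  Classes are assigned to positions uniformly at random.

`simulate_experiment` implements the hierarchical generative process used
for the sample-size simulation: 36 participants × 5 trials per condition
× 6 conditions; group means `b_S = 1, σ_ρ = 15, σ_d = −1` (feature) and
`b_S = 2, σ_ρ = 10, σ_d = −1` (conjunction); class bias 0 in the equal
conditions and `logit(0.6) = 0.405` toward the rarer class in the scarce
conditions.  Per-participant random effects are independent normals per
parameter and condition with default sds 0.5 (log-odds parameters) and
2.0 (tuning parameters) — the exact magnitudes are not printed in the
source analyses, so these are package defaults chosen to give visible but
bounded heterogeneity, and they are configurable.  Timestamps are
cumulative gamma inter-selection intervals (shape 4, mean 0.8 s) so the
timing-based exclusion rules can be exercised; an optional error rate
produces terminated attempts.

What the generator does *not* emulate: perceptual difficulty itself
(feature vs conjunction differ only through their generating parameters),
learning or fatigue across trials, response-time structure beyond i.i.d.
gamma gaps, and distractor-click dynamics beyond the optional truncation.
Passing recovery tests therefore demonstrate that the inference machinery
is calibrated for data generated by this model family — not that real
foraging data obey it.

## Data handling

Event data live in two flat CSV files (one row per selection; one row per
display item), pixels bottom-left origin, seconds from trial onset,
UTF-8/LF; floats are written with `repr` and parsed with round-trip
precision so write → read is lossless.  Exclusions follow the
pre-registered rules: terminated attempts first, then any trial with an
inter-selection gap above 5 s (the first selection's gap is measured from
trial onset — a package convention, since the rule's treatment of the
pre-first-click interval is unstated), then participants left with fewer
than 5 valid trials in any condition.  The pass is idempotent and its
report reconciles counts exactly.  A first/second-half splitter supports
learning-effect analyses.

## Recovery analysis problem sizes

`scripts/acceptance.py` runs the recovery analysis at 36 participants × 5
trials per condition, fitting each difficulty's three ratio conditions
jointly (540 trials per fit) with 4 chains × 700 warmup × 2000 thinned-
by-2 iterations; the scarcity bias is reported marginalised over the two
difficulties and the two scarce conditions (sign-aligned), matching how
the scarcity criterion itself marginalises.  The test suite runs the same
pipeline at 24 participants.  At these sizes the dominant uncertainty in
any single recovered group mean is participant sampling (re_sd/√J ≈
0.08–0.10 log-odds), which the marginalisation averages down.

## Known limitations

* Two target classes only; no memory, patch-leaving, value or
  response-time extensions.
* The spatial kernel forms are declared package choices, not claims about
  any other implementation's exact forms.
* Random-walk MCMC: fits with many participants × conditions are minutes,
  not seconds; a gradient-based sampler (`sampler="nuts"`) is declared in
  the configuration surface but not implemented.
* The correlated-random-effects (LKJ) model variant is out of scope.
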