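# Methods

## Item model

An item is a set of `n_units` (default 20) emblem–frame associations shown
in a 5 × 4 learning matrix and probed in a four-alternative recognition
format. The difficulty-determining radical is visual information load:

* **Level 1** — 20 original emblems, 20 original frames; every stimulus is
  identified by shape alone.
* **Level 2** — same emblems; the frame inventory is rebuilt from four base
  shapes (rectangle, trapeze, pentagon, hexagon), each complete or with one
  of four edges erased (4 × 5 = 20 frames). Frames must now be encoded by
  shape *and* line completeness.
* **Level 3** — same frames; the emblem inventory is rebuilt from four
  rotatable shapes at 0/90/180/270° (16) plus a ring with a gap at
  top/right/bottom/left (4). Emblems must be encoded by shape *and*
  direction.

The original stimulus set is only partially enumerated in public sources
(right triangle, circle with missing quadrant, circle with prong, L-shape,
black ring, plus sign; rectangle, trapeze, pentagon, hexagon, square). The
remaining shapes in this package are simple, visually distinct parametric
forms chosen to fill the inventories to 20; pixel fidelity to any
particular historical art set is a non-goal. Edges are numbered
counter-clockwise starting from the bottom(-most) edge, and the four erased
variants of a base shape use edges 1–4.

**Incidentals.** Pairing (a uniform bijection emblem→frame), learning-cell
order, recall order, distractor triples and answer-option order are drawn
from independent named substreams of a single item seed
(`SeedSequence([seed, stream_id])`), so adding a new incidental never
perturbs existing ones and items regenerate byte-identically.

**Distractor balance.** Each unit gets 3 distractors, distinct and
different from its correct frame, with every inventory frame appearing
exactly `3·n_units / 20` times (3 for full items) across all distractor
slots — otherwise exclusion strategies could solve items. The assignment
deals a shuffled pool of balanced frame tokens and repairs conflicts by
random pairwise swaps accepted only when they strictly reduce the violation
count; this cannot cycle and in practice finishes in a handful of swaps
(hard cap 10,000, raising an error if ever hit). Because three distinct
distractors plus a distinct correct frame need at least four frames,
`n_units` is bounded below by 4.

**Rendering.** Frames are vertex lists in unit coordinates; an erased edge
is simply not drawn. Emblems are drawn filled at orientation 0 and rotated
by exact 90° pixel permutations, so a rendered rotated emblem equals the
rotated render — a property the tests assert. Drawing uses no
antialiasing; output PNGs are byte-identical across runs for fixed
`(spec, config)`. The answer sheet exists in the original 5 × 4 matrix
format and in a vertical one-unit-per-row format (the variant used in
scrolling web surveys). A JSON manifest maps each recall position to the
answer slot holding the correct frame; the one-minute learning time is
advisory metadata.

## Statistical models

For person ν and item i,

    Y_νi ~ Poisson(μ_νi),  log μ_νi = θ̃_ν + x_νi'β,  θ̃_ν ~ N(0, ζ).

Designs are cell-mean coded with no global intercept: one β per item
(RPCM), one per radical level (RPCM-r), a single intercept (person-only
null model), or item dummies plus group main effects and group × item
interactions (DIF models, dummy coding with the first group and first item
as references). `exp(β)` is the expected score at average ability; Wald
CIs are formed on the log scale and exponentiated, giving the asymmetric
intervals count models report. The Poisson model deliberately ignores the
0–20 score bound, as is conventional; a ceiling warning would be the
analyst's cue that censoring matters.

**Estimation.** The marginal likelihood integrates θ̃ out per person with
*adaptive* Gauss–Hermite quadrature (default 15 nodes): nodes are centred
at the person's posterior mode (found by safeguarded Newton on the strictly
concave inner problem) and scaled by the posterior curvature. L-BFGS-B
maximises over (β, log ζ) with analytic scores obtained from the Fisher
identity (posterior-expected complete-data score); the observed information
is the central difference of that analytic gradient, inverted for the
covariance matrix. Starting values: Poisson-GLM (IRLS) for β,
method-of-moments on person totals for ζ. log ζ is box-bounded in
[−13, 3]; a solution at the lower bound is reported as ζ = 0 with a
boundary flag. Accuracy checks in the test suite: 15-node AGQ matches
brute-force trapezoid integration to well below 1e−6 on small instances
and 15 vs 61 nodes agree to 1e−4 on study-sized data.

**CMP extension.** The Conway–Maxwell–Poisson pmf
`P(Y=j) ∝ λ^j/(j!)^ν` is used in *mean* parameterisation: for each
requested mean the rate is solved by Newton on log λ (the map is monotone
with derivative Var[Y]), so β keeps the same expected-score reading as in
the Poisson models and ν = 1 recovers them exactly (verified to 1e−10).
The normalising series is evaluated on a support grid sized from the
largest requested mean and smallest ν (roughly mean + 15 standard
deviations, capped at 200 terms) with an explicit tail-mass guard that
raises rather than silently truncating. Rate solves are warm-started from
the previous optimiser step and fall back to a cold start after long
line-search jumps. Dispersion parameters are optimised on the log scale,
bounded to ν ∈ [~0.3, ~12] — far outside anything bounded count scores
produce, but inside the truncation budget. Variants: global dispersion,
per-item, or per-radical-level, crossed with items-or-radical fixed
effects. Empirical-Bayes posterior moments under a CMP fit use the CMP
likelihood, so posterior standard errors (and hence conditional
reliabilities) are dispersion-adjusted.

**Inference.** Likelihood-ratio tests clip the statistic at zero and use
the χ² upper tail with df equal to the parameter-count difference. AIC =
2k − 2ℓ and BIC = k·log(persons × items) − 2ℓ.

## Diagnostics

* **Pearson residuals** `(y − μ̂)/√μ̂` with μ̂ from the empirical-Bayes
  posterior-mean abilities; returned as a matrix and a plot-ready long
  table.
* **Dispersion index** φ = Σr²/(n_obs − n_params). The default
  (`conditional`) variant conditions on the EB person estimates — the
  convention of standard mixed-model software — and therefore sits
  somewhat below 1 even for model-exact data, because the person effects
  absorb part of the residual variation (about P/n_obs worth). A
  `marginal` variant standardises against the lognormal-mixture mean and
  variance and is calibrated to 1 under the model; the test suite checks
  both behaviours.
* **Covariate-adjusted frequencies**: for each score value, the expected
  count over all person–item cells with the person effect integrated over
  the fitted N(0, ζ) (41-node quadrature), next to observed counts.
* **Item fit**: persons are split into five total-score quantile groups
  (ties at a boundary go to the lower group; an emptied group triggers
  rank-based regrouping with a warning). Because the total score is
  sufficient for the person parameter, the expected score given the total
  is T·π_i with π_i ∝ exp(x'β) (the person effect cancels); per item the
  group sums of observed minus expected are standardised by the
  multinomial variance T·π(1−π) and squared-summed over groups, referred
  to χ² with df = number of groups. An EB-predicted/Poisson-variance
  variant was evaluated and rejected during development: it rejects a true
  model at ~4× the nominal rate because shrinkage biases score-group
  expected sums, while the conditional form holds its size (~0.02–0.05
  over null replicates).
* **DIF**: the RPCM extended by group main effects (additive model) and
  additionally by (G−1)(I−1) group × item interactions; per-term Wald
  tests (no multiplicity correction — with many terms isolated small
  p-values are expected by chance, which callers must keep in mind) plus
  the two LRTs (additive vs interaction; base vs additive).
* **Classical**: per-item median/mean/SD/min/max and part-whole corrected
  discrimination (zero-variance items yield a warning and a missing
  value); Cronbach's α with the exact F-distribution interval
  (df (n−1, (n−1)(k−1))).
* **Conditional reliability** ζ̂/(ζ̂ + s_ν²) per person — exactly 0.5 when
  the posterior variance equals the ability variance.

## Synthetic data

`simulate_responses` draws exactly from the fitted models' generative
process: θ̃ ~ N(0, sd²), counts Poisson (or mean-parameterised CMP via
inverse-cdf sampling) at exp(θ̃ + σ̃), optionally right-censored at the
maximum score. `synthesize_study` fixes the reference study conditions:
208 persons in three presentation-order groups of 63/76/69, nine items in
three families with counts-scale family easiness (10.80, 9.08, 7.12),
within-family log-easiness jitter of SD 0.04 (so isomorphs differ slightly,
and the radical-vs-items LRT is occasionally significant, as observed in
practice), person SD 0.229, censoring at 20. `make_block_design` builds
the three-condition presentation design: a warm-up block in increasing
difficulty for everyone, then two blocks whose level orders form Latin
squares across conditions.

What the generator does *not* emulate: the response process at the level of
single associations (no 1-in-4 guessing floor — counts are generated at the
item level exactly as the RPCM assumes), real response-style heterogeneity,
and the underdispersion strength of real bounded-score data. Censoring at
20 produces mild underdispersion (the acceptance script measures φ ≈ 0.94
at these parameters), offered as one candidate mechanism, not a claim about
the true cause; real bounded-score data can be considerably more
underdispersed, so tests passing on synthetic data demonstrate correctness
of the machinery under the model, not that real data meet the model. Quantities that depend on the real
dispersion level (Cronbach's α, φ itself, CMP improvement LRTs) therefore
differ between synthetic runs and published empirical values, while
structural quantities (family easiness, person SD, LRT for item effects,
person-parameter correlations, minimum conditional reliability) land on
the encoded values up to sampling error.

## Numerical choices and problem sizes

Default quadrature: 15 nodes (adaptive), 41 for frequency marginalisation.
Rate-solve tolerance for the CMP mean constraint: 1e−11 relative. The
recovery/test-size study in the acceptance script uses 100 replicates of
the 208 × 9 design, which keeps the whole script around half a minute while
Monte-Carlo SEs stay small enough for 3-SE bias checks. Stochastic test
assertions use 3 Monte-Carlo SE bands measured from the replicates
themselves (e.g. the minimum conditional reliability has seed-to-seed SD
≈ 0.013 under the study-design generator).

## Known limitations

* The legacy `.rda` converter needs `Rscript` or `pyreadr` at call time;
  the core package never depends on R.
* Wald intervals throughout; profile-likelihood intervals are not
  implemented.
* The CMP support grid caps at 200 terms: means far above the figural
  score range (≫ 20) with strong overdispersion raise an explicit error
  instead of fitting.
* No multiple-testing correction in DIF per-coefficient tests (reported
  raw, with the caveat above).
* Joint (fixed-person) maximum likelihood is deliberately absent: with one
  parameter per person it is inconsistent for item parameters at this
  design size.
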