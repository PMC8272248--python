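# Methods

## Aggregation operators

An aggregation function is a map `p: [0,1]^n → [0,1]` with `p(0,…,0)=0`,
`p(1,…,1)=1` and coordinate-wise (non-strict) monotonicity. The registry
holds n-ary operators (means, medians, OWA, the weighted ratio form) and
bivariate ones (symmetric sums, t-norms, Stolarsky means, the two-branch
generalized-Choquet blend). Bivariate operators are lifted to `n`
arguments by a left fold `r_k = op(r_{k-1}, v_k)`; the fold order is the
fixed classifier-registry order (alphabetical model names) by default,
with a per-operator or per-call option to fold in descending value order.
Folds of non-associative operators depend on this order, which is why it
is pinned and documented rather than left to container ordering.

Three registered forms deserve comment, because their printed sources are
ambiguous or defective and the adopted readings are deliberate choices:

* **Two-branch blend** `L(x,y) = a·x+(1−a)·y (x≥y); (1−b)·x+b·y (else)`,
  with `a,b ∈ [0,1]`. Each branch is a convex combination, which is the
  only reading that keeps outputs in `[0,1]` for every parameter choice.
* **Log-generator form** `2^(log₂(1+x)·log₂(1+y)) − 1`. The generator
  `t ↦ log₂(1+t)` maps `[0,1]` onto itself; multiplying generator images
  and pulling back yields an aggregation function with neutral element 1.
  The literal log-product expression (which evaluates to 2 at `(1,1)`)
  is registered separately as `log_product_literal` with documented
  boundary/range violations, so the two can be compared.
* **Exponential-generator t-norm**
  `M(x,y) = (ln(e^(x^−α) + e^(y^−α) − e))^(−1/α)`, `α > 0`. Continuous
  Archimedean t-norm with neutral element 1 and annihilator 0 (limit for
  zero arguments). It is evaluated through a log-sum-exp rewrite because
  `e^(y^−α)` overflows for `y ≲ 0.14` at `α = 3.3`; below `y ≈ 1e−93`
  even the generator value overflows and the dominant term makes the
  t-norm equal `min(x,y)` to double precision, which is what is returned
  there. The rewrite is exact, not an approximation.

The printed Bertino-copula-derived form `min(x,y)² (x≤y); max(x,y)²−|x−y|`
is kept exactly as printed; it is asymmetric, non-monotone in part of the
unit square, and negative on part of it (`f(0.5,0.05) = −0.2`). Both
defects are recorded as *documented axiom exceptions*: the axiom checker
fails an operator only on undocumented violations. The censored midpoint
substitutes 0.5 for any argument in the half-open interval `[0.5, 0.7)`
before averaging; 0.7 itself is not censored.

The axiom checker tests boundaries to `1e−9`, monotonicity non-strictly on
seeded random pairs `x ≤ y`, and range on the sampled values; a 0.01-step
exhaustive grid oracle over the unit square is used in the test suite to
confirm the sampled verdicts for bivariate operators.

## Sugeno λ-measure and integrals

Densities `g_i ∈ [0,1]` (one per classifier) determine λ through
`1 + λ = Π(1 + λ g_i)`: λ = 0 exactly when `Σ g_i = 1`, λ < 0 when the
densities oversum, λ > 0 when they undersum. The solver brackets the
non-zero root (Brent, residual < 1e−12, plus Newton polish). Subset
measures use the closed form `g(A) = (Π_{i∈A}(1+λg_i) − 1)/λ`; the
nested-set recurrence `g(A_{i+1}) = g(A_i) + g_{i+1} + λ g_{i+1} g(A_i)`
is the equivalent incremental form used along the sorted profile.

With `h_(1) ≥ … ≥ h_(n)` (stable sort; ties keep original index order,
which cannot change the integral because tied increments vanish) and
`h_(n+1) = 0`:

* Choquet: `Σ (h_(i) − h_(i+1)) · g(A_i)` — idempotent, monotone,
  internal, and equal to the weighted mean for additive measures.
* Sugeno: `max_i min(h_(i), g(A_i))`.
* Generalized form I (capped increments):
  `Σ M(min(h_(i),g(A_i)) − min(h_(i+1),g(A_i)), g(A_i))` for a t-norm `M`.
* Generalized form II: `Σ [min(M(h_(i),g(A_i)),g(A_i)) −
  min(M(h_(i+1),g(A_i)),g(A_i))]`.

Both generalized forms are clamped to `[0,1]` (they are pre-aggregation
functions, not aggregation functions, and individual summands can
overshoot). Form I feeds `M` the capped increment and `g(A_i)`; the
source expression is typographically ambiguous on this point, so the
choice is isolated in one function and an alternate reading can be
swapped in without touching callers.

**Density clipping.** When densities are per-classifier accuracies, eight
near-perfect classifiers push the normalization root within one
double-precision ulp of −1, where no solver can resolve it. Accuracy-
derived densities are therefore clipped into `[10⁻³, 0.98]` before the
measure is built. With eight densities at the 0.98 cap the root sits at
`λ ≈ −1 + 2.6·10⁻¹⁴`, still representable; the clip changes densities
only for classifiers whose CV accuracy exceeds 98%, where the measure is
already saturated near the unanimity measure.

## Fusion

For each observation and each class, the probabilities assigned to that
class by all classifiers are aggregated; the predicted label is the
argmax over the three class scores, ties broken by the lowest class
index. Scores are *not* renormalized across classes — operators act on
each class column independently. Weight-taking operators receive raw
CV accuracies (the weighted ratio form, weighted mean/median); OWA
weights are either a named profile (uniform, max, min, olympic, linear)
or the accuracies sorted descending and normalized to sum 1, since OWA
weights formally must sum to 1.

Grid expansion: the default grids sweep the two-branch blend on a 51×51
`(a,b)` lattice (the >1000-member pre-aggregation family), Stolarsky
exponents, a fine α grid for the exponential-generator t-norm, OWA
profiles, the parameterless operators, and the four integral rules with
several t-norms — 2694 variants in total. Two sub-grids exist for
repeated-protocol work: a compact one (62 variants) and a dominance grid
(611 variants, two-branch lattice at 21×21 plus descending-fold twins of
the bivariate headline operators).

## Study protocol

One repetition: (1) hold out all three rows of 6 randomly chosen
participants (18 test observations, balanced 6/6/6 by construction);
(2) z-score every feature on training statistics only (zero-variance
features are dropped with a warning; the threshold is relative,
`sd > 1e−12·max(1,|μ|)`, so constant features whose float std is noise
are caught); (3) optionally select features — per repetition on training
rows, or once globally; (4) fit the eight-model roster; (5) derive
fuzzy-measure densities by participant-grouped k-fold CV on the training
table; (6) build the test-set probability cube, fuse with every operator
variant, and record accuracies alongside the individual models.
Repetition seeds are drawn sequentially from a `default_rng(master_seed)`
stream, so a report is reproducible from its master seed alone.

Roster details: SVMs (linear, inhomogeneous quadratic and cubic
polynomial kernels) are wrapped in sigmoid (Platt) calibration on
internal folds to produce probabilities; logistic regression, k-NN
(k=5), a decision tree, a 60-tree random forest and a one-hidden-layer
MLP (32 units, 300 iterations) complete it. Model sizes are chosen for
~70-row training tables; they are deliberately small.

Feature selection mirrors the screen-then-test convention: a K-S
normality check on pooled within-class standardized residuals and
Levene's variance-homogeneity test (both at α = 0.05) screen features;
one-way ANOVA (α = 0.05) selects among the survivors; Tukey's HSD
identifies which class pairs differ for each significant feature. A
switch includes screen-failing features in selection when the screens
are not wanted.

## Synthetic generator

Value model per participant `p`, feature `f`, class `c`:

    x = base_f + pattern_{f,c} · effect_scale · sd_f + b_{p,f} + ε

`b_{p,f}` is a participant effect shared across the participant's three
rows (drawn from the feature's own noise shape so skew is not washed
out), `ε` is within-class noise. Twenty named features cover fixations,
saccades, blinks, pupil diameter and task performance; the default
patterns encode which class pairs separate on which features (response
number separates all three levels; response time separates low from the
harder two; fixation/saccade/blink counts separate high from the rest;
three features carry no class effect and skewed noise so they tend to
fail the normality screen). `effect_scale = 2.0` is the calibration at
which the roster's individual accuracies land in the high-80s-to-mid-90s
band under the subject-independent protocol, leaving realistic headroom
for fusion; `participant_sd = 0.6` induces clear intraclass correlation.
`GeneratorConfig.null()` gives the i.i.d. Gaussian null (no class
effects, no participant effects) used to calibrate the selection
procedure: with participant effects present, one-way ANOVA across the
three within-participant conditions is *conservative*, so the nominal 5%
false-selection rate is only expected under the i.i.d. null that matches
ANOVA's independence assumption.

What the generator does **not** emulate: raw gaze streams and event
detection, inter-feature correlation beyond the shared participant
effect (features are conditionally independent given participant and
class; real fixation/saccade counts are strongly coupled), floor/ceiling
effects in counts, and any nonlinearity in the class structure. Because
classes differ only in Gaussian mean shifts, linear models (logistic
regression, linear SVM) are near-optimal on these tables — on some
generated datasets a single linear model dominates every fusion rule, a
regime the package reports honestly rather than hiding (see the
dominance experiment below). Passing tests on this generator therefore
validate the machinery and the qualitative fusion behaviour, not any
claim about real eye-tracking data.

## Fusion-dominance experiment

`fusion_dominance_experiment` regenerates the study `n_runs` times
(fresh generator seed per run), runs 12 protocol repetitions per study
(216 test observations), grid-searches the 611-variant dominance grid,
and compares the best fused mean accuracy with the best individual
model's mean accuracy. At the default master seed the median improvement
is about +1.4 percentage points and fusion is strictly better in 88% of
runs; in a small minority of generated datasets a dominant logistic
regression stays ahead of every operator by up to ~2 points (verified
stable under 4× more repetitions). Twelve repetitions per run keep the
50-run experiment near ten minutes on one CPU; the within-study protocol
itself supports the conventional 200 repetitions.

## Known limitations

* The λ-measure family cannot express arbitrary interaction patterns;
  only density-driven (Sugeno) measures are supported, and densities come
  from the CV heuristic, not optimization.
* The printed Bertino form and the literal log-product form violate
  aggregation axioms by construction; they are kept for fidelity and
  flagged, not repaired.
* Stolarsky means with `r < 0` are defined at zero arguments by their
  continuous limit (0); `r ∈ {0, 1}` is rejected.
* Fused scores of range-violating operators (the printed Bertino form)
  can leave `[0,1]`; argmax decisions remain well-defined.
* The generator's Gaussian class structure favours linear models; see
  above for what this implies about dominance results.
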