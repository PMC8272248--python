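# aggfuse

Aggregation-function and fuzzy-integral based **classifier fusion** for
three-level cognitive-workload recognition from eye-tracking and task
performance features.

## The problem

Cognitive workload studies based on the Digit Symbol Substitution Test
(DSST) record, per participant and task difficulty block, a small table of
eye-activity features (fixation counts and durations, saccade counts and
amplitudes, blinks, pupil diameter) plus task performance (response count,
response time, errors), and ask a classifier to recognize the workload
level (low / medium / high). Individual classic models — SVMs, k-NN,
decision trees, random forests, logistic regression, an MLP — reach
different accuracies; their per-class probability outputs can be **fused**
by an aggregation operator, and with the right operator the fused decision
beats the best individual model.

`aggfuse` provides:

* a registry of aggregation operators: means, OWA, t-norms, symmetric
  sums, Stolarsky means, and the two-branch generalized-Choquet blend
  `L(x,y) = a·x + (1−a)·y if x ≥ y else (1−b)·x + b·y`, plus an axiom
  checker (boundary conditions, coordinate-wise monotonicity, range);
* Sugeno λ-fuzzy measures built from per-classifier cross-validated
  accuracies `g_i` (λ solves `1 + λ = Π(1 + λ g_i)`), the **Choquet
  integral** `Σ (h_(i) − h_(i+1)) g(A_i)`, the **Sugeno integral**
  `max_i min(h_(i), g(A_i))`, and two generalized pre-aggregation
  integral forms in which a t-norm `M` enters the summand;
* a fusion engine that aggregates per-classifier class probabilities
  class-by-class and predicts the argmax, with parameter-grid expansion
  (>2000 operator variants) and validation-accuracy ranking;
* the study protocol: z-score normalization on training statistics,
  K-S/Levene screens + one-way ANOVA + Tukey HSD feature selection,
  repeated subject-independent splits (6 held-out participants → 18
  balanced test observations), per-repetition fuzzy-measure densities
  from participant-grouped cross-validation;
* a synthetic generator emulating the study's 29-participant × 3-class
  × 20-feature table with class-dependent means, participant random
  effects and configurable noise shapes, so the whole pipeline is
  testable without the (unavailable) original recordings.

## Worked example

```python
import aggfuse as af

# densities = cross-validated accuracies of three classifiers
m = af.measure_from_accuracies(
    [0.90, 0.85, 0.80], ["logistic_regression", "random_forest", "knn"]
)
print(m.lam)                 # -0.996818  (densities oversum, λ < 0)
print(m.g([0, 1]))           # 0.987434   (measure of {LR, RF})

probs = [0.70, 0.55, 0.20]   # one class's probability from each classifier
print(af.choquet_integral(probs, m))   # 0.680602
print(af.sugeno_integral(probs, m))    # 0.7

from aggfuse.operators import generalized_choquet_form
print(generalized_choquet_form(0.8, 0.2, a=0.01, b=0.99))  # 0.206
```

End-to-end on synthetic data:

```bash
aggfuse simulate --seed 7 --out features.csv
aggfuse select --data features.csv
aggfuse run-protocol --data features.csv --repetitions 30 --seed 7 \
    --out ranking.csv
```

`run-protocol` prints a ranking in which fusion operators (e.g. the
generalized-Choquet blend and the Choquet integral) sit at or above the
best individual classifier's mean accuracy.

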