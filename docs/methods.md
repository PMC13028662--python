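# Methods

## The experiment and its model

The package targets four-factor Box–Behnken designs (BBD): for every
unordered factor pair, four runs at the (±1, ±1) edge midpoints with the
other factors at center, plus C₀ replicated center runs — N = 2k(k−1) + C₀,
so 27 runs for k = 4, C₀ = 3. Factor coding is linear in the midpoint and
half-range of each factor's actual levels (50–100 % ethanol, 400–800 W,
2–4 min, 30–50 mL/g in the packaged study); this is the only coding
consistent with the packaged design table, and it makes the coded design
orthogonal enough for a full quadratic fit.

The canonical response model is the **full second-order polynomial** in
coded factors — 15 terms for k = 4 (intercept, 4 linear, 6 interaction,
4 quadratic). Reduced displays that drop non-significant terms are common
in reports, but only the full model reproduces the packaged per-run
prediction columns, so the full model is what `QuadraticSurfaceRegressor`
fits and serializes; pruning is intentionally not implemented.

### Estimation and ANOVA

- The fit is **unweighted OLS on the 27 run means** (via statsmodels
  behind the estimator surface). Replicate SDs are stored but not used as
  weights: the packaged RMSE values (6.94 and 1.60) are exactly the
  residual-df convention on run means, which pins down both choices.
- RMSE = √(SSE/(n−p)) with n−p = 12 — the square root of the residual
  variance as design-of-experiments software reports it, not the
  n-divisor machine-learning convention (that one is used only in
  `knn.evaluate`, where surrogate models are compared).
- Lack of fit partitions SSE using pure error from replicated design
  points — only the three center runs in a BBD (df = 2). The reproduced
  p-values (0.1245, 0.1823) agree with the published 0.1246/0.1826 to the
  precision the inputs allow.
- Coefficient p-values are two-sided t-tests on 12 df; the model test is
  the usual F on (p−1, n−p). No multiplicity correction is applied — the
  table is descriptive, matching standard DoE practice.

Two reporting quirks of the source tables are handled explicitly rather
than reconciled: the printed AlCl₃ R² (0.96) and FCRC R² (0.99) correspond
to **truncation** of the computed 0.9680/0.9973, so tests assert the
truncation-or-rounding band instead of strict 2-dp rounding; and one
FCRC prediction cell (run 22) disagrees with the model that reproduces the
other 53 cells by exactly 3.00 with an identical decimal fraction — a
misprinted integer digit. The fixture stores the value as printed and
flags it in `MISPRINTED_PREDICTION_RUNS`; tests assert the 3.00 offset so
the discrepancy stays visible instead of being silently absorbed.
Similarly, the printed AlCl₃ x₁² coefficient (0.07) is not reproduced by
the fit (0.20) although every prediction is — it is carried in the fixture
but is not a test target. The center-level AlCl₃ response is quoted
inconsistently across the source (37.38 / 37.24 / 37.23); the fitted
intercept 37.24 is treated as authoritative.

## KNN surrogate

`KNNRegressor` is deliberately brute-force (n = 27): prediction averages
the k nearest training targets with equal, 1/d, or 1/d² weights. Conventions
that the field's numerical environments disagree on are fixed as follows:

- **Jaccard on real vectors** counts coordinate value inequality over the
  either-nonzero support (0/0 → 0), the pdist convention of the software
  family these models come from — *not* scipy's presence/absence variant,
  which is a different quantity; this is the one hand-rolled metric.
- **Hamming** is the fraction of exactly unequal coordinates; **cosine /
  correlation / Spearman** are one minus the similarity with degenerate
  (zero or constant) vectors given distance 1; Spearman uses average ranks
  on ties. **Mahalanobis / standardized Euclidean** statistics come from
  the training inputs only, ridge-regularized (1e−8) when near-singular.
- **Zero-distance rule**: if any selected neighbor is at distance 0 the
  prediction is the unweighted mean of the zero-distance targets. On the
  training set this reproduces every unreplicated target exactly; at
  replicated center runs it returns the replicate-group mean, which is why
  training correlations under distance weighting are ≈0.9999 rather than
  exactly 1.
- Ties at the k-th neighbor break by ascending training index (stable
  sort), making predictions order-reproducible.

Normalization to [−1, +1] is fitted on the **entire dataset before
splitting** (the workflow's stated preprocessing order); the 70/30 split
is a seeded uniform partition with ⌈0.7n⌉ training members. Because the
original split membership is unknowable, published surrogate R/RMSE values
are treated as qualitative references; tests instead pin the behavioral
properties (exhaustive-search equivalence on enumerable spaces, baseline
dominance, training-set behavior).

## Dragonfly optimization

The source workflow names the dragonfly algorithm but not its equations;
the implementation follows the canonical formulation: velocity =
weighted sum of separation, alignment, cohesion, food attraction, enemy
repulsion, plus inertia; neighborhood radius growing from span/4 by 2·span
per unit progress; inertia annealed 0.9→0.4; s/a/c as random multiples of
a coefficient decaying 0.1→0 over the first half of the run; Lévy flight
(exponent 1.5, Mantegna sampling) for isolated agents; steps clipped to
span/10 and positions clipped to bounds with the offending velocity
component zeroed. All schedule constants are `DAConfig` fields. Defaults
(100 iterations, 30 agents) are the study's stated budget.

MODA keeps a bounded archive of non-dominated solutions; food is drawn by
roulette from sparse hypercube segments of objective space (10 segments
per objective over the archive bounding box), the enemy from crowded ones,
and overflow evicts from the most crowded segment. Archive capacity (100)
and segment count are explicit package choices — the study does not state
its settings.

**Hyperparameter tuning** encodes (metric index, weighting index, k,
Minkowski exponent) as a continuous box, rounding discrete dimensions at
evaluation time; the exponent is bounded to [1, 10]. The objective is
validation RMSE. A sane baseline (Euclidean, equal weights, k = 3) is
injected into the initial swarm, so the tuner can never return a
configuration worse than it. The reported best is re-derived as the argmin
of the evaluation log, not trusted from swarm state.

## Desirability optimization

The workflow names desirability-based validation without defining the
transform; the package uses the Derringer maximize form — d = 0 below the
lower anchor, ((y−L)/(T−L))^s up to the target, 1 above — with s = 1 and
anchors at each response's observed minimum/maximum by default, combined
by geometric mean. With those anchors the two fitted surfaces exceed both
targets on a region of the domain, so the overall desirability saturates
at 1 there; ties on that plateau break toward the largest summed
standardized prediction, which pushes the optimum to jointly higher
responses and lands at the upper power/time bounds (800 W, 4 min), in line
with the study's reported optimum. The optimizer is a dense coded-grid
scan (21 points per axis) seeding a bounded Nelder–Mead refinement whose
result is accepted only if it does not lose desirability.

For the MODA branch, surrogates are trained on **all** 27 runs — the
train/validation split exists only for tuning — and the compromise point
is the archive member maximizing the *sum* of predicted responses, the
aggregate the study validates against. The published optimum row for this
branch garbles two coordinates (X₂ = 804, missing X₃); the fixture follows
the study's consistently stated optimum (50 %, 800 W, 4 min, 47.28 mL/g).
Its printed summed experimental response (425.0077) also does not equal
its printed components (376.8514 + 49.1614 = 426.0128); the validation
report always recomputes componentwise sums.

## Synthetic data

`simulate_bbd_dataset` draws n_reps independent Gaussian replicates around
a known quadratic surface at each design point and records their mean and
sample SD — the structure the analysis assumes. Noise is homoscedastic
(default SD 2 response units, inside the 0.3–4.7 range of replicate SDs in
the study data; triplicates by default). Real replicate SDs vary by run
and may be mean-dependent; the generator does not emulate that, nor OVAT
screening or kinetic effects, so passing recovery tests demonstrate
correctness of the estimators under the stated model, not robustness to
heteroscedasticity. Recovery checks run 50 seeded replicates (500 would
tighten the bands but adds nothing qualitative); a pooled 95 %-CI coverage
band of 90–100 % is used at that replicate count.

## Degenerate inputs and numerical choices

- Constant features make [−1, +1] normalization undefined → error.
- Zero response variance makes Pearson correlation undefined → error for
  the inter-response correlation; `knn.evaluate` reports R as missing when
  predictions are constant.
- Rank-deficient quadratic design matrices and n ≤ p fits are rejected.
- Pure error requires ≥ 2 replicates of some design point and a positive
  pure-error SS; otherwise lack-of-fit fields are absent, not zero.
- All stochastic stages take explicit integer seeds and are reproducible
  bit-for-bit; CSV round-trips preserve numeric fields to 1e−12 (values
  are written with `repr`).

## Known limitations

- The KNN surrogate with Jaccard distance is piecewise constant over most
  of a continuous domain (almost all vector pairs differ in every
  coordinate, giving distance 1); it interpolates the design points
  perfectly but generalizes poorly between them, and MODA over such a
  surrogate can collapse to few archive points. That behavior is faithful
  to the method, not a defect of the optimizer.
- Published surrogate performance metrics depend on an unknown split and
  are not reproduction targets.
- No blocking, no central-composite designs, no term selection, and no
  constraint handling beyond box bounds.
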