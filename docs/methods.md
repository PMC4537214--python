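# Methods

## Model class

For one phenotype `y` over `n` samples with feature matrix `X` (n × p) and
candidate binary splits `Z` (n × T), a model consists of: an optional
committed split `t`; disjoint sets of shared, arm-1 and arm-0 features; a
global intercept; and, when a split is committed, an arm-1 intercept
offset. Predictions are

```
ŷ_i = β₀ + Σⱼ βˢⱼ x_ij + δ(z_it=1)(β₀ᵗ + Σⱼ βᵗ¹ⱼ x_ij) + δ(z_it=0) Σⱼ βᵗ⁰ⱼ x_ij.
```

A feature holds at most one role. The formal model class would permit a
feature to carry shared and contextual coefficients simultaneously;
exclusivity keeps designs full-rank at the small n this method targets and
makes roles interpretable. The arm intercept offset exists so that a mean
difference between contexts cannot masquerade as a contextual feature
effect.

Continuous (expression, copy-number) columns are z-scored within each
fitting set before search; mutation columns stay 0/1. Coefficients are
reported on that standardized scale, which makes the fixed per-coefficient
bit cost (below) mean the same thing for every feature.

## Description length

Model search minimizes a two-part code:

```
DL = (n/2)·log₂(RSS / df)  +  Σ_selected cost(j)  +  cost(split)
```

* **Residual code.** `(n/2)·log₂(RSS/df)` with `df = n − m` (m = number of
  fitted coefficients including intercepts) is the Gaussian code length of
  the residuals under the unbiased noise-variance estimate, up to
  model-independent constants. The df correction matters: with the
  maximum-likelihood variant `RSS/n`, every added coefficient makes
  further *relative* RSS reductions cheaper, and once transfer lowers
  selection costs the forward search runs away into dense, noise-fitting
  models. With the honest df a coefficient that absorbs only its expected
  share of noise buys no code-length reduction. `RSS` is floored at
  `1e−12·n` so perfect fits stay finite. The public helper is
  `data_bits(rss, n, df=None)`; `df` defaults to `n`, and the search
  passes `n − m`.
* **Feature cost.** Under uniform coding each selected feature costs
  `log₂(p) + 2` bits: `log₂(p)` to name it among p candidates and 2 to
  encode its coefficient. The cost is role-independent.
* **Split cost.** Committing the single allowed split costs `log₂(T)`
  bits to name it plus 2 bits for the arm-intercept offset, which is an
  estimated coefficient like any other and is priced as one. T = 1 makes
  naming free; T = 0 disables contextual moves.

`dl_scale` (default 1.0) multiplies the selection-cost side, exposing the
effective penalty scale.

## Greedy search

Pure forward-stepwise. Candidate moves at each step: add an unused
feature as shared, or add it arm-specifically under a split (committing
that split if none is committed; at most one split per model, and a commit
is only offered jointly with a first contextual feature). The move with
the lowest resulting DL is accepted if it strictly decreases DL; ties
within 1e−9 bits prefer shared over contextual, then lower feature index,
then lower split index, then arm 1. After every accepted move all
coefficients are refit by OLS on the active design; nothing is shrunk.
Move evaluation is incremental: candidate columns are orthogonalized
against the current design's QR basis, so a step scores all p·(1 + 2T)
moves with a handful of matrix products.

Guards: a move is disallowed (not an error) when the design would exceed
`n − 1` coefficients, when a candidate column is numerically collinear
with the active design (relative squared norm < 1e−8), or when a
contextual move targets an arm with fewer than `min_arm_size = 5` fitting
samples.

On 100 random strong-signal instances (n = 50, p = 8, T = 2, ≤ 3 true
features at 5× noise sd) the greedy solution matches the exhaustively
enumerated DL optimum's selected structure ≥ 90% of the time and never
undercuts its DL (`tests/test_acceptance.py`, `scripts/acceptance.py`).

## Bootstrap protocol and weighted fitting

B resamples of the n samples, drawn with replacement to the original size,
are generated once per run and reused for every phenotype and iteration,
so all phenotypes train on the same resampled cell lines. Samples missing
a phenotype are dropped per phenotype from each replicate; replicates left
with fewer than 10 usable samples are skipped and that phenotype's
effective B reduced.

Each replicate is fitted through its distinct rows with multiplicity
weights. Minimizing the multiplicity-weighted squared error is *exactly*
the OLS fit on the expanded resample, but the residual code then counts
each distinct cell line once (`data_bits` with n = number of distinct
rows). Coding duplicated rows as independent observations double-counts
the same noise realization and roughly doubles spurious selection gains —
measured on pure-noise phenotypes, expanded-row fits selected ~7 decoys
per replicate where full-data fits select none; the weighted form restores
parity. Standardization uses weighted means and variances.

## Transfer of selection priors

Similarity weights are `w_yk = σ(c·(r_yk − r₀))` with the Pearson
correlation `r_yk` computed on pairwise-complete observations; defaults
c = 8, r₀ = 0.5. Centring the sigmoid means an uncorrelated pair
(r ≈ 0) receives weight ≈ 0.02 rather than 0.5: phenotypes that share no
response profile should not exchange priors, and in panels with several
unrelated phenotype groups an uncentred weight measurably leaks each
group's reliable markers into the other groups' models. Pairs with fewer
than 3 complete observations fall back to r = 0 with a warning. The
uncentred form is available via `sigmoid_center=0`.

Priors pool the any-role selection frequencies:

```
P_y(βⱼ ≠ 0) = (Σ_{k≠y} w_yk·τ_jk + a) / (Σ_{k≠y} w_yk + b),   a = b = 0.5.
```

The phenotype's own frequencies are excluded — its evidence re-enters
through the next bootstrap round; `include_self=True` adds them. The
denominator is implemented as written above (`eq4_denominator=
"as_printed"`); the standard beta-posterior form `Σw + a + b` is available.
Split-commitment frequencies update split priors identically. With zero
total neighbour weight the priors degenerate to the uninformative 0.5.

**Prior → cost.** The update has a hard floor `P0_y = a/(Σ w_yk + b)`,
reached when no neighbour ever selects a feature. Costs are the
log-affine interpolation anchored at two invariants — no evidence keeps
the uniform cost, certainty pays only the coefficient bits:

```
cost(j) = 2 + log₂(p) · log(Pⱼ) / log(P0_y)        (feature)
cost(t) = log₂(T) · log(split_Pⱼ) / log(P0_y)      (split)
```

Costs are therefore always within `[2, log₂(p)+2]` and monotone in P.
The direct map `−log₂(P) + 2` capped at uniform (`anchored=False`) treats
the floor itself as evidence: every feature in the panel then gets a 2–4
bit ambient discount per iteration, which in benchmark runs floods models
with decoys within two iterations. The anchored form leaves no-evidence
features priced exactly as in iteration 1, while a single similar
neighbour that selects a feature in every bootstrap run (P = 1) drives its
cost to the 2-bit minimum — the regime in which a weak phenotype inherits
a marker from a strongly driven, correlated neighbour.

## Iteration and finalization

Iteration 1 uses uniform costs. After each iteration, priors are
recomputed from the current iteration's frequencies only and converted to
the next iteration's costs. Defaults: B = 100 resamples, 10 iterations,
τ threshold 0.3 (`split_threshold` defaults to the same value). After the
last iteration, per phenotype: features with final τ ≥ 0.3 are kept with
their majority role across that iteration's runs (ties → shared); the most
frequently committed split is kept if its frequency passes the threshold
(ties → lowest index); contextual roles without a surviving split fall
back to shared; coefficients are refit by OLS on the full
phenotype-complete sample set. An empty selection yields an
intercept-only model.

## Evaluation harness

Ten-fold cross-validation draws a seeded random partition shared across
phenotypes; the *entire* loop (bootstraps, iterations, transfer,
finalization) reruns inside each training fold. Intercept-only fold
models predict the fold's training mean. Out-of-fold Pearson and Spearman
correlations are the metrics; a constant prediction vector is scored
(0, 0) with a flag, the value a mean fallback must get to be comparable.
`adjusted_r2` uses `1 − (1−R²)(n−1)/(n−q−1)` with q counting all fitted
coefficients except the global intercept (the arm offset counts).

## Synthetic panels

The generator emulates the statistical structure the method assumes, not
any particular real panel: 20% mutation columns ~ Bernoulli(q),
q ∈ [0.1, 0.4]; the rest standard normal with correlation 0.3 in blocks of
10 (co-expressed modules); T balanced random splits; K phenotypes in
groups that share true features and split, with per-phenotype ±20%
coefficient jitter. True effects act on the *standardized* feature scale
(so mutation and expression features carry comparable signal per unit
coefficient) with coefficients ±Uniform(0.5, 1.5);
`round(k_true·frac_contextual)` of each group's features are arm-specific.
`noise_sd` is by default a noise-to-signal ratio (Gaussian noise sd =
`noise_sd` × the phenotype's signal sd); `noise_relative=False` makes it
absolute. What the generator does **not** emulate: heavy-tailed and
batch-structured expression noise, linkage between mutation and copy
number, dose–response measurement error, or splits correlated with the
feature matrix — retrieval scores here bound what the algorithm can do
when its model class is correct, not performance on real panels.

The benchmark used by the tests and the acceptance script scales the
protocol to desk size — K = 20 phenotypes in 4 groups, n = 60, p = 100,
T = 3, B = 25, 5 iterations — and evaluates at noise 0.5×, 1× and 2× the
signal sd. At 0.5× the method recovers planted features with median
precision/recall 1.0 and identifies the true split in ~85–95% of
phenotypes; both degrade monotonically as noise doubles, and the
final-iteration F-measure never falls below iteration 1's. The
`transfer_scenario` helper builds the two-phenotype rescue case (one
strong, one too weak to pay the uniform cost alone; correlation ≈ 0.26)
in which the weak phenotype acquires the marker only when transfer is
enabled.

## Known limitations

* One split per model; multi-way or nested contexts are out of scope.
* L0 selection keeps one representative of a collinear cluster; the
  τ threshold is set at 0.3 (rather than the 0.5 customary for elastic
  net stability selection) partly to compensate, but correlated features
  still split their frequencies.
* Weak contextual effects (|β| ≲ 0.6 on the standardized scale at n = 60,
  noise 0.5× signal) are frequently absorbed as shared effects or missed;
  split identification degrades accordingly.
* The transfer weights assume phenotype similarity is well summarized by
  a (sign-sensitive) correlation; anticorrelated phenotypes never
  exchange priors even though a sign-flipped marker would be informative.
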