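# cherreg — contextual sparse regression for pharmacogenomics

`cherreg` learns sparse linear models of drug sensitivity from pooled
cancer cell-line panels. Pooling related cancer types buys statistical
power, but the genetics of response often differ between contexts (cancer
type, tissue, subtype). The package therefore fits models in which each
selected genomic predictor is either **shared** across the whole pool or
**contextual** — active only in one arm of a binary *split* of the
samples, chosen from a set of candidate splits during fitting:

```
y_i = β₀ + Σⱼ βˢⱼ x_ij + δ(z_it = 1)(β₀ᵗ + Σⱼ βᵗ¹ⱼ x_ij) + δ(z_it = 0) Σⱼ βᵗ⁰ⱼ x_ij + ε_i
```

where `x_ij` are genomic features (binary mutation calls, continuous
expression and copy-number values), `z_it` is the indicator of candidate
split `t`, and at most one split may be committed per model.

Three ingredients make the selection robust at the small sample sizes
typical of per-cancer panels:

1. **L0/MDL selection.** Model search minimizes a description length:
   Gaussian code length of the residuals plus selection costs in bits —
   `log₂(p) + 2` per selected feature under uniform coding (`log₂(p)` to
   name the feature, 2 to encode its coefficient) and `log₂(T)` to commit
   a split. Search is greedy forward-stepwise; coefficients are refit by
   OLS after every accepted move and never shrunk.
2. **Bootstrap stability selection.** The fit is repeated over B
   bootstrap resamples (shared across phenotypes); only features whose
   selection frequency τ in the final iteration reaches a threshold
   (default τ ≥ 0.3) enter the final model.
3. **Transfer between correlated phenotypes.** Selection frequencies are
   pooled across phenotypes with similarity weights
   `w_yk = σ(c·(r_yk − r₀))` (sigmoid of the phenotype correlation) into
   inclusion priors `P_y(βⱼ ≠ 0) = (Σₖ w_yk τ_jk + a) / (Σₖ w_yk + b)`,
   a = b = 0.5, which are converted back into per-feature selection costs
   for the next iteration. A drug too weakly associated with a marker to
   afford its selection cost alone can inherit a cheaper cost from a
   correlated drug that selects the marker reliably.

## Worked example

```python
import numpy as np
from cher import CherRegressor
from cher.synthetic import generate, score_retrieval

# synthetic panel: 60 cell lines, 100 features (20% mutation), 3 candidate
# splits, 20 phenotypes in 4 correlated groups, noise at half the signal sd
ds, truth = generate(n=60, p=100, K=20, groups=4, noise_sd=0.5, seed=1)

est = CherRegressor(B=25, n_iter=5, random_state=1).fit(ds.X, ds.Y, ds.Z)

k = 1
for s in est.result_.selected[k]:
    print(ds.feature_names[s.index], s.role, round(s.tau, 2))
print("split:", est.models_[k].split)

scores = score_retrieval(
    [set(s.index for s in sel) for sel in est.result_.selected], truth)
print("median precision/recall/F:", np.median(scores, axis=0))
```

prints

```
expr027 arm1 0.92
expr028 shared 1.0
expr068 shared 1.0
split: 2
median precision/recall/F: [1. 1. 1.]
```

Phenotype 1 was generated from shared effects of `expr028`/`expr068` plus
an effect of `expr027` confined to arm 1 of split 2; the fitted model
recovers all three features, their roles, and the true split (`tau` is the
fraction of bootstrap fits selecting the feature in the last iteration).
Across all 20 phenotypes the median feature-retrieval precision, recall
and F-measure are 1.0 at this noise level.

## Command line

```bash
cher simulate --out panel/ --seed 3                    # write a synthetic panel as TSV
cher fit --features F.tsv --feature-meta FM.tsv \
         --phenotypes P.tsv --pheno-meta PM.tsv \
         --splits S.tsv --out models/ --B 100 --iters 10 --tau 0.3 --seed 17
cher crossval ... --folds 10                           # out-of-fold Pearson/Spearman
```

`cher fit` applies the standard pre-modeling filters (mutation features
mutated in <10% of samples dropped, expression variance < 0.2 and
copy-number variance < 0.15 dropped, IC50 phenotypes with >80% invalid
entries excluded and the rest log-transformed), aligns the tables on
shared sample ids, runs the full loop and writes one JSON model per
phenotype plus a run log.

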