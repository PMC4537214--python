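"""Synthetic pharmacogenomic panels with planted ground truth.

The generator emulates the statistical structure of a pooled cell-line
panel: a mixed feature matrix (binary mutation calls plus block-correlated
continuous expression/copy-number values), a few candidate binary splits of
the samples (one of which may truly condition the genetics of response),
and groups of correlated drug-sensitivity phenotypes built from the
split-conditioned linear generative form

    y = X bS + 1[z = 1] X b1 + 1[z = 0] X b0 + noise.

Phenotypes within a group share true features and split, with coefficients
jittered so the group is correlated but not identical — the situation the
transfer step is designed to exploit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .l0 import Dataset

__all__ = [
    "SimTruth",
    "PhenotypeTruth",
    "generate",
    "transfer_scenario",
    "score_retrieval",
    "score_split",
]


@dataclass
class PhenotypeTruth:
    features: dict[int, tuple[str, float]]  # index -> (role, coefficient)
    split: int | None
    noise_sd: float
    group: int

    @property
    def feature_set(self) -> set[int]:
        return set(self.features)


@dataclass
class SimTruth:
    phenotypes: list[PhenotypeTruth]
    params: dict = field(default_factory=dict)


def generate(
    n: int = 60,
    p: int = 100,
    T: int = 3,
    K: int = 20,
    groups: int = 4,
    k_true: int = 3,
    frac_contextual: float = 1 / 3,
    noise_sd: float = 0.5,
    seed: int = 0,
    *,
    noise_relative: bool = True,
    mutation_frac: float = 0.2,
    block_size: int = 10,
    block_rho: float = 0.3,
    missing_frac: float = 0.0,
) -> tuple[Dataset, SimTruth]:
    """Simulate an aligned panel with planted predictors.

    Features: ``mutation_frac`` of the p columns are Bernoulli(q) mutation
    calls with q drawn uniformly in [0.1, 0.4]; the rest are standard
    normal with correlation ``block_rho`` inside consecutive blocks of
    ``block_size`` columns (co-expressed gene modules).  Splits: T balanced
    binary partitions of the samples.  Each phenotype group draws k_true
    distinct true features, of which round(k_true * frac_contextual) are
    contextual (arm-specific under the group's true split); coefficients
    are +-Uniform(0.5, 1.5), jittered by +-20% per phenotype within a
    group.  Gaussian noise is added with standard deviation ``noise_sd``
    times the phenotype's signal sd when ``noise_relative`` (the default,
    so noise_sd is a noise-to-signal ratio), else absolute.

    Returns the dataset and the ground truth needed for retrieval scoring.
    """
    if k_true > p:
        raise ValueError("k_true cannot exceed p")
    if groups > K:
        raise ValueError("cannot have more groups than phenotypes")
    if not 0 <= frac_contextual <= 1:
        raise ValueError("frac_contextual must be in [0, 1]")
    n_ctx = int(round(k_true * frac_contextual))
    if n_ctx > 0 and T == 0:
        raise ValueError("contextual true features require at least one candidate split")

    rng = np.random.default_rng(seed)
    p_mut = int(round(mutation_frac * p))
    p_cont = p - p_mut

    # mutation columns: guaranteed non-constant is not enforced; rare
    # all-zero columns are legal input (they are simply never selectable)
    q = rng.uniform(0.1, 0.4, size=p_mut)
    X_mut = (rng.random((n, p_mut)) < q).astype(float)

    cols = []
    done = 0
    while done < p_cont:
        b = min(block_size, p_cont - done)
        cov = np.full((b, b), block_rho)
        np.fill_diagonal(cov, 1.0)
        L = np.linalg.cholesky(cov)
        cols.append(rng.standard_normal((n, b)) @ L.T)
        done += b
    X_cont = np.concatenate(cols, axis=1) if cols else np.zeros((n, 0))
    X = np.concatenate([X_mut, X_cont], axis=1)
    binary_mask = np.zeros(p, dtype=bool)
    binary_mask[:p_mut] = True

    Z = np.zeros((n, T))
    for t in range(T):
        perm = rng.permutation(n)
        Z[perm[: n // 2], t] = 1.0

    # true effects act on the standardized feature scale so mutation and
    # expression features carry comparable signal per unit coefficient
    Xstd = (X - X.mean(axis=0)) / np.where(X.std(axis=0) == 0, 1.0, X.std(axis=0))

    group_of = np.arange(K) % groups
    group_feats, group_roles, group_coefs, group_split = {}, {}, {}, {}
    for g in range(groups):
        feats = rng.choice(p, size=k_true, replace=False)
        roles = ["shared"] * k_true
        split = None
        if n_ctx > 0:
            ctx_pos = rng.choice(k_true, size=n_ctx, replace=False)
            for pos in ctx_pos:
                roles[pos] = "arm1" if rng.random() < 0.5 else "arm0"
            split = int(rng.integers(T))
        coefs = rng.uniform(0.5, 1.5, size=k_true) * rng.choice([-1.0, 1.0], size=k_true)
        group_feats[g], group_roles[g], group_coefs[g], group_split[g] = feats, roles, coefs, split

    Y = np.zeros((n, K))
    truths = []
    for k in range(K):
        g = group_of[k]
        feats, roles, base, split = group_feats[g], group_roles[g], group_coefs[g], group_split[g]
        coefs = base * rng.uniform(0.8, 1.2, size=k_true)
        signal = np.zeros(n)
        fdict = {}
        for j, role, c in zip(feats, roles, coefs):
            x = Xstd[:, j]
            if role == "shared":
                signal += c * x
            elif role == "arm1":
                signal += c * x * Z[:, split]
            else:
                signal += c * x * (1.0 - Z[:, split])
            fdict[int(j)] = (role, float(c))
        sd_eff = noise_sd * signal.std() if noise_relative else noise_sd
        Y[:, k] = signal + rng.normal(0.0, sd_eff, size=n)
        truths.append(PhenotypeTruth(features=fdict, split=split, noise_sd=float(sd_eff), group=int(g)))

    if missing_frac > 0:
        Y[rng.random((n, K)) < missing_frac] = np.nan

    ds = Dataset(
        X=X,
        Y=Y,
        Z=Z,
        ids=[f"S{i:04d}" for i in range(n)],
        feature_names=[f"mut{j:03d}" if j < p_mut else f"expr{j - p_mut:03d}" for j in range(p)],
        phenotype_names=[f"drug{k:02d}_ACT" for k in range(K)],
        split_names=[f"split{t}" for t in range(T)],
        binary_mask=binary_mask,
    )
    params = dict(n=n, p=p, T=T, K=K, groups=groups, k_true=k_true,
                  frac_contextual=frac_contextual, noise_sd=noise_sd,
                  noise_relative=noise_relative, seed=seed)
    return ds, SimTruth(phenotypes=truths, params=params)


def transfer_scenario(
    seed: int = 0,
    n: int = 60,
    p: int = 60,
    beta_strong: float = 2.0,
    beta_weak: float = 0.3,
    noise_sd: float = 1.0,
) -> tuple[Dataset, int]:
    """Two correlated phenotypes driven by one feature, strong in the first
    and too weak in the second to pay the uniform selection cost on its own.

    The weak phenotype can only acquire the feature through the prior
    lowered by its correlated, strongly-driven neighbour — the scenario in
    which transfer between drugs with similar response profiles pays off.
    Returns the dataset and the index of the shared true feature.
    """
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    g = 0
    y_strong = beta_strong * X[:, g] + rng.normal(0, noise_sd, n)
    y_weak = beta_weak * X[:, g] + rng.normal(0, noise_sd, n)
    Z = np.zeros((n, 1))
    Z[rng.permutation(n)[: n // 2], 0] = 1.0
    ds = Dataset(
        X=X,
        Y=np.column_stack([y_strong, y_weak]),
        Z=Z,
        ids=[f"S{i:04d}" for i in range(n)],
        phenotype_names=["drug_strong", "drug_weak"],
        binary_mask=np.zeros(p, dtype=bool),
    )
    return ds, g


def score_retrieval(selected: list[set[int]] | list[dict], truth: SimTruth):
    """Precision / recall / F-measure of planted-feature retrieval.

    ``selected`` holds one feature-index collection per phenotype.
    Precision is 0 for an empty selection; F is the harmonic mean of
    precision and recall, 0 when both vanish.  Returns an array of shape
    (K, 3) with columns (precision, recall, F).
    """
    out = np.zeros((len(truth.phenotypes), 3))
    for k, tr in enumerate(truth.phenotypes):
        sel = set(selected[k])
        true = tr.feature_set
        hit = len(sel & true)
        prec = hit / len(sel) if sel else 0.0
        rec = hit / len(true) if true else 1.0
        f = 2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0
        out[k] = (prec, rec, f)
    return out


def score_split(finalized_splits: list[int | None], truth: SimTruth) -> float:
    """Fraction of phenotypes whose finalized split matches the truth.

    A phenotype generated without a split counts as correct exactly when no
    split was finalized for it.
    """
    correct = sum(
        1 for s, tr in zip(finalized_splits, truth.phenotypes) if s == tr.split
    )
    return correct / len(truth.phenotypes)
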