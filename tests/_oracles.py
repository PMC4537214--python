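"""Independent brute-force oracles used by the test suite.

The exhaustive description-length search enumerates every model in the
class (feature subsets up to a size cap, all shared/arm role assignments,
every candidate split) and scores each by ordinary least squares plus the
same bit-cost definitions the package documents.  It shares no code with
the greedy search path.
"""

from __future__ import annotations

import itertools

import numpy as np

RSS_EPS = 1e-12


def _dl(y, cols, n, pen):
    A = np.column_stack(cols)
    m = A.shape[1]
    if m > n - 1:
        return None
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    rss = max(float(resid @ resid), RSS_EPS * n)
    return 0.5 * n * np.log2(rss / (n - m)) + pen


def exhaustive_dl_search(X, y, Z, feature_cost, split_cost, *, max_k=3,
                         min_arm_size=5, coef_bits=2.0, standardize=True):
    """Minimum description length over all models with <= max_k features.

    Returns (best_dl, structure) where structure is
    (split, frozenset shared, frozenset arm1, frozenset arm0).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    Z = np.zeros((n, 0)) if Z is None else np.asarray(Z, dtype=float)
    T = Z.shape[1]
    if standardize:
        sd = X.std(axis=0)
        binary = np.array([set(np.unique(c)) <= {0.0, 1.0} for c in X.T])
        mean = np.where(binary, 0.0, X.mean(axis=0))
        sd = np.where(binary | (sd == 0), 1.0, sd)
        X = (X - mean) / sd

    ones = np.ones(n)
    best = (np.inf, (None, frozenset(), frozenset(), frozenset()))

    def consider(dl, structure):
        nonlocal best
        if dl is not None and dl < best[0]:
            best = (dl, structure)

    # split-free models, all features shared
    for k in range(max_k + 1):
        for S in itertools.combinations(range(p), k):
            pen = sum(feature_cost[j] for j in S)
            dl = _dl(y, [ones] + [X[:, j] for j in S], n, pen)
            consider(dl, (None, frozenset(S), frozenset(), frozenset()))

    # split models: every role assignment with at least one contextual
    # feature; the arm-1 intercept offset is part of the design and pays
    # coef_bits on top of the split cost
    for t in range(T):
        z = Z[:, t]
        n1 = int((z == 1).sum())
        if n1 < min_arm_size or n - n1 < min_arm_size:
            continue
        for k in range(1, max_k + 1):
            for S in itertools.combinations(range(p), k):
                for roles in itertools.product((0, 1, 2), repeat=k):
                    if all(r == 0 for r in roles):
                        continue
                    cols = [ones]
                    shared, arm1, arm0 = [], [], []
                    for j, r in zip(S, roles):
                        (shared, arm1, arm0)[r].append(j)
                    cols += [X[:, j] for j in shared]
                    cols.append(z)
                    cols += [X[:, j] * z for j in arm1]
                    cols += [X[:, j] * (1 - z) for j in arm0]
                    pen = (sum(feature_cost[j] for j in S)
                           + split_cost[t] + coef_bits)
                    dl = _dl(y, cols, n, pen)
                    consider(dl, (t, frozenset(shared), frozenset(arm1),
                                  frozenset(arm0)))
    return best


def random_strong_instance(rng, n=50, p=8, T=2, max_true=3, coef=5.0, noise_sd=1.0):
    """A random regression instance with planted strong predictors.

    Each true coefficient has magnitude ``coef`` times the noise standard
    deviation; roughly one instance in three carries a contextual effect.
    Returns (X, y, Z, truth) with truth = (split, shared, arm1, arm0).
    """
    X = rng.standard_normal((n, p))
    Z = np.zeros((n, T))
    for t in range(T):
        Z[rng.permutation(n)[: n // 2], t] = 1.0
    k = int(rng.integers(1, max_true + 1))
    feats = rng.choice(p, size=k, replace=False)
    contextual = rng.random() < 1 / 3
    split = int(rng.integers(T)) if contextual else None
    shared, arm1, arm0 = [], [], []
    y = rng.normal(0.0, noise_sd, n)
    for i, j in enumerate(feats):
        b = coef * noise_sd * rng.choice([-1.0, 1.0])
        if contextual and i == 0:
            arm = int(rng.integers(2))
            mask = Z[:, split] if arm == 1 else 1 - Z[:, split]
            y += b * X[:, j] * mask
            (arm1 if arm == 1 else arm0).append(int(j))
        else:
            y += b * X[:, j]
            shared.append(int(j))
    truth = (split, frozenset(shared), frozenset(arm1), frozenset(arm0))
    return X, y, Z, truth
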