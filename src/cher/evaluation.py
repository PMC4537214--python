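"""Ten-fold cross-validation harness and evaluation metrics.

The entire learning procedure — shared bootstraps, iterative transfer,
stability-thresholded finalization — runs inside each training fold, so the
held-out correlations measure the full pipeline, not just the final OLS
refit.  When a fold yields an intercept-only model its held-out prediction
is the training mean of that phenotype, which is what the intercept-only
OLS fit returns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import stats

from .driver import CherConfig, run_cher
from .l0 import CherModel, Dataset, predict

__all__ = ["CVResult", "cross_validate", "correlation_metrics", "adjusted_r2"]


class CorrelationMetrics(NamedTuple):
    pearson: float
    spearman: float
    constant_prediction: bool


def correlation_metrics(pred, obs) -> CorrelationMetrics:
    """Pearson and Spearman correlation between predictions and truth.

    NaN pairs are dropped; fewer than 3 remaining pairs is an error.  A
    constant prediction vector has no defined correlation and is reported
    as (0, 0) with the flag set — the score a pure mean-fallback must get
    to be comparable with informative models.
    """
    pred = np.asarray(pred, dtype=float).ravel()
    obs = np.asarray(obs, dtype=float).ravel()
    if pred.shape != obs.shape:
        raise ValueError("pred and obs must have equal length")
    ok = ~(np.isnan(pred) | np.isnan(obs))
    pred, obs = pred[ok], obs[ok]
    if pred.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(pred) == 0 or np.ptp(obs) == 0:
        return CorrelationMetrics(0.0, 0.0, True)
    r_p = stats.pearsonr(pred, obs).statistic
    r_s = stats.spearmanr(pred, obs).statistic
    return CorrelationMetrics(float(r_p), float(r_s), False)


@dataclass
class CVResult:
    predictions: np.ndarray          # (n, K), NaN where phenotype unobserved
    fold_assignment: np.ndarray      # (n,) fold index per sample
    pearson: np.ndarray              # (K,)
    spearman: np.ndarray             # (K,)
    constant_flag: np.ndarray        # (K,) bool
    fold_features: list[list[list[int]]]  # [fold][phenotype] -> selected indices


def cross_validate(ds: Dataset, cfg: CherConfig, folds: int = 10,
                   seed: int | None = None) -> CVResult:
    """Out-of-fold predictions for every phenotype under a shared partition.

    The sample partition is drawn once from ``seed`` (defaulting to the
    config seed) and shared across phenotypes; a held-out sample receives a
    prediction for a phenotype only if that phenotype is observed for it.
    """
    n, K = ds.n, ds.K
    if n < folds:
        raise ValueError("need at least as many samples as folds")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    fold_of = np.zeros(n, dtype=int)
    fold_of[rng.permutation(n)] = np.arange(n) % folds

    preds = np.full((n, K), np.nan)
    fold_features: list[list[list[int]]] = []
    for f in range(folds):
        test = fold_of == f
        train = ~test
        sub = Dataset(
            X=ds.X[train],
            Y=ds.Y[train],
            Z=ds.Z[train],
            ids=[i for i, t in zip(ds.ids, train) if t],
            feature_names=ds.feature_names,
            phenotype_names=ds.phenotype_names,
            split_names=ds.split_names,
            binary_mask=ds.binary_mask,
        )
        res = run_cher(sub, cfg)
        fold_features.append([[s.index for s in sel] for sel in res.selected])
        for k in range(K):
            yhat = predict(res.models[k], ds.X[test], ds.Z[test] if ds.T else None)
            obs_test = ~np.isnan(ds.Y[test, k])
            idx = np.flatnonzero(test)[obs_test]
            preds[idx, k] = yhat[obs_test]

    pear = np.zeros(K)
    spear = np.zeros(K)
    const = np.zeros(K, dtype=bool)
    for k in range(K):
        obs = ~np.isnan(ds.Y[:, k])
        m = correlation_metrics(preds[obs, k], ds.Y[obs, k])
        pear[k], spear[k], const[k] = m

    return CVResult(
        predictions=preds,
        fold_assignment=fold_of,
        pearson=pear,
        spearman=spear,
        constant_flag=const,
        fold_features=fold_features,
    )


def adjusted_r2(model: CherModel, X, y, Z=None) -> float:
    """Variance explained by the selected features, penalized for their count.

    adj R^2 = 1 - (1 - R^2)(n - 1)/(n - q - 1) with q the number of fitted
    coefficients excluding the global intercept (the arm intercept offset
    counts).  Returns NaN when n - q - 1 <= 0.
    """
    y = np.asarray(y, dtype=float).ravel()
    obs = ~np.isnan(y)
    y = y[obs]
    X = np.asarray(X, dtype=float)[obs]
    if Z is not None:
        Z = np.asarray(Z, dtype=float)[obs]
    n = y.size
    q = model.n_coefficients
    if n - q - 1 <= 0:
        return float("nan")
    yhat = predict(model, X, Z)
    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0:
        return float("nan")
    rss = float(((y - yhat) ** 2).sum())
    r2 = 1.0 - rss / tss
    return 1.0 - (1.0 - r2) * (n - 1) / (n - q - 1)
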