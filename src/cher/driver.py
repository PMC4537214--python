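"""Orchestration of the full learning loop.

One run proceeds as: draw B bootstrap resamples of the samples once (shared
across phenotypes and iterations); in each iteration fit the greedy MDL
model to every resample of every phenotype under the current per-phenotype
cost model (uniform coding in iteration 1); summarize selection frequencies
tau; convert them through the similarity-weighted prior update into the
next iteration's costs.  After the last iteration, features with final
tau >= tau_threshold are kept (role = majority role over the final
iteration's runs), the most frequently committed split is kept if its
frequency passes split_threshold, and coefficients are refit by OLS on the
full phenotype-complete sample set.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .l0 import CherModel, CostModel, Dataset, greedy_fit, predict, refit_model, uniform_costs
from .transfer import BootstrapSummary, PriorState, phenotype_similarity, priors_to_costs, update_priors

__all__ = [
    "CherConfig",
    "CherResult",
    "make_bootstrap_indices",
    "run_iteration",
    "run_cher",
    "CherRegressor",
]

log = logging.getLogger(__name__)

ROLES = ("shared", "arm1", "arm0")


@dataclass
class CherConfig:
    """Tunable parameters of the learning loop.

    Defaults: 100 bootstrap runs, 10
    iterations, final selection at tau >= 0.3 with non-informative
    hyper-parameters a = b = 0.5.  Similarity weights use a sigmoid in the
    phenotype correlation centred at r = 0.5 so only substantially
    correlated phenotypes exchange priors.
    """

    B: int = 100
    n_iter: int = 10
    tau_threshold: float = 0.3
    split_threshold: float | None = None  # defaults to tau_threshold
    seed: int = 0
    sigmoid_scale: float = 8.0
    sigmoid_center: float = 0.5
    anchored_costs: bool = True
    a: float = 0.5
    b: float = 0.5
    dl_scale: float = 1.0
    eq4_denominator: str = "as_printed"
    include_self: bool = False
    min_arm_size: int = 5
    min_boot_samples: int = 10
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if not (0 < self.tau_threshold <= 1):
            raise ValueError("tau_threshold must be in (0, 1]")
        if self.split_threshold is None:
            self.split_threshold = self.tau_threshold


@dataclass
class SelectedFeature:
    index: int
    role: str
    tau: float
    name: str | None = None


@dataclass
class CherResult:
    """Everything a run produced: final models plus per-iteration state."""

    models: list[CherModel]
    summaries: list[BootstrapSummary]      # one per iteration
    priors: list[PriorState]               # one per iteration after the first
    selected: list[list[SelectedFeature]]  # per phenotype
    W: np.ndarray | None
    config: CherConfig
    phenotype_names: list[str] | None = None
    feature_names: list[str] | None = None
    split_names: list[str] | None = None

    @property
    def final_tau(self) -> np.ndarray:
        return self.summaries[-1].tau

    def model_dict(self, k: int) -> dict:
        """JSON-ready description of phenotype k's final model."""
        m = self.models[k]
        fname = (lambda j: self.feature_names[j]) if self.feature_names else str
        sel = self.selected[k]
        return {
            "phenotype": self.phenotype_names[k] if self.phenotype_names else str(k),
            "split": (self.split_names[m.split] if self.split_names and m.split is not None
                      else m.split),
            "shared": {fname(j): b for j, b in m.beta_shared.items()},
            "arm1": {fname(j): b for j, b in m.beta_arm1.items()},
            "arm0": {fname(j): b for j, b in m.beta_arm0.items()},
            "intercept": m.intercept,
            "intercept_arm_offset": m.intercept_arm_offset,
            "tau": {fname(s.index): s.tau for s in sel},
            "iterations": len(self.summaries),
            "config": asdict(self.config),
        }


def make_bootstrap_indices(n: int, B: int, seed: int) -> list[np.ndarray]:
    """B index vectors of length n drawn with replacement, reproducibly.

    Generated once per run and reused for every phenotype and iteration so
    that all phenotypes see the same resampled cell lines.
    """
    if n < 2:
        raise ValueError("need at least two samples to bootstrap")
    rng = np.random.default_rng(seed)
    return [rng.integers(0, n, size=n) for _ in range(B)]


def run_iteration(
    ds: Dataset,
    costs: list[CostModel],
    indices: list[np.ndarray],
    cfg: CherConfig,
) -> BootstrapSummary:
    """Fit every bootstrap replicate of every phenotype; tally selections.

    Samples missing the phenotype are dropped from each replicate;
    replicates left with fewer than ``cfg.min_boot_samples`` usable samples
    are skipped (B reduced for that phenotype).
    """
    n, p, K, T = ds.n, ds.p, ds.K, ds.T
    counts = {role: np.zeros((p, K)) for role in ROLES}
    any_counts = np.zeros((p, K))
    split_counts = np.zeros((T, K))
    B_eff = np.zeros(K, dtype=int)

    for k in range(K):
        obs = ~np.isnan(ds.Y[:, k])
        for idx in indices:
            sub = idx[obs[idx]]
            if sub.size < cfg.min_boot_samples:
                log.debug("phenotype %d: bootstrap replicate skipped (%d samples)", k, sub.size)
                continue
            B_eff[k] += 1
            # fit the resample through its distinct rows + multiplicities:
            # the coefficient fit is identical, the residual code is honest
            uniq, mult = np.unique(sub, return_counts=True)
            model = greedy_fit(
                ds.X[uniq],
                ds.Y[uniq, k],
                ds.Z[uniq] if T else None,
                costs[k],
                binary_mask=ds.binary_mask,
                standardize=cfg.standardize,
                min_arm_size=cfg.min_arm_size,
                dl_scale=cfg.dl_scale,
                sample_weight=mult,
            )
            for j, role in model.selected_features().items():
                counts[role][j, k] += 1
                any_counts[j, k] += 1
            if model.split is not None:
                split_counts[model.split, k] += 1

    denom = np.maximum(B_eff, 1).astype(float)
    return BootstrapSummary(
        tau=any_counts / denom,
        freq_shared=counts["shared"] / denom,
        freq_arm1=counts["arm1"] / denom,
        freq_arm0=counts["arm0"] / denom,
        split_freq=split_counts / denom,
        B=len(indices),
        B_eff=B_eff,
    )


def _finalize_phenotype(ds: Dataset, k: int, summary: BootstrapSummary,
                        costs: CostModel, cfg: CherConfig):
    """Stability-thresholded model assembly for one phenotype."""
    tau_k = summary.tau[:, k]
    keep = np.flatnonzero(tau_k >= cfg.tau_threshold)

    split = None
    if ds.T > 0:
        sf = summary.split_freq[:, k]
        t_star = int(np.argmax(sf))  # ties -> lowest index
        if sf[t_star] >= cfg.split_threshold:
            split = t_star

    shared, arm1, arm0 = [], [], []
    selected = []
    for j in keep:
        freqs = (summary.freq_shared[j, k], summary.freq_arm1[j, k], summary.freq_arm0[j, k])
        role = ROLES[int(np.argmax(freqs))]  # argmax ties -> shared (first)
        if split is None and role != "shared":
            role = "shared"  # contextual role without a surviving split
        {"shared": shared, "arm1": arm1, "arm0": arm0}[role].append(int(j))
        selected.append(SelectedFeature(index=int(j), role=role, tau=float(tau_k[j])))

    obs = ~np.isnan(ds.Y[:, k])
    model = refit_model(
        ds.X[obs],
        ds.Y[obs, k],
        ds.Z[obs] if ds.T else None,
        shared,
        arm1,
        arm0,
        split,
        costs,
        binary_mask=ds.binary_mask,
        standardize=cfg.standardize,
        dl_scale=cfg.dl_scale,
    )
    return model, selected


def run_cher(ds: Dataset, cfg: CherConfig, checkpoint_dir: str | Path | None = None) -> CherResult:
    """The full iterative loop on an aligned dataset.

    Iteration 1 uses uniform coding (every feature log2(p)+2 bits, every
    split log2(T) bits); each subsequent iteration prices features by the
    similarity-pooled priors of the previous iteration's selection
    frequencies.  With a single phenotype, or ``n_iter=1``, no transfer
    occurs and the run reduces to plain bootstrapped L0 selection.
    """
    K, p, T = ds.K, ds.p, ds.T
    indices = make_bootstrap_indices(ds.n, cfg.B, cfg.seed)
    costs = [uniform_costs(p, T) for _ in range(K)]
    W = (phenotype_similarity(ds.Y, cfg.sigmoid_scale, cfg.sigmoid_center)
         if K >= 2 else None)

    summaries: list[BootstrapSummary] = []
    priors: list[PriorState] = []
    for it in range(cfg.n_iter):
        summary = run_iteration(ds, costs, indices, cfg)
        summaries.append(summary)
        if it + 1 < cfg.n_iter and W is not None:
            ps = update_priors(
                summary, W, cfg.a, cfg.b,
                include_self=cfg.include_self,
                denominator=cfg.eq4_denominator,
                sigmoid_scale=cfg.sigmoid_scale,
            )
            priors.append(ps)
            costs = [priors_to_costs(ps, p, T, k, anchored=cfg.anchored_costs)
                     for k in range(K)]
        if checkpoint_dir is not None:
            _checkpoint(checkpoint_dir, it, summary)

    models, selected = [], []
    for k in range(K):
        m, sel = _finalize_phenotype(ds, k, summaries[-1], costs[k], cfg)
        if ds.feature_names:
            for s in sel:
                s.name = ds.feature_names[s.index]
        models.append(m)
        selected.append(sel)

    return CherResult(
        models=models,
        summaries=summaries,
        priors=priors,
        selected=selected,
        W=W,
        config=cfg,
        phenotype_names=ds.phenotype_names,
        feature_names=ds.feature_names,
        split_names=ds.split_names,
    )


def _checkpoint(directory, iteration, summary):
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    state = {
        "iteration": iteration,
        "tau": summary.tau.tolist(),
        "split_freq": summary.split_freq.tolist(),
        "B_eff": summary.B_eff.tolist(),
    }
    (directory / f"iteration_{iteration:02d}.json").write_text(json.dumps(state))


class CherRegressor(RegressorMixin, BaseEstimator):
    """Multi-phenotype contextual sparse regression with stability selection
    and transfer.

    Fits one sparse split-conditioned linear model per phenotype column of
    ``Y``, using bootstrap stability selection and iterative sharing of
    feature-selection priors between correlated phenotypes.

    Parameters
    ----------
    B : int
        Bootstrap resamples per iteration (default 100).
    n_iter : int
        Learning iterations (default 10); 1 disables transfer.
    tau_threshold : float
        Minimum final-iteration selection frequency for a feature to enter
        the final model (default 0.3).
    split_threshold : float or None
        Minimum commitment frequency for a split; None reuses
        ``tau_threshold``.
    random_state : int
        Seed for the shared bootstrap resamples.

    Attributes
    ----------
    result_ : CherResult
    models_ : list of CherModel, one per phenotype
    tau_ : (p, K) final-iteration selection frequencies

    Examples
    --------
    >>> from cher.synthetic import generate
    >>> ds, truth = generate(seed=0)
    >>> est = CherRegressor(B=25, n_iter=3, random_state=0).fit(ds.X, ds.Y, ds.Z)
    >>> preds = est.predict(ds.X, ds.Z)
    """

    def __init__(
        self,
        B: int = 100,
        n_iter: int = 10,
        tau_threshold: float = 0.3,
        split_threshold: float | None = None,
        sigmoid_scale: float = 8.0,
        sigmoid_center: float = 0.5,
        anchored_costs: bool = True,
        a: float = 0.5,
        b: float = 0.5,
        dl_scale: float = 1.0,
        eq4_denominator: str = "as_printed",
        include_self: bool = False,
        min_arm_size: int = 5,
        min_boot_samples: int = 10,
        standardize: bool = True,
        random_state: int = 0,
    ):
        self.B = B
        self.n_iter = n_iter
        self.tau_threshold = tau_threshold
        self.split_threshold = split_threshold
        self.sigmoid_scale = sigmoid_scale
        self.sigmoid_center = sigmoid_center
        self.anchored_costs = anchored_costs
        self.a = a
        self.b = b
        self.dl_scale = dl_scale
        self.eq4_denominator = eq4_denominator
        self.include_self = include_self
        self.min_arm_size = min_arm_size
        self.min_boot_samples = min_boot_samples
        self.standardize = standardize
        self.random_state = random_state

    def _config(self) -> CherConfig:
        return CherConfig(
            B=self.B,
            n_iter=self.n_iter,
            tau_threshold=self.tau_threshold,
            split_threshold=self.split_threshold,
            seed=self.random_state,
            sigmoid_scale=self.sigmoid_scale,
            sigmoid_center=self.sigmoid_center,
            anchored_costs=self.anchored_costs,
            a=self.a,
            b=self.b,
            dl_scale=self.dl_scale,
            eq4_denominator=self.eq4_denominator,
            include_self=self.include_self,
            min_arm_size=self.min_arm_size,
            min_boot_samples=self.min_boot_samples,
            standardize=self.standardize,
        )

    def fit(self, X, Y, Z=None):
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        n = X.shape[0]
        Z = np.zeros((n, 0)) if Z is None else np.asarray(Z, dtype=float)
        ds = Dataset(X=X, Y=Y, Z=Z, ids=[str(i) for i in range(n)])
        self.result_ = run_cher(ds, self._config())
        self.models_ = self.result_.models
        self.tau_ = self.result_.final_tau
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X, Z=None):
        check_is_fitted(self, "result_")
        cols = [predict(m, X, Z) for m in self.models_]
        out = np.column_stack(cols)
        return out[:, 0] if out.shape[1] == 1 else out
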