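"""L0-penalized greedy regression with an optional sample split.

The model class is a linear regression in which each selected predictor is
either *shared* (one coefficient for all samples) or *contextual* (a
coefficient active only in one arm of a binary split of the samples).  Model
search minimizes a two-part description length:

    DL(model) = data_bits(RSS, n) + sum of selection costs (bits)

where ``data_bits`` is the Gaussian code length of the residuals and each
selected coefficient pays a cost in bits (``log2(p) + 2`` under uniform
coding: ``log2(p)`` to name the feature, 2 to encode its coefficient).
Committing a split costs ``log2(T)`` bits, paid once per model; at most one
split may be committed.  Search is pure forward-stepwise: the move (add a
feature as shared, or as arm-specific, possibly committing a split) with the
largest description-length reduction is taken until no move pays for itself.
Coefficients are refit by ordinary least squares after every accepted move
and are never shrunk.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "CostModel",
    "CherModel",
    "Dataset",
    "data_bits",
    "uniform_costs",
    "greedy_fit",
    "refit_model",
    "predict",
    "L0ContextRegressor",
]

#: residual sum of squares is floored at RSS_EPS * n before taking logs
RSS_EPS = 1e-12
#: ties in description length within this many bits are broken deterministically
TIE_TOL = 1e-9
#: relative squared-norm threshold below which a candidate column is
#: considered collinear with the active design and its move disallowed
COLLINEAR_TOL = 1e-8


def data_bits(rss: float | np.ndarray, n: int, df: int | None = None) -> float | np.ndarray:
    """Gaussian code length of residuals, in bits, up to model-free constants.

    Parameters
    ----------
    rss : float or ndarray
        Residual sum of squares, >= 0.  Floored at ``RSS_EPS * n`` so a
        perfect fit yields a finite (large, negative) code length rather
        than minus infinity.
    n : int
        Number of samples coded, >= 1.
    df : int, optional
        Residual degrees of freedom used to estimate the noise variance
        (``n`` minus the number of fitted coefficients).  Defaults to ``n``.
        The model search passes the honest df so that a parameter absorbing
        only its expected share of noise buys no code-length reduction —
        without this correction forward selection under low selection costs
        runs away, since every added parameter makes further *relative* RSS
        reductions cheaper.

    Returns
    -------
    bits : float or ndarray
        ``(n / 2) * log2(rss / df)``.  Halving the RSS at fixed n and df
        reduces the code length by exactly ``n/2`` bits.
    """
    if n < 1:
        raise ValueError("data_bits requires n >= 1")
    if df is None:
        df = n
    if df < 1:
        raise ValueError("data_bits requires df >= 1")
    rss = np.maximum(np.asarray(rss, dtype=float), RSS_EPS * n)
    out = 0.5 * n * np.log2(rss / df)
    return float(out) if out.ndim == 0 else out


@dataclass
class CostModel:
    """Per-feature and per-split selection costs in bits.

    ``feature_cost[j]`` is the full price of selecting feature ``j`` in any
    role, *inclusive* of the ``coef_bits`` needed to encode its coefficient.
    ``split_cost[t]`` is the one-time price of committing split ``t``.
    """

    feature_cost: np.ndarray
    split_cost: np.ndarray
    coef_bits: float = 2.0

    def __post_init__(self) -> None:
        self.feature_cost = np.asarray(self.feature_cost, dtype=float)
        self.split_cost = np.asarray(self.split_cost, dtype=float)
        if self.feature_cost.ndim != 1 or self.split_cost.ndim != 1:
            raise ValueError("costs must be 1-D arrays")
        if not (np.all(np.isfinite(self.feature_cost)) and np.all(self.feature_cost >= 0)):
            raise ValueError("feature costs must be finite and >= 0")
        if not (np.all(np.isfinite(self.split_cost)) and np.all(self.split_cost >= 0)):
            raise ValueError("split costs must be finite and >= 0")

    @property
    def p(self) -> int:
        return self.feature_cost.shape[0]

    @property
    def T(self) -> int:
        return self.split_cost.shape[0]


def uniform_costs(p: int, T: int) -> CostModel:
    """Uniform-coding costs: ``log2(p) + 2`` bits per feature, ``log2(T)`` per split.

    With a single candidate split (T = 1) naming it is free; with no splits
    (T = 0) the split-cost vector is empty and contextual moves are
    impossible.
    """
    if p < 1:
        raise ValueError("uniform_costs requires p >= 1")
    if T < 0:
        raise ValueError("T must be >= 0")
    return CostModel(
        feature_cost=np.full(p, np.log2(p) + 2.0),
        split_cost=np.full(T, np.log2(T) if T > 0 else 0.0)[:T],
    )


@dataclass
class CherModel:
    """A fitted sparse split-conditioned linear model.

    A feature holds at most one role: shared, arm-1-specific (active where
    the committed split indicator is 1) or arm-0-specific.  When a split is
    committed the model carries an arm-1 intercept offset, priced into the
    split cost, so that mean differences between the two contexts are not
    absorbed by contextual feature coefficients.
    """

    split: int | None
    beta_shared: dict[int, float]
    beta_arm1: dict[int, float]
    beta_arm0: dict[int, float]
    intercept: float
    intercept_arm_offset: float
    dl_total: float
    rss: float
    n_used: int
    scale_mean: np.ndarray | None = None
    scale_sd: np.ndarray | None = None
    dl_path: list[float] = field(default_factory=list)

    @property
    def n_coefficients(self) -> int:
        """Fitted coefficients excluding the global intercept."""
        q = len(self.beta_shared) + len(self.beta_arm1) + len(self.beta_arm0)
        if self.split is not None:
            q += 1  # arm intercept offset
        return q

    def selected_features(self) -> dict[int, str]:
        """Map feature index -> role for every selected feature."""
        out = {j: "shared" for j in self.beta_shared}
        out.update({j: "arm1" for j in self.beta_arm1})
        out.update({j: "arm0" for j in self.beta_arm0})
        return out


@dataclass
class Dataset:
    """Aligned feature / phenotype / split matrices for one sample pool."""

    X: np.ndarray  # (n, p)
    Y: np.ndarray  # (n, K), NaN = missing
    Z: np.ndarray  # (n, T) binary split indicators
    ids: list[str]
    feature_names: list[str] | None = None
    phenotype_names: list[str] | None = None
    split_names: list[str] | None = None
    binary_mask: np.ndarray | None = None  # (p,) True for 0/1-valued features

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        if self.Y.ndim == 1:
            self.Y = self.Y[:, None]
        self.Z = np.asarray(self.Z, dtype=float)
        if self.Z.ndim == 1:
            self.Z = self.Z[:, None]
        n = self.X.shape[0]
        if self.Y.shape[0] != n or self.Z.shape[0] != n or len(self.ids) != n:
            raise ValueError("X, Y, Z and ids must agree on the number of samples")
        if self.binary_mask is None:
            self.binary_mask = detect_binary_columns(self.X)
        else:
            self.binary_mask = np.asarray(self.binary_mask, dtype=bool)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def K(self) -> int:
        return self.Y.shape[1]

    @property
    def T(self) -> int:
        return self.Z.shape[1]


def detect_binary_columns(X: np.ndarray) -> np.ndarray:
    """True for columns whose values all lie in {0, 1} (e.g. mutation calls)."""
    X = np.asarray(X, dtype=float)
    return np.array([np.all((col == 0) | (col == 1)) for col in X.T], dtype=bool)


def _weighted_standardize(X, binary_mask, w):
    """Z-score continuous columns over the fitting set (weights =
    multiplicities); binary columns stay 0/1.  Zero-variance continuous
    columns become identically zero and are later rejected by the
    collinearity guard."""
    wn = w / w.sum()
    mean = wn @ X
    var = wn @ (X - mean) ** 2
    sd = np.sqrt(var)
    mean = np.where(binary_mask, 0.0, mean)
    sd = np.where(binary_mask | (sd == 0), 1.0, sd)
    return (X - mean) / sd, mean, sd


def _build_design(Xs, z, shared, arm1, arm0, split, ones=None):
    """Active OLS design: [1 | shared | z-offset | arm1*z | arm0*(1-z)].

    ``ones`` substitutes the intercept column (sqrt-weights under weighted
    fitting, in which case Xs and z are already weight-scaled).
    """
    n = Xs.shape[0]
    cols = [np.ones(n) if ones is None else ones]
    cols += [Xs[:, j] for j in shared]
    if split is not None:
        cols.append(z)
        cols += [Xs[:, j] * z for j in arm1]
        cols += [Xs[:, j] * (1.0 - z) for j in arm0]
    return np.column_stack(cols)


def _ols(A, y):
    beta, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    return beta, float(resid @ resid)


def _batch_gains(Q, r, C):
    """RSS reduction from adding each column of C to a design with basis Q.

    For a single added column c the refit RSS drops by (c_perp . r)^2 /
    ||c_perp||^2 where c_perp is c orthogonalized against the active design.
    Columns (near-)collinear with the design get gain -inf (move disallowed).
    """
    Cp = C - Q @ (Q.T @ C)
    n2 = np.einsum("ij,ij->j", Cp, Cp)
    orig = np.einsum("ij,ij->j", C, C)
    ok = n2 > COLLINEAR_TOL * np.maximum(orig, 1e-300)
    num = Cp.T @ r
    with np.errstate(divide="ignore", invalid="ignore"):
        gains = np.where(ok, num**2 / np.where(ok, n2, 1.0), -np.inf)
    return gains


def greedy_fit(
    X: np.ndarray,
    y: np.ndarray,
    Z: np.ndarray | None = None,
    costs: CostModel | None = None,
    *,
    binary_mask: np.ndarray | None = None,
    standardize: bool = True,
    min_arm_size: int = 5,
    dl_scale: float = 1.0,
    sample_weight: np.ndarray | None = None,
) -> CherModel:
    """Forward-stepwise MDL search for a split-conditioned sparse model.

    Candidate moves at each step: add an unused feature as shared; or add it
    as arm-specific under a split, committing that split (and paying its
    cost plus an arm intercept offset) if none is committed yet.  The move
    minimizing total description length is accepted; search stops when no
    move strictly decreases it.  Ties within ``TIE_TOL`` bits prefer shared
    over contextual, then the lowest feature index, then the lowest split
    index, then arm 1 over arm 0.

    Parameters
    ----------
    X : (n, p) array
        Feature matrix, no missing values.
    y : (n,) array
        Phenotype, no missing values (the caller drops missing samples).
    Z : (n, T) array or None
        Candidate binary splits; None disables contextual moves.
    costs : CostModel, optional
        Selection costs; defaults to uniform coding for this p and T.
    binary_mask : (p,) bool array, optional
        Marks 0/1 features exempt from standardization; auto-detected when
        omitted.
    standardize : bool
        Z-score continuous columns within the fitting set (coefficients are
        reported on that scale).
    min_arm_size : int
        A contextual move is disallowed when its target arm has fewer
        fitting samples than this.
    dl_scale : float
        Multiplier on the selection-cost side of the description length.
    sample_weight : (n,) array, optional
        Observation multiplicities (e.g. bootstrap counts over the distinct
        samples).  Coefficients minimize the weighted squared error — for
        integer multiplicities exactly the OLS fit on the expanded
        resample — while residuals are coded once per distinct row, so a
        resample never counts the same observation's noise twice.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.shape[0] != n:
        raise ValueError("X and y disagree on n")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("greedy_fit does not accept missing values")
    Z = np.zeros((n, 0)) if Z is None else np.asarray(Z, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    T = Z.shape[1]
    if costs is None:
        costs = uniform_costs(p, T)
    if costs.p != p or costs.T != T:
        raise ValueError("cost model does not match X / Z dimensions")

    if binary_mask is None:
        binary_mask = detect_binary_columns(X)
    if sample_weight is None:
        w = np.ones(n)
    else:
        w = np.asarray(sample_weight, dtype=float)
        if w.shape != (n,) or np.any(w <= 0):
            raise ValueError("sample_weight must be positive with one entry per row")
    if standardize:
        Xs, mu, sd = _weighted_standardize(X, binary_mask, w)
    else:
        Xs, mu, sd = X, np.zeros(p), np.ones(p)

    # scale rows by sqrt of normalized weights: least squares in this space
    # is the multiplicity-weighted fit, and its RSS codes each row once
    sw = np.sqrt(w * (n / w.sum()))
    Xw = Xs * sw[:, None]
    yw = y * sw
    Zw = Z * sw[:, None]

    shared: list[int] = []
    arm1: list[int] = []
    arm0: list[int] = []
    split: int | None = None
    pen = 0.0

    A = _build_design(Xw, None, shared, arm1, arm0, None, ones=sw)
    beta, rss = _ols(A, yw)
    dl_cur = data_bits(rss, n, n - 1) + dl_scale * pen
    dl_path = [dl_cur]

    arm_sizes = (Z > 0).sum(axis=0)  # distinct fitting rows with z=1 per split

    while A.shape[1] < n:
        Q, _ = np.linalg.qr(A)
        r = yw - Q @ (Q.T @ yw)
        rss = float(r @ r)
        used = set(shared) | set(arm1) | set(arm0)
        avail = np.array([j for j in range(p) if j not in used], dtype=int)
        if avail.size == 0:
            break
        m = A.shape[1]

        cand_dl, cand_prio, cand_j, cand_t, cand_arm = [], [], [], [], []

        def push(dl, prio, j, t, arm):
            cand_dl.append(dl)
            cand_prio.append(np.full(dl.shape, prio))
            cand_j.append(j)
            cand_t.append(np.full(dl.shape, t))
            cand_arm.append(np.full(dl.shape, arm))

        # shared moves
        if m + 1 <= n - 1:
            gains = _batch_gains(Q, r, Xw[:, avail])
            dl = data_bits(np.maximum(rss - gains, 0.0), n, n - m - 1) + dl_scale * (
                pen + costs.feature_cost[avail]
            )
            dl = np.where(np.isfinite(gains), dl, np.inf)
            push(dl, 0, avail, -1, -1)

        # contextual moves
        split_choices = range(T) if split is None else [split]
        for t in split_choices:
            committing = split is None
            n_extra = 2 if committing else 1
            if m + n_extra > n - 1:
                continue
            z = Z[:, t]
            zcol = Zw[:, t]
            if committing:
                zp = zcol - Q @ (Q.T @ zcol)
                nz2 = float(zp @ zp)
                if nz2 <= COLLINEAR_TOL * max(float(zcol @ zcol), 1e-300):
                    continue  # split constant within the fitting set
                qz = zp / np.sqrt(nz2)
                gain_z = float(qz @ r) ** 2
                Qt = np.column_stack([Q, qz])
                pen_extra = costs.split_cost[t] + costs.coef_bits
            else:
                gain_z = 0.0
                Qt = Q
                pen_extra = 0.0
            for arm, mask in ((1, z), (0, 1.0 - z)):
                n_arm = arm_sizes[t] if arm == 1 else n - arm_sizes[t]
                if n_arm < min_arm_size:
                    continue
                gains = _batch_gains(Qt, r, Xw[:, avail] * mask[:, None])
                total = gain_z + gains
                dl = data_bits(np.maximum(rss - total, 0.0), n, n - m - n_extra) + dl_scale * (
                    pen + pen_extra + costs.feature_cost[avail]
                )
                dl = np.where(np.isfinite(gains), dl, np.inf)
                # arm-order tiebreak: arm1 before arm0
                push(dl, 1, avail, t, 1 - arm)

        if not cand_dl:
            break
        dls = np.concatenate(cand_dl)
        if not np.any(np.isfinite(dls)):
            break
        best = dls.min()
        if best >= dl_cur - TIE_TOL:
            break  # no move strictly decreases the description length
        prios = np.concatenate(cand_prio)
        js = np.concatenate(cand_j)
        ts = np.concatenate(cand_t)
        arms = np.concatenate(cand_arm)
        near = dls <= best + TIE_TOL
        order = np.lexsort((arms[near], ts[near], js[near], prios[near]))
        pick = np.flatnonzero(near)[order[0]]

        j, t, prio, arm_code = int(js[pick]), int(ts[pick]), int(prios[pick]), int(arms[pick])
        if prio == 0:
            shared.append(j)
        else:
            if split is None:
                split = t
                pen += costs.split_cost[t] + costs.coef_bits  # offset coefficient
            (arm1 if arm_code == 0 else arm0).append(j)
        pen += costs.feature_cost[j]

        A = _build_design(
            Xw, Zw[:, split] if split is not None else None, shared, arm1, arm0, split, ones=sw
        )
        beta, rss = _ols(A, yw)
        dl_cur = data_bits(rss, n, n - A.shape[1]) + dl_scale * pen
        dl_path.append(dl_cur)

    return _assemble(beta, rss, dl_cur, n, shared, arm1, arm0, split, mu, sd, dl_path)


def _assemble(beta, rss, dl, n, shared, arm1, arm0, split, mu, sd, dl_path):
    i = 0
    intercept = float(beta[i]); i += 1
    b_shared = {}
    for j in shared:
        b_shared[j] = float(beta[i]); i += 1
    offset = 0.0
    b1, b0 = {}, {}
    if split is not None:
        offset = float(beta[i]); i += 1
        for j in arm1:
            b1[j] = float(beta[i]); i += 1
        for j in arm0:
            b0[j] = float(beta[i]); i += 1
    return CherModel(
        split=split,
        beta_shared=b_shared,
        beta_arm1=b1,
        beta_arm0=b0,
        intercept=intercept,
        intercept_arm_offset=offset,
        dl_total=float(dl),
        rss=float(rss),
        n_used=n,
        scale_mean=mu,
        scale_sd=sd,
        dl_path=dl_path,
    )


def refit_model(
    X: np.ndarray,
    y: np.ndarray,
    Z: np.ndarray | None,
    shared: list[int],
    arm1: list[int],
    arm0: list[int],
    split: int | None,
    costs: CostModel | None = None,
    *,
    binary_mask: np.ndarray | None = None,
    standardize: bool = True,
    dl_scale: float = 1.0,
) -> CherModel:
    """OLS refit of a fixed model structure (no search).

    Used to finalize stability-selected features on the full sample set.
    Contextual roles require ``split``; passing contextual features without
    a split is an error.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    Z = np.zeros((n, 0)) if Z is None else np.asarray(Z, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    if split is None and (arm1 or arm0):
        raise ValueError("contextual features require a committed split")
    if costs is None:
        costs = uniform_costs(p, Z.shape[1])
    if binary_mask is None:
        binary_mask = detect_binary_columns(X)
    if standardize:
        Xs, mu, sd = _weighted_standardize(X, binary_mask, np.ones(n))
    else:
        Xs, mu, sd = X, np.zeros(p), np.ones(p)
    z = Z[:, split] if split is not None else None
    A = _build_design(Xs, z, shared, arm1, arm0, split)
    beta, rss = _ols(A, y)
    pen = sum(costs.feature_cost[j] for j in itertools.chain(shared, arm1, arm0))
    if split is not None:
        pen += costs.split_cost[split] + costs.coef_bits
    dl = data_bits(rss, n, max(n - A.shape[1], 1)) + dl_scale * pen
    return _assemble(beta, rss, dl, n, shared, arm1, arm0, split, mu, sd, [dl])


def predict(model: CherModel, X: np.ndarray, Z: np.ndarray | None = None) -> np.ndarray:
    """Predict phenotype values from a fitted model.

    yhat_i = intercept + sum_j bS_j x_ij
             + 1[z_it = 1] (offset + sum_j b1_j x_ij)
             + 1[z_it = 0] sum_j b0_j x_ij
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if model.scale_mean is not None:
        if p != model.scale_mean.shape[0]:
            raise ValueError("X has a different number of features than the model")
        Xs = (X - model.scale_mean) / model.scale_sd
    else:
        Xs = X
    yhat = np.full(n, model.intercept)
    for j, b in model.beta_shared.items():
        yhat += b * Xs[:, j]
    if model.split is not None:
        Z = np.zeros((n, 0)) if Z is None else np.asarray(Z, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
        if model.split >= Z.shape[1]:
            raise ValueError("Z lacks the model's committed split column")
        z = Z[:, model.split]
        yhat += z * model.intercept_arm_offset
        for j, b in model.beta_arm1.items():
            yhat += b * Xs[:, j] * z
        for j, b in model.beta_arm0.items():
            yhat += b * Xs[:, j] * (1.0 - z)
    return yhat


class L0ContextRegressor(RegressorMixin, BaseEstimator):
    """Sklearn-style wrapper around the greedy MDL search for one phenotype.

    Parameters mirror :func:`greedy_fit`; ``costs=None`` uses uniform
    coding.  The split matrix ``Z`` is passed to :meth:`fit` and
    :meth:`predict` alongside ``X``.

    Attributes
    ----------
    model_ : CherModel
        The fitted sparse model.
    n_features_in_ : int
    """

    def __init__(
        self,
        costs: CostModel | None = None,
        standardize: bool = True,
        min_arm_size: int = 5,
        dl_scale: float = 1.0,
        binary_mask=None,
    ):
        self.costs = costs
        self.standardize = standardize
        self.min_arm_size = min_arm_size
        self.dl_scale = dl_scale
        self.binary_mask = binary_mask

    def fit(self, X, y, Z=None):
        X = np.asarray(X, dtype=float)
        self.model_ = greedy_fit(
            X,
            y,
            Z,
            self.costs,
            binary_mask=self.binary_mask,
            standardize=self.standardize,
            min_arm_size=self.min_arm_size,
            dl_scale=self.dl_scale,
        )
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X, Z=None):
        check_is_fitted(self, "model_")
        return predict(self.model_, X, Z)
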