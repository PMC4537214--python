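"""Cross-phenotype transfer of feature-selection evidence.

Bootstrap selection frequencies of each feature (and each candidate split)
are pooled across phenotypes into inclusion priors by a similarity-weighted
beta-smoothed average,

    P_y(beta_j != 0) = (sum_k w_yk tau_jk + a) / (sum_k w_yk + b),

with non-informative hyper-parameters a = b = 0.5 and weights w_yk obtained
by a sigmoid transform of the Pearson correlation between phenotypes y and
k.  Priors are then converted back into selection costs for the next round
of model search.

Two calibration points pin the default prior-to-cost transform.  The
formula above has a hard floor P0_y = a / (sum_k w_yk + b), reached when no
neighbour ever selects the feature; a feature sitting at that baseline has
contributed no transfer evidence and must keep the uniform selection cost
log2(p) + 2, else every feature in the panel gets cheaper with each
iteration and stability selection degenerates into dense, noise-chasing
models.  At the other end P = 1 (every similar neighbour selects the
feature in every bootstrap run) leaves only the coefficient bits to pay.
Costs interpolate log-affinely between these anchors,

    cost_j = coef_bits + log2(p) * log(P_j) / log(P0_y),

so transfer can only reallocate naming bits it has evidence for, never
dilute the coding of the whole feature space.  The direct (unanchored)
map ``-log2(P) + coef_bits`` capped at the uniform cost is available via
``anchored=False``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .l0 import CostModel

__all__ = [
    "BootstrapSummary",
    "PriorState",
    "phenotype_similarity",
    "update_priors",
    "priors_to_costs",
]

P_FLOOR = 1e-4


@dataclass
class BootstrapSummary:
    """Selection frequencies over bootstrap resamples.

    tau[j, k] is the fraction of (usable) bootstrap runs in which feature j
    entered phenotype k's model in any role; the per-role frequencies and
    the split-commitment frequencies are kept alongside.  ``B_eff[k]`` is
    the number of runs actually used for phenotype k (replicates with too
    few observed samples are skipped).
    """

    tau: np.ndarray          # (p, K) any-role selection frequency
    freq_shared: np.ndarray  # (p, K)
    freq_arm1: np.ndarray    # (p, K)
    freq_arm0: np.ndarray    # (p, K)
    split_freq: np.ndarray   # (T, K)
    B: int
    B_eff: np.ndarray        # (K,)

    def __post_init__(self) -> None:
        for a in (self.tau, self.freq_shared, self.freq_arm1, self.freq_arm0, self.split_freq):
            if np.any((a < 0) | (a > 1)):
                raise ValueError("selection frequencies must lie in [0, 1]")


@dataclass
class PriorState:
    """Per-phenotype inclusion probabilities for features and splits.

    ``baseline[y]`` is the prior value a feature with zero selection
    frequency among all neighbours would receive — the anchor that the
    cost transform maps to the uniform selection cost.
    """

    P: np.ndarray         # (p, K), entries in (0, 1]
    split_P: np.ndarray   # (T, K)
    baseline: np.ndarray  # (K,) no-evidence prior a / (sum w + b)
    a: float
    b: float
    W: np.ndarray         # (K, K) similarity weights
    sigmoid_scale: float


def phenotype_similarity(Y: np.ndarray, sigmoid_scale: float = 8.0,
                         center: float = 0.5, min_pairs: int = 3) -> np.ndarray:
    """Sigmoid-transformed Pearson correlation between phenotype columns.

    w_yk = 1 / (1 + exp(-c * (r_yk - center))) on pairwise-complete
    observations.  The transition is centred at ``center`` so that only
    substantially correlated phenotypes carry weight: with the defaults
    (c = 8, center = 0.5) an uncorrelated pair gets w ~ 0.02 and a pair at
    r = 0.9 gets w ~ 0.96.  Drug-response phenotypes with near-zero
    correlation share no predictive programme, and giving them appreciable
    weight lets features popular elsewhere leak into unrelated models.
    Pairs with fewer than ``min_pairs`` complete observations fall back to
    r = 0 with a warning.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2 or Y.shape[1] < 2:
        raise ValueError("phenotype_similarity needs at least two phenotypes")
    df = pd.DataFrame(Y)
    R = df.corr(min_periods=min_pairs).to_numpy()
    counts = (~df.isna()).astype(float).to_numpy()
    npairs = counts.T @ counts
    bad = np.isnan(R) | (npairs < min_pairs)
    np.fill_diagonal(bad, False)
    if bad.any():
        warnings.warn(
            "some phenotype pairs have fewer than %d complete observations; "
            "their similarity defaults to the r = 0 weight" % min_pairs
        )
        R = np.where(bad, 0.0, R)
    np.fill_diagonal(R, 1.0)
    return expit(sigmoid_scale * (R - center))


def update_priors(
    bs: BootstrapSummary,
    W: np.ndarray,
    a: float = 0.5,
    b: float = 0.5,
    *,
    include_self: bool = False,
    denominator: str = "as_printed",
    sigmoid_scale: float = 8.0,
) -> PriorState:
    """Pool selection frequencies into inclusion priors.

    The sum over neighbours k excludes the phenotype itself by default (its
    own evidence re-enters through the next bootstrap round).  The
    denominator is ``sum_k w_yk + b`` as printed; ``denominator=
    "beta_posterior"`` uses the standard beta-posterior form
    ``sum w + a + b``.  A phenotype with zero total neighbour weight gets
    the uninformative prior 0.5 for every feature (the literal formula
    would give a/b = 1); under the anchored cost transform this maps back
    to uniform costs, i.e. no transfer.
    """
    if denominator not in ("as_printed", "beta_posterior"):
        raise ValueError("denominator must be 'as_printed' or 'beta_posterior'")
    W = np.asarray(W, dtype=float)
    K = W.shape[0]
    Wn = W.copy()
    if not include_self:
        np.fill_diagonal(Wn, 0.0)
    wsum = Wn.sum(axis=0)  # (K,)
    den = wsum + (b if denominator == "as_printed" else a + b)
    baseline = np.where(wsum == 0, 0.5, a / den)

    def pool(freq):
        num = freq @ Wn + a  # (p, K): sum_k w_yk freq_jk + a
        P = num / den
        P = np.where(wsum == 0, 0.5, P)
        return np.clip(P, P_FLOOR, 1.0)

    if np.any(wsum == 0):
        warnings.warn("phenotype with zero neighbour weight: priors uninformative (0.5)")
    return PriorState(
        P=pool(bs.tau),
        split_P=pool(bs.split_freq) if bs.split_freq.size else bs.split_freq.reshape(0, K),
        baseline=np.clip(baseline, P_FLOOR, 1.0),
        a=a,
        b=b,
        W=W,
        sigmoid_scale=sigmoid_scale,
    )


def priors_to_costs(ps: PriorState, p: int, T: int, phenotype: int,
                    coef_bits: float = 2.0, anchored: bool = True) -> CostModel:
    """Convert one phenotype's priors into selection costs in bits.

    Anchored (default): costs interpolate log-affinely between the two
    calibration points — the no-evidence baseline keeps the uniform cost
    ``log2(p) + coef_bits`` and P = 1 costs ``coef_bits`` alone:

        cost_j = coef_bits + log2(p) * log(P_j) / log(baseline_y)

    Split costs are rescaled identically between ``log2(T)`` and 0.

    Unanchored: ``cost_j = -log2(P_j) + coef_bits`` capped at the uniform
    cost (and split costs at ``log2(T)``).

    Either way no feature cost falls below ``coef_bits``, none exceeds the
    uniform cost, and costs are monotone decreasing in P.
    """
    P = ps.P[:, phenotype]
    P0 = ps.baseline[phenotype]
    if anchored:
        if P0 >= 1.0:
            ratio = np.ones_like(P)
        else:
            ratio = np.clip(np.log(P) / np.log(P0), 0.0, 1.0)
        fcost = coef_bits + np.log2(p) * ratio
        if T > 0:
            sP = ps.split_P[:, phenotype]
            sratio = (np.clip(np.log(sP) / np.log(P0), 0.0, 1.0)
                      if P0 < 1.0 else np.ones_like(sP))
            scost = (np.log2(T) if T > 1 else 0.0) * sratio
        else:
            scost = np.zeros(0)
    else:
        fcost = np.minimum(-np.log2(P) + coef_bits, np.log2(p) + coef_bits)
        if T > 0:
            sP = ps.split_P[:, phenotype]
            scost = np.clip(-np.log2(sP), 0.0, np.log2(T) if T > 1 else 0.0)
        else:
            scost = np.zeros(0)
    return CostModel(feature_cost=fcost, split_cost=scost, coef_bits=coef_bits)
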