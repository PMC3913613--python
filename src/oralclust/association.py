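"""Rank-based association statistics.

Species co-occurrence structure is measured with Spearman rank correlation
(converted to the distance 1 - rho for clustering), between-cluster
association with the Escoufier RV coefficient on column-wise
rank-transformed abundance blocks, and separation of sample groupings with
ANOSIM (analysis of similarities). All significance tests are permutation
tests with the add-one convention p = (1 + #exceed) / (1 + n_perm), so a
reported p is never exactly zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata


def spearman_distance(abund: pd.DataFrame) -> pd.DataFrame:
    """Species-by-species distance d = 1 - Spearman rho (midranks for ties).

    ``abund`` is samples x species. A species constant across samples has
    undefined rank correlation; its distances are set to 1 (no information)
    with a warning.
    """
    if abund.shape[0] < 3:
        raise ValueError("need at least 3 samples for rank correlations")
    X = abund.to_numpy(dtype=float)
    ranks = np.apply_along_axis(rankdata, 0, X)
    sd = ranks.std(axis=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant species: distance set to 1",
            stacklevel=2)
    R = ranks - ranks.mean(axis=0)
    denom = np.sqrt((R**2).sum(axis=0))
    denom[constant] = 1.0
    C = (R / denom).T @ (R / denom)
    C[constant, :] = 0.0
    C[:, constant] = 0.0
    d = 1.0 - C
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=abund.columns, columns=abund.columns)


# ---------------------------------------------------------------------------
# RV coefficient
# ---------------------------------------------------------------------------

@dataclass
class RvResult:
    rv: float
    p: float | None
    n_perm: int | None


def _prepare_rv_block(X: pd.DataFrame | np.ndarray, rank_transform: bool) -> np.ndarray:
    A = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    if A.ndim == 1:
        A = A[:, None]
    if A.size == 0:
        raise ValueError("empty matrix")
    if rank_transform:
        A = np.apply_along_axis(rankdata, 0, A)
    const = A.std(axis=0) == 0
    if const.any():
        warnings.warn(f"dropping {int(const.sum())} constant column(s)", stacklevel=2)
        A = A[:, ~const]
        if A.shape[1] == 0:
            raise ValueError("all columns constant")
    return A - A.mean(axis=0)


def rv_coefficient(X, Y, rank_transform: bool = True) -> float:
    """Escoufier RV between two blocks observed on the same samples.

    RV = trace(X'Y Y'X) / sqrt(trace((X'X)^2) trace((Y'Y)^2)) on
    column-centred (and by default column-wise midrank-transformed) blocks;
    ranges 0..1, and reduces to the squared Pearson correlation when both
    blocks have a single column.
    """
    A = _prepare_rv_block(X, rank_transform)
    B = _prepare_rv_block(Y, rank_transform)
    if A.shape[0] != B.shape[0]:
        raise ValueError("X and Y must share the sample set")
    num = float(np.sum((A.T @ B)**2))
    den = np.sqrt(float(np.sum((A.T @ A)**2)) * float(np.sum((B.T @ B)**2)))
    if den == 0:
        raise ValueError("degenerate block with zero total variance")
    return num / den


def rv_permutation_test(X, Y, n_perm: int = 999, seed: int = 0,
                        rank_transform: bool = True) -> RvResult:
    """Permutation p for RV, shuffling the rows of Y."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    A = _prepare_rv_block(X, rank_transform)
    B = _prepare_rv_block(Y, rank_transform)

    def rv(a, b):
        num = float(np.sum((a.T @ b)**2))
        den = np.sqrt(float(np.sum((a.T @ a)**2)) * float(np.sum((b.T @ b)**2)))
        return num / den

    obs = rv(A, B)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        if rv(A, B[rng.permutation(B.shape[0])]) >= obs - 1e-12:
            exceed += 1
    return RvResult(obs, (1 + exceed) / (1 + n_perm), n_perm)


# ---------------------------------------------------------------------------
# ANOSIM
# ---------------------------------------------------------------------------

@dataclass
class AnosimResult:
    r: float
    p: float | None
    n_perm: int | None
    group_sizes: dict


def _anosim_r(rank_d: np.ndarray, between: np.ndarray, divisor: float) -> float:
    return float((rank_d[between].mean() - rank_d[~between].mean()) / divisor)


def anosim(dist: pd.DataFrame, groups, n_perm: int = 999, seed: int = 0) -> AnosimResult:
    """ANOSIM R = (mean between-group rank - mean within-group rank) / (n(n-1)/4).

    All n(n-1)/2 pairwise distances are ranked once with midranks; the
    permutation null shuffles group labels freely. Requires every group to
    have at least 2 members.
    """
    groups = np.asarray(pd.Series(groups).loc[list(dist.index)]
                        if isinstance(groups, (dict, pd.Series)) else groups)
    D = dist.to_numpy(dtype=float)
    n = D.shape[0]
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).any():
        raise ValueError(f"groups of size 1: {labels[counts < 2].tolist()}")
    iu = np.triu_indices(n, k=1)
    rank_d = rankdata(D[iu])
    divisor = n * (n - 1) / 4.0
    between = groups[iu[0]] != groups[iu[1]]
    obs = _anosim_r(rank_d, between, divisor)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        g = groups[rng.permutation(n)]
        if _anosim_r(rank_d, g[iu[0]] != g[iu[1]], divisor) >= obs - 1e-12:
            exceed += 1
    return AnosimResult(obs, (1 + exceed) / (1 + n_perm), n_perm,
                        dict(zip(labels.tolist(), counts.tolist())))
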