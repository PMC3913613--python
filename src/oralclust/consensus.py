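"""Consensus clustering with item-consensus robustness filtering.

Cluster stability is assessed by repeatedly clustering random subsamples of
the items (drawn without replacement at proportion ``p``) and recording,
for every pair of items, the fraction of co-sampled runs in which they were
placed in the same cluster — the consensus matrix M_K. The number of
clusters K is chosen from the relative change of the area under the
empirical CDF of the M_K entries as K grows (the delta-area elbow), and
items are kept as *robust* cluster members only when their item consensus
is high for their own cluster and low for every other.

Two base clusterers are provided: unweighted average-linkage agglomeration
(UPGMA) for species and partitioning around medoids (PAM, BUILD + SWAP)
for subjects. Distances are supplied by the caller (1 - Spearman rank
correlation for species; Euclidean distance of PCA scores for subjects);
restricting a precomputed distance matrix to a subsample is equivalent to
recomputing it on the subsample for these distance types.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform


# ---------------------------------------------------------------------------
# Base clusterers
# ---------------------------------------------------------------------------

def _check_dist(dist: np.ndarray) -> np.ndarray:
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-10):
        raise ValueError("distance matrix must have zero diagonal")
    return d


def average_linkage(dist: np.ndarray, k: int) -> np.ndarray:
    """UPGMA agglomeration cut into exactly k clusters (labels 0..k-1)."""
    d = _check_dist(dist)
    n = d.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside [1, {n}]")
    if k == n:
        return np.arange(n)
    Z = linkage(squareform(d, checks=False), method="average")
    labels = fcluster(Z, t=k, criterion="maxclust") - 1
    return labels


def pam(dist: np.ndarray, k: int, seed: int | None = None
        ) -> tuple[np.ndarray, np.ndarray]:
    """Partitioning around medoids: greedy BUILD then steepest-descent SWAP.

    Deterministic given the distance matrix: ties are broken by the lowest
    candidate index, so ``seed`` is accepted for interface symmetry only.
    Returns (labels, medoid indices); cost is the total distance of each
    item to its cluster medoid.
    """
    d = _check_dist(dist)
    n = d.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside [1, {n}]")
    # BUILD: start from the 1-medoid minimizer, greedily add the point that
    # most reduces total cost.
    medoids = [int(np.argmin(d.sum(axis=1)))]
    while len(medoids) < k:
        cur = d[:, medoids].min(axis=1)
        gains = np.maximum(cur[None, :] - d, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    medoids = sorted(medoids)

    def cost(meds: list[int]) -> float:
        return float(d[:, meds].min(axis=1).sum())

    best = cost(medoids)
    improved = True
    while improved:
        improved = False
        best_swap, best_cost = None, best
        for mi, m in enumerate(medoids):
            for h in range(n):
                if h in medoids:
                    continue
                trial = medoids[:mi] + [h] + medoids[mi + 1:]
                c = cost(trial)
                if c < best_cost - 1e-12:
                    best_cost, best_swap = c, (mi, h)
        if best_swap is not None:
            mi, h = best_swap
            medoids[mi] = h
            medoids = sorted(medoids)
            best = best_cost
            improved = True
    med = np.asarray(medoids)
    labels = np.argmin(d[:, med], axis=1)
    labels[med] = np.arange(k)  # medoids belong to their own cluster
    return labels, med


def pam_labels(dist: np.ndarray, k: int, seed: int | None = None) -> np.ndarray:
    return pam(dist, k, seed)[0]


BASE_CLUSTERERS: dict[str, Callable[[np.ndarray, int], np.ndarray]] = {
    "average_linkage": average_linkage,
    "pam": pam_labels,
}


# ---------------------------------------------------------------------------
# Consensus engine
# ---------------------------------------------------------------------------

@dataclass
class ConsensusRun:
    items: list[str]
    k_range: tuple[int, ...]
    consensus: dict[int, pd.DataFrame]
    areas: dict[int, float]
    deltas: dict[int, float]
    selected_k: int
    assignments: dict[int, pd.Series]
    item_consensus_scores: dict[int, pd.DataFrame]
    h: int
    p: float
    seed: int
    never_cosampled_pairs: int = 0

    @property
    def selected_assignment(self) -> pd.Series:
        return self.assignments[self.selected_k]


@dataclass
class RobustClusters:
    clusters: dict[int, list[str]]
    excluded: dict[str, str] = field(default_factory=dict)

    @property
    def labels(self) -> dict[str, int]:
        return {m: k for k, mem in self.clusters.items() for m in mem}


def consensus_cdf_area(m: pd.DataFrame | np.ndarray) -> float:
    """Area under the empirical CDF of the off-diagonal consensus entries.

    A(K) = integral over [0, 1] of the ECDF of the n(n-1)/2 upper-triangular
    entries, computed exactly as the step sum
    sum_l (x_l - x_{l-1}) * CDF(x_{l-1}) over the sorted distinct values
    (with the endpoint 1 included), which equals 1 - mean(entries). Fully
    polarised consensus (all entries 1) gives 0 mass below 1, hence A = 0;
    all-zero entries give A = 1.
    """
    M = m.to_numpy() if isinstance(m, pd.DataFrame) else np.asarray(m)
    iu = np.triu_indices(M.shape[0], k=1)
    vals = np.sort(M[iu])
    n = len(vals)
    if n == 0:
        return 0.0
    xs = np.unique(np.concatenate([vals, [1.0]]))
    area, prev_x = 0.0, 0.0
    for x in xs:
        cdf_prev = np.searchsorted(vals, prev_x, side="right") / n
        area += (x - prev_x) * cdf_prev
        prev_x = x
    return float(area)


def select_k(areas: dict[int, float], epsilon: float = 0.1) -> tuple[int, dict[int, float]]:
    """Delta-area elbow: K* is the largest K whose relative area gain > epsilon.

    Delta(2) = A(2); Delta(K) = (A(K) - A(K-1)) / A(K-1) for K > 2 (defined
    as A(K) with a warning when A(K-1) = 0).
    """
    ks = sorted(areas)
    if not ks or ks[0] != 2 or ks != list(range(2, ks[-1] + 1)):
        raise ValueError("areas must cover consecutive K starting at 2")
    deltas: dict[int, float] = {2: areas[2]}
    for k in ks[1:]:
        prev = areas[k - 1]
        if prev == 0:
            import warnings
            warnings.warn(f"A({k - 1}) = 0; Delta({k}) set to A({k})", stacklevel=2)
            deltas[k] = areas[k]
        else:
            deltas[k] = (areas[k] - prev) / prev
    candidates = [k for k in ks if deltas[k] > epsilon]
    return (max(candidates) if candidates else ks[0]), deltas


def consensus_cluster(dist: pd.DataFrame, method: str | Callable = "average_linkage",
                      k_range: tuple[int, ...] = (2, 3, 4, 5, 6),
                      h: int = 1000, p: float = 0.8, seed: int = 0,
                      epsilon: float = 0.1, strict: bool = False) -> ConsensusRun:
    """Subsampled consensus clustering over a precomputed distance matrix.

    For each of ``h`` subsamples, ceil(p*n) items are drawn without
    replacement, the distance matrix restricted to them is clustered into K
    groups for every K in ``k_range``, and co-clustering is tallied.
    M_K(i,j) = (# co-clustered) / (# co-sampled); pairs never co-sampled get
    0 (error if ``strict``). The per-K assignment clusters 1 - M_K with
    average linkage; K* comes from the delta-area rule.
    """
    if h < 1 or not 0 < p <= 1:
        raise ValueError("need h >= 1 and 0 < p <= 1")
    items = list(dist.index)
    d = _check_dist(dist.to_numpy())
    n = len(items)
    k_range = tuple(sorted(k_range))
    if k_range[0] < 2 or k_range[-1] > n - 1:
        raise ValueError(f"k_range must lie within [2, {n - 1}]")
    clusterer = BASE_CLUSTERERS[method] if isinstance(method, str) else method
    m_sub = int(np.ceil(p * n))
    rng = np.random.default_rng(seed)

    cosampled = np.zeros((n, n), dtype=np.int64)
    coclustered = {k: np.zeros((n, n), dtype=np.int64) for k in k_range}
    for _ in range(h):
        idx = np.sort(rng.choice(n, size=m_sub, replace=False))
        sub = d[np.ix_(idx, idx)]
        ind = np.zeros(n, dtype=bool)
        ind[idx] = True
        cosampled += np.outer(ind, ind)
        for k in k_range:
            labels = clusterer(sub, k)
            for lab in np.unique(labels):
                mem = idx[labels == lab]
                sel = np.zeros(n, dtype=bool)
                sel[mem] = True
                coclustered[k] += np.outer(sel, sel)

    never = cosampled == 0
    np.fill_diagonal(never, False)
    n_never = int(never.sum() // 2)
    if n_never and strict:
        raise ValueError(
            f"{n_never} item pairs never co-sampled; increase h (h={h})")

    consensus, areas, assignments, item_cons = {}, {}, {}, {}
    safe = np.where(cosampled == 0, 1, cosampled)
    for k in k_range:
        M = coclustered[k] / safe
        M[never] = 0.0
        np.fill_diagonal(M, 1.0)
        Mdf = pd.DataFrame(M, index=items, columns=items)
        consensus[k] = Mdf
        areas[k] = consensus_cdf_area(Mdf)
        labels = average_linkage(1.0 - M, k)  # diag(M) = 1, so diag is 0
        assignments[k] = pd.Series(labels, index=items)
        item_cons[k] = item_consensus(Mdf, assignments[k])

    k_star, deltas = select_k(areas, epsilon)
    return ConsensusRun(items, k_range, consensus, areas, deltas, k_star,
                        assignments, item_cons, h, p, seed, n_never)


def item_consensus(m: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """m_i(k): mean consensus of item i with the members of cluster k.

    The item itself is excluded from its own cluster's average; a singleton
    cluster therefore has no defined value for its own member (NaN).
    """
    M = m.to_numpy()
    items = list(m.index)
    labs = labels.loc[items].to_numpy()
    ks = np.unique(labs)
    out = np.full((len(items), len(ks)), np.nan)
    for kj, k in enumerate(ks):
        members = labs == k
        size = members.sum()
        for i in range(len(items)):
            denom = size - (1 if members[i] else 0)
            if denom == 0:
                continue
            s = M[i, members].sum() - (M[i, i] if members[i] else 0.0)
            out[i, kj] = s / denom
    return pd.DataFrame(out, index=items, columns=ks)


def robust_members(item_cons: pd.DataFrame, labels: pd.Series,
                   hi: float = 0.6, lo: float = 0.4) -> RobustClusters:
    """Keep items with own-cluster consensus >= hi and <= lo elsewhere.

    Both thresholds are inclusive. Items whose own-cluster score is
    undefined (singleton clusters) are excluded.
    """
    clusters: dict[int, list[str]] = {int(k): [] for k in item_cons.columns}
    excluded: dict[str, str] = {}
    for item in item_cons.index:
        own = int(labels.loc[item])
        m_own = item_cons.loc[item, own]
        others = item_cons.loc[item].drop(own)
        if pd.isna(m_own):
            excluded[item] = "singleton cluster: item consensus undefined"
        elif m_own < hi:
            excluded[item] = f"own-cluster consensus {m_own:.3f} < {hi}"
        elif (others.dropna() > lo).any():
            worst = float(others.dropna().max())
            excluded[item] = f"other-cluster consensus {worst:.3f} > {lo}"
        else:
            clusters[own].append(item)
    return RobustClusters({k: v for k, v in clusters.items() if v}, excluded)
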