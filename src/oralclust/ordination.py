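"""Ordination and beta-diversity inference.

Community turnover is analysed on Hellinger-transformed abundances
(square-root of per-sample relative abundances), for which Euclidean
distance equals the Hellinger distance between profiles and PCA/RDA become
ecologically meaningful. Partial redundancy analysis partitions the total
variance of the transformed table into a conditioned fraction (Subject,
between-host differences), a constrained fraction (Day, biofilm maturation)
and a residual; significance of the day term uses a pseudo-F with
permutations of day labels restricted to within-subject strata. A
multivariate dispersion test (distances to group centroids in the
principal-coordinate embedding) checks homogeneity of spread.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def hellinger(table: pd.DataFrame) -> pd.DataFrame:
    """sqrt of row-relative abundances; every output row has unit norm."""
    vals = table.to_numpy(dtype=float)
    sums = vals.sum(axis=1)
    if (sums <= 0).any():
        bad = [s for s, t in zip(table.index, sums) if t <= 0]
        raise ValueError(f"zero-sum rows cannot be Hellinger-transformed: {bad}")
    out = np.sqrt(vals / sums[:, None])
    return pd.DataFrame(out, index=table.index, columns=table.columns)


# ---------------------------------------------------------------------------
# PCA (scaling 1) and species projection
# ---------------------------------------------------------------------------

@dataclass
class Ordination:
    eigenvalues: np.ndarray
    proportions: np.ndarray
    sample_scores: pd.DataFrame  # scaling 1: inter-sample distances preserved
    centering: np.ndarray
    components: np.ndarray = field(repr=False)  # axes x features


def pca(matrix: pd.DataFrame, n_axes: int | None = None) -> Ordination:
    """Column-centred SVD of a samples-by-features matrix.

    Eigenvalues are d_k^2/(n-1). Sample scores use scaling 1 (U·d), so
    Euclidean distances among scores reproduce distances among the centred
    input rows. Axis signs are fixed by making the largest-magnitude loading
    of each axis positive.
    """
    X = matrix.to_numpy(dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("PCA needs at least 2 samples")
    center = X.mean(axis=0)
    Xc = X - center
    U, d, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign: largest |loading| positive per axis
    signs = np.sign(Vt[np.arange(Vt.shape[0]), np.argmax(np.abs(Vt), axis=1)])
    signs[signs == 0] = 1.0
    U, Vt = U * signs, Vt * signs[:, None]
    eig = d**2 / (n - 1)
    keep = min(n_axes, len(eig)) if n_axes else len(eig)
    total = eig.sum()
    props = eig / total if total > 0 else np.zeros_like(eig)
    scores = pd.DataFrame(
        (U * d)[:, :keep], index=matrix.index,
        columns=[f"PC{k + 1}" for k in range(keep)])
    return Ordination(eig[:keep], props[:keep], scores, center, Vt[:keep])


def weighted_average_scores(abund: pd.DataFrame, ordination: Ordination) -> pd.DataFrame:
    """Project species into the sample PCA space by abundance-weighted means.

    Species j's score on axis k is the mean of the sample scores on axis k
    weighted by the species' abundances across samples. Species with zero
    total abundance carry no information and are dropped with a warning.
    """
    if list(abund.index) != list(ordination.sample_scores.index):
        raise ValueError("sample sets of abundance table and ordination differ")
    W = abund.to_numpy(dtype=float)
    totals = W.sum(axis=0)
    zero = totals == 0
    if zero.any():
        warnings.warn(
            f"dropping {int(zero.sum())} all-zero species from projection",
            stacklevel=2)
    S = ordination.sample_scores.to_numpy()
    scores = (W[:, ~zero].T @ S) / totals[~zero, None]
    return pd.DataFrame(scores, index=abund.columns[~zero],
                        columns=ordination.sample_scores.columns)


# ---------------------------------------------------------------------------
# Partial RDA
# ---------------------------------------------------------------------------

@dataclass
class RdaPartition:
    total_inertia: float
    conditioned_fraction: float  # Subject
    constrained_fraction: float  # Day
    residual_fraction: float
    adjusted_r2: float
    pseudo_f: float
    df_constrained: int
    df_conditioned: int
    df_residual: int
    permutation_p: float | None = None
    n_perm: int | None = None


def _orthonormal_basis(X: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Orthonormal basis of the column space of X (rank-revealing)."""
    if X.size == 0:
        return np.zeros((X.shape[0], 0))
    Q, R = np.linalg.qr(X)
    if R.size == 0:
        return np.zeros((X.shape[0], 0))
    diag = np.abs(np.diag(R))
    keep = diag > tol * max(diag.max(), 1.0)
    return Q[:, keep]


def _day_matrix(day: np.ndarray, as_factor: bool) -> np.ndarray:
    if as_factor:
        levels = np.unique(day)
        if len(levels) < 2:
            raise ValueError("day has a single level")
        dummies = (day[:, None] == levels[None, :-1]).astype(float)
        return dummies
    return day.astype(float)[:, None]


def _partition_core(Yc: np.ndarray, Qs: np.ndarray, day: np.ndarray,
                    as_factor: bool) -> tuple[float, int]:
    """Constrained sum of squares of day after removing the subject span."""
    X = _day_matrix(day, as_factor)
    X = X - X.mean(axis=0)
    Xres = X - Qs @ (Qs.T @ X) if Qs.shape[1] else X
    Qx = _orthonormal_basis(Xres)
    if Qx.shape[1] < X.shape[1]:
        raise ValueError("day is collinear with the subject term")
    Yres = Yc - Qs @ (Qs.T @ Yc) if Qs.shape[1] else Yc
    fitted = Qx @ (Qx.T @ Yres)
    return float((fitted**2).sum()), Qx.shape[1]


def partial_rda(Y: pd.DataFrame, day: np.ndarray, subject: np.ndarray,
                day_as_factor: bool = False) -> RdaPartition:
    """Variance partition of Y ~ day + Condition(subject).

    Inertia is total variance (sum of column variances, divisor n-1). The
    conditioned fraction is the share explained by subject indicators; the
    constrained fraction is the additional share explained by day after
    residualizing both Y and day on subjects; the adjusted R^2 of the day
    term applies the Ezekiel correction to the semipartial R^2.
    """
    Yv = Y.to_numpy(dtype=float)
    n = Yv.shape[0]
    day = np.asarray(day)
    subject = np.asarray(subject)
    if not (len(day) == len(subject) == n):
        raise ValueError("day/subject length mismatch")
    single = [s for s in np.unique(subject)
              if len(np.unique(day[subject == s])) < 2]
    if single and len(np.unique(subject)) > 1:
        warnings.warn(
            f"subjects observed at a single day only: {single}", stacklevel=2)
    Yc = Yv - Yv.mean(axis=0)
    total_ss = float((Yc**2).sum())
    if total_ss == 0:
        raise ValueError("Y has zero variance")
    levels = np.unique(subject)
    Z = (subject[:, None] == levels[None, :]).astype(float)
    Z = Z - Z.mean(axis=0)
    Qs = _orthonormal_basis(Z)
    g = Qs.shape[1]  # rank of the centred subject term (S-1, or 0 if 1 level)
    cond_ss = float(((Qs @ (Qs.T @ Yc))**2).sum()) if g else 0.0
    constr_ss, m = _partition_core(Yc, Qs, day, day_as_factor)
    resid_ss = total_ss - cond_ss - constr_ss
    df_resid = n - 1 - g - m
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")
    r2 = constr_ss / total_ss
    adj = 1.0 - (1.0 - r2) * (n - g - 1) / (n - g - 1 - m)
    return RdaPartition(
        total_inertia=total_ss / (n - 1),
        conditioned_fraction=cond_ss / total_ss,
        constrained_fraction=r2,
        residual_fraction=resid_ss / total_ss,
        adjusted_r2=adj,
        pseudo_f=(constr_ss / m) / (resid_ss / df_resid),
        df_constrained=m, df_conditioned=g, df_residual=df_resid)


def permute_within_strata(values: np.ndarray, strata_indices: list[np.ndarray],
                          rng: np.random.Generator) -> np.ndarray:
    """Shuffle ``values`` independently inside each stratum's index set."""
    out = np.asarray(values).copy()
    for idx in strata_indices:
        out[idx] = out[idx][rng.permutation(len(idx))]
    return out


def stratified_permutation_test(Y: pd.DataFrame, day: np.ndarray,
                                subject: np.ndarray, n_perm: int, seed: int,
                                day_as_factor: bool = False) -> RdaPartition:
    """Permutation test of the day term, shuffling day within each subject.

    p = (1 + #{F_perm >= F_obs}) / (1 + n_perm); samples are never exchanged
    across subjects.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    part = partial_rda(Y, day, subject, day_as_factor)
    rng = np.random.default_rng(seed)
    Yv = Y.to_numpy(dtype=float)
    Yc = Yv - Yv.mean(axis=0)
    subject = np.asarray(subject)
    day = np.asarray(day)
    levels = np.unique(subject)
    Z = (subject[:, None] == levels[None, :]).astype(float)
    Qs = _orthonormal_basis(Z - Z.mean(axis=0))
    strata = [np.flatnonzero(subject == s) for s in levels]
    n = len(day)
    total_ss = float((Yc**2).sum())
    cond_ss = float(((Qs @ (Qs.T @ Yc))**2).sum()) if Qs.shape[1] else 0.0
    exceed = 0
    for _ in range(n_perm):
        perm_day = permute_within_strata(day, strata, rng)
        constr_ss, m = _partition_core(Yc, Qs, perm_day, day_as_factor)
        resid_ss = total_ss - cond_ss - constr_ss
        f_perm = (constr_ss / m) / (resid_ss / (n - 1 - Qs.shape[1] - m))
        if f_perm >= part.pseudo_f - 1e-12:
            exceed += 1
    part.permutation_p = (1 + exceed) / (1 + n_perm)
    part.n_perm = n_perm
    return part


# ---------------------------------------------------------------------------
# Multivariate dispersion (homogeneity of spread)
# ---------------------------------------------------------------------------

def _pcoa_embedding(dist: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Principal-coordinate embedding; tiny negative eigenvalues clamped."""
    n = dist.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (dist**2) @ J
    vals, vecs = np.linalg.eigh(B)
    vals = vals[::-1].copy()
    vecs = vecs[:, ::-1]
    vals[np.abs(vals) < tol * max(abs(vals).max(), 1.0)] = 0.0
    vals[vals < 0] = 0.0
    return vecs * np.sqrt(vals)[None, :]


def dispersion_test(dist: pd.DataFrame, groups: np.ndarray, n_perm: int,
                    seed: int, strata: np.ndarray | None = None) -> dict:
    """Permutation test for homogeneity of multivariate dispersion.

    Each sample's distance to its group centroid is computed in the PCoA
    embedding of ``dist``; the statistic is the one-way ANOVA F of those
    distances across groups; the p-value permutes group labels (within
    ``strata`` when given). Size-1 groups are excluded with a warning.
    """
    groups = np.asarray(groups)
    D = dist.to_numpy(dtype=float)
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    small = labels[counts < 2]
    if small.size:
        warnings.warn(f"excluding size-1 groups: {small.tolist()}", stacklevel=2)
        keep = ~np.isin(groups, small)
        D = D[np.ix_(keep, keep)]
        groups = groups[keep]
        if strata is not None:
            strata = np.asarray(strata)[keep]
    coords = _pcoa_embedding(D)

    def f_stat(g: np.ndarray) -> float:
        d = np.empty(len(g))
        for lab in np.unique(g):
            idx = g == lab
            cen = coords[idx].mean(axis=0)
            d[idx] = np.linalg.norm(coords[idx] - cen, axis=1)
        labs = np.unique(g)
        k = len(labs)
        grand = d.mean()
        between = sum((g == l).sum() * (d[g == l].mean() - grand)**2 for l in labs)
        within = sum(((d[g == l] - d[g == l].mean())**2).sum() for l in labs)
        if within <= 1e-30:
            return 0.0 if between <= 1e-30 else np.inf
        return (between / (k - 1)) / (within / (len(d) - k))

    obs = f_stat(groups)
    rng = np.random.default_rng(seed)
    if strata is None:
        strata_idx = [np.arange(len(groups))]
    else:
        strata = np.asarray(strata)
        strata_idx = [np.flatnonzero(strata == s) for s in np.unique(strata)]
    exceed = 0
    for _ in range(n_perm):
        perm = permute_within_strata(groups, strata_idx, rng)
        if f_stat(perm) >= obs - 1e-12:
            exceed += 1
    return {"f": obs, "p": (1 + exceed) / (1 + n_perm), "n_perm": n_perm}
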