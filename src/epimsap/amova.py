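"""Molecular distances, two-level AMOVA with permutation Phi tests, and ordination.

The analysis of molecular variance partitions squared pairwise distances
into among- and within-group components.  For N samples in G groups of
sizes n_g:

    SS_total  = (1/N) * sum_{i<j} d2_ij
    SS_within = sum_g (1/n_g) * sum_{i<j in g} d2_ij
    SS_among  = SS_total - SS_within
    sigma2_w  = SS_within / (N - G)
    sigma2_a  = (SS_among/(G-1) - sigma2_w) / n0,
                n0 = (N - sum_g n_g^2 / N) / (G - 1)
    Phi       = sigma2_a / (sigma2_a + sigma2_w)

Phi_PT is this statistic on squared Hamming distances of binary band
matrices; Phi_ST is the same statistic on the MSL/NML binary recodes.
Significance comes from random relabelling permutations with fixed group
sizes and the add-one p estimator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA as _SkPCA

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceMatrix",
    "AMOVAResult",
    "Ordination",
    "pairwise_distance",
    "amova_two_group",
    "pcoa",
    "pca",
]


@dataclass
class DistanceMatrix:
    """Symmetric matrix of squared pairwise molecular distances.

    ``metric`` is ``hamming_sq`` (mismatch count; squared Euclidean for 0/1
    data) or ``gower`` (proportion of mismatching variables).  Gower values
    are used directly as dissimilarities by UPGMA.
    """

    values: np.ndarray
    ids: list[str]
    metric: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.ids):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        if v.size and np.nanmax(np.abs(np.diag(v))) > 1e-12:
            raise ValueError("distance matrix must have zero diagonal")
        if np.any(v[~np.isnan(v)] < 0):
            raise ValueError("distances must be non-negative")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


@dataclass
class AMOVAResult:
    ss_among: float
    ss_within: float
    df_among: int
    df_within: int
    ms_among: float
    ms_within: float
    sigma2_among: float        # clamped at 0
    sigma2_among_raw: float    # unclamped
    sigma2_within: float
    n0: float
    phi: float
    p_value: float
    n_permutations: int
    seed: int | None
    group_sizes: dict

    @property
    def ss_total(self) -> float:
        return self.ss_among + self.ss_within

    def to_frame(self) -> pd.DataFrame:
        """Classic AMOVA table layout (source, df, SS, MS, variance, %)."""
        tot = self.sigma2_among + self.sigma2_within
        return pd.DataFrame(
            {
                "source": ["among_groups", "within_groups"],
                "df": [self.df_among, self.df_within],
                "SS": [self.ss_among, self.ss_within],
                "MS": [self.ms_among, self.ms_within],
                "variance": [self.sigma2_among, self.sigma2_within],
                "pct_variance": [
                    100 * self.sigma2_among / tot if tot > 0 else 0.0,
                    100 * self.sigma2_within / tot if tot > 0 else 100.0,
                ],
            }
        )


@dataclass
class Ordination:
    coordinates: pd.DataFrame      # samples x axes
    eigenvalues: np.ndarray        # positive eigenvalues, descending
    percent_variance: np.ndarray
    negative_eigenvalues: np.ndarray


def _codes(matrix: pd.DataFrame) -> np.ndarray:
    """Integer codes per cell with -1 for missing, for any cell dtype."""
    arr = matrix.to_numpy(dtype=object)
    flat = pd.factorize(pd.array(arr.ravel()), use_na_sentinel=True)[0]
    return flat.reshape(arr.shape)


def pairwise_distance(matrix: pd.DataFrame, metric: str = "hamming_sq") -> DistanceMatrix:
    """Pairwise distances between sample rows of a binary or categorical matrix.

    ``hamming_sq``: number of mismatching loci (pairwise-complete);
    ``gower``: proportion of mismatching loci among jointly non-missing ones.
    A sample pair with no jointly scored locus is an error.
    """
    if metric not in ("hamming_sq", "gower"):
        raise ValueError(f"unknown metric {metric!r}")
    n = matrix.shape[0]
    if n < 2:
        raise ValueError("need at least two samples")
    codes = _codes(matrix)
    present = codes >= 0
    joint = present.astype(np.int64) @ present.T.astype(np.int64)
    off = ~np.eye(n, dtype=bool)
    if (joint[off] == 0).any():
        i, j = np.argwhere((joint == 0) & off)[0]
        raise ValueError(
            f"samples {matrix.index[i]!r} and {matrix.index[j]!r} share no scored loci"
        )
    mism = np.zeros((n, n), dtype=float)
    for i in range(n):
        both = present[i] & present
        mism[i] = np.sum(both & (codes[i] != codes), axis=1)
    np.fill_diagonal(mism, 0.0)
    values = mism if metric == "hamming_sq" else mism / joint
    return DistanceMatrix(values=values, ids=list(matrix.index), metric=metric)


def _ss_terms(V: np.ndarray, indicators: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """SS_within for each row of boolean group-A ``indicators`` (vectorised).

    Exploits sum_{i<j in g} d2 = m_g^T V m_g / 2 for an indicator vector m_g.
    """
    A = indicators.astype(float)
    colsum = V.sum(axis=0)
    t = A @ V
    ss_a = np.einsum("ij,ij->i", t, A) / (2.0 * sizes[0])
    tb = colsum[None, :] - t
    ss_b = np.einsum("ij,ij->i", tb, 1.0 - A) / (2.0 * sizes[1])
    return ss_a + ss_b


def amova_two_group(
    D: DistanceMatrix,
    groups: Mapping[str, str],
    n_perm: int = 9999,
    seed: int | None = None,
) -> AMOVAResult:
    """Two-group AMOVA: variance components, Phi, and a permutation p-value.

    A negative among-group component is clamped to zero for Phi (the raw
    value is kept in ``sigma2_among_raw``); p uses the add-one estimator
    (1 + #{Phi_perm >= Phi_obs}) / (n_perm + 1) over random relabellings
    with fixed group sizes.
    """
    levels = sorted({groups[s] for s in D.ids})
    if len(levels) != 2:
        raise ValueError(f"exactly two groups required, got {levels}")
    labels = np.array([groups[s] for s in D.ids])
    n_a = int((labels == levels[0]).sum())
    n_b = int((labels == levels[1]).sum())
    if n_a == 0 or n_b == 0:
        raise ValueError("both groups must be non-empty")
    if min(n_a, n_b) == 1:
        logger.warning("amova_two_group: a group of size 1; estimates will be unstable")
    N, G = n_a + n_b, 2
    V = D.values
    sizes = np.array([n_a, n_b], dtype=float)

    ss_total = V.sum() / (2.0 * N)
    obs_ind = (labels == levels[0])[None, :]
    ss_within = float(_ss_terms(V, obs_ind, sizes)[0])
    ss_among = ss_total - ss_within
    df_among, df_within = G - 1, N - G
    ms_among = ss_among / df_among
    ms_within = ss_within / df_within
    n0 = (N - (n_a**2 + n_b**2) / N) / (G - 1)
    sigma2_w = ms_within
    sigma2_a_raw = (ms_among - sigma2_w) / n0

    def _phi(s2a: np.ndarray, s2w: np.ndarray) -> np.ndarray:
        s2a = np.maximum(s2a, 0.0)
        denom = s2a + s2w
        with np.errstate(invalid="ignore", divide="ignore"):
            phi = np.where(denom > 0, s2a / np.where(denom > 0, denom, 1.0), 0.0)
        return np.clip(phi, 0.0, 1.0)

    phi_obs = float(_phi(np.array([sigma2_a_raw]), np.array([sigma2_w]))[0])

    rng = np.random.default_rng(seed)
    if n_perm > 0:
        perm_ind = np.zeros((n_perm, N), dtype=bool)
        for k in range(n_perm):
            idx = rng.permutation(N)[:n_a]
            perm_ind[k, idx] = True
        ss_w_perm = _ss_terms(V, perm_ind, sizes)
        ss_a_perm = ss_total - ss_w_perm
        s2w_perm = ss_w_perm / df_within
        s2a_perm = (ss_a_perm / df_among - s2w_perm) / n0
        phi_perm = _phi(s2a_perm, s2w_perm)
        p = (1.0 + float(np.sum(phi_perm >= phi_obs))) / (n_perm + 1.0)
    else:
        p = float("nan")

    return AMOVAResult(
        ss_among=float(ss_among),
        ss_within=float(ss_within),
        df_among=df_among,
        df_within=df_within,
        ms_among=float(ms_among),
        ms_within=float(ms_within),
        sigma2_among=float(max(sigma2_a_raw, 0.0)),
        sigma2_among_raw=float(sigma2_a_raw),
        sigma2_within=float(sigma2_w),
        n0=float(n0),
        phi=phi_obs,
        p_value=float(p),
        n_permutations=n_perm,
        seed=seed,
        group_sizes={levels[0]: n_a, levels[1]: n_b},
    )


def pcoa(D: DistanceMatrix, eig_tol: float = 1e-9) -> Ordination:
    """Principal coordinate analysis (classical MDS) of squared distances.

    Gower double-centering of -1/2 d2 followed by eigendecomposition; axes
    are eigenvectors scaled by sqrt(eigenvalue), kept for positive
    eigenvalues only.  Negative eigenvalues (non-Euclidean input) are
    reported and their axes dropped.
    """
    V = D.values
    if np.isnan(V).any():
        raise ValueError("distance matrix contains NaN")
    n = D.n
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ V @ J
    B = (B + B.T) / 2.0
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    scale = max(abs(eigval[0]), 1.0) if n else 1.0
    pos = eigval > eig_tol * scale
    neg = eigval[eigval < -eig_tol * scale]
    if neg.size:
        logger.info("pcoa: %d negative eigenvalues (min %.3g) dropped", neg.size, neg.min())
    lam = eigval[pos]
    coords = eigvec[:, pos] * np.sqrt(lam)
    total_pos = lam.sum() if lam.size else 1.0
    axes = [f"PCo{k + 1}" for k in range(lam.size)]
    if lam.size == 0:
        coords = np.zeros((n, 1))
        axes, lam = ["PCo1"], np.array([0.0])
        pct = np.array([0.0])
    else:
        pct = 100.0 * lam / total_pos
    return Ordination(
        coordinates=pd.DataFrame(coords, index=D.ids, columns=axes),
        eigenvalues=np.asarray(lam, dtype=float),
        percent_variance=pct,
        negative_eigenvalues=neg,
    )


def pca(matrix: pd.DataFrame, n_axes: int | None = None) -> Ordination:
    """PCA of a binary recode matrix; missing cells mean-imputed per locus."""
    if matrix.shape[0] < 2 or matrix.shape[1] < 1:
        raise ValueError("PCA needs >= 2 samples and >= 1 locus")
    X = matrix.to_numpy(dtype=float)
    if np.isnan(X).any():
        logger.info("pca: mean-imputing %d missing cells per-locus", int(np.isnan(X).sum()))
        col_mean = np.nanmean(X, axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
        idx = np.where(np.isnan(X))
        X[idx] = col_mean[idx[1]]
    if np.allclose(X, X[0]):
        logger.warning("pca: zero-variance matrix; returning all-zero scores")
        coords = pd.DataFrame(
            np.zeros((X.shape[0], 1)), index=matrix.index, columns=["PC1"]
        )
        return Ordination(coords, np.array([0.0]), np.array([0.0]), np.array([]))
    k = min(X.shape[0] - 1, X.shape[1]) if n_axes is None else n_axes
    model = _SkPCA(n_components=k, svd_solver="full")
    scores = model.fit_transform(X)
    lam = model.explained_variance_
    keep = lam > 1e-12 * max(lam[0], 1.0)
    scores, lam = scores[:, keep], lam[keep]
    axes = [f"PC{k + 1}" for k in range(scores.shape[1])]
    return Ordination(
        coordinates=pd.DataFrame(scores, index=matrix.index, columns=axes),
        eigenvalues=lam,
        percent_variance=100.0 * model.explained_variance_ratio_[keep],
        negative_eigenvalues=np.array([]),
    )
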