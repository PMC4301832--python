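"""Multimorbidity clusters: tetrachoric correlations and factor analysis.

Binary condition indicators are modelled as thresholded bivariate normals;
the tetrachoric correlation of a 2×2 contingency table is the ML estimate of
the latent correlation with thresholds fixed at the probit quantiles of the
margins (with thresholds fixed, the MLE is the ρ that matches the model's
both-present quadrant probability to the observed one). The pairwise
tetrachoric matrix feeds an exploratory factor analysis (principal-axis
extraction, oblique oblimin rotation); factors with correlation-matrix
eigenvalue ≥ 1 are retained and a condition joins a cluster when the absolute
rotated pattern loading is ≥ 0.25. Conditions may belong to several clusters
— overlap is the phenomenon of interest, not an error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator
from statsmodels.multivariate.factor import Factor
from statsmodels.multivariate.factor_rotation import rotate_factors

from .cohort import ConditionMatrix

logger = logging.getLogger(__name__)

_RHO_BOUND = 0.9999


def bivariate_normal_cdf(h: float, k: float, rho: float) -> float:
    """P(X ≤ h, Y ≤ k) for standard bivariate normal with correlation rho."""
    if rho >= 1 - 1e-12:
        return float(stats.norm.cdf(min(h, k)))
    if rho <= -1 + 1e-12:
        return float(max(stats.norm.cdf(h) + stats.norm.cdf(k) - 1, 0.0))
    dist = stats.multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]])
    return float(dist.cdf([h, k]))


def tetrachoric_correlation(counts) -> float:
    """Tetrachoric correlation of a 2×2 table ``[[n11, n10], [n01, n00]]``.

    Rows index the first variable (present/absent), columns the second. A 0.5
    continuity correction is applied to all cells when any cell is zero.
    Degenerate margins (a variable entirely present or absent) yield NaN.
    """
    t = np.asarray(counts, dtype=float)
    if t.shape != (2, 2) or (t < 0).any() or t.sum() <= 0:
        raise ValueError("counts must be a nonnegative 2×2 table with positive total")
    if (t == 0).any():
        t = t + 0.5
    n = t.sum()
    p1 = (t[0, 0] + t[0, 1]) / n  # P(X=1)
    p2 = (t[0, 0] + t[1, 0]) / n  # P(Y=1)
    if min(p1, p2) <= 0 or max(p1, p2) >= 1:
        return float("nan")
    p11 = t[0, 0] / n
    h = stats.norm.ppf(1 - p1)
    k = stats.norm.ppf(1 - p2)

    def quadrant_gap(rho: float) -> float:
        # P(X>h, Y>k; rho) − observed p11, via inclusion–exclusion
        both = bivariate_normal_cdf(h, k, rho)
        return (1 - stats.norm.cdf(h) - stats.norm.cdf(k) + both) - p11

    lo, hi = quadrant_gap(-_RHO_BOUND), quadrant_gap(_RHO_BOUND)
    if hi < 0:  # observed association beyond the model's range
        return _RHO_BOUND
    if lo > 0:
        return -_RHO_BOUND
    return float(optimize.brentq(quadrant_gap, -_RHO_BOUND, _RHO_BOUND, xtol=1e-10))


def pair_table(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """2×2 contingency table [[n11, n10], [n01, n00]] of two 0/1 vectors."""
    x = np.asarray(x, bool)
    y = np.asarray(y, bool)
    return np.array(
        [[(x & y).sum(), (x & ~y).sum()], [(~x & y).sum(), (~x & ~y).sum()]], dtype=float
    )


def nearest_psd(corr: np.ndarray) -> np.ndarray:
    """Eigenvalue clipping at 0 followed by diagonal renormalization."""
    w, v = np.linalg.eigh(corr)
    repaired = (v * np.clip(w, 0, None)) @ v.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return repaired


def tetrachoric_matrix(matrix) -> pd.DataFrame:
    """Pairwise tetrachoric correlation matrix of a binary patients × conditions frame.

    Degenerate variables (all 0 or all 1) are excluded with a warning and
    listed in ``.attrs['excluded']``. If the pairwise matrix is indefinite it
    is repaired to the nearest PSD correlation (``.attrs['psd_repaired']``).
    """
    data = matrix.data if isinstance(matrix, ConditionMatrix) else pd.DataFrame(matrix)
    means = data.mean(axis=0)
    excluded = list(data.columns[(means <= 0) | (means >= 1)])
    if excluded:
        logger.warning("excluding degenerate conditions from correlation: %s", excluded)
        data = data.drop(columns=excluded)
    cols = list(data.columns)
    X = data.to_numpy().astype(bool)
    p = len(cols)
    corr = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            corr[i, j] = corr[j, i] = tetrachoric_correlation(pair_table(X[:, i], X[:, j]))
    repaired = False
    if np.linalg.eigvalsh(corr).min() < -1e-10:
        corr = nearest_psd(corr)
        repaired = True
        logger.info("pairwise tetrachoric matrix was indefinite; PSD repair applied")
    out = pd.DataFrame(corr, index=cols, columns=cols)
    out.attrs["excluded"] = excluded
    out.attrs["psd_repaired"] = repaired
    return out


@dataclass
class ClusterSolution:
    """Factor-analytic multimorbidity clusters."""

    correlation: pd.DataFrame
    eigenvalues: np.ndarray
    loadings: pd.DataFrame  # oblimin-rotated pattern matrix, conditions × factors
    assignments: dict[str, frozenset[str]]
    labels: list[str]

    @property
    def n_factors(self) -> int:
        return self.loadings.shape[1]

    def membership_frame(self) -> pd.DataFrame:
        rows = [
            (cond, lab, float(self.loadings.at[cond, lab]))
            for cond in self.loadings.index
            for lab in sorted(self.assignments[cond])
        ]
        return pd.DataFrame(rows, columns=["condition", "cluster", "loading"])


def assignments_from_loadings(
    loadings: pd.DataFrame, loading_threshold: float = 0.25
) -> dict[str, frozenset[str]]:
    """condition → set of cluster labels with |pattern loading| ≥ threshold."""
    return {
        cond: frozenset(loadings.columns[loadings.loc[cond].abs() >= loading_threshold])
        for cond in loadings.index
    }


def _canonicalize(loadings: np.ndarray) -> np.ndarray:
    """Deterministic factor order (explained variance desc.) and sign (largest loading > 0)."""
    order = np.argsort(-(loadings**2).sum(axis=0), kind="stable")
    L = loadings[:, order]
    for j in range(L.shape[1]):
        if L[np.abs(L[:, j]).argmax(), j] < 0:
            L[:, j] = -L[:, j]
    return L


def extract_factors(
    correlation: pd.DataFrame,
    eigen_threshold: float = 1.0,
    loading_threshold: float = 0.25,
    labels: list[str] | None = None,
) -> ClusterSolution:
    """Exploratory factor analysis of a (tetrachoric) correlation matrix.

    The number of retained factors is the count of correlation-matrix
    eigenvalues ≥ ``eigen_threshold`` (Kaiser rule). Extraction is
    principal-axis factoring; with ≥ 2 factors the loading matrix is
    obliquely rotated (oblimin, γ=0).
    """
    corr = correlation.to_numpy() if isinstance(correlation, pd.DataFrame) else np.asarray(correlation)
    conds = (
        list(correlation.index)
        if isinstance(correlation, pd.DataFrame)
        else [f"v{i}" for i in range(corr.shape[0])]
    )
    if np.linalg.eigvalsh(corr).min() < -1e-8:
        raise ValueError(
            "correlation matrix is not positive semidefinite; repair it first "
            "(see nearest_psd / tetrachoric_matrix)"
        )
    eigenvalues = np.sort(np.linalg.eigvalsh(corr))[::-1]
    n_factors = int((eigenvalues >= eigen_threshold).sum())
    corr_df = pd.DataFrame(corr, index=conds, columns=conds)
    if n_factors == 0:
        logger.warning("no eigenvalue ≥ %.2f: empty cluster solution", eigen_threshold)
        empty = pd.DataFrame(index=conds)
        return ClusterSolution(corr_df, eigenvalues, empty, {c: frozenset() for c in conds}, [])

    fa = Factor(corr=corr_df, n_factor=n_factors, method="pa", smc=True)
    res = fa.fit()
    raw = np.asarray(res.loadings)[:, :n_factors]
    if n_factors > 1:
        with np.errstate(divide="ignore"):  # rotation's progress table logs step sizes
            raw, _ = rotate_factors(raw, "oblimin", 0.0, "oblique")
    L = _canonicalize(raw)
    if labels is None:
        labels = [f"cluster_{j + 1}" for j in range(n_factors)]
    if len(labels) != n_factors:
        raise ValueError(f"{len(labels)} labels for {n_factors} factors")
    loadings = pd.DataFrame(L, index=conds, columns=labels)
    return ClusterSolution(
        correlation=corr_df,
        eigenvalues=eigenvalues,
        loadings=loadings,
        assignments=assignments_from_loadings(loadings, loading_threshold),
        labels=labels,
    )


def classify_triad(triple, assignments: dict[str, frozenset[str]]) -> str:
    """Cluster label of a triad from its cluster-assigned members only.

    Returns the common cluster label, ``'both'`` when two clusters occur
    among assigned members, and ``'none'`` when no member is assigned.
    Unassigned ("no pattern") members never block a cluster label.
    """
    unknown = [g for g in triple if g not in assignments]
    if unknown:
        raise KeyError(f"conditions missing from cluster assignments: {unknown}")
    present = set().union(*(assignments[g] for g in triple))
    if not present:
        return "none"
    if len(present) == 1:
        return next(iter(present))
    return "both"


class TetrachoricFactorClusters(BaseEstimator):
    """Estimator: binary condition matrix → overlapping multimorbidity clusters.

    Fitted attributes: ``correlation_`` (pairwise tetrachoric matrix),
    ``eigenvalues_``, ``n_factors_``, ``loadings_`` (rotated pattern matrix),
    ``assignments_`` and ``solution_``.
    """

    def __init__(self, eigen_threshold: float = 1.0, loading_threshold: float = 0.25):
        self.eigen_threshold = eigen_threshold
        self.loading_threshold = loading_threshold

    def fit(self, X, y=None):
        self.correlation_ = tetrachoric_matrix(X)
        self.solution_ = extract_factors(
            self.correlation_, self.eigen_threshold, self.loading_threshold
        )
        self.eigenvalues_ = self.solution_.eigenvalues
        self.n_factors_ = self.solution_.n_factors
        self.loadings_ = self.solution_.loadings
        self.assignments_ = self.solution_.assignments
        return self

    def classify(self, triple) -> str:
        return classify_triad(triple, self.assignments_)
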