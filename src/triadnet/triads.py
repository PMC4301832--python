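"""Disease triads: observed/expected prevalence screen.

A triad is an unordered combination of three diagnosis groups. Its expected
prevalence under mutual independence is the product of the three marginal
prevalences in the (gendered) multimorbid cohort; the observed prevalence is
the fraction of patients carrying all three conditions simultaneously. Triads
are retained when observed prevalence ≥ ``min_prev`` (relevance) and
O/E = observed/expected ≥ ``min_oe`` (association). Both thresholds are
inclusive. This is a fixed-threshold screen, not a hypothesis test — no
multiple-testing correction applies.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .cohort import ConditionMatrix

logger = logging.getLogger(__name__)

STAT_COLUMNS = [
    "group_a", "group_b", "group_c",
    "observed_prev", "expected_prev", "oe_ratio",
    "passes_prevalence", "passes_oe", "selected",
]


def enumerate_triads(group_ids: list[str]) -> list[tuple[str, str, str]]:
    """All C(n,3) unordered triples in canonical (sorted-within, lexicographic) order."""
    if len(set(group_ids)) < 3:
        raise ValueError("need at least 3 distinct groups to form triads")
    return list(itertools.combinations(sorted(group_ids), 3))


def triad_observed_prevalence(matrix: ConditionMatrix, triple) -> float:
    """Fraction of cohort patients having all three conditions of the triple."""
    triple = list(triple)
    unknown = set(triple) - set(matrix.group_ids)
    if unknown:
        raise KeyError(f"unknown groups in triple: {sorted(unknown)}")
    return float(matrix.data[triple].all(axis=1).mean())


def triad_expected_prevalence(prevalence: pd.Series, triple) -> float:
    """Expected prevalence under independence: product of the three marginals."""
    missing = [g for g in triple if g not in prevalence.index]
    if missing:
        raise KeyError(f"marginal prevalence missing for: {missing}")
    return float(np.prod([prevalence[g] for g in triple]))


def compute_oe(observed: float, expected: float) -> float:
    """Observed/expected ratio; full precision (reports round to 2 decimals)."""
    if expected > 0:
        return observed / expected
    return float("inf") if observed > 0 else float("nan")


def _triad_counts(X: np.ndarray) -> np.ndarray:
    """counts[i, j, k] = number of rows with columns i, j and k all 1 (i<j<k used)."""
    n, p = X.shape
    counts = np.zeros((p, p, p), dtype=np.int64)
    Xf = X.astype(np.float64)
    for i in range(p):
        sub = Xf[X[:, i] == 1]
        counts[i] = sub.T @ sub if len(sub) else 0.0
    return counts


def compute_triad_stats(
    matrix: ConditionMatrix,
    prevalence: pd.Series | None = None,
    min_prev: float = 0.01,
    min_oe: float = 2.0,
) -> pd.DataFrame:
    """O/E statistics for every triad of the matrix's groups.

    ``prevalence`` defaults to the matrix's own marginals; passing the
    printed (rounded) marginals instead reproduces published O/E values
    computed on rounded inputs.
    """
    if matrix.n_patients == 0:
        raise ValueError("empty cohort")
    gids = matrix.group_ids
    prev = matrix.data.mean(axis=0) if prevalence is None else prevalence
    counts = _triad_counts(matrix.data.to_numpy())
    pos = {g: i for i, g in enumerate(gids)}

    rows = []
    for a, b, c in enumerate_triads(gids):
        i, j, k = sorted((pos[a], pos[b], pos[c]))
        obs = counts[i, j, k] / matrix.n_patients
        exp = triad_expected_prevalence(prev, (a, b, c))
        oe = compute_oe(obs, exp)
        rows.append((a, b, c, obs, exp, oe))
    stats = pd.DataFrame(rows, columns=STAT_COLUMNS[:6])
    stats["passes_prevalence"] = stats["observed_prev"] >= min_prev
    stats["passes_oe"] = stats["oe_ratio"] >= min_oe
    n_undef = int((~np.isfinite(stats["oe_ratio"])).sum())
    if n_undef:
        logger.warning("%d triads with expected prevalence 0 excluded from selection", n_undef)
        stats.loc[~np.isfinite(stats["oe_ratio"]), "passes_oe"] = False
    stats["selected"] = stats["passes_prevalence"] & stats["passes_oe"]
    return stats


@dataclass
class TriadSelection:
    """Staged triad screen result: all triads → prevalent → selected."""

    gender: str | None
    min_prev: float
    min_oe: float
    stats: pd.DataFrame
    section: pd.Series | None = field(default=None)  # cluster labels, filled later

    @property
    def selected(self) -> pd.DataFrame:
        sel = self.stats[self.stats["selected"]]
        return sel.sort_values(
            ["oe_ratio", "observed_prev"], ascending=False, kind="mergesort"
        ).reset_index(drop=True)

    @property
    def counts(self) -> dict[str, int]:
        return {
            "all": int(len(self.stats)),
            "prevalent": int(self.stats["passes_prevalence"].sum()),
            "selected": int(self.stats["selected"].sum()),
        }

    def triples(self) -> list[tuple[str, str, str]]:
        sel = self.selected
        return list(zip(sel["group_a"], sel["group_b"], sel["group_c"]))


def select_triads(
    stats: pd.DataFrame,
    min_prev: float = 0.01,
    min_oe: float = 2.0,
    gender: str | None = None,
) -> TriadSelection:
    """Apply the inclusive prevalence/O-E thresholds to a triad statistics table."""
    stats = stats.copy()
    stats["passes_prevalence"] = stats["observed_prev"] >= min_prev
    stats["passes_oe"] = np.isfinite(stats["oe_ratio"]) & (stats["oe_ratio"] >= min_oe)
    stats["selected"] = stats["passes_prevalence"] & stats["passes_oe"]
    sel = TriadSelection(gender=gender, min_prev=min_prev, min_oe=min_oe, stats=stats)
    logger.info("triad screen (gender=%s): %s", gender, sel.counts)
    return sel


class TriadScreen(BaseEstimator):
    """Estimator wrapper: fit on a gendered multimorbid ConditionMatrix.

    Fitted attributes: ``prevalence_`` (marginals used), ``stats_`` (full
    triad table), ``selection_`` (TriadSelection with staged counts).
    """

    def __init__(self, min_prev: float = 0.01, min_oe: float = 2.0):
        self.min_prev = min_prev
        self.min_oe = min_oe

    def fit(self, X: ConditionMatrix, y=None):
        if self.min_prev < 0 or self.min_oe < 0:
            raise ValueError("thresholds must be non-negative")
        gender = X.meta["gender"].iloc[0] if X.meta["gender"].nunique() == 1 else None
        self.prevalence_ = X.data.mean(axis=0)
        self.stats_ = compute_triad_stats(X, min_prev=self.min_prev, min_oe=self.min_oe)
        self.selection_ = select_triads(self.stats_, self.min_prev, self.min_oe, gender)
        return self
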