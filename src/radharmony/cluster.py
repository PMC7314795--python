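"""Unsupervised discovery of harmonization labels.

When acquisition settings are too heterogeneous to assign batch labels by
hand, samples are grouped by agglomerative hierarchical clustering under
Euclidean distance, and the number of clusters is chosen by maximizing the
mean silhouette width over a candidate range.  Because radiomic features
span wildly different physical units, features are z-scored before distance
computation (otherwise volume-scale features dominate).

A discovered clustering is only usable as a harmonization label if it
reflects acquisition differences rather than outcome: ``outcome_balance_check``
compares per-cluster event rates with a two-proportion test and flags
suspicious imbalance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import chi2_contingency
from sklearn.metrics import silhouette_score
from statsmodels.stats.proportion import proportions_ztest

from .types import FeatureTable

LINKAGES = ("ward", "average", "complete")


@dataclass
class ClusteringResult:
    linkage_matrix: np.ndarray
    silhouette_by_k: dict[int, float]
    chosen_k: int
    labels: np.ndarray
    outcome_balance: Optional[dict[str, float]] = None

    def __post_init__(self) -> None:
        best = max(self.silhouette_by_k.values())
        if self.silhouette_by_k[self.chosen_k] < best - 1e-12:
            raise ValueError("chosen_k does not maximize the silhouette profile")
        if len(np.unique(self.labels)) != self.chosen_k:
            raise ValueError("labels must take exactly chosen_k distinct values")


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return (x - x.mean(axis=0)) / sd


def hierarchical_cluster(
    table: FeatureTable,
    k: int,
    linkage_method: str = "ward",
    standardize: bool = True,
) -> np.ndarray:
    """Cut the agglomerative tree at k clusters; returns string labels 'c1'..'ck'."""
    if linkage_method not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    n = table.n_samples
    if not (2 <= k <= n - 1):
        raise ValueError(f"k must lie in [2, {n - 1}], got {k}")
    x = _zscore(table.values) if standardize else table.values
    lm = linkage(x, method=linkage_method, metric="euclidean")
    flat = fcluster(lm, t=k, criterion="maxclust")
    return np.array([f"c{c}" for c in flat])


def silhouette_select_k(
    table: FeatureTable,
    k_range: tuple[int, int] = (2, 10),
    linkage_method: str = "ward",
    standardize: bool = True,
    outcome: Optional[np.ndarray] = None,
) -> ClusteringResult:
    """Choose the number of clusters maximizing mean silhouette width.

    Ties break toward smaller k: fewer labels leave more samples per batch
    for the downstream harmonization estimation.
    """
    n = table.n_samples
    if n < 4:
        raise ValueError("silhouette selection needs at least 4 samples")
    k_min, k_max = k_range
    k_max = min(k_max, n - 1)
    if not (2 <= k_min <= k_max):
        raise ValueError(f"k range [{k_min}, {k_max}] invalid for n={n}")
    x = _zscore(table.values) if standardize else table.values
    lm = linkage(x, method=linkage_method, metric="euclidean")

    profile: dict[int, float] = {}
    flats: dict[int, np.ndarray] = {}
    for k in range(k_min, k_max + 1):
        flat = fcluster(lm, t=k, criterion="maxclust")
        if len(np.unique(flat)) != k:  # maxclust could not split this far
            continue
        flats[k] = flat
        profile[k] = float(silhouette_score(x, flat, metric="euclidean"))
    if not profile:
        raise ValueError("no k in range produced a valid clustering")
    chosen = min(profile, key=lambda k: (-profile[k], k))
    labels = np.array([f"c{c}" for c in flats[chosen]])
    balance = None
    if outcome is not None:
        balance, _ = outcome_balance_check(labels, outcome)
    return ClusteringResult(lm, profile, chosen, labels, balance)


def outcome_balance_check(
    labels: np.ndarray,
    outcome: np.ndarray,
    alpha: float = 0.05,
) -> tuple[dict[str, float], bool]:
    """Per-cluster event rates plus a confounding flag.

    Flags (returns True) when the rates differ beyond sampling noise (overall
    two-proportion/chi-square test p < alpha), warning that the clusters may
    encode outcome rather than acquisition effects.
    """
    labels = np.asarray(labels)
    outcome = np.asarray(outcome, dtype=float)
    if labels.shape[0] != outcome.shape[0]:
        raise ValueError("labels and outcome must align on samples")
    vals = np.unique(outcome)
    if not np.all(np.isin(vals, [0.0, 1.0])):
        raise ValueError(f"outcome must be binary 0/1, found values {vals}")
    uniq = sorted(set(labels))
    counts = np.array([outcome[labels == c].sum() for c in uniq])
    nobs = np.array([(labels == c).sum() for c in uniq])
    rates = {c: float(k / n) for c, k, n in zip(uniq, counts, nobs)}
    if len(uniq) < 2 or np.all(counts == 0) or np.all(counts == nobs):
        return rates, False
    if len(uniq) == 2:
        _, p = proportions_ztest(counts, nobs)
    else:
        tab = np.stack([counts, nobs - counts], axis=1)
        _, p, _, _ = chi2_contingency(tab)
    flagged = bool(p < alpha)
    if flagged:
        import warnings

        warnings.warn(
            f"per-cluster event rates {rates} differ (p={p:.3g} < {alpha}): "
            "clusters may encode outcome rather than acquisition effects",
            stacklevel=2,
        )
    return rates, flagged
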