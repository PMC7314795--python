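"""Harmonization-quality battery.

Four complementary views of how much batch structure remains in a feature
table: per-feature one-way ANOVA across labels (how many features still
differ significantly between batches), an aggregate coefficient-of-variation
score (overall dispersion), a top-2 PCA summary (visual/geometric batch
separation), and the confusion-matrix classifier metrics BAcc and MCC used
to compare downstream models.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA

from .types import FeatureTable


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.tp + self.fp + self.tn + self.fn < 1:
            raise ValueError("confusion counts must total at least 1")


@dataclass
class EvaluationReport:
    anova_p: np.ndarray
    frac_significant: float
    cov_aggregate: float
    pca_scores: np.ndarray
    pca_explained: tuple[float, float]
    per_label_summaries: dict[str, dict[str, np.ndarray]]

    def to_dict(self) -> dict:
        return {
            "frac_significant": self.frac_significant,
            "cov_aggregate": self.cov_aggregate,
            "pca_explained": list(self.pca_explained),
            "anova_p": self.anova_p.tolist(),
        }


def per_feature_anova(
    table: FeatureTable, labels: np.ndarray, alpha: float = 0.01
) -> tuple[np.ndarray, float]:
    """One-way fixed-effects F-test per feature; returns (p-values, fraction < alpha)."""
    labels = np.asarray(labels)
    uniq = sorted(set(labels))
    if len(uniq) < 2:
        raise ValueError("ANOVA needs at least 2 labels")
    groups_idx = [np.flatnonzero(labels == u) for u in uniq]
    for u, idx in zip(uniq, groups_idx):
        if len(idx) < 2:
            raise ValueError(f"label {u!r} has fewer than 2 samples")
    pvals = np.empty(table.n_features)
    for j in range(table.n_features):
        groups = [table.values[idx, j] for idx in groups_idx]
        with np.errstate(invalid="ignore", divide="ignore"):
            f, p = stats.f_oneway(*groups)
        if not np.isfinite(p):  # all groups constant and equal -> no evidence
            p = 1.0
        pvals[j] = p
    frac = float(np.mean(pvals < alpha))
    return pvals, frac


def aggregate_cov(table: FeatureTable) -> float:
    """Sum over features of |SD/mean| x 100 (percent), one scalar per table.

    Features with exactly zero mean are excluded (their COV is undefined);
    constant features contribute 0.
    """
    mean = table.values.mean(axis=0)
    sd = table.values.std(axis=0, ddof=1)
    ok = mean != 0
    if not ok.any():
        raise ValueError("all features have zero mean: aggregate COV undefined")
    return float(np.sum(np.abs(sd[ok] / mean[ok])) * 100.0)


def pca_top2(
    table: FeatureTable, scale: bool = True
) -> tuple[np.ndarray, tuple[float, float]]:
    """Scores on the top two principal axes plus explained-variance fractions.

    Features are centered and (by default) z-scored, i.e. correlation PCA,
    because radiomic features span very different physical scales.  Each
    component's sign is fixed so its largest-magnitude loading is positive.
    """
    if table.n_samples < 3:
        raise ValueError("PCA summary needs at least 3 samples")
    x = table.values - table.values.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    keep = sd > 0
    if keep.sum() < 2:
        raise ValueError("fewer than 2 non-degenerate dimensions")
    x = x[:, keep]
    if scale:
        x = x / sd[keep]
    pca = PCA(n_components=2)
    scores = pca.fit_transform(x)
    for c in range(2):
        load = pca.components_[c]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, c] *= -1
    ev = pca.explained_variance_ratio_
    return scores, (float(ev[0]), float(ev[1]))


def balanced_accuracy(c: ConfusionCounts) -> float:
    """(sensitivity + specificity) / 2."""
    if c.tp + c.fn < 1:
        raise ValueError("no positive samples: sensitivity undefined")
    if c.tn + c.fp < 1:
        raise ValueError("no negative samples: specificity undefined")
    sens = c.tp / (c.tp + c.fn)
    spec = c.tn / (c.tn + c.fp)
    return (sens + spec) / 2.0


def matthews_cc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient in [-1, 1]; 0 when any marginal is zero."""
    denom2 = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if denom2 == 0:
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / float(np.sqrt(denom2))


def evaluate(
    table: FeatureTable,
    labels: np.ndarray,
    alpha: float = 0.01,
) -> EvaluationReport:
    """Run the full battery against a set of batch labels."""
    pvals, frac = per_feature_anova(table, labels, alpha)
    cov = aggregate_cov(table)
    scores, explained = pca_top2(table)
    summaries = {}
    for u in sorted(set(labels)):
        sub = table.values[np.asarray(labels) == u]
        summaries[u] = {"mean": sub.mean(axis=0), "sd": sub.std(axis=0, ddof=1)}
    return EvaluationReport(pvals, frac, cov, scores, explained, summaries)
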