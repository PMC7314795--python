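"""Core domain types shared by every radharmony module.

A multicenter radiomics analysis revolves around three objects: the feature
table itself (samples x features, real-valued), the batch design describing
which acquisition batch (center, scanner, protocol cluster) each sample came
from together with any biological covariates that must be preserved, and a
run configuration selecting the harmonization variant and its knobs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

VARIANTS = ("combat", "m-combat", "b-combat", "bm-combat")
PRIORS = ("nonparametric", "parametric", "none")


@dataclass
class FeatureTable:
    """A samples x features real-valued matrix with named rows and columns.

    Rows are samples (patients), columns are radiomic features.  Values must
    be finite: the harmonization moment estimators silently corrupt under NaN
    propagation, so missing data is rejected at construction.
    """

    sample_ids: list[str]
    feature_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_names = [str(f) for f in self.feature_names]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix (samples x features)")
        n, g = self.values.shape
        if n != len(self.sample_ids):
            raise ValueError(
                f"{len(self.sample_ids)} sample ids but {n} rows of values"
            )
        if g != len(self.feature_names):
            raise ValueError(
                f"{len(self.feature_names)} feature names but {g} columns of values"
            )
        if n < 2:
            raise ValueError("a feature table needs at least 2 samples")
        if g < 1:
            raise ValueError("a feature table needs at least 1 feature")
        dup = _duplicates(self.sample_ids)
        if dup:
            raise ValueError(f"duplicated sample ids: {sorted(dup)}")
        dup = _duplicates(self.feature_names)
        if dup:
            raise ValueError(f"duplicated feature names: {sorted(dup)}")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                "non-finite value at sample "
                f"{self.sample_ids[bad[0]]!r}, feature {self.feature_names[bad[1]]!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.feature_names
        )

    def copy_with(self, values: np.ndarray) -> "FeatureTable":
        """Same sample/feature labels, new values (shape-checked)."""
        return FeatureTable(list(self.sample_ids), list(self.feature_names), values)


@dataclass
class BatchDesign:
    """Per-sample batch labels plus optional biological covariates.

    Batch labels are nominal strings end-to-end; integer-looking labels carry
    no order.  ``covariates`` is an optional n x p real design matrix whose
    effect the harmonization must preserve.  ``reference_label`` marks the
    batch that reference-mode (M-/BM-) harmonization maps every other batch
    onto.
    """

    labels: np.ndarray
    covariates: Optional[np.ndarray] = None
    covariate_names: Optional[list[str]] = None
    reference_label: Optional[str] = None

    def __post_init__(self) -> None:
        self.labels = np.asarray([str(x) for x in np.asarray(self.labels).ravel()])
        if self.covariates is not None:
            self.covariates = np.asarray(self.covariates, dtype=float)
            if self.covariates.ndim == 1:
                self.covariates = self.covariates[:, None]
            if self.covariates.shape[0] != self.labels.shape[0]:
                raise ValueError("covariate rows must match number of samples")
            if not np.all(np.isfinite(self.covariates)):
                raise ValueError("covariates must be finite")
            p = self.covariates.shape[1]
            if self.covariate_names is None:
                self.covariate_names = [f"x{k}" for k in range(p)]
            if len(self.covariate_names) != p:
                raise ValueError("covariate_names must match covariate columns")
            if np.linalg.matrix_rank(self.covariates) < p:
                raise ValueError("covariate matrix is rank deficient")
        sizes = self.batch_sizes()
        small = [b for b, n in sizes.items() if n < 2]
        if small:
            warnings.warn(
                f"batches with fewer than 2 samples: {small}; "
                "location/scale estimates will be unreliable or impossible",
                stacklevel=2,
            )
        if self.reference_label is not None:
            self.reference_label = str(self.reference_label)
            if self.reference_label not in sizes:
                raise ValueError(
                    f"reference label {self.reference_label!r} not among batches "
                    f"{sorted(sizes)}"
                )

    @property
    def n_samples(self) -> int:
        return self.labels.shape[0]

    def batches(self) -> list[str]:
        """Unique batch labels in order of first appearance."""
        seen: dict[str, None] = {}
        for x in self.labels:
            seen.setdefault(x)
        return list(seen)

    def batch_sizes(self) -> dict[str, int]:
        return {b: int(np.sum(self.labels == b)) for b in self.batches()}

    def batch_indices(self) -> dict[str, np.ndarray]:
        return {b: np.flatnonzero(self.labels == b) for b in self.batches()}

    def largest_batch(self) -> str:
        sizes = self.batch_sizes()
        return max(sizes, key=lambda b: sizes[b])

    def subset(self, idx: np.ndarray) -> "BatchDesign":
        return BatchDesign(
            labels=self.labels[idx],
            covariates=None if self.covariates is None else self.covariates[idx],
            covariate_names=self.covariate_names,
            reference_label=self.reference_label,
        )


@dataclass
class RunConfig:
    """Run-level configuration for a harmonization + evaluation pass."""

    variant: str = "combat"
    prior: str = "nonparametric"
    n_bootstrap: int = 1000
    seed: int = 0
    anova_alpha: float = 0.01
    cluster_k_range: tuple[int, int] = (2, 10)
    reference_label: Optional[str] = None
    bootstrap_mode: str = "case"
    literal_bootstrap_form: bool = False

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        if self.prior not in PRIORS:
            raise ValueError(f"prior must be one of {PRIORS}, got {self.prior!r}")
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")
        if not (0.0 < self.anova_alpha < 1.0):
            raise ValueError("anova_alpha must lie in (0, 1)")
        lo, hi = self.cluster_k_range
        if lo < 2 or hi < lo:
            raise ValueError("cluster_k_range must satisfy 2 <= k_min <= k_max")
        if self.bootstrap_mode not in ("case", "parametric"):
            raise ValueError("bootstrap_mode must be 'case' or 'parametric'")


def _duplicates(items: Sequence[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for x in items:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup
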