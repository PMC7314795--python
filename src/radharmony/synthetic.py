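"""Synthetic multicenter radiomic-like feature tables with known ground truth.

The generator implements exactly the generative model the harmonization
assumes:

    Y_ijg = alpha_g + X_ij beta_g + sigma_g * (gamma_ig + delta_ig * eps_ijg)

with eps iid standard Normal, gamma_ig an additive per-batch shift expressed
in sigma_g units and delta_ig a multiplicative per-batch scale distortion.
Because batch effects are injected in sigma_g units, "effect size" is
comparable across features regardless of their physical scale.

The binary outcome is drawn from a logistic model on the *pre-batch-effect*
biological signal (the eps values of a chosen set of informative features),
so biology is batch-independent by construction; an optional confounded mode
makes the event rate vary by batch to exercise downstream sanity checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .types import BatchDesign, FeatureTable

Range = tuple[float, float]


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic multicenter cohort.

    ``gamma`` controls the per-batch additive shifts (in sigma_g units):

    * a scalar s draws gamma_ig ~ Uniform(-s, s) — continuous shifts with
      dense bounded support, so no feature's batch effect is an isolated
      outlier among the others (default);
    * a (lo, hi) range draws magnitudes uniformly, with a random sign per
      batch and feature when ``alternate_shift_signs`` is set;
    * an explicit (I x G) array is used as-is.

    ``delta`` (multiplicative scale distortions) may be a (lo, hi) range or
    an array.  Base feature means and scales are drawn from their ranges per
    feature, emulating the wildly different physical units of radiomic
    features.
    """

    batch_sizes: Sequence[int] = (60, 60, 60)
    n_features: int = 100
    base_mean_range: Range = (-5.0, 50.0)
    base_scale_range: Range = (0.5, 5.0)
    gamma: Union[float, Range, np.ndarray] = 3.5
    delta: Union[Range, np.ndarray] = (0.7, 1.4)
    alternate_shift_signs: bool = True
    covariate_effect: Optional[float] = None
    n_informative: int = 5
    outcome_effect: float = 1.0
    event_rate: float = 0.25
    confounded_outcome: bool = False
    equicorrelation: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.batch_sizes) < 1:
            raise ValueError("need at least one batch")
        if any(n < 2 for n in self.batch_sizes):
            raise ValueError("every batch needs >= 2 samples")
        if self.n_features < 1:
            raise ValueError("need at least one feature")
        if not (0.0 < self.event_rate < 1.0):
            raise ValueError("event_rate must lie in (0, 1)")
        if not (0.0 <= self.equicorrelation < 1.0):
            raise ValueError("equicorrelation must lie in [0, 1)")
        if isinstance(self.delta, np.ndarray):
            if np.any(self.delta <= 0):
                raise ValueError("delta factors must be positive")
        elif self.delta[0] <= 0:
            raise ValueError("delta factors must be positive")
        if self.n_informative > self.n_features:
            raise ValueError("n_informative cannot exceed n_features")

    @property
    def n_batches(self) -> int:
        return len(self.batch_sizes)

    @property
    def n_samples(self) -> int:
        return int(sum(self.batch_sizes))


@dataclass
class SyntheticTruth:
    """Ground-truth parameters behind a generated table."""

    gamma: np.ndarray  # I x G, in sigma_g units
    delta: np.ndarray  # I x G, multiplicative
    alpha: np.ndarray  # G base means
    sigma: np.ndarray  # G base scales
    informative: np.ndarray  # indices of outcome-informative features
    outcome_coef: np.ndarray  # logistic coefficients on the informative eps
    outcome_intercept: float
    batch_order: list[str]

    def standardized_truth(
        self, batch_sizes: Sequence[int]
    ) -> tuple[np.ndarray, np.ndarray]:
        """The identifiable (gamma, delta) on the grand-standardized scale.

        Grand-mode standardization centers on the size-weighted batch mean and
        divides by the pooled within-batch SD, so the recoverable effects are
        gamma_z = (gamma - weighted mean gamma) / s and delta_z = delta / s
        with s^2 the size-weighted mean of delta^2.
        """
        w = np.asarray(batch_sizes, dtype=float)
        w /= w.sum()
        gbar = w @ self.gamma
        s = np.sqrt(w @ self.delta**2)
        return (self.gamma - gbar) / s, self.delta / s


def _draw(rng: np.random.Generator, spec_val, shape) -> np.ndarray:
    if isinstance(spec_val, np.ndarray):
        arr = np.broadcast_to(np.asarray(spec_val, dtype=float), shape)
        return arr.copy()
    lo, hi = spec_val
    return rng.uniform(lo, hi, size=shape)


def generate(
    spec: SyntheticSpec,
) -> tuple[FeatureTable, BatchDesign, np.ndarray, SyntheticTruth]:
    """Generate (table, design, outcome, truth), fully reproducible from the seed."""
    rng = np.random.default_rng(spec.seed)
    I, G, n = spec.n_batches, spec.n_features, spec.n_samples
    sizes = list(spec.batch_sizes)

    alpha = rng.uniform(*spec.base_mean_range, size=G)
    sigma = rng.uniform(*spec.base_scale_range, size=G)
    if isinstance(spec.gamma, (int, float)):
        s = float(spec.gamma)
        gamma = rng.uniform(-s, s, size=(I, G))
    else:
        gamma = _draw(rng, spec.gamma, (I, G))
        if spec.alternate_shift_signs and not isinstance(spec.gamma, np.ndarray) and I > 1:
            # give each batch-feature shift a random sign: magnitudes drawn
            # from the same one-sided range would otherwise nearly coincide
            # across batches and leave no between-batch difference to
            # correct, and all centers would shift along the same direction
            # in feature space (scanner effects hit different feature
            # families differently)
            gamma = gamma * rng.choice([-1.0, 1.0], size=(I, G))
    delta = _draw(rng, spec.delta, (I, G))

    labels = np.concatenate(
        [np.repeat(f"batch{i + 1}", sizes[i]) for i in range(I)]
    )
    if spec.equicorrelation > 0:
        # shared latent factor induces pairwise correlation rho among features
        rho = spec.equicorrelation
        shared = rng.standard_normal((n, 1))
        eps = np.sqrt(rho) * shared + np.sqrt(1 - rho) * rng.standard_normal((n, G))
    else:
        eps = rng.standard_normal((n, G))

    covariates = None
    beta = np.zeros(G)
    if spec.covariate_effect is not None:
        covariates = rng.standard_normal((n, 1))
        beta = np.full(G, float(spec.covariate_effect))

    y = np.empty((n, G))
    start = 0
    for i in range(I):
        stop = start + sizes[i]
        y[start:stop] = alpha + sigma * (gamma[i] + delta[i] * eps[start:stop])
        start = stop
    if covariates is not None:
        y += covariates @ beta[None, :]

    informative = rng.choice(G, size=spec.n_informative, replace=False)
    coef = np.full(spec.n_informative, float(spec.outcome_effect))
    lp = eps[:, informative] @ coef

    def mean_rate(c: float) -> float:
        return float(expit(lp + c).mean()) - spec.event_rate

    intercept = brentq(mean_rate, -50.0, 50.0)
    p = expit(lp + intercept)
    if spec.confounded_outcome:
        # tilt per-batch event rates around the target to emulate outcome-
        # confounded clusters
        tilts = np.linspace(-1.0, 1.0, I)
        start = 0
        for i in range(I):
            stop = start + sizes[i]
            p[start:stop] = expit(lp[start:stop] + intercept + tilts[i])
            start = stop
    outcome = (rng.uniform(size=n) < p).astype(int)

    table = FeatureTable(
        [f"s{j:04d}" for j in range(n)],
        [f"feat{g:03d}" for g in range(G)],
        y,
    )
    design = BatchDesign(
        labels=labels,
        covariates=covariates,
        covariate_names=["cov0"] if covariates is not None else None,
    )
    truth = SyntheticTruth(
        gamma=gamma,
        delta=delta,
        alpha=alpha,
        sigma=sigma,
        informative=np.sort(informative),
        outcome_coef=coef,
        outcome_intercept=float(intercept),
        batch_order=[f"batch{i + 1}" for i in range(I)],
    )
    return table, design, outcome, truth


def shift_recovery_spec(
    seed: int = 0,
    n_per_batch: int = 50,
    n_features: int = 100,
    shift_levels: Sequence[float] = (-1.5, 0.0, 1.5),
    shift_jitter: float = 0.15,
    scale_levels: Sequence[float] = (0.8, 1.0, 1.25),
    scale_jitter: float = 0.05,
    batch_sizes: Optional[Sequence[int]] = None,
    **kwargs,
) -> SyntheticSpec:
    """A homogeneous-batch-effect study with known ground truth.

    Each batch's additive shift is its level plus Normal(0, shift_jitter^2)
    per-feature jitter, and its scale factor the level times a lognormal
    jitter — the regime the empirical-Bayes prior models (a center affects
    all features similarly in sigma units), where pooling across features
    genuinely stabilizes the per-feature estimates.  ``batch_sizes``
    overrides the equal ``n_per_batch`` split; extra keyword arguments pass
    through to :class:`SyntheticSpec`.
    """
    rng = np.random.default_rng((seed + 1_000_003) % (2**31 - 1))
    I, G = len(shift_levels), n_features
    if batch_sizes is None:
        batch_sizes = tuple([n_per_batch] * I)
    elif len(batch_sizes) != I:
        raise ValueError("batch_sizes must match the number of shift levels")
    gamma = np.asarray(shift_levels, dtype=float)[:, None] + rng.normal(
        0.0, shift_jitter, size=(I, G)
    )
    delta = np.asarray(scale_levels, dtype=float)[:, None] * np.exp(
        rng.normal(0.0, scale_jitter, size=(I, G))
    )
    return SyntheticSpec(
        batch_sizes=tuple(batch_sizes),
        n_features=G,
        gamma=gamma,
        delta=delta,
        seed=seed,
        **kwargs,
    )


def lacc_like_preset(seed: int = 0) -> SyntheticSpec:
    """A cohort shaped like a 3-center cervical-cancer PET/MR study:
    197 patients split 119/50/28, 173 features, 34% event rate."""
    return SyntheticSpec(
        batch_sizes=(119, 50, 28),
        n_features=173,
        gamma=3.5,
        delta=(0.7, 1.4),
        event_rate=0.34,
        seed=seed,
    )


def lalc_like_preset(seed: int = 0) -> SyntheticSpec:
    """A cohort shaped like a 2-cluster laryngeal-cancer CE-CT study:
    98 patients split 60/38, 173 features, 15% event rate."""
    return SyntheticSpec(
        batch_sizes=(60, 38),
        n_features=173,
        gamma=3.5,
        delta=(0.7, 1.4),
        event_rate=0.15,
        seed=seed,
    )
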