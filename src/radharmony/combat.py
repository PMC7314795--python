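"""The four-variant ComBat harmonization engine.

Location-scale batch-effect model: observed feature values decompose as

    Y_ijg = alpha_g + X_ij beta_g + sigma_g (gamma_ig + delta_ig eps_ijg)

for batch i, sample j, feature g, with gamma the additive and delta the
multiplicative per-batch distortion.  Harmonization proceeds in three steps:
(1) standardize to Z, (2) estimate per-batch location/scale effects on Z and
stabilize them by empirical-Bayes shrinkage pooling across features (Normal
prior on gamma, Inverse-Gamma prior on delta^2, hyperparameters by method of
moments), (3) remove the shrunken effects and restore the target location
and scale.

Variants:

* ``combat``    — grand-mean standardization; output centered on the pooled
                  cohort location/scale.
* ``m-combat``  — batchwise standardization; output mapped onto a chosen
                  reference batch's location/scale, leaving the reference
                  batch (essentially) untouched.
* ``b-combat``  / ``bm-combat`` — same functional forms, but every
                  coefficient is the Monte-Carlo mean over B stratified
                  bootstrap refits, stabilizing the estimation.

The grand-mode parametric and nonparametric paths reproduce the standard
reference implementation (the sva lineage) to numerical
precision: pooled variance with the 1/N divisor, within-batch delta^2 with
the n-1 divisor, the same method-of-moments hyperparameters, the same
iterative parametric posterior solution and the same Monte-Carlo
nonparametric integration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .types import BatchDesign, FeatureTable, RunConfig

logger = logging.getLogger(__name__)

__all__ = [
    "StandardizationEstimates",
    "StandardizedData",
    "BatchEffectEstimates",
    "PriorHyperparameters",
    "HarmonizationModel",
    "fit_standardization",
    "estimate_batch_effects",
    "fit_priors_and_shrink",
    "adjust",
    "bootstrap_fit",
    "apply_model",
    "harmonize",
]


# ---------------------------------------------------------------------------
# model containers
# ---------------------------------------------------------------------------


@dataclass
class StandardizationEstimates:
    """OLS location/scale estimates used to form Z.

    ``mode='grand'``: alpha is the per-feature grand intercept (weighted mean
    of batch intercepts, shape G) and sigma the pooled residual SD (shape G).
    ``mode='batchwise'``: alpha and sigma are per-batch per-feature (I x G).
    ``beta`` holds covariate coefficients (p x G), empty if no covariates.
    """

    mode: str
    alpha: np.ndarray
    sigma: np.ndarray
    beta: np.ndarray
    batch_order: list[str]

    def __post_init__(self) -> None:
        if self.mode not in ("grand", "batchwise"):
            raise ValueError("mode must be 'grand' or 'batchwise'")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma estimates must be strictly positive")


@dataclass
class StandardizedData:
    z: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.z)):
            raise ValueError("standardized data contains non-finite values")


@dataclass
class BatchEffectEstimates:
    """Raw and (optionally) EB-shrunken batch effects, shape I x G each."""

    batch_order: list[str]
    gamma_hat: np.ndarray
    delta2_hat: np.ndarray
    gamma_star: Optional[np.ndarray] = None
    delta2_star: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if np.any(self.delta2_hat <= 0):
            raise ValueError("raw delta^2 estimates must be strictly positive")
        if self.delta2_star is not None and np.any(self.delta2_star <= 0):
            raise ValueError("shrunken delta^2 estimates must be strictly positive")


@dataclass
class PriorHyperparameters:
    """Method-of-moments hyperparameters, one entry per batch.

    gamma_ig ~ Normal(gamma_bar_i, tau2_i); delta2_ig ~ InvGamma(a_i, b_i).
    """

    batch_order: list[str]
    gamma_bar: np.ndarray
    tau2: np.ndarray
    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        import warnings

        if np.any(self.tau2 < 0):
            raise ValueError("prior variance tau2 must be non-negative")
        if np.any(self.tau2 == 0):
            warnings.warn(
                "degenerate gamma prior (tau2 = 0): all features share the same "
                "raw location effect; shrinkage will return it unchanged",
                stacklevel=2,
            )
        if np.any(self.a <= 1):
            warnings.warn(
                "Inverse-Gamma shape <= 1 for some batch: prior mean of delta^2 "
                "is infinite; estimates may be unstable",
                stacklevel=2,
            )


@dataclass
class HarmonizationModel:
    """Everything needed to audit or re-apply a fitted harmonization."""

    variant: str
    prior: str
    standardization: StandardizationEstimates
    effects: BatchEffectEstimates
    hyperparameters: Optional[PriorHyperparameters]
    reference_label: Optional[str] = None
    n_bootstrap: Optional[int] = None
    seed: Optional[int] = None
    n_degenerate_redraws: int = 0

    def __post_init__(self) -> None:
        is_boot = self.variant in ("b-combat", "bm-combat")
        if is_boot and self.n_bootstrap is None:
            raise ValueError("bootstrap variants must record n_bootstrap")
        if not is_boot and self.n_bootstrap is not None:
            raise ValueError("non-bootstrap variants must not carry n_bootstrap")

    def to_dict(self) -> dict:
        hp = self.hyperparameters
        return {
            "variant": self.variant,
            "prior": self.prior,
            "reference_label": self.reference_label,
            "n_bootstrap": self.n_bootstrap,
            "seed": self.seed,
            "n_degenerate_redraws": self.n_degenerate_redraws,
            "batch_order": self.effects.batch_order,
            "standardization": {
                "mode": self.standardization.mode,
                "alpha": self.standardization.alpha.tolist(),
                "sigma": self.standardization.sigma.tolist(),
                "beta": self.standardization.beta.tolist(),
            },
            "effects": {
                "gamma_hat": self.effects.gamma_hat.tolist(),
                "delta2_hat": self.effects.delta2_hat.tolist(),
                "gamma_star": self.effects.gamma_star.tolist(),
                "delta2_star": self.effects.delta2_star.tolist(),
            },
            "hyperparameters": None
            if hp is None
            else {
                "gamma_bar": hp.gamma_bar.tolist(),
                "tau2": hp.tau2.tolist(),
                "a": hp.a.tolist(),
                "b": hp.b.tolist(),
            },
        }


# ---------------------------------------------------------------------------
# step 1: standardization
# ---------------------------------------------------------------------------


def _check_variances(
    var: np.ndarray, feature_names: list[str], where: str, drop_degenerate: bool
) -> np.ndarray:
    """Return boolean keep-mask over features; error on zero variance unless dropping."""
    bad = ~(var > 0)
    if bad.ndim == 2:
        bad = bad.any(axis=0)
    if bad.any():
        names = [feature_names[j] for j in np.flatnonzero(bad)]
        if not drop_degenerate:
            raise ValueError(
                f"zero-variance feature(s) {where}: {names}; "
                "drop them or pass drop_degenerate"
            )
        logger.warning("dropping %d degenerate feature(s) %s: %s", len(names), where, names)
    return ~bad


def drop_degenerate_features(
    table: FeatureTable, design: BatchDesign, mode: str = "grand"
) -> FeatureTable:
    """Remove features with zero pooled (grand) or within-batch (batchwise) variance."""
    within = np.stack(
        [table.values[idx].var(axis=0) for idx in design.batch_indices().values()]
    )
    # grand mode only needs some within-batch spread; batchwise needs it in
    # every batch
    var = within.max(axis=0) if mode == "grand" else within
    keep = _check_variances(var, table.feature_names, f"({mode} mode)", True)
    if keep.all():
        return table
    return FeatureTable(
        list(table.sample_ids),
        [f for f, k in zip(table.feature_names, keep) if k],
        table.values[:, keep],
    )


def _ols_fit(
    y: np.ndarray, design: BatchDesign
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Joint OLS on batch indicators + covariates.

    Returns (batch_coefs I x G, beta p x G, fitted_covariate_part n x G).
    """
    batches = design.batches()
    n = y.shape[0]
    dmat = np.zeros((n, len(batches)))
    for i, b in enumerate(batches):
        dmat[design.labels == b, i] = 1.0
    if design.covariates is not None:
        dmat = np.hstack([dmat, design.covariates])
    coef, *_ = np.linalg.lstsq(dmat, y, rcond=None)
    batch_coefs = coef[: len(batches)]
    beta = coef[len(batches):]
    xbeta = (
        design.covariates @ beta
        if design.covariates is not None
        else np.zeros_like(y)
    )
    return batch_coefs, beta, xbeta


def fit_standardization(
    table: FeatureTable,
    design: BatchDesign,
    mode: str = "grand",
    drop_degenerate: bool = False,
) -> tuple[StandardizedData, StandardizationEstimates, FeatureTable]:
    """Standardize Y to Z under the grand (Eq-1 style) or batchwise model.

    Grand mode: Z = (Y - alpha_g - X beta_g) / sigma_g with alpha_g the
    sample-size-weighted mean of batch intercepts and sigma_g^2 the pooled
    residual variance (1/N divisor).  Batchwise mode: per-batch intercept and
    scale (ddof=1), so Z has mean 0 and unit sample variance inside every
    batch.  Returns the (possibly degeneracy-pruned) table actually used.
    """
    if mode not in ("grand", "batchwise"):
        raise ValueError("mode must be 'grand' or 'batchwise'")
    if design.n_samples != table.n_samples:
        raise ValueError("table and design disagree on sample count")
    if drop_degenerate:
        table = drop_degenerate_features(table, design, mode)
    y = table.values
    batches = design.batches()
    sizes = design.batch_sizes()
    n = table.n_samples

    batch_coefs, beta, xbeta = _ols_fit(y, design)

    # degeneracy is judged on exact within-batch constancy, not on the
    # residual variance, which carries ~1e-30 lstsq rounding for constant
    # features
    within_var = np.stack(
        [y[design.labels == b].var(axis=0) for b in batches]
    )
    if mode == "grand":
        _check_variances(
            within_var.max(axis=0), table.feature_names, "(pooled)", False
        )
        weights = np.array([sizes[b] / n for b in batches])
        alpha = weights @ batch_coefs  # (G,)
        resid = y - xbeta
        for i, b in enumerate(batches):
            resid[design.labels == b] -= batch_coefs[i]
        var_pooled = (resid**2).mean(axis=0)  # 1/N divisor, as in reference ComBat
        sigma = np.sqrt(var_pooled)
        z = (y - alpha[None, :] - xbeta) / sigma[None, :]
        est = StandardizationEstimates("grand", alpha, sigma, beta, batches)
    else:
        yc = y - xbeta
        alpha = np.zeros((len(batches), table.n_features))
        sigma = np.zeros_like(alpha)
        z = np.empty_like(y)
        for i, b in enumerate(batches):
            idx = design.labels == b
            if sizes[b] < 2:
                raise ValueError(f"batch {b!r} has < 2 samples: cannot standardize")
            alpha[i] = yc[idx].mean(axis=0)
            var_i = yc[idx].var(axis=0, ddof=1)
            _check_variances(var_i, table.feature_names, f"(batch {b!r})", False)
            sigma[i] = np.sqrt(var_i)
            z[idx] = (yc[idx] - alpha[i]) / sigma[i]
        est = StandardizationEstimates("batchwise", alpha, sigma, beta, batches)
    return StandardizedData(z), est, table


# ---------------------------------------------------------------------------
# step 2: batch effects + empirical Bayes shrinkage
# ---------------------------------------------------------------------------


def estimate_batch_effects(
    z: StandardizedData, design: BatchDesign
) -> BatchEffectEstimates:
    """Raw per-batch location/scale effects on the standardized scale.

    gamma_hat_ig is the within-batch mean of Z, delta2_hat_ig the within-batch
    sample variance (ddof=1).
    """
    batches = design.batches()
    g = z.z.shape[1]
    gamma = np.zeros((len(batches), g))
    delta2 = np.zeros_like(gamma)
    for i, b in enumerate(batches):
        idx = design.labels == b
        ni = int(idx.sum())
        if ni < 2:
            raise ValueError(
                f"batch {b!r} has {ni} sample(s): within-batch variance undefined"
            )
        gamma[i] = z.z[idx].mean(axis=0)
        delta2[i] = z.z[idx].var(axis=0, ddof=1)
        if np.any(delta2[i] <= 0):
            raise ValueError(
                f"batch {b!r} has zero within-batch variance for some feature(s)"
            )
    return BatchEffectEstimates(batches, gamma, delta2)


def _aprior(d2: np.ndarray) -> float:
    m, s2 = d2.mean(), d2.var(ddof=1)
    return (2 * s2 + m**2) / s2


def _bprior(d2: np.ndarray) -> float:
    m, s2 = d2.mean(), d2.var(ddof=1)
    return (m * s2 + m**3) / s2


def _it_sol(
    z_batch: np.ndarray,
    g_hat: np.ndarray,
    d2_hat: np.ndarray,
    g_bar: float,
    t2: float,
    a: float,
    b: float,
    conv: float = 1e-4,
    max_iter: int = 500,
) -> tuple[np.ndarray, np.ndarray]:
    """Iterative conditional posterior means under Normal/Inverse-Gamma conjugacy."""
    n = z_batch.shape[0]
    g_old = g_hat.copy()
    d_old = d2_hat.copy()
    for it in range(max_iter):
        g_new = (t2 * n * g_hat + d_old * g_bar) / (t2 * n + d_old)
        sum2 = ((z_batch - g_new[None, :]) ** 2).sum(axis=0)
        d_new = (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)
        # signed denominators, mirroring the reference implementation's
        # stopping rule so the iterates stop at the same count; an exactly
        # unchanged coefficient (e.g. gamma identically 0 in batchwise mode)
        # contributes no change rather than 0/0
        with np.errstate(divide="ignore", invalid="ignore"):
            rg = np.abs(g_new - g_old) / g_old
            rd = np.abs(d_new - d_old) / d_old
        rg[g_new == g_old] = 0.0
        rd[d_new == d_old] = 0.0
        change = max(np.max(rg), np.max(rd))
        g_old, d_old = g_new, d_new
        if change < conv:
            return g_new, d_new
    raise RuntimeError(
        f"parametric EB iteration did not converge within {max_iter} iterations "
        f"(last change {change:.3g}, tolerance {conv:g})"
    )


def _np_eprior(
    z_batch: np.ndarray, g_hat: np.ndarray, d2_hat: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Nonparametric Monte-Carlo posterior integration.

    Each feature's posterior effect is the likelihood-weighted average of every
    other feature's raw estimates, the weight being the Normal likelihood of
    the feature's standardized values under the other feature's (gamma, delta^2).
    Computed in log space (mathematically identical to the reference's direct
    product, without underflow).
    """
    n, g = z_batch.shape
    # log L[g, g'] = -n/2 log(2 pi d2_g') - sum_j (z_jg - gamma_g')^2 / (2 d2_g')
    sq = (z_batch[:, :, None] - g_hat[None, None, :]) ** 2  # n x g x g'
    sum2 = sq.sum(axis=0)  # g x g'
    logl = -0.5 * n * np.log(2 * np.pi * d2_hat)[None, :] - sum2 / (2 * d2_hat[None, :])
    np.fill_diagonal(logl, -np.inf)  # exclude the feature itself
    shift = logl.max(axis=1, keepdims=True)
    w = np.exp(logl - shift)
    w /= w.sum(axis=1, keepdims=True)
    return w @ g_hat, w @ d2_hat


def fit_priors_and_shrink(
    raw: BatchEffectEstimates,
    prior: str,
    z: Optional[StandardizedData] = None,
    design: Optional[BatchDesign] = None,
) -> tuple[Optional[PriorHyperparameters], BatchEffectEstimates]:
    """Empirical-Bayes shrinkage of the raw batch effects.

    ``prior='none'`` copies the raw estimates (diagnostic/oracle mode).  The
    parametric and nonparametric modes need the standardized data ``z`` and
    the ``design`` because the posterior solutions condition on it.
    """
    nbatch, g = raw.gamma_hat.shape
    if prior == "none":
        out = BatchEffectEstimates(
            raw.batch_order,
            raw.gamma_hat,
            raw.delta2_hat,
            raw.gamma_hat.copy(),
            raw.delta2_hat.copy(),
        )
        return None, out
    if prior not in ("parametric", "nonparametric"):
        raise ValueError(f"unknown prior {prior!r}")
    if g < 2:
        raise ValueError("EB shrinkage pools across features: need >= 2 features")
    if z is None or design is None:
        raise ValueError(f"prior={prior!r} requires the standardized data and design")

    gamma_bar = raw.gamma_hat.mean(axis=1)
    tau2 = raw.gamma_hat.var(axis=1, ddof=1)
    a = np.array([_aprior(raw.delta2_hat[i]) for i in range(nbatch)])
    b = np.array([_bprior(raw.delta2_hat[i]) for i in range(nbatch)])
    hp = PriorHyperparameters(raw.batch_order, gamma_bar, tau2, a, b)

    gamma_star = np.empty_like(raw.gamma_hat)
    delta2_star = np.empty_like(raw.delta2_hat)
    for i, bname in enumerate(raw.batch_order):
        zb = z.z[design.labels == bname]
        if prior == "parametric":
            gamma_star[i], delta2_star[i] = _it_sol(
                zb, raw.gamma_hat[i], raw.delta2_hat[i], gamma_bar[i], tau2[i], a[i], b[i]
            )
        else:
            gamma_star[i], delta2_star[i] = _np_eprior(
                zb, raw.gamma_hat[i], raw.delta2_hat[i]
            )
    out = BatchEffectEstimates(
        raw.batch_order, raw.gamma_hat, raw.delta2_hat, gamma_star, delta2_star
    )
    return hp, out


# ---------------------------------------------------------------------------
# step 3: adjustment
# ---------------------------------------------------------------------------


def adjust(
    z: StandardizedData,
    est: StandardizationEstimates,
    eff: BatchEffectEstimates,
    design: BatchDesign,
    table: FeatureTable,
    mode: str = "grand",
    reference_label: Optional[str] = None,
) -> FeatureTable:
    """Remove the shrunken batch effects and restore the target location/scale.

    Grand mode restores the pooled location/scale; reference mode restores the
    reference batch's own location/scale, so harmonized values stay on that
    batch's physical scale.
    """
    if eff.gamma_star is None or eff.delta2_star is None:
        raise ValueError("batch effects have not been shrunken (or prior='none' copied)")
    unseen = [b for b in design.batches() if b not in eff.batch_order]
    if unseen:
        raise ValueError(
            f"batch label(s) {unseen} were not seen at fit time; the model "
            "cannot extrapolate to unseen batches"
        )
    xbeta = (
        design.covariates @ est.beta
        if design.covariates is not None
        else np.zeros_like(z.z)
    )
    if mode == "grand":
        scale_target = est.sigma[None, :]
        loc_target = est.alpha[None, :] + xbeta
    elif mode == "reference":
        if reference_label is None:
            raise ValueError("reference mode needs a reference label")
        if est.mode != "batchwise":
            raise ValueError("reference-mode adjustment needs batchwise standardization")
        r = est.batch_order.index(reference_label)
        scale_target = est.sigma[r][None, :]
        loc_target = est.alpha[r][None, :] + xbeta
    else:
        raise ValueError("mode must be 'grand' or 'reference'")

    out = np.empty_like(z.z)
    for i, b in enumerate(eff.batch_order):
        idx = design.labels == b
        if not idx.any():
            continue
        out[idx] = (
            scale_target
            / np.sqrt(eff.delta2_star[i])[None, :]
            * (z.z[idx] - eff.gamma_star[i][None, :])
        )
    out += loc_target
    return table.copy_with(out)


# ---------------------------------------------------------------------------
# bootstrap-stabilized fitting (B-ComBat / BM-ComBat)
# ---------------------------------------------------------------------------


def _point_fit(
    table: FeatureTable,
    design: BatchDesign,
    mode: str,
    prior: str,
) -> tuple[StandardizedData, StandardizationEstimates, BatchEffectEstimates, Optional[PriorHyperparameters]]:
    std_mode = "grand" if mode == "grand" else "batchwise"
    z, est, _ = fit_standardization(table, design, std_mode)
    raw = estimate_batch_effects(z, design)
    hp, eff = fit_priors_and_shrink(raw, prior, z, design)
    return z, est, eff, hp


def bootstrap_fit(
    table: FeatureTable,
    design: BatchDesign,
    mode: str,
    B: int,
    seed: int,
    prior: str = "nonparametric",
    bootstrap_mode: str = "case",
    reference_label: Optional[str] = None,
) -> HarmonizationModel:
    """Fit ComBat/M-ComBat coefficients as Monte-Carlo means over B bootstrap refits.

    Samples are resampled with replacement stratified within batch ("case"
    mode) or drawn from the fitted Normal location-scale model ("parametric"
    mode); the full estimation is re-run on each resample and the coefficient
    sets are averaged arithmetically.  Resamples leaving any batch with a
    zero-variance feature are redrawn and counted; more than 50% redraws is an
    error.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    sizes = design.batch_sizes()
    small = [b for b, n in sizes.items() if n < 3]
    if small:
        raise ValueError(
            f"bootstrap variants need >= 3 samples per batch; too small: {small}"
        )
    rng = np.random.default_rng(seed)
    batches = design.batches()
    idx_by_batch = design.batch_indices()

    # point fit: fixes the batch order, provides the generative model for the
    # parametric bootstrap, and anchors the output containers
    z0, est0, eff0, hp0 = _point_fit(table, design, mode, prior)

    # coefficients are averaged in the raw-data frame: each resample's
    # (gamma*, delta*) live on that resample's own standardized scale, so
    # averaging them directly would mix incommensurate frames and accumulate
    # ratio (Jensen) biases from the fluctuating sigma_k.  The raw-frame
    # per-batch location m = alpha + sigma*gamma* and scale s = sigma*delta*
    # are frame-free; their means reduce to the single-fit coefficients at
    # B=1 and are converted back to standardized-scale coefficients at the
    # end.
    sum_alpha = np.zeros_like(est0.alpha)
    sum_sigma = np.zeros_like(est0.sigma)
    sum_beta = np.zeros_like(est0.beta)
    sum_loc_star = np.zeros_like(eff0.gamma_star)
    sum_scale_star = np.zeros_like(eff0.delta2_star)
    sum_loc_hat = np.zeros_like(eff0.gamma_hat)
    sum_scale_hat = np.zeros_like(eff0.delta2_hat)

    def _raw_frame(est_k, eff_k):
        if est_k.mode == "grand":
            a = est_k.alpha[None, :]
            s = est_k.sigma[None, :]
        else:
            a = est_k.alpha
            s = est_k.sigma
        loc_star = a + s * eff_k.gamma_star
        scale_star = s * np.sqrt(eff_k.delta2_star)
        loc_hat = a + s * eff_k.gamma_hat
        scale_hat = s * np.sqrt(eff_k.delta2_hat)
        return loc_star, scale_star, loc_hat, scale_hat

    n_redraws = 0
    max_attempts = 2 * B + 10
    done = 0
    while done < B:
        if n_redraws > max_attempts - B:
            raise RuntimeError(
                f"more than 50% of bootstrap resamples were degenerate "
                f"({n_redraws} redraws for {done} accepted); use larger batches "
                "or a smaller B"
            )
        if bootstrap_mode == "case":
            rows = np.concatenate(
                [rng.choice(idx_by_batch[b], size=sizes[b], replace=True) for b in batches]
            )
            rt = FeatureTable(
                [f"s{t}" for t in range(table.n_samples)],
                list(table.feature_names),
                table.values[rows],
            )
            rd = design.subset(rows)
        else:  # model-based parametric bootstrap: simulate Z ~ N(gamma, delta2)
            zsim = np.empty_like(z0.z)
            for i, b in enumerate(batches):
                idx = design.labels == b
                zsim[idx] = rng.normal(
                    eff0.gamma_hat[i], np.sqrt(eff0.delta2_hat[i]), size=zsim[idx].shape
                )
            xbeta = (
                design.covariates @ est0.beta
                if design.covariates is not None
                else 0.0
            )
            if est0.mode == "grand":
                ysim = zsim * est0.sigma[None, :] + est0.alpha[None, :] + xbeta
            else:
                ysim = np.empty_like(zsim)
                for i, b in enumerate(batches):
                    idx = design.labels == b
                    ysim[idx] = zsim[idx] * est0.sigma[i] + est0.alpha[i]
                ysim += xbeta
            rt = table.copy_with(ysim)
            rd = design
        try:
            _, est_k, eff_k, _ = _point_fit(rt, rd, mode, prior)
        except (ValueError, RuntimeError):
            n_redraws += 1
            continue
        # the resample's batch order matches: subset() and copy preserve labels
        loc_star, scale_star, loc_hat, scale_hat = _raw_frame(est_k, eff_k)
        sum_alpha += est_k.alpha
        sum_sigma += est_k.sigma
        sum_beta += est_k.beta
        sum_loc_star += loc_star
        sum_scale_star += scale_star
        sum_loc_hat += loc_hat
        sum_scale_hat += scale_hat
        done += 1

    alpha_bar = sum_alpha / B
    sigma_bar = sum_sigma / B
    est_bar = StandardizationEstimates(
        est0.mode, alpha_bar, sigma_bar, sum_beta / B, batches
    )
    a_b = alpha_bar[None, :] if est0.mode == "grand" else alpha_bar
    s_b = sigma_bar[None, :] if est0.mode == "grand" else sigma_bar
    eff_bar = BatchEffectEstimates(
        batches,
        (sum_loc_hat / B - a_b) / s_b,
        (sum_scale_hat / B / s_b) ** 2,
        (sum_loc_star / B - a_b) / s_b,
        (sum_scale_star / B / s_b) ** 2,
    )
    variant = "b-combat" if mode == "grand" else "bm-combat"
    return HarmonizationModel(
        variant=variant,
        prior=prior,
        standardization=est_bar,
        effects=eff_bar,
        hyperparameters=hp0,
        reference_label=reference_label,
        n_bootstrap=B,
        seed=seed,
        n_degenerate_redraws=n_redraws,
    )


# ---------------------------------------------------------------------------
# top-level dispatch
# ---------------------------------------------------------------------------


def _literal_adjust(
    table: FeatureTable,
    design: BatchDesign,
    est: StandardizationEstimates,
    eff: BatchEffectEstimates,
    mode: str,
    reference_label: Optional[str],
) -> FeatureTable:
    """The literal bootstrap adjustment form: divide the centered raw values by
    delta* without the sigma rescaling.  Changes the output scale; kept as an
    explicitly requested alternative behaviour."""
    xbeta = (
        design.covariates @ est.beta
        if design.covariates is not None
        else np.zeros_like(table.values)
    )
    if mode == "grand":
        loc = est.alpha[None, :] + xbeta
    else:
        r = est.batch_order.index(reference_label)
        loc = est.alpha[r][None, :] + xbeta
    out = np.empty_like(table.values)
    for i, b in enumerate(eff.batch_order):
        idx = design.labels == b
        out[idx] = (table.values[idx] - loc[idx] - eff.gamma_star[i][None, :]) / np.sqrt(
            eff.delta2_star[i]
        )[None, :]
    out += loc
    return table.copy_with(out)


def apply_model(
    table: FeatureTable,
    design: BatchDesign,
    model: HarmonizationModel,
) -> FeatureTable:
    """Re-apply a fitted harmonization to rows from the same batches.

    Every batch label must have been seen at fit time — the location-scale
    model carries no information about unseen batches and cannot
    extrapolate to them.
    """
    est, eff = model.standardization, model.effects
    unseen = [b for b in design.batches() if b not in eff.batch_order]
    if unseen:
        raise ValueError(
            f"batch label(s) {unseen} were not seen at fit time; the model "
            "cannot extrapolate to unseen batches"
        )
    xbeta = (
        design.covariates @ est.beta
        if design.covariates is not None
        else np.zeros_like(table.values)
    )
    if est.mode == "grand":
        z = StandardizedData(
            (table.values - est.alpha[None, :] - xbeta) / est.sigma[None, :]
        )
        mode = "grand"
    else:
        zm = np.empty_like(table.values)
        for i, b in enumerate(est.batch_order):
            idx = design.labels == b
            if idx.any():
                zm[idx] = (table.values[idx] - xbeta[idx] - est.alpha[i]) / est.sigma[i]
        z = StandardizedData(zm)
        mode = "reference"
    return adjust(z, est, eff, design, table, mode, model.reference_label)


def harmonize(
    table: FeatureTable,
    design: BatchDesign,
    config: RunConfig,
) -> tuple[FeatureTable, HarmonizationModel]:
    """Run one of the four harmonization variants end to end.

    For the reference-mode variants (m-combat, bm-combat) the reference batch
    is ``config.reference_label`` or ``design.reference_label``; when neither
    is set the largest batch is used, and logged.
    """
    variant = config.variant
    mode = "grand" if variant in ("combat", "b-combat") else "reference"
    ref = None
    if mode == "reference":
        ref = config.reference_label or design.reference_label
        if ref is None:
            ref = design.largest_batch()
            logger.info("no reference label given: using largest batch %r", ref)
        if ref not in design.batches():
            raise ValueError(f"reference label {ref!r} not among batches")

    if variant in ("combat", "m-combat"):
        z, est, table_used, = fit_standardization(
            table, design, "grand" if mode == "grand" else "batchwise"
        )
        raw = estimate_batch_effects(z, design)
        hp, eff = fit_priors_and_shrink(raw, config.prior, z, design)
        model = HarmonizationModel(
            variant=variant,
            prior=config.prior,
            standardization=est,
            effects=eff,
            hyperparameters=hp,
            reference_label=ref,
        )
        out = adjust(z, est, eff, design, table_used, mode, ref)
    else:
        model = bootstrap_fit(
            table,
            design,
            mode,
            B=config.n_bootstrap,
            seed=config.seed,
            prior=config.prior,
            bootstrap_mode=config.bootstrap_mode,
            reference_label=ref,
        )
        est, eff = model.standardization, model.effects
        if config.literal_bootstrap_form:
            out = _literal_adjust(table, design, est, eff, mode, ref)
        else:
            # standardize the original data with the averaged coefficients and
            # apply the usual adjustment form
            xbeta = (
                design.covariates @ est.beta
                if design.covariates is not None
                else np.zeros_like(table.values)
            )
            if est.mode == "grand":
                z = StandardizedData(
                    (table.values - est.alpha[None, :] - xbeta) / est.sigma[None, :]
                )
            else:
                zm = np.empty_like(table.values)
                for i, b in enumerate(est.batch_order):
                    idx = design.labels == b
                    zm[idx] = (table.values[idx] - xbeta[idx] - est.alpha[i]) / est.sigma[i]
                z = StandardizedData(zm)
            out = adjust(z, est, eff, design, table, mode, ref)
    logger.info(
        "harmonized %d samples x %d features with %s (prior=%s)",
        table.n_samples,
        table.n_features,
        variant,
        config.prior,
    )
    return out, model
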