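"""Unit and property tests for the location-scale harmonization engine."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from radharmony import BatchDesign, FeatureTable, RunConfig, apply_model, harmonize
from radharmony.combat import (
    StandardizedData,
    adjust,
    bootstrap_fit,
    estimate_batch_effects,
    fit_priors_and_shrink,
    fit_standardization,
)

from conftest import random_table


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------


def closed_form_grand(values, labels):
    """Independent transcription of grand-mode prior=none harmonization:
    per-batch z-score (ddof=1) rescaled to the pooled scale (1/N residual
    variance) and the size-weighted grand mean."""
    out = np.empty_like(values)
    batches = list(dict.fromkeys(labels))
    n = len(labels)
    grand = np.zeros(values.shape[1])
    resid_ss = np.zeros(values.shape[1])
    for b in batches:
        idx = labels == b
        grand += idx.sum() / n * values[idx].mean(axis=0)
        resid_ss += ((values[idx] - values[idx].mean(axis=0)) ** 2).sum(axis=0)
    pooled_sd = np.sqrt(resid_ss / n)
    for b in batches:
        idx = labels == b
        z = (values[idx] - values[idx].mean(axis=0)) / values[idx].std(axis=0, ddof=1)
        out[idx] = z * pooled_sd + grand
    return out


def test_grand_standardization_matches_direct_transcription(toy_ab):
    table, design = toy_ab
    z, est, _ = fit_standardization(table, design, "grand")
    assert est.alpha[0] == pytest.approx(7.0)
    # pooled residual variance with the 1/N divisor: (1+0+1+1+0+1)/6
    assert est.sigma[0] ** 2 == pytest.approx(4.0 / 6.0)
    expect = (table.values - 7.0) / np.sqrt(4.0 / 6.0)
    np.testing.assert_allclose(z.z, expect, atol=1e-12)


def test_grand_z_has_mean_zero_single_batch():
    table = FeatureTable(["a", "b", "c"], ["f"], np.array([[1.0], [2.0], [3.0]]))
    design = BatchDesign(labels=np.array(["x", "x", "x"]))
    z, _, _ = fit_standardization(table, design, "grand")
    assert z.z.mean() == pytest.approx(0.0, abs=1e-12)


def test_batchwise_z_centered_unit_scale_per_batch(toy_ab):
    table, design = toy_ab
    z, est, _ = fit_standardization(table, design, "batchwise")
    for b in ("A", "B"):
        idx = design.labels == b
        assert z.z[idx].mean() == pytest.approx(0.0, abs=1e-12)
        assert z.z[idx].std(ddof=1) == pytest.approx(1.0)
    np.testing.assert_allclose(z.z[:3, 0], [-1.0, 0.0, 1.0])


def test_zero_variance_feature_rejected_or_dropped():
    values = np.column_stack([np.arange(6.0), np.full(6, 3.0)])
    table = FeatureTable([f"s{i}" for i in range(6)], ["ok", "flat"], values)
    design = BatchDesign(labels=np.array(["a"] * 3 + ["b"] * 3))
    with pytest.raises(ValueError, match="flat"):
        fit_standardization(table, design, "grand")
    _, _, used = fit_standardization(table, design, "grand", drop_degenerate=True)
    assert used.feature_names == ["ok"]


# ---------------------------------------------------------------------------
# batch-effect estimation + shrinkage
# ---------------------------------------------------------------------------


def test_batch_effects_match_bruteforce_groupby():
    table, design = random_table(11, n_per_batch=(9, 7), n_features=5)
    z, _, _ = fit_standardization(table, design, "grand")
    eff = estimate_batch_effects(z, design)
    for i, b in enumerate(design.batches()):
        sub = z.z[design.labels == b]
        for g in range(5):
            assert eff.gamma_hat[i, g] == pytest.approx(sub[:, g].mean())
            assert eff.delta2_hat[i, g] == pytest.approx(sub[:, g].var(ddof=1))


def test_identical_batches_give_identical_gamma():
    half = np.random.default_rng(0).normal(size=(5, 3))
    table = FeatureTable(
        [f"s{i}" for i in range(10)], ["a", "b", "c"], np.vstack([half, half])
    )
    design = BatchDesign(labels=np.array(["x"] * 5 + ["y"] * 5))
    z, _, _ = fit_standardization(table, design, "grand")
    eff = estimate_batch_effects(z, design)
    np.testing.assert_allclose(eff.gamma_hat[0], eff.gamma_hat[1], atol=1e-12)


def test_single_sample_batch_and_constant_batch_error():
    table = FeatureTable(
        [f"s{i}" for i in range(5)], ["f"], np.arange(5.0)[:, None]
    )
    with pytest.warns(UserWarning):
        design = BatchDesign(labels=np.array(["a"] * 4 + ["b"]))
    z = StandardizedData(table.values.copy())
    with pytest.raises(ValueError, match="variance undefined"):
        estimate_batch_effects(z, design)
    design2 = BatchDesign(labels=np.array(["a"] * 3 + ["b"] * 2))
    zc = StandardizedData(np.array([[0.0], [1.0], [2.0], [5.0], [5.0]]))
    with pytest.raises(ValueError, match="zero within-batch variance"):
        estimate_batch_effects(zc, design2)


def test_prior_none_copies_raw_estimates_bitwise():
    table, design = random_table(3)
    z, _, _ = fit_standardization(table, design, "grand")
    raw = estimate_batch_effects(z, design)
    hp, eff = fit_priors_and_shrink(raw, "none")
    assert hp is None
    np.testing.assert_array_equal(eff.gamma_star, raw.gamma_hat)
    np.testing.assert_array_equal(eff.delta2_star, raw.delta2_hat)


@pytest.mark.parametrize("prior", ["parametric", "nonparametric"])
def test_identical_raw_gammas_are_left_unshrunk(prior):
    # all features share gamma_hat; the prior concentrates on that common
    # value so shrinkage has nowhere to pull
    rng = np.random.default_rng(4)
    n, g = 40, 12
    scales = rng.uniform(0.5, 2.0, g)
    z = np.vstack(
        [0.8 + scales * rng.standard_normal((n, g)), rng.standard_normal((n, g))]
    )
    labels = np.array(["a"] * n + ["b"] * n)
    z[:n] -= z[:n].mean(axis=0) - 0.8  # exact common batch mean 0.8
    design = BatchDesign(labels=labels)
    sd = StandardizedData(z)
    raw = estimate_batch_effects(sd, design)
    assert np.allclose(raw.gamma_hat[0], 0.8)
    _, eff = fit_priors_and_shrink(raw, prior, sd, design)
    np.testing.assert_allclose(eff.gamma_star[0], raw.gamma_hat[0], atol=1e-8)


def test_parametric_shrinkage_is_a_convex_pull():
    # gamma_hat ~ N(0.5, 0.1^2) across 50 features: every shrunken gamma lies
    # between its raw value and the prior mean
    rng = np.random.default_rng(7)
    n, g = 30, 50
    gammas = rng.normal(0.5, 0.1, g)
    z = gammas + rng.standard_normal((2 * n, g))
    design = BatchDesign(labels=np.array(["a"] * n + ["b"] * n))
    sd = StandardizedData(z)
    raw = estimate_batch_effects(sd, design)
    hp, eff = fit_priors_and_shrink(raw, "parametric", sd, design)
    for i in range(2):
        gbar = hp.gamma_bar[i]
        lo = np.minimum(raw.gamma_hat[i], gbar) - 1e-10
        hi = np.maximum(raw.gamma_hat[i], gbar) + 1e-10
        assert np.all(eff.gamma_star[i] >= lo) and np.all(eff.gamma_star[i] <= hi)


def test_shrinkage_requires_multiple_features():
    table, design = random_table(9, n_features=1)
    z, _, _ = fit_standardization(table, design, "grand")
    raw = estimate_batch_effects(z, design)
    with pytest.raises(ValueError, match="2 features"):
        fit_priors_and_shrink(raw, "parametric", z, design)


# ---------------------------------------------------------------------------
# adjustment / harmonize dispatch
# ---------------------------------------------------------------------------


def test_prior_none_aligns_batch_means_on_grand_mean(toy_ab):
    table, design = toy_ab
    out, _ = harmonize(table, design, RunConfig(variant="combat", prior="none"))
    assert out.values[:3].mean() == pytest.approx(7.0, abs=1e-10)
    assert out.values[3:].mean() == pytest.approx(7.0, abs=1e-10)


def test_mcombat_maps_other_batch_onto_reference(toy_ab):
    table, design = toy_ab
    out, model = harmonize(table, design, RunConfig(variant="m-combat", prior="none"))
    assert model.reference_label == "A"
    np.testing.assert_allclose(out.values[3:, 0], [1.0, 2.0, 3.0], atol=1e-10)
    np.testing.assert_allclose(out.values[:3, 0], [1.0, 2.0, 3.0], atol=1e-10)


def test_mcombat_reference_defaults_to_largest_batch():
    table, design = random_table(21, n_per_batch=(5, 12))
    _, model = harmonize(table, design, RunConfig(variant="m-combat", prior="none"))
    assert model.reference_label == "b1"


def test_closed_form_oracle_on_random_fixtures():
    for seed in range(5):
        table, design = random_table(seed, n_per_batch=(7, 5, 9), n_features=3)
        out, _ = harmonize(table, design, RunConfig(variant="combat", prior="none"))
        expect = closed_form_grand(table.values, design.labels)
        np.testing.assert_allclose(out.values, expect, atol=1e-10)


def test_single_batch_mcombat_is_identity():
    rng = np.random.default_rng(2)
    table = FeatureTable(
        [f"s{i}" for i in range(8)], ["f", "g"], rng.normal(5, 2, (8, 2))
    )
    design = BatchDesign(labels=np.array(["only"] * 8))
    out, _ = harmonize(table, design, RunConfig(variant="m-combat", prior="none"))
    np.testing.assert_allclose(out.values, table.values, atol=1e-10)


def test_grand_mode_repeat_contracts_by_known_factor(toy_ab):
    # with the reference variance convention (pooled 1/N, within-batch n-1) a
    # second prior=none pass contracts toward the grand mean by exactly
    # sqrt((N - I)/N); M-ComBat's consistent batchwise convention is exactly
    # idempotent
    table, design = toy_ab
    once, _ = harmonize(table, design, RunConfig(variant="combat", prior="none"))
    twice, _ = harmonize(once, design, RunConfig(variant="combat", prior="none"))
    factor = np.sqrt((6 - 2) / 6)
    np.testing.assert_allclose(
        twice.values, 7.0 + (once.values - 7.0) * factor, atol=1e-10
    )
    m_once, _ = harmonize(table, design, RunConfig(variant="m-combat", prior="none"))
    m_twice, _ = harmonize(m_once, design, RunConfig(variant="m-combat", prior="none"))
    np.testing.assert_allclose(m_twice.values, m_once.values, atol=1e-10)


def test_apply_model_rejects_unseen_batch(toy_ab):
    table, design = toy_ab
    _, model = harmonize(table, design, RunConfig(variant="combat", prior="none"))
    bad = BatchDesign(labels=np.array(["A"] * 3 + ["C"] * 3))
    with pytest.raises(ValueError, match="unseen"):
        apply_model(table, bad, model)


def test_apply_model_reproduces_fit_output(toy_ab):
    table, design = toy_ab
    for variant in ("combat", "m-combat"):
        out, model = harmonize(table, design, RunConfig(variant=variant, prior="none"))
        again = apply_model(table, design, model)
        np.testing.assert_allclose(again.values, out.values, atol=1e-10)


def test_covariate_effect_is_preserved():
    rng = np.random.default_rng(3)
    n = 40
    x = rng.standard_normal((n, 1))
    labels = np.array(["a"] * 20 + ["b"] * 20)
    base = rng.standard_normal((n, 3))
    base[labels == "b"] += 2.5
    values = base + 1.7 * x
    table = FeatureTable([f"s{i}" for i in range(n)], ["f", "g", "h"], values)
    design = BatchDesign(labels=labels, covariates=x, covariate_names=["age"])
    out, model = harmonize(table, design, RunConfig(variant="combat", prior="none"))
    # batch means of the covariate-residual align; the covariate slope stays
    resid = out.values - x @ model.standardization.beta
    np.testing.assert_allclose(
        resid[labels == "a"].mean(axis=0), resid[labels == "b"].mean(axis=0), atol=1e-8
    )
    slope = np.linalg.lstsq(
        np.hstack([x, np.ones((n, 1))]), out.values, rcond=None
    )[0][0]
    np.testing.assert_allclose(slope, np.full(3, 1.7), atol=0.35)


# ---------------------------------------------------------------------------
# bootstrap variants
# ---------------------------------------------------------------------------


def test_bootstrap_seeding_is_reproducible():
    table, design = random_table(13, n_per_batch=(6, 6))
    a = bootstrap_fit(table, design, "grand", B=5, seed=42, prior="none")
    b = bootstrap_fit(table, design, "grand", B=5, seed=42, prior="none")
    np.testing.assert_array_equal(a.effects.gamma_star, b.effects.gamma_star)
    np.testing.assert_array_equal(a.standardization.sigma, b.standardization.sigma)
    c = bootstrap_fit(table, design, "grand", B=5, seed=43, prior="none")
    assert not np.array_equal(a.effects.gamma_star, c.effects.gamma_star)


@pytest.mark.parametrize("mode", ["case", "parametric"])
def test_bootstrap_monte_carlo_agreement(mode):
    # doubling B moves the averaged coefficients by no more than 3 Monte-
    # Carlo standard errors (estimated from two independent half-size runs)
    table, design = random_table(17, n_per_batch=(12, 10), n_features=6, scale=1.0)
    kw = dict(prior="none", bootstrap_mode=mode)
    g_half1 = bootstrap_fit(table, design, "grand", B=120, seed=1, **kw).effects.gamma_star
    g_half2 = bootstrap_fit(table, design, "grand", B=120, seed=2, **kw).effects.gamma_star
    g_full = bootstrap_fit(table, design, "grand", B=240, seed=3, **kw).effects.gamma_star
    mc_se = np.sqrt(((g_half1 - g_half2) ** 2).mean() / 2.0)
    drift = np.abs(g_full - (g_half1 + g_half2) / 2.0).mean()
    assert drift <= 3.0 * mc_se + 1e-12


def test_bootstrap_with_b1_reduces_to_point_fit():
    # parametric-free check: case resampling cannot be forced to identity,
    # but the raw-frame averaging must reduce to the single-fit coefficients
    # when the "resample" is the data itself (model-based draw with the point
    # fit's own randomness removed is not available, so compare B=1 case
    # refit against a direct refit of the same resample)
    table, design = random_table(19, n_per_batch=(8, 8))
    m1 = bootstrap_fit(table, design, "grand", B=1, seed=0, prior="none")
    rng = np.random.default_rng(0)
    idx = np.concatenate(
        [
            rng.choice(np.flatnonzero(design.labels == b), size=8, replace=True)
            for b in design.batches()
        ]
    )
    rt = FeatureTable([f"s{t}" for t in range(16)], table.feature_names, table.values[idx])
    rd = design.subset(idx)
    z, est, _ = fit_standardization(rt, rd, "grand")
    raw = estimate_batch_effects(z, rd)
    np.testing.assert_allclose(m1.effects.gamma_star, raw.gamma_hat, atol=1e-10)
    np.testing.assert_allclose(m1.standardization.sigma, est.sigma, atol=1e-12)


def test_bootstrap_requires_three_samples_per_batch():
    table, design = random_table(23, n_per_batch=(2, 8))
    with pytest.raises(ValueError, match=">= 3 samples"):
        bootstrap_fit(table, design, "grand", B=3, seed=0, prior="none")


def test_literal_bootstrap_form_changes_scale(toy_ab):
    table, design = toy_ab
    cfg = RunConfig(variant="b-combat", prior="none", n_bootstrap=10, seed=0)
    default, _ = harmonize(table, design, cfg)
    cfg_lit = RunConfig(
        variant="b-combat", prior="none", n_bootstrap=10, seed=0,
        literal_bootstrap_form=True,
    )
    literal, _ = harmonize(table, design, cfg_lit)
    assert not np.allclose(default.values, literal.values)


# ---------------------------------------------------------------------------
# properties
# ---------------------------------------------------------------------------


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    seed=st.integers(0, 10_000),
    sizes=st.lists(st.integers(4, 9), min_size=2, max_size=3),
    g=st.integers(1, 4),
)
def test_batch_mean_alignment_property(seed, sizes, g):
    """After exact (prior=none) harmonization every feature's per-batch means
    coincide with the grand mean, for any fixture."""
    table, design = random_table(seed, n_per_batch=tuple(sizes), n_features=g)
    out, _ = harmonize(table, design, RunConfig(variant="combat", prior="none"))
    expect = closed_form_grand(table.values, design.labels)
    np.testing.assert_allclose(out.values, expect, atol=1e-9)
    means = [out.values[design.labels == b].mean(axis=0) for b in design.batches()]
    for m in means[1:]:
        np.testing.assert_allclose(m, means[0], atol=1e-9)


@settings(max_examples=15, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_reference_rows_untouched_property(seed):
    """M-ComBat with prior=none returns the reference batch bit-for-bit (to
    numerical precision), whatever the data."""
    table, design = random_table(seed, n_per_batch=(6, 8, 5), n_features=3)
    cfg = RunConfig(variant="m-combat", prior="none", reference_label="b2")
    out, _ = harmonize(table, design, cfg)
    idx = design.labels == "b2"
    np.testing.assert_allclose(out.values[idx], table.values[idx], atol=1e-9)
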