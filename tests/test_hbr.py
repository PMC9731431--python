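"""HBR estimator: recovery, shrinkage, z-scoring, posterior predictive."""

import warnings

import numpy as np
import pytest

from conftest import FAST
from fednorm.hbr import HBRNormativeModel, HyperpriorSpec, build_and_fit
from fednorm.synthetic_data import CohortSpec, SiteSpec, generate_cohort


def one_region(sites, seed=0, **kw):
    defaults = dict(n_regions=1, intercepts=(2.5,), slopes=(-0.01,), sex_offsets=(0.06,), seed=seed)
    defaults.update(kw)
    return generate_cohort(CohortSpec(sites=tuple(sites), **defaults))


def batch_slopes_age_units(model):
    """Posterior draws of each batch's age slope, in phenotype/year."""
    lo, hi = model.fit_range_
    theta = model.posterior_["coef"].reshape(-1, model.registry_.n_batches, model._k)
    return theta[:, :, 1] * 2.0 / (hi - lo)


def test_true_slopes_fall_in_credible_intervals(cohort, hbr_model):
    # truth: slope of region_000 is -0.010 scaled per site
    true_by_site = {"site0": -0.010, "site1": -0.010 * 0.85,
                    "site2": -0.010 * 1.15, "site3": -0.010}
    slopes = batch_slopes_age_units(hbr_model)
    hits = 0
    for b, (site, _) in enumerate(hbr_model.registry_.batches):
        lo, hi = np.percentile(slopes[:, b], [2.5, 97.5])
        hits += lo <= true_by_site[site] <= hi
    assert hits >= len(hbr_model.registry_.batches) - 1


def test_noise_sd_recovered_per_site(cohort, hbr_model):
    """The estimated per-batch noise sd tracks the *realized* residual
    spread of that batch (the finite-sample oracle from the generator's
    ground truth), with partial pooling allowed to shrink it slightly."""
    _, train, _ = cohort
    resid = train.phenotypes["region_000"] - train.truth["mu"]["region_000"]
    grouped = train.covariates.groupby(["site", "sex"])
    for b, key in enumerate(hbr_model.registry_.batches):
        empirical = resid.loc[grouped.groups[key]].std()
        assert hbr_model._noise_sd_batch[b] == pytest.approx(empirical, rel=0.15)


def test_heldout_zscores_are_standardized(cohort, hbr_model):
    _, _, test = cohort
    z = hbr_model.zscore(test.covariates, test.y("region_000"))
    # bounds reflect MC error at ~120 held-out subjects across 8 batches
    assert abs(z.mean()) < 0.3
    assert z.std() == pytest.approx(1.0, abs=0.2)


def test_predict_is_permutation_equivariant(cohort, hbr_model):
    _, _, test = cohort
    perm = np.random.default_rng(0).permutation(test.n_subjects)
    mu, sg = hbr_model.predict_dist(test.covariates)
    mu_p, sg_p = hbr_model.predict_dist(test.covariates.iloc[perm])
    np.testing.assert_array_equal(mu_p, mu[perm])
    np.testing.assert_array_equal(sg_p, sg[perm])


def test_sigma_is_strictly_positive(cohort, hbr_model):
    _, _, test = cohort
    _, sigma = hbr_model.predict_dist(test.covariates)
    assert np.all(sigma > 0)


def test_unseen_batch_errors_unless_prior_fallback_requested(hbr_model):
    X = {"age": [40.0], "site": ["elsewhere"], "sex": ["F"]}
    with pytest.raises(KeyError, match="elsewhere"):
        hbr_model.predict_dist(X)
    mu, sigma = hbr_model.predict_dist(X, allow_unseen=True)
    # the prior-level prediction is the population-mean curve
    a = hbr_model.posterior_["mu_coef"].reshape(-1, hbr_model._k).mean(axis=0)
    phi = hbr_model._design(np.array([40.0]))
    assert mu[0] == pytest.approx(float((phi @ a)[0]), abs=1e-10)
    assert sigma[0] > 0


def test_noiseless_limit_recovers_the_true_line():
    data = one_region([SiteSpec("a", 150, (10, 80), noise_sd=1e-6)], seed=3)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = build_and_fit(data, "region_000", sampler=FAST, random_state=0)
    mu = model.predict(data.covariates)
    np.testing.assert_allclose(mu, data.truth["mu"]["region_000"], atol=1e-3)


def test_partial_pooling_shrinks_small_batches_together():
    """Two small batches generated from identical parameters: the HBR
    estimates sit closer to each other than independent OLS fits do."""
    sites = [SiteSpec("a", 15, (10, 80), noise_sd=0.3, sex_ratio=0.0),
             SiteSpec("b", 15, (10, 80), noise_sd=0.3, sex_ratio=0.0)]
    gaps_hbr, gaps_ols = [], []
    for seed in range(5):
        data = one_region(sites, seed=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = build_and_fit(data, "region_000", sampler=FAST, random_state=seed)
        mu_a = model.predict({"age": [45.0], "site": ["a"], "sex": ["M"]})[0]
        mu_b = model.predict({"age": [45.0], "site": ["b"], "sex": ["M"]})[0]
        gaps_hbr.append(abs(mu_a - mu_b))
        ols = []
        for s in ("a", "b"):
            rows = data.covariates["site"] == s
            A = np.column_stack([np.ones(rows.sum()), data.age[rows]])
            beta, *_ = np.linalg.lstsq(A, data.y("region_000")[rows], rcond=None)
            ols.append(beta[0] + 45.0 * beta[1])
        gaps_ols.append(abs(ols[0] - ols[1]))
    assert np.mean(gaps_hbr) < np.mean(gaps_ols)


def test_single_batch_agrees_with_maximum_likelihood():
    data = one_region([SiteSpec("a", 400, (10, 80), noise_sd=0.15, sex_ratio=0.0)], seed=9)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = build_and_fit(data, "region_000", sampler=FAST, random_state=1)
    A = np.column_stack([np.ones(data.n_subjects), data.age])
    beta, *_ = np.linalg.lstsq(A, data.y("region_000"), rcond=None)
    mu_ml = A @ beta
    mu = model.predict(data.covariates)
    resid_sd = (data.y("region_000") - mu_ml).std()
    posterior_unc = resid_sd / np.sqrt(data.n_subjects)
    assert np.max(np.abs(mu - mu_ml)) < 4 * posterior_unc


class TestPosteriorPredictive:
    def test_default_grid_yields_800_rows_per_site(self, hbr_model):
        synth = hbr_model.sample_posterior_predictive(rng=0)
        counts = synth.covariates.groupby("site").size()
        assert (counts == 800).all()

    def test_deterministic_under_seed(self, hbr_model):
        s1 = hbr_model.sample_posterior_predictive(rng=42)
        s2 = hbr_model.sample_posterior_predictive(rng=42)
        assert s1.phenotypes.equals(s2.phenotypes)

    def test_degenerate_posterior_gives_identical_replicates(self, hbr_model):
        import copy

        degenerate = copy.deepcopy(hbr_model)
        degenerate._theta_flat = np.repeat(degenerate._theta_flat[:1], len(degenerate._theta_flat), axis=0)
        degenerate._log_noise_flat = np.full_like(degenerate._log_noise_flat, -700.0)
        synth = degenerate.sample_posterior_predictive(rng=0)
        cell = synth.covariates.reset_index().groupby(["site", "sex", "age"]).groups
        y = synth.phenotypes.iloc[:, 0]
        for rows in cell.values():
            assert y.iloc[rows if isinstance(rows, np.ndarray) else list(rows)].nunique() == 1

    def test_sample_mean_converges_to_predictive_mean(self, hbr_model):
        synth = hbr_model.sample_posterior_predictive(
            ages=[50.0], sites=["site0"], sexes=["F"], n_reps=4000, rng=1)
        mu, sigma = hbr_model.predict_dist(
            {"age": [50.0], "site": ["site0"], "sex": ["F"]})
        assert synth.phenotypes.iloc[:, 0].mean() == pytest.approx(
            mu[0], abs=4 * sigma[0] / np.sqrt(4000) + 0.01)

    def test_unknown_site_raises(self, hbr_model):
        with pytest.raises(KeyError, match="nowhere"):
            hbr_model.sample_posterior_predictive(sites=["nowhere"], rng=0)


def test_fit_input_validation():
    model = HBRNormativeModel()
    with pytest.raises(ValueError, match="empty"):
        model.fit({"age": [], "site": [], "sex": []}, [])
    with pytest.raises(ValueError, match="noise_mode"):
        HBRNormativeModel(noise_mode="warped").fit(
            {"age": [1.0], "site": ["a"], "sex": ["F"]}, [1.0])
    with pytest.raises(ValueError, match="hyperprior shape mismatch"):
        HBRNormativeModel(hyperprior=HyperpriorSpec.default(4), draws=10, tune=10).fit(
            {"age": [1.0, 2.0], "site": ["a", "a"], "sex": ["F", "F"]}, [1.0, 2.0])


def test_hyperprior_spec_validation():
    with pytest.raises(ValueError, match="strictly positive"):
        HyperpriorSpec(m_mu=(0,), s_mu=(0.0,), m_logsd=(0,), s_logsd=(1,),
                       m_mu_sigma=(0,), s_mu_sigma=(1,), m_logsd_sigma=(0,), s_logsd_sigma=(1,))
    with pytest.raises(ValueError, match="non-finite"):
        HyperpriorSpec(m_mu=(np.nan,), s_mu=(1.0,), m_logsd=(0,), s_logsd=(1,),
                       m_mu_sigma=(0,), s_mu_sigma=(1,), m_logsd_sigma=(0,), s_logsd_sigma=(1,))
    spec = HyperpriorSpec.default(2)
    assert spec.s_mu[0] == pytest.approx(np.sqrt(1000.0))
    assert spec.s_logsd[0] == 2.5


def test_heteroscedastic_mode_tracks_growing_variance():
    sites = [SiteSpec("a", 500, (10, 80), noise_sd=0.08, sex_ratio=0.0)]
    data = generate_cohort(CohortSpec(
        sites=tuple(sites), n_regions=1, intercepts=(2.5,), slopes=(-0.01,),
        sex_offsets=(0.0,), heteroscedastic=True, variance_slope=2.0, seed=6))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = build_and_fit(data, "region_000", noise_mode="heteroscedastic",
                              sampler=FAST, random_state=2)
    X_young = {"age": [15.0], "site": ["a"], "sex": ["M"]}
    X_old = {"age": [75.0], "site": ["a"], "sex": ["M"]}
    s_young = model.predict_dist(X_young)[1][0]
    s_old = model.predict_dist(X_old)[1][0]
    assert s_old > 1.5 * s_young  # true ratio ~ 2.9


def test_save_load_round_trip_preserves_predictions(tmp_path, cohort, hbr_model):
    from fednorm.cli_io import load_model, save_model

    _, _, test = cohort
    save_model(hbr_model, tmp_path / "m")
    back = load_model(tmp_path / "m")
    mu0, s0 = hbr_model.predict_dist(test.covariates)
    mu1, s1 = back.predict_dist(test.covariates)
    np.testing.assert_array_equal(mu0, mu1)
    np.testing.assert_array_equal(s0, s1)
    assert back.region_ == hbr_model.region_
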