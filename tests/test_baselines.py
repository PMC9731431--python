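"""Baseline strategies: pooling variants and ComBat harmonization."""

import subprocess
import warnings

import numpy as np
import pandas as pd
import pytest

from conftest import FAST
from fednorm.baselines import (
    CombatHarmonizer,
    FixedEffectNormativeModel,
    NoPoolingNormativeModel,
    PooledNormativeModel,
    combat_apply,
    combat_fit,
    fit_fixed_effect,
    fit_naive_pooling,
    fit_no_pooling,
)
from fednorm.evaluation import site_leakage_audit
from fednorm.hbr import build_and_fit
from fednorm.synthetic_data import (
    CohortSpec,
    SiteSpec,
    generate_cohort,
    generate_confounded_cohort,
)


def cohort_without_site_effects(n=250, seed=21):
    sites = [SiteSpec(f"s{i}", n, (10, 80), 0.0, 1.0, 0.12) for i in range(3)]
    return generate_cohort(CohortSpec(
        sites=tuple(sites), n_regions=1, intercepts=(2.5,), slopes=(-0.009,),
        sex_offsets=(0.06,), seed=seed))


def two_site_shifted(n=400, shift=2.0, seed=13):
    # single-sex so hand-rolled OLS oracles need no sex column
    sites = [SiteSpec("a", n, (10, 80), 0.0, 1.0, 0.2, sex_ratio=1.0),
             SiteSpec("b", n, (10, 80), shift, 1.0, 0.2, sex_ratio=1.0)]
    return generate_cohort(CohortSpec(
        sites=tuple(sites), n_regions=1, intercepts=(2.5,), slopes=(-0.01,),
        sex_offsets=(0.0,), seed=seed))


def test_all_strategies_agree_when_sites_are_exchangeable():
    data = cohort_without_site_effects()
    models = [
        fit_naive_pooling(data, "region_000"),
        fit_fixed_effect(data, "region_000"),
        fit_no_pooling(data, "region_000"),
    ]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        models.append(build_and_fit(data, "region_000", sampler=FAST, random_state=0))
    true_mu = data.truth["mu"]["region_000"].to_numpy()
    preds = [m.predict(data.covariates) for m in models]
    for mu in preds:
        assert np.sqrt(np.mean((mu - true_mu) ** 2)) < 0.05
    for mu in preds[1:]:
        assert np.max(np.abs(mu - preds[0])) < 0.08


def test_naive_pooling_averages_the_site_intercepts():
    data = two_site_shifted()
    model = fit_naive_pooling(data, "region_000")
    mu_mid = model.predict({"age": [45.0], "site": ["a"], "sex": ["F"]})[0]
    per_site = []
    for s in ("a", "b"):
        rows = (data.covariates["site"] == s).to_numpy()
        A = np.column_stack([np.ones(rows.sum()), data.age[rows]])
        beta, *_ = np.linalg.lstsq(A, data.y("region_000")[rows], rcond=None)
        per_site.append(beta[0] + 45 * beta[1])
    assert mu_mid == pytest.approx(np.mean(per_site), abs=0.05)


def test_naive_pooling_zscores_leak_the_site_label():
    data = two_site_shifted()
    model = fit_naive_pooling(data, "region_000")
    z = model.zscore(data.covariates, data.y("region_000"))
    _, acc = site_leakage_audit(z[:, None], data.covariates["site"].to_numpy(object),
                                random_state=0)
    assert acc > 0.9


def test_fixed_effect_recovers_the_additive_shift():
    data = two_site_shifted()
    model = fit_fixed_effect(data, "region_000")
    assert model.site_effects_["b"] == pytest.approx(2.0, abs=0.05)


def test_fixed_effect_on_single_site_equals_naive_pooling():
    site = [SiteSpec("only", 300, (10, 80), 0.0, 1.0, 0.15)]
    data = generate_cohort(CohortSpec(sites=tuple(site), n_regions=1, intercepts=(2.5,),
                                      slopes=(-0.01,), sex_offsets=(0.05,), seed=2))
    naive = fit_naive_pooling(data, "region_000")
    fixed = fit_fixed_effect(data, "region_000")
    np.testing.assert_allclose(fixed.predict(data.covariates), naive.predict(data.covariates),
                               atol=1e-8)


def test_fixed_effect_fails_loudly_on_unseen_site():
    data = two_site_shifted()
    model = fit_fixed_effect(data, "region_000")
    with pytest.raises(KeyError, match="unseen"):
        model.predict({"age": [40.0], "site": ["new_site"], "sex": ["F"]})


def test_no_pooling_is_exactly_per_batch_least_squares():
    data = two_site_shifted(n=200)
    model = fit_no_pooling(data, "region_000")
    from fednorm.design import expand_basis

    for b, (site, sex) in enumerate(model.registry_.batches):
        rows = ((data.covariates["site"] == site) & (data.covariates["sex"] == sex)).to_numpy()
        phi = expand_basis(data.age[rows], model.basis_, model.fit_range_)
        beta, *_ = np.linalg.lstsq(phi, data.y("region_000")[rows], rcond=None)
        np.testing.assert_allclose(model.coefs_[b], beta, atol=1e-8)


def test_no_pooling_flags_underdetermined_batches():
    sites = [SiteSpec("big", 100, (10, 80), sex_ratio=0.5),
             SiteSpec("tiny", 1, (10, 80), sex_ratio=1.0)]
    data = generate_cohort(CohortSpec(sites=tuple(sites), n_regions=1, intercepts=(2.5,),
                                      slopes=(-0.01,), sex_offsets=(0.0,), seed=1))
    model = fit_no_pooling(data, "region_000")
    assert ("tiny", "F") in model.unusable_batches_
    with pytest.warns(UserWarning, match="unusable"):
        mu, sigma = model.predict_dist({"age": [30.0], "site": ["tiny"], "sex": ["F"]})
    assert np.isnan(mu[0]) and np.isnan(sigma[0])


class TestCombat:
    def multi_region(self, shift=True, n=200, seed=31):
        shifts = (0.0, 0.5, -0.4) if shift else (0.0, 0.0, 0.0)
        scales = (1.0, 1.3, 0.8) if shift else (1.0, 1.0, 1.0)
        sites = [SiteSpec(f"s{i}", n, (10, 80), shifts[i], 1.0, 0.15 * scales[i])
                 for i in range(3)]
        return generate_cohort(CohortSpec(
            sites=tuple(sites), n_regions=4,
            intercepts=(2.5, 2.4, 2.6, 2.3), slopes=(-0.01, -0.006, -0.012, -0.003),
            sex_offsets=(0.05, 0.02, -0.03, 0.04), seed=seed))

    @staticmethod
    def design(data):
        male = (data.covariates["sex"] == "M").astype(float).to_numpy()
        return np.column_stack([data.age, male])

    def test_harmonization_equalizes_batch_location_and_scale(self):
        data = self.multi_region()
        Y = data.phenotypes.to_numpy()
        site = data.covariates["site"].to_numpy(object)
        Y_adj = CombatHarmonizer().fit_transform(Y, site, self.design(data))
        # deviations from the *population* (unshifted) curve: the truth mu
        # includes the additive site shift, so subtract it back out
        shifts = {"s0": 0.0, "s1": 0.5, "s2": -0.4}
        shift_per_row = np.array([shifts[s] for s in site])
        pop_mu = data.truth["mu"].to_numpy() - shift_per_row[:, None]
        resid_raw = Y - pop_mu
        resid_adj = Y_adj - pop_mu
        for j in range(Y.shape[1]):
            raw_means = [resid_raw[site == s, j].mean() for s in ("s0", "s1", "s2")]
            adj_means = [resid_adj[site == s, j].mean() for s in ("s0", "s1", "s2")]
            assert np.ptp(raw_means) > 0.8
            assert np.ptp(adj_means) < 0.12
            adj_resid_sds = [resid_adj[site == s, j].std() for s in ("s0", "s1", "s2")]
            raw_resid_sds = [resid_raw[site == s, j].std() for s in ("s0", "s1", "s2")]
            assert np.ptp(adj_resid_sds) < 0.6 * np.ptp(raw_resid_sds)

    def test_no_batch_effect_means_near_identity(self):
        data = self.multi_region(shift=False)
        Y = data.phenotypes.to_numpy()
        Y_adj = CombatHarmonizer().fit_transform(
            Y, data.covariates["site"].to_numpy(object), self.design(data))
        assert np.mean(np.abs(Y_adj - Y)) < 0.02  # EB shrinkage tolerance

    def test_parameters_learned_on_train_apply_to_test(self):
        data = self.multi_region()
        train, test = data.split(0.8, np.random.default_rng(0))
        params = combat_fit(train.phenotypes.to_numpy(),
                            train.covariates["site"].to_numpy(object), self.design(train))
        Y_adj = combat_apply(params, test.phenotypes.to_numpy(),
                             test.covariates["site"].to_numpy(object), self.design(test))
        site = test.covariates["site"].to_numpy(object)
        shifts = {"s0": 0.0, "s1": 0.5, "s2": -0.4}
        pop_mu = test.truth["mu"].to_numpy() - np.array([shifts[s] for s in site])[:, None]
        resid = Y_adj - pop_mu
        for j in range(Y_adj.shape[1]):
            means = [resid[site == s, j].mean() for s in ("s0", "s1", "s2")]
            assert np.ptp(means) < 0.2

    def test_matches_reference_r_implementation(self, tmp_path):
        """Parametric EB ComBat agrees with the standard Bioconductor
        implementation (sva::ComBat) on a shared fixture."""
        rng = np.random.default_rng(42)
        n, G = 60, 5
        batch = np.repeat(["b1", "b2", "b3"], 20)
        age = rng.uniform(10, 80, n)
        male = rng.integers(0, 2, n).astype(float)
        shift = np.array([0.0, 0.5, -0.3])[np.repeat([0, 1, 2], 20)]
        Y = (2.5 - 0.01 * age[:, None] + 0.1 * male[:, None]
             + rng.normal(0, 0.2, (n, G)) + shift[:, None] * np.array([1, 1.2, 0.8, 1, 1.1]))
        design = np.column_stack([age, male])
        params = combat_fit(Y, batch, design)
        Y_adj = combat_apply(params, Y, batch, design)

        pd.DataFrame(Y).to_csv(tmp_path / "Y.csv", index=False)
        pd.DataFrame({"batch": batch, "age": age, "male": male}).to_csv(
            tmp_path / "meta.csv", index=False)
        script = f"""
        suppressMessages(library(sva))
        Y <- as.matrix(read.csv("{tmp_path}/Y.csv"))
        meta <- read.csv("{tmp_path}/meta.csv")
        mod <- model.matrix(~age+male, data=meta)
        out <- ComBat(dat=t(Y), batch=meta$batch, mod=mod, par.prior=TRUE)
        write.csv(t(out), "{tmp_path}/Yadj_r.csv", row.names=FALSE)
        """
        (tmp_path / "run.R").write_text(script)
        subprocess.run(["Rscript", str(tmp_path / "run.R")], check=True, capture_output=True)
        Y_r = pd.read_csv(tmp_path / "Yadj_r.csv").to_numpy()
        np.testing.assert_allclose(Y_adj, Y_r, atol=1e-5)

    def test_site_correlated_subtype_signal_is_attenuated(self):
        """The harmonization failure mode: an unlabeled biological
        effect correlated with site is partly removed by ComBat."""
        from scipy import stats

        # no explicit site shift: the only site-correlated variation is the
        # latent subtype itself, which harmonization cannot distinguish
        # from a batch effect
        sites = [SiteSpec("a", 800, (10, 90), 0.0, 1.0, 0.15),
                 SiteSpec("b", 800, (10, 90), 0.0, 1.0, 0.15)]
        spec = CohortSpec(sites=tuple(sites), n_regions=3,
                          intercepts=(2.5, 2.4, 2.6), slopes=(-0.01, -0.008, -0.005),
                          sex_offsets=(0.05, 0.0, 0.02), seed=17)
        data = generate_confounded_cohort(spec, 0.9, subtype_effect=1.0)
        sub = data.truth["subtype"].to_numpy().astype(bool)
        Y = data.phenotypes.to_numpy()
        Y_adj = CombatHarmonizer().fit_transform(
            Y, data.covariates["site"].to_numpy(object), self.design(data))
        resid = Y - data.truth["mu"].to_numpy()
        resid_adj = Y_adj - data.truth["mu"].to_numpy()
        t_before = stats.ttest_ind(resid[sub, 0], resid[~sub, 0]).statistic
        t_after = stats.ttest_ind(resid_adj[sub, 0], resid_adj[~sub, 0]).statistic
        assert t_before > 5
        assert t_after < 0.7 * t_before

    def test_single_batch_raises(self):
        Y = np.random.default_rng(0).normal(size=(20, 3))
        with pytest.raises(ValueError, match="two batches"):
            combat_fit(Y, ["a"] * 20, np.ones((20, 1)))

    def test_tiny_batch_raises(self):
        Y = np.random.default_rng(0).normal(size=(11, 3))
        with pytest.raises(ValueError, match=">= 2 samples"):
            combat_fit(Y, ["a"] * 10 + ["b"], np.ones((11, 1)))
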