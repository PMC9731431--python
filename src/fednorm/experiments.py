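"""Cohort-level harness and the package's benchmark experiments.

The five strategies ({"hbr", "naive", "fixed", "nopool", "combat"})
expose the same cohort-level surface here: ``fit_strategy`` trains one
model per region (for ComBat: one harmonizer across regions plus a
pooled model per harmonized region) and the returned ``StrategyFit``
computes z-score tables and per-region RHO/SMSE/MSLL on held-out data.

The module also hosts the four benchmark experiments the test suite and
``scripts/acceptance.py`` run at different scales: sequential federated
extension vs the centralized fit, the site-leakage audit of naive
pooling vs HBR z-scores, informative-prior adaptation vs no pooling on
small clinical sites, and credible-interval calibration of the slope
posteriors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import baselines, evaluation, hbr
from .baselines import CombatHarmonizer
from .dataset import NormativeDataset

STRATEGIES = ("hbr", "naive", "fixed", "nopool", "combat")


def _combat_design(data: NormativeDataset):
    cov = data.covariates
    male = (cov["sex"].astype(str) != sorted(cov["sex"].astype(str).unique())[0]).astype(float)
    return np.column_stack([cov["age"].to_numpy(float), male.to_numpy()])


@dataclass
class StrategyFit:
    """A strategy fitted to every region of a training cohort."""

    strategy: str
    regions: list
    models: dict = field(default_factory=dict)        # region -> estimator
    harmonizer: CombatHarmonizer | None = None
    train_moments: dict = field(default_factory=dict)  # region -> (mean, var)

    def _phenotypes(self, data: NormativeDataset) -> pd.DataFrame:
        if self.harmonizer is not None:
            Y = self.harmonizer.transform(
                data.phenotypes[self.regions].to_numpy(float),
                data.covariates["site"].to_numpy(object),
                _combat_design(data),
            )
            return pd.DataFrame(Y, index=data.phenotypes.index, columns=self.regions)
        return data.phenotypes[self.regions]

    def predict_dist(self, data: NormativeDataset, region: str, **kw):
        return self.models[region].predict_dist(data.covariates, **kw)

    def zscores(self, data: NormativeDataset, **kw) -> pd.DataFrame:
        """Per-subject, per-region deviation z-scores."""
        phe = self._phenotypes(data)
        out = {}
        for region in self.regions:
            out[region] = self.models[region].zscore(data.covariates, phe[region].to_numpy(float), **kw)
        return pd.DataFrame(out, index=data.covariates.index)

    def metrics(self, data: NormativeDataset, **kw) -> pd.DataFrame:
        """Per-region RHO/SMSE/MSLL on (held-out) data.

        The trivial predictor of MSLL uses the training moments of the
        same region, computed across all training subjects.
        """
        phe = self._phenotypes(data)
        rows = {}
        for region in self.regions:
            mu, sigma = self.predict_dist(data, region, **kw)
            m0, v0 = self.train_moments[region]
            rows[region] = evaluation.metrics(phe[region].to_numpy(float), mu, sigma, m0, v0)
        return pd.DataFrame(rows).T


def fit_strategy(
    train: NormativeDataset,
    strategy: str,
    basis="linear",
    regions=None,
    sampler: dict | None = None,
    noise_mode: str = "homoscedastic",
    random_state=None,
) -> StrategyFit:
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; choose from {STRATEGIES}")
    regions = list(regions) if regions is not None else train.regions
    fit = StrategyFit(strategy=strategy, regions=regions)

    train_phe = train.phenotypes[regions]
    if strategy == "combat":
        fit.harmonizer = CombatHarmonizer().fit(
            train_phe.to_numpy(float),
            train.covariates["site"].to_numpy(object),
            _combat_design(train),
        )
        train_phe = fit._phenotypes(train)

    ss = np.random.SeedSequence(random_state).spawn(len(regions))
    for region, seq in zip(regions, ss):
        y = train_phe[region].to_numpy(float)
        fit.train_moments[region] = (float(y.mean()), float(y.var()))
        if strategy == "hbr":
            model = hbr.HBRNormativeModel(
                basis=basis, noise_mode=noise_mode,
                random_state=int(seq.generate_state(1)[0] % (2**31)),
                **(sampler or {}),
            )
            model.fit(train.covariates, y)
            model.region_ = region
        elif strategy == "naive" or strategy == "combat":
            model = baselines.PooledNormativeModel(basis=basis)
            model.fit(train.covariates, y)
        elif strategy == "fixed":
            model = baselines.FixedEffectNormativeModel(basis=basis)
            model.fit(train.covariates, y)
        else:
            model = baselines.NoPoolingNormativeModel(basis=basis)
            model.fit(train.covariates, y)
        model.region_ = region
        fit.models[region] = model
    return fit


# -- benchmark experiments -------------------------------------------------

def _seeded(seed, salt):
    return int(np.random.SeedSequence((seed, salt)).generate_state(1)[0] % (2**31))


def extension_vs_centralized(
    n_sites=8, n_per_site=150, n_regions=20,
    sampler=None, seed=0,
):
    """Sequential federated extension versus one centralized fit.

    Generates a multi-site cohort with heterogeneous region-wise age
    effects, fits HBR per region on all training data at once
    (centralized), and separately by visiting one site at a time with
    posterior-predictive synthetic stand-ins for earlier sites
    (extension). Returns the per-region held-out RHO of both models and
    the coefficient of determination (squared Pearson correlation)
    between the two RHO vectors across regions.
    """
    from scipy import stats

    from .federation import extend
    from .synthetic_data import generate_cohort, multisite_spec

    sampler = sampler or {"chains": 1, "tune": 300, "draws": 300}
    spec = multisite_spec(n_sites=n_sites, n_per_site=n_per_site,
                          n_regions=n_regions, seed=seed)
    data = generate_cohort(spec)
    train, test = data.split(0.8, np.random.default_rng(_seeded(seed, 1)))
    sites = train.sites

    rho_full, rho_ext = [], []
    for j, region in enumerate(train.regions):
        full = hbr.build_and_fit(train, region, sampler=sampler,
                                 random_state=_seeded(seed, 100 + j))
        first = train.subset((train.covariates["site"] == sites[0]).to_numpy())
        model = hbr.build_and_fit(first, region, sampler=sampler,
                                  random_state=_seeded(seed, 200 + j))
        for i, site in enumerate(sites[1:], start=1):
            part = train.subset((train.covariates["site"] == site).to_numpy())
            model = extend(model, part, rng=_seeded(seed, 300 + 10 * j + i),
                           sampler=sampler,
                           random_state=_seeded(seed, 400 + 10 * j + i))
        y = test.y(region)
        rho_full.append(stats.pearsonr(y, full.predict(test.covariates))[0])
        rho_ext.append(stats.pearsonr(y, model.predict(test.covariates))[0])
    rho_full = np.asarray(rho_full)
    rho_ext = np.asarray(rho_ext)
    r2 = float(stats.pearsonr(rho_full, rho_ext)[0] ** 2)
    return {"rho_full": rho_full, "rho_extended": rho_ext, "r_squared": r2}


def site_leakage_experiment(
    n_sites=4, n_per_site=150, n_regions=20,
    sampler=None, seed=0,
):
    """Naive-pooling vs HBR z-scores under the site-classification audit.

    One cohort with strong additive site shifts (evenly spread over
    about +/- 3 noise sds, so every site pair differs by at least ~2
    noise sds) and multiplicative slope/noise differences; both
    strategies are fitted on the same 80% healthy split and audited on
    the held-out 20%. The site effects are constructed, not drawn, so
    the audited condition is the same for every seed; the seed governs
    subjects and noise.
    """
    from .synthetic_data import CohortSpec, SiteSpec, generate_cohort

    sampler = sampler or {"chains": 1, "tune": 300, "draws": 300}
    shifts = np.linspace(-0.35, 0.35, n_sites)
    scales = np.linspace(0.8, 1.2, n_sites)
    noise_sds = np.linspace(0.08, 0.15, n_sites)
    sites = tuple(
        SiteSpec(f"site_{i:02d}", n_per_site, (10.0, 90.0),
                 intercept_shift=float(shifts[i]),
                 slope_scale=float(scales[i]),
                 noise_sd=float(noise_sds[i]))
        for i in range(n_sites)
    )
    rng = np.random.default_rng(_seeded(seed, 9))
    spec = CohortSpec(
        sites=sites, n_regions=n_regions,
        intercepts=tuple(2.5 + rng.uniform(-0.3, 0.3, n_regions)),
        slopes=tuple(-np.linspace(0.0, 0.012, n_regions)),
        sex_offsets=tuple(rng.uniform(-0.1, 0.1, n_regions)),
        seed=seed,
    )
    data = generate_cohort(spec)
    train, test = data.split(0.8, np.random.default_rng(_seeded(seed, 2)))

    out = {}
    for strategy in ("naive", "hbr"):
        sf = fit_strategy(train, strategy, sampler=sampler if strategy == "hbr" else None,
                          random_state=_seeded(seed, 3))
        z = sf.zscores(test)
        _, acc = evaluation.site_leakage_audit(
            z.to_numpy(), test.covariates["site"].to_numpy(object),
            random_state=_seeded(seed, 4))
        out[f"{strategy}_accuracy"] = acc
    return out


def adaptation_vs_no_pooling(
    n_reference_sites=6, n_reference_per_site=100, n_local_sites=10,
    n_local_train=10, n_local_test=150,
    sampler=None, seed=0,
):
    """Informative-prior adaptation vs independent fits on tiny sites.

    A reference model is trained on a healthy multi-site cohort and its
    hyperparameter posterior exported. Each simulated clinical site has
    only ``n_local_train`` subjects for recalibration; MSLL on that
    site's held-out subjects compares the adapted model against the
    no-pooling fit on the same local data. Local sites are single-sex
    so the no-pooling contrast always has one determinate batch.
    """
    from .federation import adapt, extract_informative_hyperprior
    from .synthetic_data import CohortSpec, SiteSpec, generate_cohort, multisite_spec

    sampler = sampler or {"chains": 1, "tune": 300, "draws": 300}
    region = "region_000"
    ref_spec = multisite_spec(n_sites=n_reference_sites,
                              n_per_site=n_reference_per_site,
                              n_regions=1, max_slope=0.01, seed=_seeded(seed, 5))
    # a single region: pin its slope to the population value
    ref_spec = CohortSpec(
        sites=ref_spec.sites, n_regions=1, intercepts=(2.5,), slopes=(-0.01,),
        sex_offsets=(0.06,), seed=ref_spec.seed)
    ref_data = generate_cohort(ref_spec)
    reference = hbr.build_and_fit(ref_data, region, sampler=sampler,
                                  random_state=_seeded(seed, 6))
    prior = extract_informative_hyperprior(reference)

    rng = np.random.default_rng(_seeded(seed, 7))
    msll_adapted, msll_nopool = [], []
    for j in range(n_local_sites):
        site = SiteSpec(
            site_id=f"clinic_{j}", n_subjects=n_local_train + n_local_test,
            age_range=(12.0, 88.0),
            intercept_shift=rng.normal(0.0, 0.2),
            slope_scale=rng.uniform(0.8, 1.2),
            noise_sd=rng.uniform(0.08, 0.15),
            sex_ratio=1.0,
        )
        local = generate_cohort(CohortSpec(
            sites=(site,), n_regions=1, intercepts=(2.5,), slopes=(-0.01,),
            sex_offsets=(0.06,), seed=_seeded(seed, 1000 + j)))
        pick = rng.permutation(local.n_subjects)
        local_train = local.subset(np.isin(np.arange(local.n_subjects), pick[:n_local_train]))
        local_test = local.subset(np.isin(np.arange(local.n_subjects), pick[n_local_train:]))

        adapted = adapt(prior, local_train, region, fit_range=reference.fit_range_,
                        sampler=sampler, random_state=_seeded(seed, 2000 + j))
        nopool = baselines.fit_no_pooling(local_train, region)

        y_train = local_train.y(region)
        m0, v0 = float(y_train.mean()), float(y_train.var())
        y = local_test.y(region)
        mu_a, s_a = adapted.predict_dist(local_test.covariates)
        mu_n, s_n = nopool.predict_dist(local_test.covariates)
        msll_adapted.append(evaluation.metrics(y, mu_a, s_a, m0, v0)["MSLL"])
        msll_nopool.append(evaluation.metrics(y, mu_n, s_n, m0, v0)["MSLL"])
    return {
        "msll_adapted": np.asarray(msll_adapted),
        "msll_no_pooling": np.asarray(msll_nopool),
    }


def slope_calibration(n_cohorts=20, n_per_site=150, sampler=None, seed=0):
    """Frequentist coverage of the 95% credible intervals for the true
    per-batch age slopes, over independently simulated cohorts.

    Site sizes keep every (site, sex) batch data-dominated (tens of
    subjects), the regime the reference cohorts live in; with only a
    handful of subjects per batch the short-chain posteriors themselves
    become the bottleneck (see the methods note).
    """
    from .synthetic_data import CohortSpec, SiteSpec, generate_cohort

    sampler = sampler or {"chains": 1, "tune": 400, "draws": 600}
    region = "region_000"
    hits = total = 0
    rng = np.random.default_rng(_seeded(seed, 8))
    for c in range(n_cohorts):
        scales = rng.uniform(0.7, 1.3, 4)
        sites = tuple(
            SiteSpec(f"s{i}", n_per_site, (10.0, 90.0),
                     intercept_shift=rng.normal(0.0, 0.2),
                     slope_scale=float(scales[i]),
                     noise_sd=rng.uniform(0.08, 0.15))
            for i in range(4)
        )
        data = generate_cohort(CohortSpec(
            sites=sites, n_regions=1, intercepts=(2.5,), slopes=(-0.01,),
            sex_offsets=(0.06,), seed=_seeded(seed, 3000 + c)))
        model = hbr.build_and_fit(data, region, sampler=sampler,
                                  random_state=_seeded(seed, 4000 + c))
        lo, hi = model.fit_range_
        theta = model.posterior_["coef"].reshape(-1, model.registry_.n_batches, model._k)
        slopes = theta[:, :, 1] * 2.0 / (hi - lo)
        by_site = {f"s{i}": -0.01 * scales[i] for i in range(4)}
        for b, (site, _) in enumerate(model.registry_.batches):
            ci_lo, ci_hi = np.percentile(slopes[:, b], [2.5, 97.5])
            hits += ci_lo <= by_site[site] <= ci_hi
            total += 1
    return {"coverage": hits / total, "n_intervals": total}
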