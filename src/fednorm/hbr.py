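"""Hierarchical Bayesian regression (HBR) for multi-site normative modeling.

The model partially pools per-batch (site x sex) regression and noise
parameters under shared Gaussian priors whose parameters (the
hyperparameters) carry weakly-informative hyperpriors:

    y_i      ~ N( phi(age) . theta_i,  sigma_i^2 )        per batch i
    theta_i  ~ N( mu_theta, diag(sd_theta)^2 )            shared prior
    mu_theta     ~ N(0, 10^3)        (variance 10^3, per coefficient)
    log sd_theta ~ N(0, 2.5^2)

with the per-batch noise either homoscedastic (log sigma_i pooled the
same way) or heteroscedastic (sigma = softplus of a linear function of
the basis, its coefficients pooled the same way). Inference is by NUTS
in the non-centered parameterization.

Partial pooling interpolates between one global fit (complete pooling)
and independent per-batch fits (no pooling): batches with many subjects
are dominated by their own likelihood while small batches shrink toward
the population prior, which is what makes few-shot adaptation to sites
with 0 or 1 subjects possible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._model import HBRPosterior, softplus
from ._sampling import sample_nuts
from .base import NormativeRegressor, check_fitted, extract_covariates
from .dataset import HEALTHY, NormativeDataset
from .design import BasisConfig, BatchRegistry, expand_basis, register_batches

__all__ = [
    "HyperpriorSpec",
    "HBRNormativeModel",
    "build_and_fit",
    "predict",
    "zscore",
    "sample_posterior_predictive",
]

NOISE_MODES = ("homoscedastic", "heteroscedastic")

#: default hyperprior constants: prior-mean variance and log-spread sd
DEFAULT_MEAN_VARIANCE = 1000.0
DEFAULT_LOGSD_SD = 2.5


@dataclass(frozen=True)
class HyperpriorSpec:
    """Gaussian hyperpriors for every hyperparameter of the model.

    ``m_mu/s_mu`` give the location/scale of the hyperprior on the prior
    mean of each mean-function coefficient; ``m_logsd/s_logsd`` the same
    for the log prior spread. The ``*_sigma`` fields are the noise-model
    counterparts (length 1 for homoscedastic noise, one per basis column
    for heteroscedastic noise). A spec extracted from a fitted model's
    posterior (`federation.extract_informative_hyperprior`) makes these
    informative and carries the reference model's knowledge.
    """

    m_mu: tuple
    s_mu: tuple
    m_logsd: tuple
    s_logsd: tuple
    m_mu_sigma: tuple
    s_mu_sigma: tuple
    m_logsd_sigma: tuple
    s_logsd_sigma: tuple

    def __post_init__(self):
        for name in self.__dataclass_fields__:
            arr = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"hyperprior field {name} contains non-finite values")
            if name.startswith("s_") and np.any(arr <= 0):
                raise ValueError(f"hyperprior scale {name} must be strictly positive")
            object.__setattr__(self, name, tuple(arr))
        if len(self.m_mu) != len(self.s_mu) or len(self.m_logsd) != len(self.s_logsd) or len(self.m_mu) != len(self.m_logsd):
            raise ValueError("mean-coefficient hyperprior fields must have equal length")
        if not (len(self.m_mu_sigma) == len(self.s_mu_sigma) == len(self.m_logsd_sigma) == len(self.s_logsd_sigma)):
            raise ValueError("noise hyperprior fields must have equal length")

    @property
    def n_coef(self) -> int:
        return len(self.m_mu)

    @property
    def n_noise_coef(self) -> int:
        return len(self.m_mu_sigma)

    @staticmethod
    def default(n_coef: int, noise_mode: str = "homoscedastic",
                mean_variance: float = DEFAULT_MEAN_VARIANCE,
                logsd_sd: float = DEFAULT_LOGSD_SD) -> "HyperpriorSpec":
        """The weakly-informative setting: mu ~ N(0, mean_variance),
        log(sd) ~ N(0, logsd_sd^2) for every hyperparameter."""
        ks = 1 if noise_mode == "homoscedastic" else n_coef
        s = float(np.sqrt(mean_variance))
        return HyperpriorSpec(
            m_mu=(0.0,) * n_coef, s_mu=(s,) * n_coef,
            m_logsd=(0.0,) * n_coef, s_logsd=(logsd_sd,) * n_coef,
            m_mu_sigma=(0.0,) * ks, s_mu_sigma=(s,) * ks,
            m_logsd_sigma=(0.0,) * ks, s_logsd_sigma=(logsd_sd,) * ks,
        )

    def as_dict(self) -> dict:
        return {name: np.asarray(getattr(self, name), dtype=float) for name in self.__dataclass_fields__}

    @staticmethod
    def from_dict(d) -> "HyperpriorSpec":
        return HyperpriorSpec(**{k: tuple(np.atleast_1d(v)) for k, v in d.items()})


class HBRNormativeModel(NormativeRegressor):
    """Partial-pooling normative regression, scikit-learn style.

    Parameters
    ----------
    basis : str or BasisConfig
        Age parameterization ({"linear", "polynomial3", "bspline3"}).
    noise_mode : {"homoscedastic", "heteroscedastic"}
    hyperprior : HyperpriorSpec or None
        ``None`` uses the weakly-informative default; pass an extracted
        spec for informative-prior adaptation.
    draws, tune, chains, target_accept, max_treedepth
        NUTS settings (per chain).
    rhat_warn, divergence_warn
        Diagnostic thresholds above which a warning is raised and
        recorded in ``diagnostics_``.
    random_state : int or None

    Fitted attributes (trailing underscore): ``registry_``, ``basis_``,
    ``fit_range_``, ``posterior_`` (named draw arrays, shape
    ``(chains, draws, ...)``), ``diagnostics_``, ``region_`` when fitted
    through :func:`build_and_fit`.
    """

    def __init__(self, basis="linear", noise_mode="homoscedastic", hyperprior=None,
                 fit_range=None, draws=1000, tune=1000, chains=2, target_accept=0.9,
                 max_treedepth=10, center_threshold=10, rhat_warn=1.05,
                 divergence_warn=0.05, random_state=None):
        self.basis = basis
        self.noise_mode = noise_mode
        self.hyperprior = hyperprior
        self.fit_range = fit_range
        self.draws = draws
        self.tune = tune
        self.chains = chains
        self.target_accept = target_accept
        self.max_treedepth = max_treedepth
        self.center_threshold = center_threshold
        self.rhat_warn = rhat_warn
        self.divergence_warn = divergence_warn
        self.random_state = random_state

    # -- fitting -----------------------------------------------------------
    def fit(self, X, y):
        if self.noise_mode not in NOISE_MODES:
            raise ValueError(f"noise_mode must be one of {NOISE_MODES}")
        age, site, sex = extract_covariates(X)
        y = np.asarray(y, dtype=float)
        if len(y) != len(age):
            raise ValueError("y length does not match X")
        if len(y) == 0:
            raise ValueError("cannot fit on zero samples")
        if not np.all(np.isfinite(y)):
            raise ValueError("y must be finite")

        self.registry_ = register_batches(site, sex)
        if self.fit_range is not None:
            lo, hi = float(self.fit_range[0]), float(self.fit_range[1])
        else:
            lo, hi = float(age.min()), float(age.max())
            if hi - lo < 1e-8:  # single-age data: widen so the basis is defined
                lo, hi = lo - 0.5, hi + 0.5
        self.fit_range_ = (lo, hi)
        self.basis_ = self.basis if isinstance(self.basis, BasisConfig) else BasisConfig(self.basis)
        phi = expand_basis(age, self.basis_, self.fit_range_)
        k = phi.shape[1]

        hyper = self.hyperprior if self.hyperprior is not None else HyperpriorSpec.default(k, self.noise_mode)
        ks = 1 if self.noise_mode == "homoscedastic" else k
        if hyper.n_coef != k or hyper.n_noise_coef != ks:
            raise ValueError(
                f"hyperprior shape mismatch: spec has {hyper.n_coef} mean / "
                f"{hyper.n_noise_coef} noise coefficients, basis needs {k} / {ks}"
            )
        self.hyperprior_ = hyper

        bidx = self.registry_.lookup(site, sex)
        post = HBRPosterior(phi, y, bidx, self.registry_.n_batches, hyper.as_dict(),
                            self.noise_mode, center_threshold=self.center_threshold)

        seeds = np.random.SeedSequence(self.random_state).spawn(self.chains)
        chain_draws, divergences, accept = [], 0, []
        for seq in seeds:
            rng = np.random.default_rng(seq)
            x0 = post.initial_point(rng)
            res = sample_nuts(
                post.logp_and_grad, x0, n_tune=self.tune, n_draws=self.draws,
                rng=rng, target_accept=self.target_accept, max_treedepth=self.max_treedepth,
            )
            chain_draws.append(res.draws)
            divergences += res.n_divergent
            accept.append(res.accept_rate)

        self._raw_draws = np.asarray(chain_draws)  # (C, D, dim)
        self._k = k
        self._ks = ks
        self._finalize_posterior()
        self._diagnose(divergences, float(np.mean(accept)))
        return self

    def _finalize_posterior(self):
        C, D, _ = self._raw_draws.shape
        k, ks, B = self._k, self._ks, self.registry_.n_batches
        flat = self._raw_draws.reshape(C * D, -1)
        i = 0
        a = flat[:, i:i + k]; i += k
        l = flat[:, i:i + k]; i += k
        E = flat[:, i:i + B * k].reshape(-1, B, k); i += B * k
        c = flat[:, i:i + ks]; i += ks
        d = flat[:, i:i + ks]; i += ks
        H = flat[:, i:i + B * ks].reshape(-1, B, ks)

        # resolve the mixed parameterization into per-batch parameters
        cent = np.array(
            [self.registry_.counts.get(b, 0) >= self.center_threshold for b in self.registry_.batches]
        )
        theta = np.where(cent[None, :, None], E, a[:, None, :] + np.exp(l)[:, None, :] * E)
        noise = np.where(cent[None, :, None], H, c[:, None, :] + np.exp(d)[:, None, :] * H)
        post = {
            "mu_coef": a.reshape(C, D, k),
            "log_sd_coef": l.reshape(C, D, k),
            "coef": theta.reshape(C, D, B, k),
            "mu_noise": c.reshape(C, D, ks),
            "log_sd_noise": d.reshape(C, D, ks),
        }
        self._theta_flat = theta
        self._theta_mean = theta.mean(axis=0)              # (B, k)
        self._theta_prior_mean = a.mean(axis=0)            # (k,)
        if self.noise_mode == "homoscedastic":
            log_noise = noise[:, :, 0]                     # (S, B)
            post["log_noise_sd"] = log_noise.reshape(C, D, B)
            self._log_noise_flat = log_noise
            self._noise_sd_batch = np.exp(log_noise).mean(axis=0)            # (B,)
            self._noise_sd_prior = float(np.exp(c[:, 0] + 0.5 * np.exp(2 * d[:, 0])).mean())
        else:
            theta_s = noise                                # (S, B, k)
            post["noise_coef"] = theta_s.reshape(C, D, B, ks)
            self._theta_sigma_flat = theta_s
            self._theta_sigma_mean = theta_s.mean(axis=0)
            self._theta_sigma_prior_mean = c.mean(axis=0)
        self.posterior_ = post

    def _diagnose(self, n_divergent, accept_rate):
        diag = {
            "n_divergent": int(n_divergent),
            "divergence_rate": n_divergent / (self.chains * self.draws),
            "accept_rate": accept_rate,
            "warnings": [],
        }
        if self.chains >= 2:
            import arviz as az

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sub = {name: arr for name, arr in self.posterior_.items()
                       if name in ("mu_coef", "log_sd_coef", "mu_noise", "log_sd_noise")}
                rhat = az.rhat(az.from_dict(posterior=sub))
                diag["rhat_max"] = float(max(float(rhat[v].max()) for v in rhat.data_vars))
        else:
            diag["rhat_max"] = float("nan")
        if diag["divergence_rate"] > self.divergence_warn:
            msg = f"divergence rate {diag['divergence_rate']:.3f} exceeds {self.divergence_warn}"
            diag["warnings"].append(msg)
            warnings.warn(msg)
        if np.isfinite(diag["rhat_max"]) and diag["rhat_max"] > self.rhat_warn:
            msg = f"max R-hat {diag['rhat_max']:.3f} exceeds {self.rhat_warn}; chains may not have converged"
            diag["warnings"].append(msg)
            warnings.warn(msg)
        self.diagnostics_ = diag

    # -- prediction --------------------------------------------------------
    def _design(self, age):
        return expand_basis(age, self.basis_, self.fit_range_)

    def predict_dist(self, X, allow_unseen=False):
        """Posterior-mean (mu, sigma) per subject.

        Batches absent from training raise unless ``allow_unseen=True``,
        in which case the learned prior provides the prediction (the
        n=0 few-shot case).
        """
        check_fitted(self, "posterior_")
        age, site, sex = extract_covariates(X)
        phi = self._design(age)
        bidx = self.registry_.lookup(site, sex, strict=not allow_unseen)
        seen = bidx >= 0
        theta = np.where(seen[:, None], self._theta_mean[bidx], self._theta_prior_mean[None, :])
        mu = np.einsum("nk,nk->n", phi, theta)
        if self.noise_mode == "homoscedastic":
            sigma = np.where(seen, self._noise_sd_batch[bidx], self._noise_sd_prior)
        else:
            sigma = np.empty(len(age))
            for b in np.unique(bidx):
                rows = bidx == b
                coefs = self._theta_sigma_flat[:, b, :] if b >= 0 else np.broadcast_to(
                    self._theta_sigma_prior_mean, (1, self._ks))
                sigma[rows] = softplus(phi[rows] @ coefs.T).mean(axis=1)
        return mu, np.maximum(sigma, 1e-12)

    # -- posterior predictive ---------------------------------------------
    def sample_posterior_predictive(self, ages=None, sites=None, sexes=None,
                                    n_reps=5, rng=None, region=None) -> NormativeDataset:
        """Draw a synthetic cohort from the posterior predictive.

        One response is drawn per (age, sex, site, rep) cell using a
        randomly selected posterior draw of all parameters; the default
        grid (ages 10..89 by 1 year, both sexes, 5 replicates) yields
        800 rows per site. Deterministic under ``rng``.
        """
        check_fitted(self, "posterior_")
        rng = np.random.default_rng(rng)
        ages = np.arange(10.0, 90.0) if ages is None else np.asarray(ages, dtype=float)
        if ages.size == 0:
            raise ValueError("empty age grid")
        known_sites = {s for s, _ in self.registry_.batches}
        sites = sorted(known_sites) if sites is None else list(sites)
        unknown = [s for s in sites if s not in known_sites]
        if unknown:
            raise KeyError(f"unknown sites requested: {unknown}")
        all_sexes = sorted({x for _, x in self.registry_.batches})
        sexes = all_sexes if sexes is None else list(sexes)

        rows_age, rows_sex, rows_site = [], [], []
        for site in sites:
            for sex in sexes:
                if (site, sex) not in self.registry_.counts:
                    continue
                n_cell = ages.size * n_reps
                rows_age.append(np.repeat(ages, n_reps))
                rows_sex.append(np.full(n_cell, sex, dtype=object))
                rows_site.append(np.full(n_cell, site, dtype=object))
        if not rows_age:
            raise ValueError("no registered (site, sex) batches selected")
        age = np.concatenate(rows_age)
        sex = np.concatenate(rows_sex)
        site = np.concatenate(rows_site)

        phi = self._design(age)
        bidx = self.registry_.lookup(site, sex)
        S = len(self._theta_flat)
        idx = rng.integers(0, S, size=len(age))
        theta = self._theta_flat[idx, bidx, :]
        mu = np.einsum("nk,nk->n", phi, theta)
        if self.noise_mode == "homoscedastic":
            sd = np.exp(self._log_noise_flat[idx, bidx])
        else:
            sd = softplus(np.einsum("nk,nk->n", phi, self._theta_sigma_flat[idx, bidx, :]))
        y = mu + sd * rng.standard_normal(len(age))

        region = region or getattr(self, "region_", None) or "y"
        index = pd.Index([f"synth-{s}-{j:05d}" for j, s in enumerate(site)], name="subject_id")
        cov = pd.DataFrame({"age": age, "sex": sex, "site": site, "group": HEALTHY}, index=index)
        phe = pd.DataFrame({region: y}, index=index)
        return NormativeDataset(cov, phe)

    # -- persistence -------------------------------------------------------
    def to_state(self):
        check_fitted(self, "posterior_")
        meta = {
            "model_type": "hbr",
            "params": {key: val for key, val in self.get_params().items()
                       if key not in ("basis", "hyperprior")},
            "basis": self.basis_.to_dict(),
            "noise_mode": self.noise_mode,
            "fit_range": list(self.fit_range_),
            "registry": self.registry_.to_dict(),
            "hyperprior": {k: list(v) for k, v in self.hyperprior_.as_dict().items()},
            "diagnostics": self.diagnostics_,
            "region": getattr(self, "region_", None),
            "k": self._k,
            "ks": self._ks,
        }
        return meta, {"draws": self._raw_draws}

    @staticmethod
    def from_state(meta, arrays) -> "HBRNormativeModel":
        if "draws" not in arrays:
            raise ValueError("model store is missing the posterior draw array")
        model = HBRNormativeModel(**meta["params"])
        model.basis = model.basis_ = BasisConfig.from_dict(meta["basis"])
        model.noise_mode = meta["noise_mode"]
        model.fit_range_ = tuple(meta["fit_range"])
        model.registry_ = BatchRegistry.from_dict(meta["registry"])
        model.hyperprior = model.hyperprior_ = HyperpriorSpec.from_dict(meta["hyperprior"])
        model.diagnostics_ = meta["diagnostics"]
        if meta.get("region"):
            model.region_ = meta["region"]
        model._raw_draws = np.asarray(arrays["draws"], dtype=float)
        model._k = int(meta["k"])
        model._ks = int(meta["ks"])
        model._finalize_posterior()
        return model


# -- module-level operation wrappers --------------------------------------

def build_and_fit(data: NormativeDataset, region: str, basis="linear", hyperprior=None,
                  noise_mode="homoscedastic", sampler: dict | None = None,
                  random_state=None) -> HBRNormativeModel:
    """Fit the HBR model to one region of a dataset."""
    model = HBRNormativeModel(basis=basis, hyperprior=hyperprior, noise_mode=noise_mode,
                              random_state=random_state, **(sampler or {}))
    model.fit(data.covariates, data.y(region))
    model.region_ = region
    return model


def predict(model: HBRNormativeModel, age, site, sex, allow_unseen=False):
    return model.predict_dist({"age": age, "site": site, "sex": sex}, allow_unseen=allow_unseen)


def zscore(model: HBRNormativeModel, data: NormativeDataset, region: str | None = None,
           allow_unseen=False):
    region = region or model.region_
    return model.zscore(data.covariates, data.y(region), allow_unseen=allow_unseen)


def sample_posterior_predictive(model: HBRNormativeModel, ages=None, sites=None,
                                sexes=None, n_reps=5, seed=None) -> NormativeDataset:
    return model.sample_posterior_predictive(ages=ages, sites=sites, sexes=sexes,
                                             n_reps=n_reps, rng=seed)
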