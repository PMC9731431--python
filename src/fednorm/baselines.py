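"""Comparison strategies for multi-site normative modeling.

Four classical alternatives to partial pooling:

* naive pooling — one global (f_mu, sigma), site structure ignored;
* fixed-effect pooling — site enters the design as one-hot covariates;
* no pooling — an independent fit per (site, sex) batch;
* ComBat harmonization — empirical-Bayes location/scale adjustment of
  the phenotypes per batch (preserving age and sex effects), followed
  by naive pooling on the harmonized data.

Mean functions are maximum-likelihood (least-squares) fits; noise is
homoscedastic (global, or per batch for no pooling). All strategies
share the ``fit`` / ``predict_dist`` / ``zscore`` surface of the HBR
estimator so evaluation harnesses are strategy-agnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .base import NormativeRegressor, check_fitted, extract_covariates
from .design import BasisConfig, expand_basis, register_batches

__all__ = [
    "PooledNormativeModel",
    "FixedEffectNormativeModel",
    "NoPoolingNormativeModel",
    "CombatParams",
    "CombatHarmonizer",
    "combat_fit",
    "combat_apply",
    "fit_naive_pooling",
    "fit_fixed_effect",
    "fit_no_pooling",
]


def _sex_onehot(sex, levels):
    unseen = sorted(set(map(str, sex)) - set(levels))
    if unseen:
        raise KeyError(f"unseen sex labels: {unseen}")
    return np.column_stack([(np.asarray(sex, dtype=object) == lv).astype(float) for lv in levels[1:]]) \
        if len(levels) > 1 else np.empty((len(sex), 0))


class _LeastSquaresModel(NormativeRegressor):
    """Shared least-squares machinery for the pooled strategies."""

    def __init__(self, basis="linear"):
        self.basis = basis

    def _mean_design(self, age, site, sex):
        raise NotImplementedError

    def fit(self, X, y):
        age, site, sex = extract_covariates(X)
        y = np.asarray(y, dtype=float)
        if len(y) != len(age):
            raise ValueError("y length does not match X")
        if not np.all(np.isfinite(y)):
            raise ValueError("y must be finite")
        self.basis_ = self.basis if isinstance(self.basis, BasisConfig) else BasisConfig(self.basis)
        lo, hi = float(age.min()), float(age.max())
        if hi - lo < 1e-8:
            lo, hi = lo - 0.5, hi + 0.5
        self.fit_range_ = (lo, hi)
        self.sex_levels_ = sorted(set(map(str, sex)))
        self.sites_ = sorted(set(map(str, site)))
        D = self._mean_design(age, site, sex)
        self.coef_, *_ = np.linalg.lstsq(D, y, rcond=None)
        resid = y - D @ self.coef_
        dof = max(len(y) - np.linalg.matrix_rank(D), 1)
        self.sigma_ = float(np.sqrt((resid**2).sum() / dof))
        self.sigma_ = max(self.sigma_, 1e-12)
        return self

    def predict_dist(self, X):
        check_fitted(self, "coef_")
        age, site, sex = extract_covariates(X)
        D = self._mean_design(age, site, sex)
        return D @ self.coef_, np.full(len(age), self.sigma_)


class PooledNormativeModel(_LeastSquaresModel):
    """Naive (complete) pooling: one global mean function and noise sd.

    Site effects are ignored entirely; sex enters as an indicator
    covariate. The resulting z-scores retain any site signal present in
    the data — the failure mode the site-leakage audit quantifies.
    """

    def _mean_design(self, age, site, sex):
        phi = expand_basis(age, self.basis_, self.fit_range_)
        return np.column_stack([phi, _sex_onehot(sex, self.sex_levels_)])


class FixedEffectNormativeModel(_LeastSquaresModel):
    """Pooling with site as a fixed effect (one-hot covariates).

    Removes additive site effects from the mean, but every deployment
    site must have been present at training time: prediction for an
    unseen site raises.
    """

    def _mean_design(self, age, site, sex):
        site = np.asarray(site, dtype=object)
        unseen = sorted(set(map(str, site)) - set(self.sites_))
        if unseen:
            raise KeyError(f"sites unseen at training time: {unseen}")
        phi = expand_basis(age, self.basis_, self.fit_range_)
        onehot = (
            np.column_stack([(site == s).astype(float) for s in self.sites_[1:]])
            if len(self.sites_) > 1
            else np.empty((len(site), 0))
        )
        return np.column_stack([phi, _sex_onehot(sex, self.sex_levels_), onehot])

    @property
    def site_effects_(self):
        """Fitted additive site coefficients relative to the first site."""
        check_fitted(self, "coef_")
        n_site = len(self.sites_) - 1
        return dict(zip(self.sites_[1:], self.coef_[-n_site:] if n_site else []))


class NoPoolingNormativeModel(NormativeRegressor):
    """Independent least-squares fit per (site, sex) batch.

    Batches with fewer rows than ``n_columns + 1`` are underdetermined
    (no residual degree of freedom for the noise sd) and are flagged
    unusable: predictions for them are NaN with a warning.
    """

    def __init__(self, basis="linear"):
        self.basis = basis

    def fit(self, X, y):
        age, site, sex = extract_covariates(X)
        y = np.asarray(y, dtype=float)
        if len(y) != len(age):
            raise ValueError("y length does not match X")
        self.basis_ = self.basis if isinstance(self.basis, BasisConfig) else BasisConfig(self.basis)
        lo, hi = float(age.min()), float(age.max())
        if hi - lo < 1e-8:
            lo, hi = lo - 0.5, hi + 0.5
        self.fit_range_ = (lo, hi)
        self.registry_ = register_batches(site, sex)
        B = self.registry_.n_batches
        bidx = self.registry_.lookup(site, sex)
        phi = expand_basis(age, self.basis_, self.fit_range_)
        k = phi.shape[1]
        self.coefs_ = np.full((B, k), np.nan)
        self.sigmas_ = np.full(B, np.nan)
        self.usable_ = np.zeros(B, dtype=bool)
        for b in range(B):
            rows = bidx == b
            n_b = int(rows.sum())
            if n_b <= k:
                continue  # underdetermined: flagged unusable
            Pb, yb = phi[rows], y[rows]
            beta, *_ = np.linalg.lstsq(Pb, yb, rcond=None)
            resid = yb - Pb @ beta
            dof = n_b - np.linalg.matrix_rank(Pb)
            if dof < 1:
                continue
            self.coefs_[b] = beta
            self.sigmas_[b] = max(float(np.sqrt((resid**2).sum() / dof)), 1e-12)
            self.usable_[b] = True
        return self

    @property
    def unusable_batches_(self):
        check_fitted(self, "usable_")
        return [b for b, ok in zip(self.registry_.batches, self.usable_) if not ok]

    def predict_dist(self, X):
        check_fitted(self, "coefs_")
        age, site, sex = extract_covariates(X)
        bidx = self.registry_.lookup(site, sex)
        phi = expand_basis(age, self.basis_, self.fit_range_)
        mu = np.einsum("nk,nk->n", phi, self.coefs_[bidx])
        sigma = self.sigmas_[bidx]
        if np.any(~self.usable_[bidx]):
            bad = sorted({self.registry_.batches[b] for b in bidx[~self.usable_[bidx]]})
            warnings.warn(f"predictions are NaN for unusable (underdetermined) batches: {bad}")
        return mu, sigma


# -- ComBat harmonization --------------------------------------------------

@dataclass
class CombatParams:
    """Parametric empirical-Bayes ComBat parameters, fitted on training data.

    ``gamma_star`` / ``delta_star`` are the shrunk additive /
    multiplicative batch effects per (batch, feature) on the
    standardized scale; ``beta_cov`` the preserved design coefficients.
    """

    batches: list
    gamma_star: np.ndarray   # (B, G)
    delta_star: np.ndarray   # (B, G), > 0
    grand_mean: np.ndarray   # (G,)
    beta_cov: np.ndarray     # (p, G)
    var_pooled: np.ndarray   # (G,)


def _batch_onehot(batch, levels):
    batch = np.asarray(batch, dtype=object)
    unseen = sorted(set(map(str, batch)) - set(levels))
    if unseen:
        raise KeyError(f"unseen batches: {unseen}")
    return np.column_stack([(batch == b).astype(float) for b in levels])


def _eb_iterate(Z_b, gamma_hat, delta_hat, gamma_bar, tau2, lam, theta, conv=1e-4, max_iter=500):
    """Iterative solution of the parametric EB estimates for one batch."""
    n_b = Z_b.shape[0]
    g, dsq = gamma_hat.copy(), delta_hat.copy()
    for _ in range(max_iter):
        g_new = (n_b * tau2 * gamma_hat + dsq * gamma_bar) / (n_b * tau2 + dsq)
        d_new = (theta + 0.5 * ((Z_b - g_new[None, :]) ** 2).sum(axis=0)) / (n_b / 2 + lam - 1)
        change = max(np.abs(g_new - g).max() / np.maximum(np.abs(g), 1e-8).max(),
                     np.abs(d_new - dsq).max() / np.maximum(np.abs(dsq), 1e-8).max())
        g, dsq = g_new, d_new
        if change < conv:
            break
    return g, dsq


def combat_fit(Y, batch, design) -> CombatParams:
    """Estimate ComBat parameters on training data.

    Parameters
    ----------
    Y : (n, G) phenotype matrix (G features, e.g. regions).
    batch : (n,) batch labels (at least 2 batches, each with >= 2 rows).
    design : (n, p) covariates whose effects are preserved (e.g. age and
        a sex indicator; no intercept column — the batch block spans it).
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    design = np.asarray(design, dtype=float)
    if design.ndim == 1:
        design = design[:, None]
    batch = np.asarray(batch, dtype=object)
    levels = sorted(set(map(str, batch)))
    if len(levels) < 2:
        raise ValueError("ComBat requires at least two batches")
    counts = np.array([(batch == b).sum() for b in levels], dtype=float)
    if counts.min() < 2:
        small = [b for b, c in zip(levels, counts) if c < 2]
        raise ValueError(f"every batch needs >= 2 samples for ComBat, got < 2 in {small}")
    n, G = Y.shape

    Bm = _batch_onehot(batch, levels)
    D = np.column_stack([Bm, design])
    Bhat, *_ = np.linalg.lstsq(D, Y, rcond=None)
    grand_mean = (counts / n) @ Bhat[: len(levels)]
    var_pooled = ((Y - D @ Bhat) ** 2).mean(axis=0)
    if np.any(var_pooled <= 0):
        raise ValueError("zero pooled residual variance; cannot standardize")
    beta_cov = Bhat[len(levels):]

    stand_mean = grand_mean[None, :] + design @ beta_cov
    Z = (Y - stand_mean) / np.sqrt(var_pooled)[None, :]

    gamma_star = np.empty((len(levels), G))
    delta_star = np.empty((len(levels), G))
    for i, b in enumerate(levels):
        rows = batch == b
        Z_b = Z[rows]
        gamma_hat = Z_b.mean(axis=0)
        delta_hat = Z_b.var(axis=0, ddof=1)
        if G >= 2:
            gamma_bar = gamma_hat.mean()
            tau2 = gamma_hat.var(ddof=1)
            nu, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
            if s2 > 0 and tau2 > 0:
                lam = (nu**2 + 2 * s2) / s2
                theta = (nu**3 + nu * s2) / s2
                g, dsq = _eb_iterate(Z_b, gamma_hat, delta_hat, gamma_bar, tau2, lam, theta)
            else:
                g, dsq = gamma_hat, delta_hat
        else:
            # a single feature gives no cross-feature prior: no shrinkage
            g, dsq = gamma_hat, delta_hat
        gamma_star[i], delta_star[i] = g, np.maximum(dsq, 1e-12)

    return CombatParams(levels, gamma_star, delta_star, grand_mean, beta_cov, var_pooled)


def combat_apply(params: CombatParams, Y, batch, design) -> np.ndarray:
    """Harmonize (possibly held-out) data with previously fitted parameters."""
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    design = np.asarray(design, dtype=float)
    if design.ndim == 1:
        design = design[:, None]
    idx = {b: i for i, b in enumerate(params.batches)}
    batch = np.array([str(b) for b in np.asarray(batch, dtype=object)], dtype=object)
    unseen = sorted(set(batch) - set(params.batches))
    if unseen:
        raise KeyError(f"batches unseen at ComBat fit time: {unseen}")
    b_i = np.array([idx[b] for b in batch])
    stand_mean = params.grand_mean[None, :] + design @ params.beta_cov
    Z = (Y - stand_mean) / np.sqrt(params.var_pooled)[None, :]
    Z_adj = (Z - params.gamma_star[b_i]) / np.sqrt(params.delta_star[b_i])
    return Z_adj * np.sqrt(params.var_pooled)[None, :] + stand_mean


class CombatHarmonizer(NormativeRegressor):
    """Estimator wrapper: fit ComBat on training data, transform held-out data.

    ``fit``/``transform`` take ``(Y, batch, design)``; the preserved
    design is typically ``[age, sex indicator]``.
    """

    def fit(self, Y, batch, design):
        self.params_ = combat_fit(Y, batch, design)
        return self

    def transform(self, Y, batch, design):
        check_fitted(self, "params_")
        return combat_apply(self.params_, Y, batch, design)

    def fit_transform(self, Y, batch, design):
        return self.fit(Y, batch, design).transform(Y, batch, design)


# -- module-level operation wrappers ---------------------------------------

def fit_naive_pooling(data, region, basis="linear") -> PooledNormativeModel:
    model = PooledNormativeModel(basis=basis).fit(data.covariates, data.y(region))
    model.region_ = region
    return model


def fit_fixed_effect(data, region, basis="linear") -> FixedEffectNormativeModel:
    model = FixedEffectNormativeModel(basis=basis).fit(data.covariates, data.y(region))
    model.region_ = region
    return model


def fit_no_pooling(data, region, basis="linear") -> NoPoolingNormativeModel:
    model = NoPoolingNormativeModel(basis=basis).fit(data.covariates, data.y(region))
    model.region_ = region
    return model
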