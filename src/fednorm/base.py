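"""Shared estimator plumbing for all normative-model strategies."""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator


def extract_covariates(X):
    """Pull (age, site, sex) arrays out of a covariate table.

    Accepts a DataFrame with columns ``age``, ``site``, ``sex`` (extra
    columns ignored) or a mapping of array-likes with those keys.
    """
    if isinstance(X, pd.DataFrame):
        missing = [c for c in ("age", "site", "sex") if c not in X.columns]
        if missing:
            raise ValueError(f"covariate table is missing columns {missing}")
        age = X["age"].to_numpy(float)
        site = X["site"].to_numpy(object)
        sex = X["sex"].to_numpy(object)
    else:
        try:
            age = np.asarray(X["age"], dtype=float)
            site = np.asarray(X["site"], dtype=object)
            sex = np.asarray(X["sex"], dtype=object)
        except (KeyError, TypeError) as err:
            raise ValueError("X must provide 'age', 'site' and 'sex'") from err
    if not (len(age) == len(site) == len(sex)):
        raise ValueError("age, site and sex must have equal length")
    if len(age) == 0:
        raise ValueError("empty covariate table")
    if not np.all(np.isfinite(age)):
        raise ValueError("ages must be finite")
    return age, site, sex


class NormativeRegressor(BaseEstimator):
    """Base class: every strategy predicts a per-subject (mu, sigma) pair.

    Subclasses implement ``fit(X, y)`` and ``predict_dist(X)``;
    ``predict`` and ``zscore`` derive from those.
    """

    def predict_dist(self, X, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def predict(self, X, **kwargs):
        return self.predict_dist(X, **kwargs)[0]

    def zscore(self, X, y, **kwargs):
        """Deviation z-scores: (y - f_mu(X)) / f_sigma(X)."""
        y = np.asarray(y, dtype=float)
        mu, sigma = self.predict_dist(X, **kwargs)
        if len(y) != len(mu):
            raise ValueError("y length does not match X")
        return (y - mu) / sigma


def check_fitted(model, attr: str) -> None:
    if not hasattr(model, attr):
        raise RuntimeError(f"{type(model).__name__} is not fitted")
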