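"""Regression-quality metrics and the site-leakage audit.

Three fit-quality metrics per region:

* RHO  — Pearson correlation between observed and predicted measures;
* SMSE — mean squared error standardized by the variance of the test
  targets (1 is the level of the trivial train-mean predictor);
* MSLL — mean standardized log loss: the negative Gaussian log density
  of the test targets under the predictive (mu, sigma), minus the same
  under the trivial predictor (training mean and variance). Negative is
  better; unlike RHO/SMSE it penalizes a miscalibrated variance.

The site-leakage audit quantifies residual site signal in z-scores:
for every pair of sites a linear SVM (C = 1) classifies the site label
from the subjects' z-score vectors under 5-fold stratified
cross-validation; mean one-vs-one balanced accuracy near 0.5 means the
deviations carry no site information.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC

__all__ = ["metrics", "site_leakage_audit"]


def metrics(y_true, mu_pred, sigma_pred, train_mean, train_var) -> dict:
    """RHO, SMSE and MSLL of Gaussian predictions on a test set."""
    y = np.asarray(y_true, dtype=float)
    mu = np.asarray(mu_pred, dtype=float)
    sigma = np.asarray(sigma_pred, dtype=float)
    if not (len(y) == len(mu) == len(sigma)):
        raise ValueError("y_true, mu_pred and sigma_pred must have equal length")
    if np.any(sigma <= 0):
        raise ValueError("sigma_pred must be strictly positive")
    if float(train_var) <= 0:
        raise ValueError("train_var must be positive")
    var_test = float(np.var(y))
    if var_test <= 0:
        raise ValueError("zero test-target variance; SMSE undefined")

    rho = float(stats.pearsonr(y, mu)[0]) if len(y) > 1 else float("nan")
    smse = float(np.mean((y - mu) ** 2) / var_test)
    nll_model = 0.5 * np.log(2 * np.pi * sigma**2) + (y - mu) ** 2 / (2 * sigma**2)
    nll_trivial = 0.5 * np.log(2 * np.pi * train_var) + (y - train_mean) ** 2 / (2 * train_var)
    msll = float(np.mean(nll_model - nll_trivial))
    return {"RHO": rho, "SMSE": smse, "MSLL": msll}


def site_leakage_audit(
    z_scores,
    site_labels,
    C: float = 1.0,
    n_folds: int = 5,
    random_state=None,
):
    """One-vs-one site classification from z-scores.

    Parameters
    ----------
    z_scores : (subjects x regions) array or DataFrame of deviations.
    site_labels : per-subject site labels (>= 2 sites).

    Returns
    -------
    (table, mean_accuracy) : per-pair balanced accuracies and their
    mean. Pairs in which either site has fewer subjects than the number
    of folds are skipped with a warning.
    """
    Z = np.asarray(z_scores, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    site = np.asarray(site_labels, dtype=object)
    if len(site) != len(Z):
        raise ValueError("site_labels length does not match z_scores")
    keep = np.all(np.isfinite(Z), axis=1)
    Z, site = Z[keep], site[keep]
    sites = sorted(set(map(str, site)))
    if len(sites) < 2:
        raise ValueError("the audit needs at least two sites")

    rows = []
    for s1, s2 in itertools.combinations(sites, 2):
        mask = (site == s1) | (site == s2)
        counts = ((site == s1).sum(), (site == s2).sum())
        if min(counts) < n_folds:
            warnings.warn(f"skipping pair ({s1}, {s2}): fewer than {n_folds} subjects in a site")
            continue
        clf = SVC(kernel="linear", C=C)
        cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=random_state)
        scores = cross_val_score(clf, Z[mask], (site[mask] == s2).astype(int),
                                 cv=cv, scoring="balanced_accuracy")
        rows.append({"site_a": s1, "site_b": s2, "balanced_accuracy": float(scores.mean())})
    if not rows:
        raise ValueError("no site pair had enough subjects for the audit")
    table = pd.DataFrame(rows)
    return table, float(table["balanced_accuracy"].mean())
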