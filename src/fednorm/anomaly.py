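"""Abnormal-probability scoring and unsupervised patient detection.

A deviation z-score is mapped to an abnormal probability index

    P_abn(z) = 2 * Phi(|z|) - 1,

the probability mass of a standard normal inside [-|z|, |z|]: zero for
a subject exactly on the norm, approaching one as |z| grows, symmetric
in the sign of the deviation. Region-wise ROC AUCs of this index
against diagnosis labels quantify how distinctive the deviations are,
with significance from label-permutation tests, Benjamini-Hochberg FDR
correction across regions, and a cross-run stability filter.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from statsmodels.stats.multitest import multipletests

__all__ = [
    "abnormal_probability",
    "detection_auc",
    "significance_and_stability",
]


def abnormal_probability(z):
    """P_abn(z) = 2 Phi(|z|) - 1 for scalar or array z (must be finite)."""
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("z-scores must be finite")
    out = 2.0 * stats.norm.cdf(np.abs(z)) - 1.0
    return float(out) if out.ndim == 0 else out


def detection_auc(scores, labels) -> float:
    """Rank-based ROC AUC of abnormality scores for patients vs healthy.

    ``labels`` is boolean-like with True/1 = patient. Both classes must
    be present. Ties are handled by the midrank convention.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("detection AUC needs both patient and healthy subjects")
    return float(roc_auc_score(labels, scores))


def _auc_matrix(rank_matrix, labels, n_pos, n_neg):
    """AUCs for all regions at once from a precomputed midrank matrix."""
    pos_rank_sum = labels.astype(float) @ rank_matrix
    return (pos_rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def permutation_auc_pvalues(scores, labels, n_permutations=1000, rng=None):
    """Two-sided permutation p-values for per-region AUCs.

    ``scores`` is (subjects x regions); diagnosis labels are shuffled at
    the subject level (the same permutation for all regions, preserving
    the cross-region correlation structure), and |AUC - 0.5| of the
    permuted labels is compared against the observed value.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1:
        scores = scores[:, None]
    labels = np.asarray(labels).astype(bool)
    if n_permutations < 100:
        warnings.warn("fewer than 100 permutations gives unstable p-values")
    n, R = scores.shape
    n_pos = int(labels.sum())
    n_neg = n - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("permutation test needs both classes")
    ranks = np.empty_like(scores)
    for j in range(R):
        ranks[:, j] = stats.rankdata(scores[:, j])
    auc_obs = _auc_matrix(ranks, labels, n_pos, n_neg)
    rng = np.random.default_rng(rng)
    exceed = np.zeros(R)
    stat_obs = np.abs(auc_obs - 0.5)
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        auc_p = _auc_matrix(ranks, perm, n_pos, n_neg)
        exceed += np.abs(auc_p - 0.5) >= stat_obs - 1e-12
    pvals = (1.0 + exceed) / (n_permutations + 1.0)
    return auc_obs, pvals


def significance_and_stability(
    runs,
    n_permutations=1000,
    stability_k=9,
    fdr_q=0.05,
    rng=None,
    region_names=None,
) -> pd.DataFrame:
    """Significant-and-stable region report across repeated runs.

    Parameters
    ----------
    runs : list of (scores, labels) pairs, one per experimental run;
        ``scores`` is (subjects x regions) abnormality indices on that
        run's test set.
    stability_k : a region is reported iff it passes FDR correction in
        at least this many runs (the default asks 9 of 10).

    Returns a DataFrame with one row per region: mean AUC, number of
    runs in which it passed FDR, and the reported flag.
    """
    rng = np.random.default_rng(rng)
    n_runs = len(runs)
    if n_runs == 0:
        raise ValueError("no runs supplied")
    aucs, passed = [], []
    for scores, labels in runs:
        auc, pvals = permutation_auc_pvalues(scores, labels, n_permutations, rng)
        reject, *_ = multipletests(pvals, alpha=fdr_q, method="fdr_bh")
        aucs.append(auc)
        passed.append(reject)
    aucs = np.asarray(aucs)
    passed = np.asarray(passed)
    R = aucs.shape[1]
    if region_names is None:
        region_names = [f"region_{j:03d}" for j in range(R)]
    runs_passed = passed.sum(axis=0)
    return pd.DataFrame(
        {
            "region": region_names,
            "mean_auc": aucs.mean(axis=0),
            "runs_passed": runs_passed,
            "reported": runs_passed >= stability_k,
        }
    ).set_index("region")
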