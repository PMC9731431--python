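"""Tabular container for multi-site normative-modeling data.

A :class:`NormativeDataset` couples a covariate table (age, sex, site,
clinical group) with a phenotype table (one column per named regional
measure, e.g. cortical thickness per region) sharing a subject-id index.
Synthetic cohorts additionally carry the generative ground truth (the
per-subject normative mean and standard deviation of every region) in
``truth`` so estimators can be tested against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REQUIRED_COVARIATES = ("age", "sex", "site")

HEALTHY = "HC"
PATIENT = "PT"


@dataclass
class NormativeDataset:
    covariates: pd.DataFrame
    phenotypes: pd.DataFrame
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        cov, phe = self.covariates, self.phenotypes
        for col in REQUIRED_COVARIATES:
            if col not in cov.columns:
                raise ValueError(f"covariates table is missing column {col!r}")
        if "group" not in cov.columns:
            cov = cov.copy()
            cov["group"] = HEALTHY
            self.covariates = cov
        if not cov.index.equals(phe.index):
            raise ValueError("covariates and phenotypes must share the same subject index")
        if cov.index.duplicated().any():
            dups = cov.index[cov.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate subject ids: {dups[:5]}")

    # -- basic accessors -------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.covariates)

    @property
    def regions(self) -> list[str]:
        return list(self.phenotypes.columns)

    @property
    def sites(self) -> list[str]:
        return sorted(self.covariates["site"].unique())

    @property
    def age(self) -> np.ndarray:
        return self.covariates["age"].to_numpy(float)

    def y(self, region: str) -> np.ndarray:
        if region not in self.phenotypes.columns:
            raise KeyError(f"unknown region {region!r}")
        return self.phenotypes[region].to_numpy(float)

    def is_healthy(self) -> np.ndarray:
        return (self.covariates["group"] == HEALTHY).to_numpy()

    # -- subsetting / combination ----------------------------------------
    def subset(self, mask) -> "NormativeDataset":
        """Return the dataset restricted to a boolean mask or index array."""
        cov = self.covariates.loc[mask] if not isinstance(mask, np.ndarray) else self.covariates[mask]
        phe = self.phenotypes.loc[cov.index]
        truth = {}
        for key, val in self.truth.items():
            truth[key] = val.loc[cov.index]
        return NormativeDataset(cov.copy(), phe.copy(), truth)

    def healthy(self) -> "NormativeDataset":
        return self.subset(self.is_healthy())

    @staticmethod
    def concat(parts: list["NormativeDataset"]) -> "NormativeDataset":
        cov = pd.concat([p.covariates for p in parts])
        phe = pd.concat([p.phenotypes for p in parts])
        keys = set.intersection(*(set(p.truth) for p in parts)) if parts else set()
        truth = {k: pd.concat([p.truth[k] for p in parts]) for k in keys}
        return NormativeDataset(cov, phe, truth)

    def split(self, train_frac: float, rng) -> tuple["NormativeDataset", "NormativeDataset"]:
        """Random train/test split, stratified by (site, sex) batch.

        Stratification keeps every observed batch represented on both
        sides whenever it has at least two subjects.
        """
        if not 0.0 < train_frac < 1.0:
            raise ValueError("train_frac must be in (0, 1)")
        rng = np.random.default_rng(rng)
        n = self.n_subjects
        train_mask = np.zeros(n, dtype=bool)
        batch_key = self.covariates["site"].astype(str) + "\x00" + self.covariates["sex"].astype(str)
        for _, idx in batch_key.groupby(batch_key).groups.items():
            pos = self.covariates.index.get_indexer(idx)
            perm = rng.permutation(len(pos))
            n_train = int(round(train_frac * len(pos)))
            n_train = min(max(n_train, 1 if len(pos) > 1 else len(pos)), len(pos) - 1) if len(pos) > 1 else len(pos)
            train_mask[pos[perm[:n_train]]] = True
        return self.subset(train_mask), self.subset(~train_mask)

    # -- persistence ------------------------------------------------------
    def to_csv(self, covariates_path, phenotypes_path, truth_path=None) -> None:
        self.covariates.to_csv(covariates_path, index_label="subject_id")
        self.phenotypes.to_csv(phenotypes_path, index_label="subject_id")
        if truth_path is not None and self.truth:
            wide = {}
            for key, val in self.truth.items():
                if isinstance(val, pd.Series):
                    wide[key] = val
                else:
                    for col in val.columns:
                        wide[f"{key}.{col}"] = val[col]
            pd.DataFrame(wide).to_csv(truth_path, index_label="subject_id")
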