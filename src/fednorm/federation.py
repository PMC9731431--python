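"""Federated model extension and informative-prior adaptation.

Two mechanisms let a reference normative model travel without its data:

* **Extension** (development phase): to add a new site's dataset to a
  model without access to the earlier sites' raw data, draw a synthetic
  cohort from the model's posterior predictive over its known batches,
  concatenate it with the new data, and refit. Repeating this as
  datasets arrive trains a reference model on fully decentralized data.

* **Adaptation** (deployment phase): summarize the posterior of the
  reference model's *hyperparameters* as Gaussian hyperpriors (a small,
  site-free JSON payload) and refit on local data only under those
  informative priors. Because small batches shrink toward the
  transferred prior, this stays well-behaved down to 0 or 1 local
  subjects per batch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import NormativeDataset
from .hbr import HBRNormativeModel, HyperpriorSpec, build_and_fit

__all__ = [
    "GenerationProtocol",
    "extend",
    "extract_informative_hyperprior",
    "adapt",
]


@dataclass(frozen=True)
class GenerationProtocol:
    """Posterior-predictive generation grid for model extension.

    The default grid — ages 10..89 in 1-year steps, both sexes, 5
    replicates per cell — produces 80 x 2 x 5 = 800 synthetic rows per
    prior site.
    """

    age_lo: float = 10.0
    age_hi: float = 90.0
    age_step: float = 1.0
    n_reps: int = 5

    @property
    def ages(self) -> np.ndarray:
        return np.arange(self.age_lo, self.age_hi, self.age_step)


def extend(
    model_prev: HBRNormativeModel,
    new_data: NormativeDataset,
    protocol: GenerationProtocol | None = None,
    rng=None,
    sampler: dict | None = None,
    random_state=None,
) -> HBRNormativeModel:
    """Refit the model with a new site's data plus a synthetic stand-in
    for all previously seen sites.

    ``new_data`` may be empty (self-distillation); its sites must not
    collide with sites already known to ``model_prev``. The returned
    model's batch registry is the union of old and new batches. Raw
    prior-stage data are never an input.
    """
    protocol = protocol or GenerationProtocol()
    region = getattr(model_prev, "region_", None)
    if region is None:
        raise ValueError("model_prev must have been fitted on a named region (build_and_fit)")
    known_sites = {s for s, _ in model_prev.registry_.batches}
    if new_data.n_subjects:
        collisions = sorted(known_sites & set(new_data.sites))
        if collisions:
            raise ValueError(f"new data reuses sites already in the model: {collisions}")
        if region not in new_data.regions:
            raise KeyError(f"new data has no region {region!r}")

    synth = model_prev.sample_posterior_predictive(
        ages=protocol.ages, n_reps=protocol.n_reps, rng=rng, region=region
    )
    parts = [synth]
    if new_data.n_subjects:
        parts.append(
            NormativeDataset(new_data.covariates.copy(), new_data.phenotypes[[region]].copy())
        )
    combined = NormativeDataset.concat(parts)

    settings = {
        "draws": model_prev.draws, "tune": model_prev.tune, "chains": model_prev.chains,
        "target_accept": model_prev.target_accept, "max_treedepth": model_prev.max_treedepth,
        "center_threshold": model_prev.center_threshold,
    }
    settings.update(sampler or {})
    return build_and_fit(
        combined, region,
        basis=model_prev.basis_, noise_mode=model_prev.noise_mode,
        sampler=settings,
        random_state=random_state if random_state is not None else model_prev.random_state,
    )


def extract_informative_hyperprior(
    model: HBRNormativeModel, scale_floor: float = 1e-3
) -> HyperpriorSpec:
    """Summarize the hyperparameter posterior as a Gaussian hyperprior.

    Each hyperparameter (prior mean per coefficient, log prior spread
    per coefficient, and the noise-model counterparts) is summarized by
    the mean and sd of its posterior draws; sds are floored at
    ``scale_floor`` so a degenerate posterior still yields a proper
    (if very confident) prior.
    """
    post = model.posterior_
    out = {}
    for name, (m_key, s_key) in {
        "mu_coef": ("m_mu", "s_mu"),
        "log_sd_coef": ("m_logsd", "s_logsd"),
        "mu_noise": ("m_mu_sigma", "s_mu_sigma"),
        "log_sd_noise": ("m_logsd_sigma", "s_logsd_sigma"),
    }.items():
        draws = post[name].reshape(-1, post[name].shape[-1])
        mean = draws.mean(axis=0)
        sd = np.maximum(draws.std(axis=0, ddof=1), scale_floor)
        if not (np.all(np.isfinite(mean)) and np.all(np.isfinite(sd))):
            raise ValueError(f"non-finite posterior summary for {name}")
        out[m_key] = tuple(mean)
        out[s_key] = tuple(sd)
    return HyperpriorSpec(**out)


def adapt(
    reference_spec: HyperpriorSpec,
    local_data: NormativeDataset,
    region: str,
    basis="linear",
    noise_mode: str = "homoscedastic",
    fit_range=None,
    sampler: dict | None = None,
    random_state=None,
) -> HBRNormativeModel:
    """Refit on local data only, under the transferred informative prior.

    The basis (and, when supplied, the reference model's ``fit_range``,
    which fixes the coordinate system the transferred coefficients live
    in) must match the reference configuration; a dimension mismatch
    raises before any sampling.
    """
    from .design import BasisConfig

    cfg = basis if isinstance(basis, BasisConfig) else BasisConfig(basis)
    ks = 1 if noise_mode == "homoscedastic" else cfg.n_columns
    if reference_spec.n_coef != cfg.n_columns or reference_spec.n_noise_coef != ks:
        raise ValueError(
            f"basis mismatch: hyperprior spec carries {reference_spec.n_coef} mean / "
            f"{reference_spec.n_noise_coef} noise coefficients but basis {cfg.kind!r} "
            f"needs {cfg.n_columns} / {ks}"
        )
    model = HBRNormativeModel(
        basis=cfg, noise_mode=noise_mode, hyperprior=reference_spec,
        fit_range=tuple(fit_range) if fit_range is not None else None,
        random_state=random_state, **(sampler or {}),
    )
    model.fit(local_data.covariates, local_data.y(region))
    model.region_ = region
    return model
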