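import numpy as np
import pytest

from fednorm.hbr import build_and_fit
from fednorm.synthetic_data import CohortSpec, SiteSpec, generate_cohort

# reduced sampler settings used throughout the suite to keep runtimes short
FAST = dict(chains=1, tune=250, draws=250)
TWO_CHAIN = dict(chains=2, tune=300, draws=300)


def four_site_spec(n_per_site=150, n_regions=2, seed=11, clinical_fraction=0.0,
                   clinical_effect=(), noise=(0.09, 0.12, 0.14, 0.10)):
    """Four sites with salient additive/multiplicative effects and
    site-specific noise, linear age curve at cortical-thickness scale."""
    shifts = (0.0, 0.30, -0.25, 0.10)
    scales = (1.0, 0.85, 1.15, 1.0)
    ranges = ((12, 80), (20, 88), (10, 70), (15, 85))
    sites = [
        SiteSpec(f"site{i}", n_per_site, ranges[i], shifts[i], scales[i], noise[i])
        for i in range(4)
    ]
    return CohortSpec(
        sites=tuple(sites), n_regions=n_regions,
        intercepts=(2.6, 2.4)[:n_regions],
        slopes=(-0.010, -0.006)[:n_regions],
        sex_offsets=(0.08, -0.05)[:n_regions],
        clinical_fraction=clinical_fraction,
        clinical_effect=clinical_effect,
        seed=seed,
    )


@pytest.fixture(scope="session")
def cohort():
    """Four-site healthy cohort with a train/test split."""
    data = generate_cohort(four_site_spec())
    train, test = data.split(0.8, np.random.default_rng(0))
    return data, train, test


@pytest.fixture(scope="session")
def hbr_model(cohort):
    """One HBR fit (region_000) reused by every read-only test."""
    _, train, _ = cohort
    return build_and_fit(train, "region_000", sampler=TWO_CHAIN, random_state=0)
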