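"""Shared fixtures: simulated experiments and their (expensive) model fits.

The fitted fixtures are session-scoped so that the recovery, variant-
contrast and residual-immigration tests share the same three replicate
fits instead of refitting per test.
"""

from __future__ import annotations

import numpy as np
import pytest

from spatialipm.inference import FitConfig, fit_ipm
from spatialipm.io import bundle_from_sim
from spatialipm.multievent import DetectionParams
from spatialipm.simulate import (
    closed_area,
    closed_scenario,
    generate_landscape,
    reduced_scenario,
    simulate_dataset,
)

REPLICATE_SEEDS = (3, 4, 5)


@pytest.fixture(scope="session")
def reduced_landscape():
    return generate_landscape(n_core_sites=64, n_peripheral_sites=32, rng_seed=1)


@pytest.fixture(scope="session")
def closed_landscape():
    return generate_landscape(
        area=closed_area(), n_core_sites=96, n_peripheral_sites=0, rng_seed=2
    )


@pytest.fixture(scope="session")
def emig_experiments(reduced_landscape):
    """Three replicates of the emigration-prone scenario, each fitted with
    both model variants."""
    out = []
    for seed in REPLICATE_SEEDS:
        sim = simulate_dataset(reduced_landscape, reduced_scenario(seed=seed))
        bundle = bundle_from_sim(sim, reduced_landscape.area)
        post_sp = fit_ipm(bundle, FitConfig.desk(seed=100 + seed))
        post_ns = fit_ipm(
            bundle, FitConfig.desk(seed=100 + seed, variant="nonspatial")
        )
        out.append((sim, post_sp, post_ns))
    return out


@pytest.fixture(scope="session")
def closed_experiments(closed_landscape):
    """Three replicates of the closed population (no immigration, negligible
    emigration), fitted with the spatial variant."""
    out = []
    for seed in REPLICATE_SEEDS:
        sim = simulate_dataset(closed_landscape, closed_scenario(seed=seed))
        bundle = bundle_from_sim(sim, closed_landscape.area)
        post = fit_ipm(
            bundle, FitConfig.desk(seed=200 + seed, compute_emigration=False)
        )
        out.append((sim, post))
    return out


@pytest.fixture(scope="session")
def ideal_experiment(closed_landscape):
    """Perfect detection, effectively infinite area: the spatial and
    non-spatial variants see identical information."""
    sc = closed_scenario(seed=9, detection=DetectionParams(1.0, 1.0, 1.0, 1.0))
    sim = simulate_dataset(closed_landscape, sc)
    bundle = bundle_from_sim(sim, closed_landscape.area)
    post_sp = fit_ipm(bundle, FitConfig.desk(seed=300, compute_emigration=False))
    post_ns = fit_ipm(bundle, FitConfig.desk(seed=300, variant="nonspatial"))
    return sim, post_sp, post_ns


def mean_rate_ci(post, name, level=0.95):
    """Posterior CI of the across-year mean rate, per habitat: (lo, hi) each
    of shape (2,)."""
    draws = post.stacked(name).mean(axis=1)
    alpha = (1 - level) / 2
    return np.quantile(draws, alpha, axis=0), np.quantile(draws, 1 - alpha, axis=0)


def covered(post, name, truth, level=0.95):
    """Whether the across-year mean truth lies inside the posterior CI,
    per habitat (bool array of shape (2,))."""
    lo, hi = mean_rate_ci(post, name, level)
    truth = np.asarray(truth)
    return (lo <= truth) & (truth <= hi)
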