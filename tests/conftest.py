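"""Shared fixtures: the default synthetic umbrella study at full density.

The full-density dataset (24 windows, 0.5 A spacing, 6 kcal/(mol A^2) bias,
20,000 stored samples per window, 300 K) is expensive to generate, so it is
session-scoped and shared by the sampler, WHAM and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from acidassoc import (
    SamplerConfig,
    WhamConfig,
    make_default_pmf,
    run_schedule,
    solve_wham,
)

#: Seed for the frozen full-density fixture.
FIXTURE_SEED = 11


@pytest.fixture(scope="session")
def default_model():
    return make_default_pmf()


@pytest.fixture(scope="session")
def default_dataset(default_model):
    """Full-density acid-acid dataset at 300 K."""
    return run_schedule(default_model, config=SamplerConfig(seed=FIXTURE_SEED))


@pytest.fixture(scope="session")
def default_profile(default_dataset):
    return solve_wham(default_dataset, WhamConfig(bin_width=0.05))


@pytest.fixture(scope="session")
def small_dataset(default_model):
    """A cheap 8-window dataset over the well region for fast WHAM tests."""
    return run_schedule(
        default_model,
        r_start=7.0,
        r_end=3.5,
        config=SamplerConfig(n_samples=3000, n_equilibration=500, seed=FIXTURE_SEED),
    )


def biased_cdf(model, center, spring_kcal, temperature, grid):
    """Quadrature CDF of the biased Boltzmann density on a fine grid."""
    from acidassoc.synthetic_umbrella import evaluate_pmf
    from acidassoc.units import kT, spring_kcal_to_kj

    w = evaluate_pmf(model, grid) + 0.5 * spring_kcal_to_kj(spring_kcal) * (grid - center) ** 2
    logp = -w / kT(temperature)
    p = np.exp(logp - logp.max())
    cdf = np.cumsum(p)
    return cdf / cdf[-1]
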