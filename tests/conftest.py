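"""Shared fixtures: default panel, synthetic cohorts, trained models.

Cohort fixtures are session-scoped because generation dominates test run
time; tests must not mutate them.
"""

import numpy as np
import pytest

from smolesy import (CohortSpec, GridSpec, collect_training_observations,
                     fit_correlation_models, load_panel, simulate_cohort)
from smolesy.synthetic import draw_sample_spec, simulate_sample


@pytest.fixture(scope="session")
def panel():
    return load_panel()


@pytest.fixture(scope="session")
def cohort_spec():
    return CohortSpec()


@pytest.fixture(scope="session")
def train_cohort(panel, cohort_spec):
    spectra, truth = simulate_cohort(60, panel, cohort_spec, seed=99)
    return spectra, truth


@pytest.fixture(scope="session")
def trained_models(panel, train_cohort):
    spectra, _ = train_cohort
    obs = collect_training_observations(spectra, panel)
    models, untrained = fit_correlation_models(obs, panel)
    assert not untrained
    return models


@pytest.fixture(scope="session")
def eval_cohort(panel, cohort_spec):
    """The cohort the acceptance accuracy figures are measured on."""
    spectra, truth = simulate_cohort(200, panel, cohort_spec, seed=1)
    return spectra, truth


@pytest.fixture(scope="session")
def single_sample(panel, cohort_spec):
    """One spectrum plus its truth table and latent sample spec."""
    rng = np.random.default_rng(7)
    spec = draw_sample_spec(rng, panel, cohort_spec, "single")
    spectrum, truth = simulate_sample(spec, panel, cohort_spec.grid,
                                      cohort_spec.water_band)
    return spectrum, truth, spec


@pytest.fixture()
def fine_grid():
    """A dense grid helper for analytic lineshape tests."""
    def make(span_ppm=0.5, n=65536, sf=600.13):
        return GridSpec(n_points=n, offset_ppm=span_ppm / 2,
                        sw_ppm=span_ppm, sf_mhz=sf)
    return make
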