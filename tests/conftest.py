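"""Shared fixtures: toy crystals, simulated data, and one refined model per
session (refinement is the expensive stage, so its results are shared)."""

import numpy as np
import pytest

from chargemc import ensemble as en
from chargemc import fixtures as fx
from chargemc import refine as rf

FIXED_ORIGIN = (("C1", "xyz"),)   # pins the floating P1 origin


@pytest.fixture(scope="session")
def diatomic_truth():
    return fx.make_toy_crystal("diatomic_p1")


@pytest.fixture(scope="session")
def bent_model():
    return fx.make_toy_crystal("bent_triatomic_pminus1")


@pytest.fixture(scope="session")
def hbond_model():
    return fx.make_toy_crystal("hbond_chain_p1")


@pytest.fixture(scope="session")
def noisy_reflections(diatomic_truth):
    spec = fx.ToySpec(noise_level=0.02, s_max=0.8, seed=7)
    return fx.simulate_intensities(diatomic_truth, spec)


@pytest.fixture(scope="session")
def exact_reflections(diatomic_truth):
    spec = fx.ToySpec(noise_level=0.0, s_max=0.8)
    return fx.simulate_intensities(diatomic_truth, spec)


@pytest.fixture(scope="session")
def refined(diatomic_truth, noisy_reflections):
    start = fx.perturb_model(diatomic_truth, seed=8, scale=0.5)
    start.atom("C1").frac[:] = diatomic_truth.atom("C1").frac
    return rf.gauss_newton_refine(start, noisy_reflections,
                                  fixed=FIXED_ORIGIN)


@pytest.fixture(scope="session")
def zero_noise_refined(diatomic_truth, exact_reflections):
    start = fx.perturb_model(diatomic_truth, seed=5, scale=0.5)
    start.atom("C1").frac[:] = diatomic_truth.atom("C1").frac
    return rf.gauss_newton_refine(start, exact_reflections,
                                  fixed=FIXED_ORIGIN)


@pytest.fixture(scope="session")
def parameter_ensemble_200(refined):
    sq = en.covariance_sqrt(refined.normal, refined.covariance)
    x_min = rf.pack_parameters(refined.model, fixed=FIXED_ORIGIN)
    return en.generate_ensemble(x_min, sq, 200, seed=42)


@pytest.fixture(scope="session")
def small_ensemble(refined):
    """N = 20 deviating models, the reference ensemble size."""
    sq = en.covariance_sqrt(refined.normal, refined.covariance)
    x_min = rf.pack_parameters(refined.model, fixed=FIXED_ORIGIN)
    return en.generate_ensemble(x_min, sq, 20, seed=11)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)
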