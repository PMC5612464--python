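"""Shared fixtures: emulated data, a calibrated reference model, and the
full ten-configuration fit (session-scoped; the expensive pieces are built
once)."""

import numpy as np
import pytest
from hypothesis import settings

from melmark.calibration import (default_parameters, fit_configuration,
                                 select_best_model)
from melmark.synthetic_aihw import AnchorSet, build_observed_series

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def anchors():
    return AnchorSet()


@pytest.fixture(scope="session")
def observed(anchors):
    return build_observed_series(anchors)


@pytest.fixture(scope="session")
def template():
    """Seed parameters for the reference (D0=0.05, p=15) configuration."""
    return default_parameters(0.05, 15.0)


@pytest.fixture(scope="session")
def reference_model(anchors):
    """Calibrated and fitted model for the reference configuration."""
    return fit_configuration(anchors, 0.05, 15.0)


@pytest.fixture(scope="session")
def all_models(anchors, observed):
    """Best-fit models for all ten (D0, p) configurations."""
    return select_best_model(anchors, observed=observed)


def random_admissible_parameters(rng):
    """A random parameter set with feasible rows, for property tests."""
    from melmark.model_core import ParameterSet
    r = rng.uniform(5e-4, 6e-3)
    d0 = rng.uniform(0.01, 0.3)
    return ParameterSet(
        I0=rng.uniform(1e-5, 5e-3), D0=d0, O0=rng.uniform(0.0, 0.1),
        r=r, p=rng.uniform(1.0, 150.0), q=rng.uniform(0.05, 0.6),
        d=rng.uniform(1e-3, 0.02), t4=rng.uniform(0.05, 0.4),
        t5=rng.uniform(0.3, 0.9), t6=rng.uniform(0.02, 0.3),
        t7=rng.uniform(0.05, 0.3), f23=rng.uniform(0.0, 0.1),
        f4=rng.uniform(0.0, 0.05))
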