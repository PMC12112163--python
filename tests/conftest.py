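"""Shared fixtures.

The medium-fixture Young/Aged co-simulations are expensive, so they are run
once per session and shared by the energy, ageing and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from emcosim.ageing import AGED_DEFAULT, age_population
from emcosim.circuit import (PopulationSpec, LayerSpec, build_population,
                             calibrate_stimulus, fixture_population)
from emcosim.coupling import run_coupled

MEDIUM_SEED = 7


@pytest.fixture(scope="session")
def medium_population():
    spec = fixture_population("medium")
    pop = build_population(spec)
    stims, rates, warns = calibrate_stimulus(pop, (1.0, 10.0), budget=6,
                                             seed=spec.seed)
    return build_population(spec, stim_overrides=stims)


@pytest.fixture(scope="session")
def medium_young(medium_population):
    return run_coupled(medium_population, 3000.0, mode="coupled",
                       seed=MEDIUM_SEED)


@pytest.fixture(scope="session")
def medium_aged(medium_population):
    aged_pop = age_population(medium_population, AGED_DEFAULT)
    return run_coupled(aged_pop, 3000.0, mode="coupled", seed=MEDIUM_SEED)


@pytest.fixture(scope="session")
def smoke_population():
    spec = fixture_population("smoke")
    return build_population(spec)


def small_test_spec(total=20, seed=5):
    """A compact two-layer population for coupling-scheme tests."""
    layers = (
        LayerSpec(layer=2, fraction=0.5, exc_fraction=0.5,
                  mixture={"cADpyr": 0.5, "cNAC": 0.5},
                  mito_density_scale=1.0),
        LayerSpec(layer=4, fraction=0.5, exc_fraction=0.5,
                  mixture={"cADpyr": 0.5, "cAC": 0.5},
                  mito_density_scale=1.1),
    )
    return PopulationSpec(total=total, layers=layers, seed=seed, name="test20")
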