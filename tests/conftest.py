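"""Shared fixtures: calibrated surfaces and one full Path-1 pipeline run."""

from __future__ import annotations

import pytest

from protonpmf import EnergeticsTarget, calibrate_surface
from protonpmf.io import default_config_path, load_config
from protonpmf.pipeline import run_pathway


@pytest.fixture(scope="session")
def path1_surface():
    return calibrate_surface(EnergeticsTarget(reaction_energy=17.6, barrier_height=18.7))


@pytest.fixture(scope="session")
def default_config():
    return load_config(default_config_path())


@pytest.fixture(scope="session")
def path1_result(default_config):
    """One full Path-1 umbrella + WHAM run, shared across tests (seed 1)."""
    return run_pathway(default_config, seed=1)
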