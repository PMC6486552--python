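"""Shared fixtures: small deterministic simulations reused across tests."""

import numpy as np
import pytest
from hypothesis import settings

from ssb_recycling.config import SimulationConfig
from ssb_recycling import sim_core as sc

settings.register_profile("det", derandomize=True, deadline=None)
settings.load_profile("det")


@pytest.fixture(scope="session")
def chase_cfg() -> SimulationConfig:
    """Chase conditions: pre-assembled labelled SSB, no solution pool."""
    return SimulationConfig(
        c_ssb=0.0,
        k_intr=0.0,
        L_mean_knt=1.4,
        initial_tetramers=40,
        duration=40.0,
        tau_b=9.5,
        noise_sd=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def chase_run(chase_cfg):
    return sc.simulate_replisome(chase_cfg)


@pytest.fixture(scope="session")
def frap_cfg() -> SimulationConfig:
    """In-vitro FRAP conditions at 10 nM with an injected 10-s exchange time."""
    return SimulationConfig(
        c_ssb=10.0,
        k_intr=0.0,
        k_fac=1.0 / (10.0 * 10.0),
        tau_b=400.0,
        pulse_times=[15.0, 50.0, 85.0],
        duration=120.0,
        noise_sd=1.0,
        seed=3,
    )


@pytest.fixture(scope="session")
def frap_run(frap_cfg):
    return sc.simulate_replisome(frap_cfg)
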