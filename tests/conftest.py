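"""Shared fixtures: small illustrative configurations used across the
suite. All data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repeatable", derandomize=True, deadline=None,
                          database=None)
settings.load_profile("repeatable")

from pcbrtm import (
    Congener,
    MicrocosmConfig,
    PufSpec,
    RTMParams,
    SpmeSpec,
    default_congeners,
)


@pytest.fixture(scope="session")
def congeners():
    return default_congeners()


@pytest.fixture(scope="session")
def pcb4(congeners):
    return congeners[0]


@pytest.fixture
def shaken_cfg():
    return MicrocosmConfig(regime="shaken")


@pytest.fixture
def nonshaken_cfg():
    return MicrocosmConfig(regime="nonshaken")


@pytest.fixture
def base_params():
    return RTMParams()


@pytest.fixture
def inert_params():
    """All exchange and reaction rates (effectively) zero: a closed,
    inert flask. Sampler rate constants must be positive, so they are set
    to values that move nothing over any tested horizon."""
    return RTMParams(
        k_bio=0.0,
        k_fast=0.0,
        k_slow=0.0,
        v_aw=0.0,
        k_bl=0.0,
        puf=PufSpec(k_puf=1e-12),
        spme=SpmeSpec(k_sp=1e-12, k_fw=1e-12),
    )


@pytest.fixture
def decay_params(inert_params):
    """Only first-order degradation of the dissolved phase active."""
    from dataclasses import replace

    return replace(inert_params, k_bio=0.3)
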