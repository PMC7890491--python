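import numpy as np
import pytest

from dspom import (
    HydroParams,
    Wetland,
    Wetlandscape,
    generate_forcing,
    generate_wetlandscape,
    simulate_hydrology,
)
from dspom.forcing import ForcingSeries


@pytest.fixture
def cone_wetland():
    """p = 2 basin: area linear in stage, volume quadratic."""
    return Wetland(id="w0", x=0.0, y=0.0, A_max=10_000.0, h_max=2.0, p=2.0, ca_ratio=1.0)


@pytest.fixture
def small_landscape():
    return generate_wetlandscape(
        n_patches=12,
        extent=(2_000.0, 2_000.0),
        area_law={"kind": "lognormal", "mean": 12_000.0, "cv": 1.0},
        h_max_law={"kind": "uniform", "low": 1.0, "high": 2.0},
        bathymetry_law={"kind": "uniform", "low": 1.5, "high": 3.0},
        ca_ratio=2.0,
        min_centre_separation=80.0,
        seed=11,
    )


@pytest.fixture
def constant_hydro(small_landscape):
    """Time-constant hydrology: no fluxes at all, wetlands stay at full pool."""
    forcing = ForcingSeries(rain=np.zeros(60), pet=np.zeros(60))
    return simulate_hydrology(
        small_landscape, forcing, HydroParams(k_leak=0.0), h0="full"
    )


@pytest.fixture
def fluctuating_hydro(small_landscape):
    forcing = generate_forcing(alpha=0.9, lambda_freq=0.2, T=365, pet=0.5, seed=7)
    return simulate_hydrology(small_landscape, forcing, HydroParams(k_leak=0.1))
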