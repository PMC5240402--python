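"""Shared fixtures: the standard two-pump scenario and its precomputed flows."""

import numpy as np
import pytest

import infusim as I
from infusim import catheter as cat
from infusim import network as net
from infusim import scenarios as scn

ML_H = 1.0 / 3600.0  # ml/h in ml/s

U_DOWNSTEP = 6.0 * ML_H
U_RED = 0.5 * ML_H
U_GREEN_OLD = 12.0 * ML_H
U_GREEN_NEW = 6.0 * ML_H
U_FINAL = U_GREEN_NEW + U_RED


@pytest.fixture(scope="session")
def std():
    return I.standard_setup()


@pytest.fixture(scope="session")
def std_transient(std):
    return net.transient_flow(std, U_DOWNSTEP)


@pytest.fixture(scope="session")
def std_horizon(std, std_transient):
    return cat.truncation_horizon(
        std_transient.theta_second, std.catheter.volume, U_FINAL
    )


@pytest.fixture(scope="session")
def std_grid(std, std_horizon):
    return scn.scenario_grid(std, std_horizon)


@pytest.fixture(scope="session")
def std_ode_flow(std, std_grid):
    return net.state_space_simulate(std, std_grid)


@pytest.fixture(scope="session")
def std_flow_total(std, std_grid):
    return net.analytic_flow_trace(std, U_DOWNSTEP, std_grid, "total")


@pytest.fixture(scope="session")
def std_flow_changed(std, std_grid):
    return net.analytic_flow_trace(std, U_DOWNSTEP, std_grid, "changed_branch")


def random_two_pump(rng, n_voxels=10_000):
    """Log-uniform draw within a factor 10 of the standard values."""
    from infusim.config import CatheterSpec, InfusionSetup, PumpChannel

    f = lambda: float(10.0 ** rng.uniform(-1.0, 1.0))
    u_old = U_GREEN_OLD * f()
    u_new = u_old * float(rng.uniform(0.1, 0.9))
    green = PumpChannel(
        "green", 1.5e-5 * f(), 23.0 * 3600.0 * f(),
        ((-3600.0, u_old), (0.0, u_new)),
    )
    red = PumpChannel(
        "red", 1.5e-5 * f(), 23.0 * 3600.0 * f(), ((-3600.0, U_RED * f()),)
    )
    cathspec = CatheterSpec(
        resistance=1145.0 * 3600.0 * f(), volume=1.0, length=1.0, n_voxels=n_voxels
    )
    return InfusionSetup((green, red), cathspec)
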