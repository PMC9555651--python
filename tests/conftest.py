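"""Shared fixtures.

The expensive artifacts (long full-memory integrations and the
Lyapunov spectrum) are computed once per session and shared between
the unit tests and the acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from fracstress import (
    FractionalOrders,
    LyapunovConfig,
    SolverConfig,
    TABLE1,
    benettin_wolf,
    find_equilibria,
    integrate,
)
from fracstress.model import params_vector, stress_field


#: Forcing/kindling settings of the chaotic reference regime.
CHAOTIC = TABLE1.replace(B=2.2, rho=11.0, omega=1.5)


@pytest.fixture(scope="session")
def chaotic_params():
    return CHAOTIC


@pytest.fixture(scope="session")
def chaotic_traj():
    """Reference chaotic run: q=0.99, h=0.01, t_end=1000, IC (1,1,1)."""
    cfg = SolverConfig(h=0.01, t_end=1000.0, initial_state=(1.0, 1.0, 1.0))
    traj = integrate(
        stress_field, FractionalOrders(0.99), cfg, params_vector=params_vector(CHAOTIC)
    )
    assert not traj.diverged
    return traj


@pytest.fixture(scope="session")
def omega1_traj():
    """Same as chaotic_traj but at forcing frequency omega = 1.0 (periodic)."""
    p = CHAOTIC.replace(omega=1.0)
    cfg = SolverConfig(h=0.01, t_end=1000.0, initial_state=(1.0, 1.0, 1.0))
    traj = integrate(
        stress_field, FractionalOrders(0.99), cfg, params_vector=params_vector(p)
    )
    assert not traj.diverged
    return traj


@pytest.fixture(scope="session")
def lyap_spectrum():
    """Benettin-Wolf spectrum of the chaotic regime (t_total=1000, h=0.01)."""
    orders = FractionalOrders(0.99)
    cfg = LyapunovConfig(
        t_total=1000.0,
        transient=100.0,
        solver=SolverConfig(h=0.01, t_end=1000.0, initial_state=(1.0, 1.0, 1.0)),
        orders=orders,
    )
    return benettin_wolf(CHAOTIC, orders, cfg)


@pytest.fixture(scope="session")
def equilibria_b22():
    return find_equilibria(CHAOTIC)
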