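"""Shared fixtures: compound models and (cached) kinetic trajectories.

The long simulations are session-scoped so each compound's network is
integrated once for the whole run, however many tests look at it.
"""

from __future__ import annotations

import pytest

from nucstab.kinetics import build_network, simulate
from nucstab.presets import build_model, load_preset
from nucstab.speciation import solve_equilibrium
from nucstab.thermo import BarrierSpec, ThermoContext

C0 = 1e-3  # mol/dm3, the standard initial nucleoside concentration


@pytest.fixture(scope="session")
def ctx():
    return ThermoContext()


@pytest.fixture(scope="session")
def models():
    return {name: build_model(load_preset(name))
            for name in ("5IdU", "6IdU", "6IUrd")}


@pytest.fixture(scope="session")
def equilibria(models):
    return {name: solve_equilibrium(m.constants, C0)
            for name, m in models.items()}


@pytest.fixture(scope="session")
def traj_6idu(models):
    # ~400 relaxation times of the 0.4 s^-1 dissociation step
    return simulate(models["6IdU"].network, C0, 1e3)


@pytest.fixture(scope="session")
def traj_6iurd(models):
    # crosses the ~13 h half-life with margin
    return simulate(models["6IUrd"].network, C0, 3e5)


@pytest.fixture(scope="session")
def traj_6iurd_no_sn2(models):
    # the SN2-free network relaxes to exactly the equilibrium system
    m = models["6IUrd"]
    net = build_network("6IUrd", BarrierSpec(
        m.config.dissociation_dG_act_kcal_per_mol), m.constants, m.ctx)
    return simulate(net, C0, 2e6)


@pytest.fixture(scope="session")
def traj_5idu(models):
    # ~27 relaxation times of the 2.7e-10 s^-1 dissociation step
    return simulate(models["5IdU"].network, C0, 1e11)
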