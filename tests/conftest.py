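"""Shared fixtures.

Two Monte Carlo runs dominate the suite's runtime and are shared
session-wide:

* ``mc_single_diffuser``: 1e6 packets from a central diffuser in a uniform
  tumor phantom — used for the energy ledger, azimuthal symmetry and the
  radial dose profile.
* ``mc_point_diffusive``: 1e6 packets from a near-point source in a
  strongly diffusive medium (mu_a << mu_s') — used for the
  diffusion-approximation cross-check.

Smaller throwaway runs are built per test.
"""

from __future__ import annotations

import numpy as np
import pytest

import ipdtsim as ipdt
from ipdtsim.phantom import OpticalProperties


@pytest.fixture(scope="session")
def tumor_params():
    return ipdt.PhotophysicalParams()


@pytest.fixture(scope="session")
def mc_single_diffuser():
    """1e6-packet run: central diffuser in a 64^3 uniform tumor phantom."""
    model = ipdt.build_uniform_phantom((64, 64, 64), (0.01, 0.01, 0.01))
    diffuser = ipdt.DiffuserSpec(
        tip_position=(0.32, 0.32, 0.12),
        axis=(0.0, 0.0, 1.0),
        radiation_length=0.4,
        outer_diameter=0.11,
        linear_power_density=200.0,
    )
    fluence = ipdt.simulate_fluence(model, diffuser, n_photons=1_000_000, seed=20260920)
    return {"model": model, "diffuser": diffuser, "fluence": fluence}


# Strongly diffusive validation medium: mu_a/mu_s' ~ 0.0075, where the
# P1 diffusion closed form is accurate at a few transport mean free paths.
DIFFUSIVE_PROPS = OpticalProperties(mu_a=0.3, mu_s=40.0, g=0.0)


@pytest.fixture(scope="session")
def mc_point_diffusive():
    """1e6-packet near-point-source run in the diffusive medium (60^3)."""
    n, sp = 60, 0.04
    model = ipdt.build_uniform_phantom((n, n, n), (sp, sp, sp), props=DIFFUSIVE_PROPS)
    c = n * sp / 2
    length = 0.05
    diffuser = ipdt.DiffuserSpec(
        tip_position=(c, c, c - length / 2),
        radiation_length=length,
        outer_diameter=0.05,
        linear_power_density=100.0,
    )
    fluence = ipdt.simulate_fluence(model, diffuser, n_photons=1_000_000, seed=4242)
    return {"model": model, "diffuser": diffuser, "fluence": fluence,
            "props": DIFFUSIVE_PROPS, "center": (c, c, c)}


@pytest.fixture()
def small_mc_run():
    """Cheap 2e4-packet run for pipeline-level tests."""
    model = ipdt.build_uniform_phantom((32, 32, 32), (0.02, 0.02, 0.02))
    diffuser = ipdt.DiffuserSpec(
        tip_position=(0.32, 0.32, 0.12),
        radiation_length=0.4,
        linear_power_density=200.0,
    )
    fluence = ipdt.simulate_fluence(model, diffuser, n_photons=20_000, seed=11)
    return {"model": model, "diffuser": diffuser, "fluence": fluence}
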