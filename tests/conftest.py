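"""Shared fixtures: small calibrated simulation sweeps reused across tests.

The exponent sweeps are expensive (minutes), so they are session-scoped and
shared between the scaling-exponent tests and the mode-ordering tests.
Budgets are desk scale: tens of replicas and trajectory spans of ~40
estimated relaxation times per point.
"""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from polyads.experiments import estimated_tau_r, run_point
from polyads.lattice_model import BULK3D, PLANE2D, SLAB, BoxSpec, ChainState, \
    EnergyParams
from polyads.mc_engine import Simulation, initial_chain

settings.register_profile(
    "package", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("package")

SPAN = 40.0


def sweep(mode, grid, e_pp=0.0, e_ps=0.0, seed=101, span=SPAN, **kw):
    """Run one exponent sweep; grid maps N -> (replicas, production or None)."""
    points = {}
    for n, (replicas, prod) in grid.items():
        if prod is None:
            prod = int(span * estimated_tau_r(n, mode, e_pp))
        points[n] = run_point(
            n, e_pp=e_pp, e_ps=e_ps, mode=mode, replicas=replicas,
            production_mcs=prod,
            seed=int(np.random.SeedSequence([seed, n]).generate_state(1)[0])
            % 2 ** 31,
            n_boot=0, **kw)
    return points


@pytest.fixture(scope="session")
def bulk_sweep():
    """Athermal bulk-3D points for N = 8..64 (alpha and beta in solution).

    Trajectory spans shrink with N (100 -> 45 estimated tau_R) so the
    statistical weight is spread roughly evenly across the grid.
    """
    grid = {8: (32, 9_200), 16: (24, 36_000), 32: (16, 135_000),
            64: (12, 505_000)}
    return sweep(BULK3D, grid, seed=211)


@pytest.fixture(scope="session")
def plane2d_sweep():
    """Athermal strictly-2D points for N = 8..32 (fully adsorbed limit)."""
    grid = {8: (32, 49_000), 16: (24, 278_000), 32: (16, 1_480_000)}
    return sweep(PLANE2D, grid, seed=223)


@pytest.fixture(scope="session")
def slab_sweep():
    """Partially adsorbed points at E_PS = 1 for N = 8..32."""
    grid = {8: (32, 27_000), 16: (24, 142_000), 32: (14, 700_000)}
    return sweep(SLAB, grid, e_ps=1.0, seed=227)


@pytest.fixture(scope="session")
def slab_diffusion_64(slab_sweep):
    """The slab grid extended to N = 64 for the diffusion fit only (the
    rotational fit there is beyond the desk budget); trajectory spans ~10
    relaxation times, ample for the centre-of-mass displacement."""
    extra = sweep(SLAB, {64: (8, 400_000)}, e_ps=1.0, seed=229)
    return {**slab_sweep, **extra}


def random_state(mode=BULK3D, n=12, e_pp=0.0, e_ps=0.0, seed=0,
                 mcs=400) -> ChainState:
    """A decorrelated chain obtained by running the kernel from a snake."""
    from polyads.lattice_model import default_box
    box = default_box(n, mode)
    state = initial_chain(n, box)
    sim = Simulation(state, EnergyParams(e_pp, e_ps), seed)
    sim.run(mcs)
    return state
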