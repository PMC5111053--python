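"""Single-monomer Metropolis dynamics and the equilibrate-then-adsorb protocol.

Dynamics are generated by local moves: a monomer chosen uniformly at random
is attempted one lattice spacing along one of the six axis directions (four
in the 2D mode).  A move is allowed when the target site is empty, both
affected bonds stay within the allowed length set, no bond crossing is
created, and any z-walls are respected; it is then accepted with the
Metropolis probability ``min(1, exp(-dE))`` at k_B*T = 1.  Time is counted
in Monte Carlo steps (MCS): one MCS equals N attempted moves, and rejected
attempts consume time like accepted ones.

Two implementations coexist deliberately: a transparent pure-Python path
(:func:`propose_move` / :func:`is_allowed` / :func:`delta_energy` /
:func:`apply_move`) used as a readable reference and in tests, and the
compiled bulk driver :class:`Simulation` used for production runs.  They
implement identical rules; the test-suite checks them against each other.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import _kernels
from .lattice_model import (
    BULK3D,
    PLANE2D,
    SLAB,
    BoxSpec,
    ChainState,
    EnergyParams,
    bond_is_valid,
    default_box,
    segments_intersect,
)

__all__ = [
    "MoveProposal",
    "RunProtocol",
    "AdsorptionError",
    "Simulation",
    "propose_move",
    "is_allowed",
    "delta_energy",
    "metropolis_accept",
    "apply_move",
    "run_mcs",
    "equilibrate_and_adsorb",
    "initial_chain",
]

AXIS_DIRECTIONS = tuple(map(tuple, _kernels._DIRS.tolist()))


class AdsorptionError(RuntimeError):
    """The chain failed to reach the surface within the configured MCS cap."""


@dataclass(frozen=True)
class MoveProposal:
    monomer_index: int
    direction: tuple[int, int, int]


@dataclass(frozen=True)
class RunProtocol:
    """Timing of one run: equilibration, post-adsorption settling, production.

    ``equilibration_mcs`` defaults to ceil(N^2.2), the Rouse-like relaxation
    timescale of the chain (the same default is reused for ``settle_mcs``,
    the time allowed after first surface contact before statistics start).
    ``sample_interval`` is the number of MCS between recorded frames.
    """

    equilibration_mcs: int
    settle_mcs: int
    production_mcs: int
    sample_interval: int = 1
    adsorption_cap_mcs: int = 500_000

    def __post_init__(self):
        if min(self.equilibration_mcs, self.settle_mcs, self.production_mcs,
               self.sample_interval) < 1:
            raise ValueError("all protocol durations must be positive")

    @classmethod
    def for_chain(cls, n: int, production_mcs: int, sample_interval: int = 1,
                  equilibration_mcs: Optional[int] = None,
                  settle_mcs: Optional[int] = None,
                  adsorption_cap_mcs: int = 500_000) -> "RunProtocol":
        tau = int(math.ceil(n ** 2.2))
        return cls(
            equilibration_mcs=equilibration_mcs if equilibration_mcs else tau,
            settle_mcs=settle_mcs if settle_mcs else tau,
            production_mcs=production_mcs,
            sample_interval=sample_interval,
            adsorption_cap_mcs=adsorption_cap_mcs,
        )


def initial_chain(n: int, box: BoxSpec, z0: Optional[int] = None) -> ChainState:
    """Compact snake configuration in a single z-plane.

    All bonds have length 1, the chain footprint is ~sqrt(N) x sqrt(N), so
    the chain never approaches half the box edge even before equilibration.
    """
    if z0 is None:
        if box.mode == PLANE2D:
            z0 = 0
        elif box.mode == SLAB:
            # just above the virtual equilibration wall at lz/4
            z0 = min(-(-box.lz // 4) + 2, box.lz - 1)
        else:
            z0 = box.lz // 2
    row_len = max(1, int(math.ceil(math.sqrt(n))))
    row_len = min(row_len, box.lx)
    if (n + row_len - 1) // row_len > box.ly:
        raise ValueError("box too small for initial configuration")
    pos = np.empty((n, 3), dtype=np.int64)
    for k in range(n):
        row, col = divmod(k, row_len)
        x = col if row % 2 == 0 else row_len - 1 - col
        pos[k] = (x, row, z0)
    return ChainState(pos, box)


# ---------------------------------------------------------------------------
# pure-Python reference path (single moves)
# ---------------------------------------------------------------------------

def propose_move(state: ChainState, rng: np.random.Generator) -> MoveProposal:
    """Uniform monomer index, uniform axis direction (4 in-plane for 2D).

    The proposal distribution is symmetric: the reverse of every proposal is
    generated with the same probability, as detailed balance requires.
    """
    ndir = 4 if state.box.mode == PLANE2D else 6
    i = int(rng.integers(state.n))
    d = AXIS_DIRECTIONS[int(rng.integers(ndir))]
    return MoveProposal(i, d)


def _trial_position(state: ChainState, proposal: MoveProposal) -> np.ndarray:
    return state.unwrapped[proposal.monomer_index] + np.asarray(proposal.direction)


def is_allowed(state: ChainState, proposal: MoveProposal,
               box: Optional[BoxSpec] = None, z_min: Optional[int] = None) -> bool:
    """Geometric admissibility of a proposal (energy plays no role here).

    Checks, in order: z-walls (including an optional virtual wall ``z_min``
    used during pre-adsorption equilibration), target-site occupancy, bond
    lengths of both affected bonds, and bond non-crossing against all
    non-adjacent bonds.
    """
    box = box or state.box
    i = proposal.monomer_index
    new = _trial_position(state, proposal)
    if not box.z_periodic:
        lo, hi = box.z_range
        if z_min is not None:
            lo = max(lo, z_min)
        if not (lo <= new[2] <= hi):
            return False
    wrapped = state.wrapped
    target = box.wrap(new)
    occupied = {tuple(p) for k, p in enumerate(wrapped) if k != i}
    if tuple(target) in occupied:
        return False
    pos = state.unwrapped
    for j in (i - 1, i + 1):
        if 0 <= j < state.n and not bond_is_valid(new - pos[j], box.mode):
            return False
    if state.n > 2:
        for jb in range(state.n - 1):
            p1, p2 = pos[jb], pos[jb + 1]
            if i > 0 and jb not in (i - 2, i - 1, i):
                if segments_intersect(pos[i - 1], new, p1, p2):
                    return False
            if i < state.n - 1 and jb not in (i - 1, i, i + 1):
                if segments_intersect(new, pos[i + 1], p1, p2):
                    return False
    return True


def contact_delta(state: ChainState, proposal: MoveProposal) -> tuple[int, int]:
    """(dn_PP, dn_PS) of an allowed proposal, from local neighbourhoods only."""
    box = state.box
    i = proposal.monomer_index
    old = state.unwrapped[i]
    new = _trial_position(state, proposal)
    wrapped = state.wrapped
    sites = {tuple(p): k for k, p in enumerate(wrapped)}
    ndir = 4 if box.mode == PLANE2D else 6
    lo_z, hi_z = box.z_range

    def nn_count(center: np.ndarray) -> int:
        c = box.wrap(center)
        count = 0
        for d in AXIS_DIRECTIONS[:ndir]:
            s = box.wrap(c + np.asarray(d))
            if not box.z_periodic and not (0 <= s[2] <= hi_z):
                continue
            k = sites.get(tuple(s))
            if k is not None and k != i and abs(k - i) != 1:
                count += 1
        return count

    dn_pp = nn_count(new) - nn_count(old)
    dn_ps = 0
    if box.mode == SLAB:
        dn_ps = int(new[2] == 1) - int(old[2] == 1)
    return dn_pp, dn_ps


def delta_energy(state: ChainState, proposal: MoveProposal,
                 params: EnergyParams) -> float:
    """Energy shift of an allowed move: ``-dn_PP*E_PP - dn_PS*E_PS``."""
    dn_pp, dn_ps = contact_delta(state, proposal)
    return -dn_pp * params.e_pp - dn_ps * params.e_ps


def metropolis_accept(de: float, rng: np.random.Generator) -> bool:
    """Accept with probability min(1, exp(-dE)) at k_B*T = 1."""
    return de <= 0.0 or rng.random() < math.exp(-de)


def apply_move(state: ChainState, proposal: MoveProposal) -> None:
    """Apply an allowed proposal in place, updating cached contact counts."""
    dn_pp, dn_ps = contact_delta(state, proposal)
    state.unwrapped[proposal.monomer_index] += np.asarray(proposal.direction)
    state.n_pp += dn_pp
    state.n_ps += dn_ps


# ---------------------------------------------------------------------------
# compiled bulk driver
# ---------------------------------------------------------------------------

class Simulation:
    """Owns one chain plus its occupancy grid and drives the compiled kernel.

    Each instance reseeds the process-wide kernel RNG at construction, so a
    given (seed, configuration) pair reproduces the trajectory bit for bit;
    run replicas sequentially, one Simulation at a time per process.
    """

    def __init__(self, state: ChainState, params: EnergyParams,
                 seed: int, box: Optional[BoxSpec] = None):
        self.state = state
        self.box = box or state.box
        self.params = params
        self.seed = int(seed) % (2 ** 31)
        self.time_mcs = 0
        b = self.box
        self.occ = np.full((b.lx, b.ly, b.lz), -1, dtype=np.int16)
        if state.n > np.iinfo(np.int16).max:
            raise ValueError("chain too long for the occupancy index type")
        self.wpos = state.wrapped
        for k, p in enumerate(self.wpos):
            if self.occ[p[0], p[1], p[2]] >= 0:
                raise ValueError("initial configuration violates self-avoidance")
            self.occ[p[0], p[1], p[2]] = k
        self.stats = np.array([state.n_pp, state.n_ps, 0, 0], dtype=np.int64)
        _kernels.seed_rng(self.seed)

    @property
    def n_pp(self) -> int:
        return int(self.stats[0])

    @property
    def n_ps(self) -> int:
        return int(self.stats[1])

    @property
    def acceptance_rate(self) -> float:
        att = int(self.stats[3])
        return int(self.stats[2]) / att if att else float("nan")

    def _kernel_args(self, z_min: Optional[int]):
        b = self.box
        lo, hi = b.z_range
        if z_min is not None:
            lo = max(lo, z_min)
        is2d = b.mode == PLANE2D
        if is2d:  # z frozen: forbid leaving the plane via the wall bounds
            lo = hi = int(self.state.unwrapped[0, 2])
        return (b.lx, b.ly, b.lz, b.z_periodic, is2d, b.mode == SLAB, lo, hi,
                float(self.params.e_pp), float(self.params.e_ps))

    def run(self, n_mcs: int, z_min: Optional[int] = None) -> None:
        """Advance the clock by ``n_mcs`` MCS (= n_mcs * N attempts)."""
        if n_mcs <= 0:
            return
        attempts = int(n_mcs) * self.state.n
        _kernels.run_steps(self.state.unwrapped, self.wpos, self.occ,
                           *self._kernel_args(z_min),
                           attempts, self.stats, False)
        self.time_mcs += int(n_mcs)
        self._sync()

    def run_until_adsorbed(self, cap_mcs: int) -> int:
        """Run until n_PS > 0; returns MCS used.  Raises on hitting the cap."""
        if self.box.mode != SLAB:
            raise ValueError("adsorption requires the slab geometry")
        if self.n_ps > 0:
            return 0
        n = self.state.n
        used = _kernels.run_steps(self.state.unwrapped, self.wpos, self.occ,
                                  *self._kernel_args(None),
                                  int(cap_mcs) * n, self.stats, True)
        self.time_mcs += -(-used // n)
        self._sync()
        if self.n_ps == 0:
            raise AdsorptionError(
                f"no surface contact within {cap_mcs} MCS (N={n})")
        return -(-used // n)

    def _sync(self) -> None:
        if self.params.e_pp == 0.0:
            # the kernel skips incremental n_pp tracking in the athermal
            # case; restore the exact count from the occupancy grid
            b = self.box
            self.stats[0] = _kernels.count_pp(
                self.wpos, self.occ, b.lx, b.ly, b.lz, b.z_periodic,
                b.mode == PLANE2D)
        self.state.n_pp = int(self.stats[0])
        self.state.n_ps = int(self.stats[1])

    def energy(self) -> float:
        return -self.n_pp * self.params.e_pp - self.n_ps * self.params.e_ps

    def sample_frame(self) -> tuple:
        """(time, com, end_to_end, rg_sq, n_pp, n_ps, energy) of the state now."""
        pos = self.state.unwrapped
        com = pos.mean(axis=0)
        ete = (pos[-1] - pos[0]).astype(np.float64)
        centred = pos - com
        rg_sq = float(np.mean(np.sum(centred * centred, axis=1)))
        return (self.time_mcs, com, ete, rg_sq, self.n_pp, self.n_ps,
                self.energy())


def run_mcs(state: ChainState, n_mcs: int, params: EnergyParams,
            box: Optional[BoxSpec] = None, rng: int | np.random.Generator = 0,
            z_min: Optional[int] = None) -> ChainState:
    """Advance ``state`` by ``n_mcs`` MCS in place and return it.

    ``rng`` is either an integer seed or a Generator (from which a seed is
    drawn) controlling the move sequence.
    """
    seed = int(rng.integers(2 ** 31)) if isinstance(rng, np.random.Generator) else int(rng)
    sim = Simulation(state, params, seed, box=box)
    sim.run(n_mcs, z_min=z_min)
    return state


def equilibrate_and_adsorb(state: ChainState, protocol: RunProtocol,
                           params: EnergyParams, box: Optional[BoxSpec] = None,
                           rng: int | np.random.Generator = 0) -> Simulation:
    """Equilibrate above a virtual wall, release, adsorb, settle.

    Phase 1: the chain is equilibrated for ``equilibration_mcs`` between a
    repulsive virtual surface at z = L_z/4 and the box top, so its internal
    structure relaxes before it feels the attractive wall.  Phase 2: the
    virtual wall is removed and the chain moves freely until the first
    surface contact (n_PS > 0), capped at ``adsorption_cap_mcs``.  Phase 3:
    ``settle_mcs`` further MCS let it settle into the adsorbed equilibrium
    state; if the settled state has detached again (possible after a
    single-monomer touch), phases 2-3 repeat, so production never starts
    desorbed.  Returns the live :class:`Simulation`, ready for production.
    """
    box = box or state.box
    if box.mode != SLAB:
        raise ValueError("the adsorption protocol requires the slab geometry")
    seed = int(rng.integers(2 ** 31)) if isinstance(rng, np.random.Generator) else int(rng)
    sim = Simulation(state, params, seed, box=box)
    virtual_wall = -(-box.lz // 4)  # ceil(lz/4): monomers keep z >= lz/4
    sim.run(protocol.equilibration_mcs, z_min=virtual_wall)
    # a first touch can be followed by immediate detachment and a long
    # excursion; repeat contact + settling until the settled state is
    # actually adsorbed, so production never starts desorbed
    for _ in range(20):
        sim.run_until_adsorbed(protocol.adsorption_cap_mcs)
        sim.run(protocol.settle_mcs)
        if sim.n_ps > 0:
            return sim
    raise AdsorptionError(
        f"chain failed to settle into the adsorbed state (N={state.n})")
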