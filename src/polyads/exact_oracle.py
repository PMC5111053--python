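"""Exhaustive enumeration of tiny-chain ensembles for exact validation.

For chains of up to four monomers every allowed configuration can be listed
by depth-first growth over the bond set (all nonzero vectors with components
in {-1, 0, 1}, i.e. squared lengths 1, 2 and 3; the in-plane subset for the
2D mode), subject to self-avoidance and the non-crossing rule.  Translations
are modded out along periodic directions: the first monomer is pinned at the
origin in x and y (and z in bulk), while in the slab the z coordinates are
enumerated explicitly between the wall (z = 1) and a reflecting top at
``z_max``.  Boltzmann weights exp(-E) with E = -n_PP*E_PP - n_PS*E_PS give
exact partition sums and exact equilibrium averages, the reference against
which the Monte Carlo engine's long-run statistics are tested — provided
the Monte Carlo run uses the identical finite box height (lz = z_max + 1).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .lattice_model import (
    BULK3D,
    PLANE2D,
    SLAB,
    EnergyParams,
    segments_intersect,
)

__all__ = ["ConfigEnsemble", "enumerate_chains", "exact_average",
           "canonical_key", "MAX_N"]

MAX_N = 4

_BONDS_3D = [np.array(v, dtype=np.int64)
             for v in itertools.product((-1, 0, 1), repeat=3) if any(v)]
_BONDS_2D = [b for b in _BONDS_3D if b[2] == 0]


def canonical_key(positions: np.ndarray, mode: str) -> tuple:
    """Translation-invariant identifier of a configuration.

    Periodic directions are referred to the first monomer; the absolute z
    is kept in the slab (the wall breaks z-translation symmetry).
    """
    pos = np.asarray(positions, dtype=np.int64)
    rel = pos - pos[0]
    if mode == SLAB:
        rel[:, 2] = pos[:, 2]
    return tuple(map(tuple, rel.tolist()))


def _contacts(pos: np.ndarray, mode: str) -> tuple[int, int]:
    n = len(pos)
    n_pp = 0
    for i in range(n):
        d = pos[i + 2:] - pos[i]
        if d.size:
            n_pp += int(np.sum(np.sum(d * d, axis=1) == 1))
    n_ps = int(np.sum(pos[:, 2] == 1)) if mode == SLAB else 0
    return n_pp, n_ps


@dataclass
class ConfigEnsemble:
    """All distinct configurations with their exact Boltzmann weights."""

    configs: list            # list of (N, 3) int arrays
    weights: np.ndarray      # exp(-E) per configuration
    z: float                 # partition sum
    mode: str
    params: EnergyParams

    def probabilities(self) -> dict:
        """Mapping canonical key -> equilibrium probability."""
        return {canonical_key(c, self.mode): float(w) / self.z
                for c, w in zip(self.configs, self.weights)}


def enumerate_chains(n: int, mode: str = BULK3D,
                     params: EnergyParams | None = None,
                     z_max: int = 6) -> ConfigEnsemble:
    """Enumerate every allowed configuration of an ``n``-monomer chain.

    Guarded at ``n <= 4``: the configuration count grows roughly as 26^(N-1)
    and exhaustive search beyond four monomers serves no validation purpose.
    """
    if n > MAX_N:
        raise ValueError(f"enumeration is limited to N <= {MAX_N}")
    if n < 1:
        raise ValueError("need at least one monomer")
    params = params or EnergyParams()
    bonds = _BONDS_2D if mode == PLANE2D else _BONDS_3D
    if mode == SLAB:
        starts = [np.array([0, 0, z], dtype=np.int64) for z in range(1, z_max + 1)]
    else:
        starts = [np.zeros(3, dtype=np.int64)]

    configs: list[np.ndarray] = []

    def grow(chain: list[np.ndarray]) -> None:
        if len(chain) == n:
            configs.append(np.array(chain, dtype=np.int64))
            return
        last = chain[-1]
        for b in bonds:
            new = last + b
            if mode == SLAB and not (1 <= new[2] <= z_max):
                continue
            if any(np.array_equal(new, p) for p in chain):
                continue
            # new bond (last, new) versus all earlier non-adjacent bonds
            if any(segments_intersect(chain[j], chain[j + 1], last, new)
                   for j in range(len(chain) - 2)):
                continue
            chain.append(new)
            grow(chain)
            chain.pop()

    for start in starts:
        grow([start])

    weights = np.empty(len(configs))
    for k, pos in enumerate(configs):
        n_pp, n_ps = _contacts(pos, mode)
        weights[k] = math.exp(n_pp * params.e_pp + n_ps * params.e_ps)
    z = float(weights.sum())
    if z <= 0:
        raise ValueError("empty ensemble")
    return ConfigEnsemble(configs, weights, z, mode, params)


def _obs_r_sq(pos: np.ndarray, mode: str, params: EnergyParams) -> float:
    d = pos[-1] - pos[0]
    return float(d @ d)


def _obs_rg_sq(pos: np.ndarray, mode: str, params: EnergyParams) -> float:
    c = pos - pos.mean(axis=0)
    return float(np.mean(np.sum(c * c, axis=1)))


def _obs_n_pp(pos, mode, params):
    return float(_contacts(pos, mode)[0])


def _obs_n_ps(pos, mode, params):
    return float(_contacts(pos, mode)[1])


def _obs_energy(pos, mode, params):
    n_pp, n_ps = _contacts(pos, mode)
    return -n_pp * params.e_pp - n_ps * params.e_ps


_NAMED_OBSERVABLES: dict[str, Callable] = {
    "r_sq": _obs_r_sq,
    "rg_sq": _obs_rg_sq,
    "n_pp": _obs_n_pp,
    "n_ps": _obs_n_ps,
    "energy": _obs_energy,
}


def exact_average(ensemble: ConfigEnsemble,
                  observable: str | Callable[[np.ndarray], float]) -> float:
    """Boltzmann-weighted exact average of an observable over the ensemble.

    ``observable`` is either a name from {r_sq, rg_sq, n_pp, n_ps, energy}
    or a callable taking an (N, 3) position array.
    """
    if isinstance(observable, str):
        fn = _NAMED_OBSERVABLES[observable]
        values = [fn(pos, ensemble.mode, ensemble.params)
                  for pos in ensemble.configs]
    else:
        values = [float(observable(pos)) for pos in ensemble.configs]
    return float(np.dot(ensemble.weights, values) / ensemble.z)
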