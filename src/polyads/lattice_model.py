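"""Geometry, constraints and energy of a single-site fluctuating-bond lattice polymer.

The model is a coarse-grained linear chain of ``N`` monomers on the simple
cubic lattice.  Each monomer occupies one lattice site (self-avoidance), and
consecutive monomers are joined by bonds whose length may fluctuate among
1, sqrt(2) and sqrt(3) (squared lengths 1, 2, 3).  Bonds are forbidden to
cross each other geometrically, which prevents the chain from passing
through itself under local single-monomer moves.

Interactions (the temperature is fixed by the convention k_B*T = 1):

* every *non-bonded* pair of monomers on nearest-neighbour sites contributes
  an attraction ``-E_PP``;
* in the adsorbing-slab geometry every monomer in the lattice layer adjacent
  to the wall (z = 1; the wall itself occupies z = 0) contributes ``-E_PS``.

Total energy: ``E = -n_PP * E_PP - n_PS * E_PS``.

Three boundary modes are supported:

``bulk3d``
    periodic in x, y and z — a free chain in dilute solution;
``slab_adsorbing``
    periodic in x and y, impenetrable walls at z = 0 and z = L_z, with the
    adsorbing layer at z = 1 — a chain near an attractive surface;
``plane2d``
    the chain is confined to a single z-plane with periodic x and y and the
    in-plane bond set {1, sqrt(2)} — the fully adsorbed (2D) limit, in which
    the surface term is a constant and is ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

__all__ = [
    "BULK3D",
    "SLAB",
    "PLANE2D",
    "MODES",
    "BoxSpec",
    "EnergyParams",
    "ChainState",
    "bond_is_valid",
    "segments_intersect",
    "count_contacts",
    "total_energy",
    "radius_of_gyration_sq",
    "default_box",
]

BULK3D = "bulk3d"
SLAB = "slab_adsorbing"
PLANE2D = "plane2d"
MODES = (BULK3D, SLAB, PLANE2D)

#: squared bond lengths allowed in three dimensions / strictly in-plane
BOND_SQ_3D = frozenset({1, 2, 3})
BOND_SQ_2D = frozenset({1, 2})


def bond_is_valid(displacement: Iterable[int], mode: str = BULK3D) -> bool:
    """True iff ``displacement`` is an allowed bond vector for ``mode``.

    Allowed squared lengths are {1, 2, 3} in ``bulk3d``/``slab_adsorbing``
    and {1, 2} in ``plane2d`` (a z-component is impossible in-plane).
    """
    dx, dy, dz = (int(c) for c in displacement)
    sq = dx * dx + dy * dy + dz * dz
    if mode == PLANE2D:
        return dz == 0 and sq in BOND_SQ_2D
    return sq in BOND_SQ_3D


def segments_intersect(a1, a2, b1, b2) -> bool:
    """Exact test whether closed segments [a1,a2] and [b1,b2] share a point.

    Endpoints are integer lattice vectors, so the test is carried out in
    exact integer arithmetic (no floating point): the segments intersect iff
    they are coplanar and the rational line-line intersection parameters both
    lie in [0, 1], or, for collinear segments, their 1-D projections overlap.
    Intended for non-adjacent bonds; bonds sharing a monomer are exempt from
    the non-crossing rule and should not be passed here.
    """
    p = np.asarray(a1, dtype=np.int64)
    u = np.asarray(a2, dtype=np.int64) - p
    q = np.asarray(b1, dtype=np.int64)
    v = np.asarray(b2, dtype=np.int64) - q
    w = q - p
    n = np.cross(u, v)
    if np.any(n != 0):
        # skew or intersecting lines: coplanarity requires w . (u x v) == 0
        if int(w @ n) != 0:
            return False
        denom = int(n @ n)
        t_num = int(np.cross(w, v) @ n)   # parameter along [a1,a2], scaled
        s_num = int(np.cross(w, u) @ n)   # parameter along [b1,b2], scaled
        return 0 <= t_num <= denom and 0 <= s_num <= denom
    # parallel lines: intersect only if collinear with overlapping spans
    if np.any(np.cross(w, u) != 0):
        return False
    uu = int(u @ u)
    if uu == 0:  # degenerate point "segment"
        vv = int(v @ v)
        if vv == 0:
            return bool(np.all(w == 0))
        s = int(-w @ v)
        return 0 <= s <= vv
    t0 = int(w @ u)
    t1 = t0 + int(v @ u)
    return max(min(t0, t1), 0) <= min(max(t0, t1), uu)


def default_box(n: int, mode: str = BULK3D) -> "BoxSpec":
    """Default simulation box for a chain of length ``n``.

    The lateral size grows as ``max(64, ceil(4 N^0.75))`` so the chain never
    interacts with its own periodic images.  In the slab geometry the height
    is smaller, ``max(24, ceil(3 N^0.6))`` — a few radii of gyration — which
    keeps the pre-adsorption equilibration region close to the surface so
    that first contact happens quickly without influencing the adsorbed
    equilibrium state.
    """
    lxy = int(max(64, np.ceil(4.0 * n ** 0.75)))
    if mode == SLAB:
        lz = int(max(24, np.ceil(3.0 * n ** 0.6)))
    elif mode == PLANE2D:
        lz = 1
    else:
        lz = lxy
    return BoxSpec(lxy, lxy, lz, mode)


@dataclass(frozen=True)
class BoxSpec:
    """Simulation box: positive integer edge lengths plus a boundary mode."""

    lx: int
    ly: int
    lz: int
    mode: str = BULK3D

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        if min(self.lx, self.ly, self.lz) < 1:
            raise ValueError("box edges must be positive integers")
        if self.mode == SLAB and self.lz < 3:
            raise ValueError("slab box needs lz >= 3 (walls at z=0 and z=lz)")

    @property
    def z_periodic(self) -> bool:
        return self.mode == BULK3D

    @property
    def z_range(self) -> tuple[int, int]:
        """Inclusive range of allowed z coordinates (slab walls excluded)."""
        if self.mode == SLAB:
            return 1, self.lz - 1
        return 0, self.lz - 1

    def wrap(self, positions: np.ndarray) -> np.ndarray:
        """Wrap unwrapped positions into the box along periodic directions."""
        pos = np.array(positions, dtype=np.int64)
        pos[..., 0] %= self.lx
        pos[..., 1] %= self.ly
        if self.z_periodic:
            pos[..., 2] %= self.lz
        return pos

    def minimum_image(self, delta: np.ndarray) -> np.ndarray:
        """Minimum-image convention applied along periodic directions."""
        d = np.array(delta, dtype=np.int64)
        for axis, (length, periodic) in enumerate(
            [(self.lx, True), (self.ly, True), (self.lz, self.z_periodic)]
        ):
            if periodic:
                d[..., axis] = (d[..., axis] + length // 2) % length - length // 2
        return d


@dataclass(frozen=True)
class EnergyParams:
    """Attraction strengths in units of k_B*T (k_B*T == 1 by convention).

    ``e_pp`` acts between non-bonded monomers at unit lattice distance,
    ``e_ps`` on monomers in the layer adjacent to the wall.  Both are
    non-negative; they enter the energy only through
    ``E = -n_PP*e_pp - n_PS*e_ps``.
    """

    e_pp: float = 0.0
    e_ps: float = 0.0

    def __post_init__(self):
        if self.e_pp < 0 or self.e_ps < 0:
            raise ValueError("attraction strengths must be non-negative")


class ChainState:
    """Mutable state of one chain: unwrapped positions plus cached contacts.

    ``unwrapped`` holds exact integer positions that never wrap, so that
    displacement statistics (MSD) are meaningful; the wrapped image is used
    for occupancy and contact counting.  ``n_pp`` and ``n_ps`` are cached and
    kept in sync incrementally by the Monte Carlo engine; they always equal a
    from-scratch :func:`count_contacts`.
    """

    __slots__ = ("box", "unwrapped", "n_pp", "n_ps")

    def __init__(self, positions: np.ndarray, box: BoxSpec):
        pos = np.array(positions, dtype=np.int64)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("positions must have shape (N, 3)")
        self.box = box
        self.unwrapped = pos
        self.n_pp, self.n_ps = count_contacts(self, box)
        self.validate()

    @property
    def n(self) -> int:
        return self.unwrapped.shape[0]

    @property
    def wrapped(self) -> np.ndarray:
        return self.box.wrap(self.unwrapped)

    def bond_vectors(self) -> np.ndarray:
        return np.diff(self.unwrapped, axis=0)

    def center_of_mass(self) -> np.ndarray:
        return self.unwrapped.mean(axis=0)

    def end_to_end(self) -> np.ndarray:
        return self.unwrapped[-1] - self.unwrapped[0]

    def validate(self) -> None:
        """Raise ``ValueError`` if any chain invariant is violated."""
        box, pos = self.box, self.unwrapped
        wrapped = self.wrapped
        lo, hi = box.z_range
        if box.mode != BULK3D:
            z = pos[:, 2]
            if z.min() < lo or z.max() > hi:
                raise ValueError("monomer outside allowed z range")
            if box.mode == PLANE2D and np.ptp(z) != 0:
                raise ValueError("plane2d chain must lie in a single z-plane")
        keys = {tuple(p) for p in wrapped}
        if len(keys) != self.n:
            raise ValueError("self-avoidance violated: duplicate site")
        for b in self.bond_vectors():
            if not bond_is_valid(b, box.mode):
                raise ValueError(f"invalid bond vector {tuple(b)}")
        nb = self.n - 1
        for i in range(nb):
            for j in range(i + 2, nb):  # consecutive bonds share a monomer
                if segments_intersect(pos[i], pos[i + 1], pos[j], pos[j + 1]):
                    raise ValueError(f"bonds {i} and {j} intersect")
        npp, nps = count_contacts(self, box)
        if (npp, nps) != (self.n_pp, self.n_ps):
            raise ValueError("cached contact counts out of sync")

    def copy(self) -> "ChainState":
        return ChainState(self.unwrapped.copy(), self.box)


def count_contacts(chain: ChainState, box: BoxSpec | None = None) -> tuple[int, int]:
    """From-scratch count of (n_PP, n_PS).

    n_PP counts unordered pairs (i, j) with |i-j| >= 2 at unit lattice
    distance under the minimum-image convention; bonded neighbours and pairs
    at distance sqrt(2) or sqrt(3) do not contribute.  n_PS counts monomers
    at z = 1 in the slab geometry and is zero otherwise.
    """
    box = box or chain.box
    pos = chain.unwrapped
    n = pos.shape[0]
    n_pp = 0
    for i in range(n):
        delta = box.minimum_image(pos[i + 2:] - pos[i])
        if delta.size:
            n_pp += int(np.sum(np.sum(delta * delta, axis=1) == 1))
    n_ps = int(np.sum(pos[:, 2] == 1)) if box.mode == SLAB else 0
    return n_pp, n_ps


def total_energy(chain: ChainState, params: EnergyParams) -> float:
    """``E = -n_PP*E_PP - n_PS*E_PS`` from the chain's cached contact counts."""
    return -chain.n_pp * params.e_pp - chain.n_ps * params.e_ps


def radius_of_gyration_sq(chain: ChainState) -> float:
    """Squared radius of gyration: mean squared distance from the centroid."""
    pos = chain.unwrapped.astype(np.float64)
    centred = pos - pos.mean(axis=0)
    return float(np.mean(np.sum(centred * centred, axis=1)))
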