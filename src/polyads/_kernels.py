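"""Numba-compiled inner loop of the single-monomer Metropolis dynamics.

The kernels operate on raw arrays: ``pos`` is the (N, 3) int64 array of
*unwrapped* monomer positions, ``wpos`` its wrapped image, and ``occ`` the
(lx, ly, lz) int32 occupancy grid over wrapped coordinates (monomer index,
or -1 for an empty site).  The Python-facing engine in
:mod:`polyads.mc_engine` owns the state objects and keeps them in sync with
these arrays.

Randomness uses numba's internal np.random state, seeded via
:func:`seed_rng`; a process therefore runs one simulation stream at a time
(replicas are run sequentially, each reseeded from its own recorded seed).

Geometry note: bond vectors and the non-crossing test use unwrapped
coordinates directly, which is exact while the chain extent stays below half
the box edge; the default boxes and compact initial configurations guarantee
this.  Contact counting goes through the wrapped occupancy grid and is hence
minimum-image by construction.
"""

import numpy as np
from numba import njit

# 6 axis directions; the first 4 are the in-plane set used in plane2d mode
_DIRS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
    dtype=np.int64,
)


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True, inline="always")
def _seg_isect(px, py, pz, ax, ay, az, qx, qy, qz, bx, by, bz):
    """Exact integer test: does segment P..P+A meet segment Q..Q+B?"""
    wx = qx - px
    wy = qy - py
    wz = qz - pz
    nx = ay * bz - az * by
    ny = az * bx - ax * bz
    nz = ax * by - ay * bx
    if nx != 0 or ny != 0 or nz != 0:
        if wx * nx + wy * ny + wz * nz != 0:
            return False  # skew lines
        denom = nx * nx + ny * ny + nz * nz
        t = (wy * bz - wz * by) * nx + (wz * bx - wx * bz) * ny + (wx * by - wy * bx) * nz
        s = (wy * az - wz * ay) * nx + (wz * ax - wx * az) * ny + (wx * ay - wy * ax) * nz
        return 0 <= t <= denom and 0 <= s <= denom
    # parallel: intersection requires collinearity and 1-D overlap
    cx = wy * az - wz * ay
    cy = wz * ax - wx * az
    cz = wx * ay - wy * ax
    if cx != 0 or cy != 0 or cz != 0:
        return False
    uu = ax * ax + ay * ay + az * az
    t0 = wx * ax + wy * ay + wz * az
    t1 = t0 + bx * ax + by * ay + bz * az
    lo = t0 if t0 < t1 else t1
    hi = t0 + t1 - lo
    if lo < 0:
        lo = 0
    if hi > uu:
        hi = uu
    return lo <= hi


@njit(cache=True)
def _crossing_free(pos, i, nx, ny, nz):
    """True iff the bonds into the trial site (nx,ny,nz) cross no other bond.

    Bonds sharing a monomer with a tested bond are exempt (they necessarily
    touch at the shared monomer).  Bonds far from the trial site are culled
    by a coordinate bound before the exact test: a tested bond spans at most
    2 in each coordinate around the trial site and any bond spans at most 1
    around its first endpoint, so |pos[j] - new|_inf > 3 excludes contact.
    """
    n = pos.shape[0]
    has_a = i > 0          # bond (i-1) -> new site
    has_b = i < n - 1      # bond new site -> (i+1)
    if has_a:
        ax = nx - pos[i - 1, 0]
        ay = ny - pos[i - 1, 1]
        az = nz - pos[i - 1, 2]
    else:
        ax = ay = az = 0
    if has_b:
        bx = pos[i + 1, 0] - nx
        by = pos[i + 1, 1] - ny
        bz = pos[i + 1, 2] - nz
    else:
        bx = by = bz = 0
    for j in range(n - 1):
        jx = pos[j, 0]
        if jx - nx > 3 or nx - jx > 3:
            continue
        jy = pos[j, 1]
        if jy - ny > 3 or ny - jy > 3:
            continue
        jz = pos[j, 2]
        if jz - nz > 3 or nz - jz > 3:
            continue
        vx = pos[j + 1, 0] - jx
        vy = pos[j + 1, 1] - jy
        vz = pos[j + 1, 2] - jz
        if has_a and (j < i - 2 or j > i):
            if _seg_isect(pos[i - 1, 0], pos[i - 1, 1], pos[i - 1, 2],
                          ax, ay, az, jx, jy, jz, vx, vy, vz):
                return False
        if has_b and (j < i - 1 or j > i + 1):
            if _seg_isect(nx, ny, nz, bx, by, bz, jx, jy, jz, vx, vy, vz):
                return False
    return True


@njit(cache=True, inline="always")
def _wrap_inc(c, length):
    if c >= length:
        return c - length
    if c < 0:
        return c + length
    return c


@njit(cache=True)
def count_pp(wpos, occ, lx, ly, lz, z_periodic, is2d):
    """Non-bonded nearest-neighbour pair count from the occupancy grid."""
    n = wpos.shape[0]
    ndir = 4 if is2d else 6
    total = 0
    for i in range(n):
        for d in range(ndir):
            sx = _wrap_inc(wpos[i, 0] + _DIRS[d, 0], lx)
            sy = _wrap_inc(wpos[i, 1] + _DIRS[d, 1], ly)
            sz = wpos[i, 2] + _DIRS[d, 2]
            if z_periodic:
                sz = _wrap_inc(sz, lz)
            if 0 <= sz < lz:
                k = occ[sx, sy, sz]
                if k > i + 1:  # each non-bonded pair counted once
                    total += 1
    return total


@njit(cache=True)
def run_steps(pos, wpos, occ, lx, ly, lz, z_periodic, is2d, count_ps,
              zmin, zmax, e_pp, e_ps, n_attempts, stats, stop_on_contact):
    """Perform ``n_attempts`` single-monomer Metropolis attempts in place.

    ``stats`` is int64[4]: running (n_pp, n_ps, accepted, attempted); the
    contact counts must be correct on entry and stay exact throughout,
    except that n_pp tracking is skipped when ``e_pp == 0`` (it cannot
    affect acceptance there; the caller recounts via :func:`count_pp` after
    the call, so Python-visible state stays exact).  With
    ``stop_on_contact`` the loop returns as soon as n_ps > 0 (used by the
    adsorption protocol).  Returns the number of attempts consumed.
    """
    n = pos.shape[0]
    ndir = 4 if is2d else 6
    max_sq = 2 if is2d else 3
    track_pp = e_pp != 0.0
    for step in range(n_attempts):
        i = np.random.randint(0, n)
        d = np.random.randint(0, ndir)
        stats[3] += 1
        oz = pos[i, 2]
        nx = pos[i, 0] + _DIRS[d, 0]
        ny = pos[i, 1] + _DIRS[d, 1]
        nz = oz + _DIRS[d, 2]
        if not z_periodic and (nz < zmin or nz > zmax):
            continue
        wx = _wrap_inc(wpos[i, 0] + _DIRS[d, 0], lx)
        wy = _wrap_inc(wpos[i, 1] + _DIRS[d, 1], ly)
        wz = _wrap_inc(wpos[i, 2] + _DIRS[d, 2], lz) if z_periodic else nz
        if occ[wx, wy, wz] >= 0:
            continue
        if i > 0:
            ux = nx - pos[i - 1, 0]
            uy = ny - pos[i - 1, 1]
            uz = nz - pos[i - 1, 2]
            if ux * ux + uy * uy + uz * uz > max_sq:
                continue
        if i < n - 1:
            ux = pos[i + 1, 0] - nx
            uy = pos[i + 1, 1] - ny
            uz = pos[i + 1, 2] - nz
            if ux * ux + uy * uy + uz * uz > max_sq:
                continue
        if n > 2 and not _crossing_free(pos, i, nx, ny, nz):
            continue
        # local change in nearest-neighbour contact counts
        dnpp = 0
        owx = wpos[i, 0]
        owy = wpos[i, 1]
        owz = wpos[i, 2]
        for d2 in range(ndir if track_pp else 0):
            sx = _wrap_inc(wx + _DIRS[d2, 0], lx)
            sy = _wrap_inc(wy + _DIRS[d2, 1], ly)
            sz = wz + _DIRS[d2, 2]
            if z_periodic:
                sz = _wrap_inc(sz, lz)
            if 0 <= sz < lz:
                k = occ[sx, sy, sz]
                if k >= 0 and k != i and k != i - 1 and k != i + 1:
                    dnpp += 1
            sx = _wrap_inc(owx + _DIRS[d2, 0], lx)
            sy = _wrap_inc(owy + _DIRS[d2, 1], ly)
            sz = owz + _DIRS[d2, 2]
            if z_periodic:
                sz = _wrap_inc(sz, lz)
            if 0 <= sz < lz:
                k = occ[sx, sy, sz]
                if k >= 0 and k != i and k != i - 1 and k != i + 1:
                    dnpp -= 1
        dnps = 0
        if count_ps:
            if nz == 1:
                dnps += 1
            if oz == 1:
                dnps -= 1
        if dnpp != 0 or dnps != 0:
            de = -dnpp * e_pp - dnps * e_ps
            if de > 0.0 and np.random.random() >= np.exp(-de):
                continue
        occ[owx, owy, owz] = -1
        occ[wx, wy, wz] = i
        pos[i, 0] = nx
        pos[i, 1] = ny
        pos[i, 2] = nz
        wpos[i, 0] = wx
        wpos[i, 1] = wy
        wpos[i, 2] = wz
        stats[0] += dnpp
        stats[1] += dnps
        stats[2] += 1
        if stop_on_contact and stats[1] > 0:
            return step + 1
    return n_attempts
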