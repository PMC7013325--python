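"""Numba kernel for voxel Monte Carlo photon-packet transport.

Standard hop/drop/spin scheme on a regular voxel lattice:

* step length sampled as ``-ln(xi)`` in dimensionless optical depth,
  consumed across voxel boundaries with partial geometric steps;
* at each interaction site the packet deposits ``W * mu_a / mu_t`` of its
  weight into the current voxel and scatters by the Henyey-Greenstein
  phase function with the local anisotropy g;
* Russian roulette below weight 1e-4 with survival probability 0.1
  (survivor weight x10); the ledger records the *net* discarded weight
  (killed weight minus survivor boosts) so that
  ``deposited + escaped + roulette_discarded == launched`` holds exactly,
  not only in expectation;
* packets leaving the grid or entering a void (label 0) voxel tally their
  remaining weight as escaped;
* voxels with mu_a = 0 additionally accumulate a track-length tally
  (weight x path length, cm) from which fluence is estimated there.

Refractive-index boundaries are matched (no Fresnel reflection or
internal fiber optics): the diffuser volume is ordinary tissue after
launch.

Reproducibility: the kernel is serial and seeds numba's internal RNG once,
so a given (inputs, seed) pair yields a bit-identical result.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

ROULETTE_THRESHOLD = 1e-4
ROULETTE_SURVIVAL = 0.1


@njit(cache=True, fastmath=True)
def _henyey_greenstein_cos(g: float) -> float:
    xi = np.random.random()
    if abs(g) < 1e-12:
        return 2.0 * xi - 1.0
    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * xi)
    cost = (1.0 + g * g - tmp * tmp) / (2.0 * g)
    if cost > 1.0:
        cost = 1.0
    elif cost < -1.0:
        cost = -1.0
    return cost


@njit(cache=True, fastmath=True)
def _scatter(ux: float, uy: float, uz: float, g: float):
    cost = _henyey_greenstein_cos(g)
    sint = math.sqrt(max(0.0, 1.0 - cost * cost))
    phi = 2.0 * math.pi * np.random.random()
    cosp = math.cos(phi)
    sinp = math.sin(phi)
    if abs(uz) > 0.99999:
        nx = sint * cosp
        ny = sint * sinp
        nz = cost * (1.0 if uz >= 0.0 else -1.0)
    else:
        temp = math.sqrt(1.0 - uz * uz)
        nx = sint * (ux * uz * cosp - uy * sinp) / temp + ux * cost
        ny = sint * (uy * uz * cosp + ux * sinp) / temp + uy * cost
        nz = -sint * cosp * temp + uz * cost
    norm = math.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / norm, ny / norm, nz / norm


@njit(cache=True, fastmath=True)
def _isotropic_hemisphere(nx: float, ny: float, nz: float):
    """Uniform direction on the hemisphere around outward normal n."""
    cost = 2.0 * np.random.random() - 1.0
    sint = math.sqrt(max(0.0, 1.0 - cost * cost))
    phi = 2.0 * math.pi * np.random.random()
    dx = sint * math.cos(phi)
    dy = sint * math.sin(phi)
    dz = cost
    if dx * nx + dy * ny + dz * nz < 0.0:
        dx = -dx
        dy = -dy
        dz = -dz
    return dx, dy, dz


@njit(cache=True, fastmath=True)
def transport_kernel(
    labels,            # (nx, ny, nz) int32, 0 = void
    mu_a_tab,          # (n_labels,) float64, /cm
    mu_s_tab,          # (n_labels,) float64, /cm
    g_tab,             # (n_labels,) float64
    sx, sy, sz,        # voxel spacing, cm
    ox, oy, oz,        # grid origin, cm
    tipx, tipy, tipz,  # proximal end of the radiation section, cm
    axx, axy, axz,     # diffuser axis (unit)
    e1x, e1y, e1z,     # first transverse basis vector (unit)
    e2x, e2y, e2z,     # second transverse basis vector (unit)
    rad_length,        # radiation length, cm
    radius,            # diffuser outer radius, cm
    n_photons,         # packets to launch
    seed,              # RNG seed (< 2^31)
    dep,               # (nx, ny, nz) float64 out: absorbed weight
    tlen,              # (nx, ny, nz) float64 out: track length (mu_a = 0 voxels)
):
    """Run the packet loop; returns (escaped_weight, roulette_net_discarded)."""
    np.random.seed(seed)
    nx_v, ny_v, nz_v = labels.shape
    escaped = 0.0
    discarded = 0.0

    for _ in range(n_photons):
        # --- launch from the lateral cylinder surface ---------------------
        a = rad_length * np.random.random()
        phi = 2.0 * math.pi * np.random.random()
        cnx = math.cos(phi) * e1x + math.sin(phi) * e2x
        cny = math.cos(phi) * e1y + math.sin(phi) * e2y
        cnz = math.cos(phi) * e1z + math.sin(phi) * e2z
        x = tipx + a * axx + radius * cnx
        y = tipy + a * axy + radius * cny
        z = tipz + a * axz + radius * cnz
        ux, uy, uz = _isotropic_hemisphere(cnx, cny, cnz)
        w = 1.0

        i = int(math.floor((x - ox) / sx))
        j = int(math.floor((y - oy) / sy))
        k = int(math.floor((z - oz) / sz))
        if (
            i < 0 or i >= nx_v or j < 0 or j >= ny_v or k < 0 or k >= nz_v
            or labels[i, j, k] == 0
        ):
            escaped += w
            continue

        s_left = -math.log(np.random.random())  # optical depth to next event
        alive = True
        while alive:
            lab = labels[i, j, k]
            mu_a = mu_a_tab[lab]
            mu_t = mu_a + mu_s_tab[lab]

            # distance to nearest voxel face along the direction of flight
            if ux > 0.0:
                tx = (((i + 1) * sx + ox) - x) / ux
            elif ux < 0.0:
                tx = ((i * sx + ox) - x) / ux
            else:
                tx = 1e30
            if uy > 0.0:
                ty = (((j + 1) * sy + oy) - y) / uy
            elif uy < 0.0:
                ty = ((j * sy + oy) - y) / uy
            else:
                ty = 1e30
            if uz > 0.0:
                tz = (((k + 1) * sz + oz) - z) / uz
            elif uz < 0.0:
                tz = ((k * sz + oz) - z) / uz
            else:
                tz = 1e30
            db = tx
            axis = 0
            if ty < db:
                db = ty
                axis = 1
            if tz < db:
                db = tz
                axis = 2
            if db < 0.0:
                db = 0.0

            step = s_left / mu_t if mu_t > 0.0 else 1e30
            if step < db:
                # interaction inside this voxel: drop then spin
                x += ux * step
                y += uy * step
                z += uz * step
                if mu_a == 0.0:
                    tlen[i, j, k] += w * step
                dw = w * mu_a / mu_t
                dep[i, j, k] += dw
                w -= dw
                if w < ROULETTE_THRESHOLD:
                    if np.random.random() <= ROULETTE_SURVIVAL:
                        discarded -= w * (1.0 / ROULETTE_SURVIVAL - 1.0)
                        w *= 1.0 / ROULETTE_SURVIVAL
                    else:
                        discarded += w
                        alive = False
                        continue
                ux, uy, uz = _scatter(ux, uy, uz, g_tab[lab])
                s_left = -math.log(np.random.random())
            else:
                # cross into the neighbouring voxel
                x += ux * db
                y += uy * db
                z += uz * db
                if mu_a == 0.0 and mu_t > 0.0:
                    tlen[i, j, k] += w * db
                if mu_t > 0.0:
                    s_left -= db * mu_t
                    if s_left < 0.0:
                        s_left = 0.0
                if axis == 0:
                    i += 1 if ux > 0.0 else -1
                elif axis == 1:
                    j += 1 if uy > 0.0 else -1
                else:
                    k += 1 if uz > 0.0 else -1
                if (
                    i < 0 or i >= nx_v or j < 0 or j >= ny_v or k < 0 or k >= nz_v
                    or labels[i, j, k] == 0
                ):
                    escaped += w
                    alive = False

    return escaped, discarded
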