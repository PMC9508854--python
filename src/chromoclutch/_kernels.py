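"""Numba-compiled inner loops of the toy-simulator Monte Carlo engine."""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=False)
def pair_energy_vs(k, centers, normals, eps_stack, r_stack, w_stack,
                   sig_in, sig_n, k_rep):
    """Sum of stacking + excluded-volume pair energies of nucleosome k."""
    n = centers.shape[0]
    e = 0.0
    ck0, ck1, ck2 = centers[k, 0], centers[k, 1], centers[k, 2]
    nk0, nk1, nk2 = normals[k, 0], normals[k, 1], normals[k, 2]
    for j in range(n):
        if j == k:
            continue
        d0 = centers[j, 0] - ck0
        d1 = centers[j, 1] - ck1
        d2 = centers[j, 2] - ck2
        r2 = d0 * d0 + d1 * d1 + d2 * d2
        r = np.sqrt(r2)
        if r <= 0.0:
            continue
        zk = d0 * nk0 + d1 * nk1 + d2 * nk2
        zj = (d0 * normals[j, 0] + d1 * normals[j, 1] + d2 * normals[j, 2])
        # stacking: alignment-gated Gaussian well
        dr = r - r_stack
        if abs(dr) < 6.0 * w_stack:
            align = (zk * zj) / r2
            e -= (eps_stack * align * align
                  * np.exp(-dr * dr / (2.0 * w_stack * w_stack)))
        # anisotropic excluded volume in both bodies' frames
        azk = abs(zk)
        azj = abs(zj)
        rin_k2 = r2 - azk * azk
        if rin_k2 < 0.0:
            rin_k2 = 0.0
        rin_j2 = r2 - azj * azj
        if rin_j2 < 0.0:
            rin_j2 = 0.0
        s_k = np.sqrt(rin_k2 / (sig_in * sig_in) + azk * azk / (sig_n * sig_n))
        s_j = np.sqrt(rin_j2 / (sig_in * sig_in) + azj * azj / (sig_n * sig_n))
        if s_k < 1.0:
            e += k_rep * (1.0 - s_k) ** 2
        if s_j < 1.0:
            e += k_rep * (1.0 - s_j) ** 2
    return e


@njit(cache=True)
def link_energy(ci, cj, wi, wj, k_link, L0, lam):
    d0 = cj[0] - ci[0]
    d1 = cj[1] - ci[1]
    d2 = cj[2] - ci[2]
    r = np.sqrt(d0 * d0 + d1 * d1 + d2 * d2)
    rest = L0 + lam * ((1.0 - wi) + (1.0 - wj))
    return 0.5 * k_link * (r - rest) ** 2


@njit(cache=True)
def d_stack_of(centers, start, stop):
    acc = 0.0
    n = 0
    for i in range(start, stop - 2):
        d0 = centers[i + 2, 0] - centers[i, 0]
        d1 = centers[i + 2, 1] - centers[i, 1]
        d2 = centers[i + 2, 2] - centers[i, 2]
        acc += np.sqrt(d0 * d0 + d1 * d1 + d2 * d2)
        n += 1
    return acc / n


@njit(cache=True)
def alpha_of(centers, start, stop):
    dmax = 0.0
    dmin = 1e300
    for i in range(start, stop - 2):
        d0 = centers[i + 2, 0] - centers[i, 0]
        d1 = centers[i + 2, 1] - centers[i, 1]
        d2 = centers[i + 2, 2] - centers[i, 2]
        d = np.sqrt(d0 * d0 + d1 * d1 + d2 * d2)
        if d > dmax:
            dmax = d
        if d < dmin:
            dmin = d
    return dmax / dmin


@njit(cache=True)
def endpoints_z_of(centers, wraps, start, stop, L0, lam):
    """(z_first_terminus, z_last_terminus) of one chain."""
    if stop - start == 1:
        l_end = L0 / 2.0 + lam * (1.0 - wraps[start])
        return centers[start, 2] - l_end, centers[start, 2] + l_end
    # first terminus
    d0 = centers[start, 0] - centers[start + 1, 0]
    d1 = centers[start, 1] - centers[start + 1, 1]
    d2 = centers[start, 2] - centers[start + 1, 2]
    r = np.sqrt(d0 * d0 + d1 * d1 + d2 * d2)
    uz = d2 / r if r > 0 else 0.0
    l_end = L0 / 2.0 + lam * (1.0 - wraps[start])
    z0 = centers[start, 2] + uz * l_end
    # last terminus
    d0 = centers[stop - 1, 0] - centers[stop - 2, 0]
    d1 = centers[stop - 1, 1] - centers[stop - 2, 1]
    d2 = centers[stop - 1, 2] - centers[stop - 2, 2]
    r = np.sqrt(d0 * d0 + d1 * d1 + d2 * d2)
    uz = d2 / r if r > 0 else 0.0
    l_end = L0 / 2.0 + lam * (1.0 - wraps[stop - 1])
    z1 = centers[stop - 1, 2] + uz * l_end
    return z0, z1
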