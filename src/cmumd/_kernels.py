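"""Numba kernels for pairwise Lennard-Jones forces under minimum image.

Two paths compute identical physics: a naive O(N^2) double loop used as the
correctness reference on small systems, and a linked-cell list used by
default when the box admits at least 3 cells per periodic dimension.  Both
support plain truncated-shifted LJ and the shifted-force variant, where the
pair force is brought continuously to zero at the cutoff:

    V_sf(r) = V(r) - V(rc) - (r - rc) V'(rc)
"""

import numba
import numpy as np

NB_OPTS = dict(cache=True, fastmath=True)


@numba.njit(**NB_OPTS)
def _pair_accumulate(dx, dy, dz, eps, sig, rc2, shift_force):
    """Return (fscale, pair_energy) for one pair; fscale multiplies the
    displacement vector."""
    r2 = dx * dx + dy * dy + dz * dz
    if r2 >= rc2 or r2 == 0.0:
        return 0.0, 0.0
    s2 = sig * sig / r2
    s6 = s2 * s2 * s2
    s12 = s6 * s6
    e = 4.0 * eps * (s12 - s6)
    # dV/dr * (1/r): fscale = 24 eps (2 s12 - s6) / r2
    fscale = 24.0 * eps * (2.0 * s12 - s6) / r2
    rc = np.sqrt(rc2)
    sc2 = sig * sig / rc2
    sc6 = sc2 * sc2 * sc2
    sc12 = sc6 * sc6
    e_rc = 4.0 * eps * (sc12 - sc6)
    if shift_force:
        r = np.sqrt(r2)
        # force magnitude at cutoff: 24 eps (2 sc12 - sc6) / rc
        f_rc = 24.0 * eps * (2.0 * sc12 - sc6) / rc
        e = e - e_rc + (r - rc) * f_rc
        fscale = fscale - f_rc / r
    else:
        e = e - e_rc
    return fscale, e


@numba.njit(**NB_OPTS)
def lj_naive(pos, box, species, eps_tab, sig_tab, rc, shift_force):
    n = pos.shape[0]
    forces = np.zeros((n, 3))
    pe = 0.0
    rc2 = rc * rc
    for i in range(n):
        for j in range(i + 1, n):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            dx -= box[0] * np.round(dx / box[0])
            dy -= box[1] * np.round(dy / box[1])
            dz -= box[2] * np.round(dz / box[2])
            eps = eps_tab[species[i], species[j]]
            sig = sig_tab[species[i], species[j]]
            fs, e = _pair_accumulate(dx, dy, dz, eps, sig, rc2, shift_force)
            if e != 0.0 or fs != 0.0:
                pe += e
                forces[i, 0] += fs * dx
                forces[i, 1] += fs * dy
                forces[i, 2] += fs * dz
                forces[j, 0] -= fs * dx
                forces[j, 1] -= fs * dy
                forces[j, 2] -= fs * dz
    return forces, pe


@numba.njit(**NB_OPTS)
def lj_cell(pos, box, species, eps_tab, sig_tab, rc, shift_force):
    n = pos.shape[0]
    forces = np.zeros((n, 3))
    pe = 0.0
    rc2 = rc * rc
    ncx = max(int(box[0] / rc), 1)
    ncy = max(int(box[1] / rc), 1)
    ncz = max(int(box[2] / rc), 1)
    ncell = ncx * ncy * ncz
    head = np.full(ncell, -1, dtype=np.int64)
    nxt = np.full(n, -1, dtype=np.int64)
    cx = np.empty(n, dtype=np.int64)
    cy = np.empty(n, dtype=np.int64)
    cz = np.empty(n, dtype=np.int64)
    for i in range(n):
        ix = int(pos[i, 0] / box[0] * ncx) % ncx
        iy = int(pos[i, 1] / box[1] * ncy) % ncy
        iz = int(pos[i, 2] / box[2] * ncz) % ncz
        cx[i], cy[i], cz[i] = ix, iy, iz
        c = (ix * ncy + iy) * ncz + iz
        nxt[i] = head[c]
        head[c] = i
    for i in range(n):
        for ox in range(-1, 2):
            jx = (cx[i] + ox) % ncx
            for oy in range(-1, 2):
                jy = (cy[i] + oy) % ncy
                for oz in range(-1, 2):
                    jz = (cz[i] + oz) % ncz
                    c = (jx * ncy + jy) * ncz + jz
                    j = head[c]
                    while j != -1:
                        if j > i:
                            dx = pos[i, 0] - pos[j, 0]
                            dy = pos[i, 1] - pos[j, 1]
                            dz = pos[i, 2] - pos[j, 2]
                            dx -= box[0] * np.round(dx / box[0])
                            dy -= box[1] * np.round(dy / box[1])
                            dz -= box[2] * np.round(dz / box[2])
                            eps = eps_tab[species[i], species[j]]
                            sig = sig_tab[species[i], species[j]]
                            fs, e = _pair_accumulate(
                                dx, dy, dz, eps, sig, rc2, shift_force
                            )
                            if e != 0.0 or fs != 0.0:
                                pe += e
                                forces[i, 0] += fs * dx
                                forces[i, 1] += fs * dy
                                forces[i, 2] += fs * dz
                                forces[j, 0] -= fs * dx
                                forces[j, 1] -= fs * dy
                                forces[j, 2] -= fs * dz
                        j = nxt[j]
    return forces, pe
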