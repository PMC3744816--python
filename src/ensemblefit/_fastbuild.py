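"""Numba-accelerated kernels for batch conformer construction and <r^-6>.

The placement program of a template is encoded into flat integer/float
arrays once and executed per ensemble in compiled code; results are
identical to the pure-numpy path in :mod:`ensemblefit.geometry` up to
floating-point associativity.  If numba is unavailable the package falls
back to the numpy implementations transparently.
"""

from __future__ import annotations

import math

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is expected in supported envs
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f

        return deco if not (args and callable(args[0])) else args[0]


# op codes
OP_ORIGIN, OP_BOND, OP_ANGLE3, OP_PLACE, OP_BIS, OP_TRIPOD = 0, 1, 2, 3, 4, 5
# dihedral modes
D_FIXED, D_TORSION, D_RING, D_REL = 0, 1, 2, 3


def encode_program(template):
    """Flatten a template's placement rows into kernel arrays."""
    from .geometry import BisectorRow, TripodRow, ZRow

    idx = template.index
    ring_names = list(template.rings)
    ring_id = {r: k for k, r in enumerate(ring_names)}
    tor_names = list(template.rotatable_bonds) + list(template.trivial_rotors)
    tor_id = {t: k for k, t in enumerate(tor_names)}

    max_states = max((len(r.states) for r in template.rings.values()), default=1)
    max_n = max((len(r.path) for r in template.rings.values()), default=1)
    ring_tor = np.zeros((max(len(ring_names), 1), max_states, max_n))
    ring_ang = np.zeros_like(ring_tor)
    for r, rname in enumerate(ring_names):
        ring = template.rings[rname]
        for s, st in enumerate(ring.states.values()):
            ring_tor[r, s, : len(st.torsions)] = st.torsions
            ring_ang[r, s, : len(st.angles)] = st.angles

    nrows = len(template.rows)
    code = np.zeros(nrows, dtype=np.int64)
    refs = np.full((nrows, 4), -1, dtype=np.int64)
    fpar = np.zeros((nrows, 2), dtype=np.float64)  # length, side/cos_t
    ang_ring = np.full((nrows, 2), -1, dtype=np.int64)  # ring id, pos
    ang_const = np.zeros(nrows, dtype=np.float64)
    dmode = np.zeros(nrows, dtype=np.int64)
    dref = np.full((nrows, 2), -1, dtype=np.int64)  # torsion id / ring id+slot / row
    doff = np.zeros(nrows, dtype=np.float64)
    atom_of_row = np.zeros(nrows, dtype=np.int64)
    row_of_atom_name = {}

    for k, row in enumerate(template.rows):
        atom_of_row[k] = idx(row.atom)
        row_of_atom_name[row.atom] = k
        if isinstance(row, ZRow):
            if row.parent is None:
                code[k] = OP_ORIGIN
                continue
            if row.angle_ref is None:
                code[k] = OP_BOND
                refs[k, 0] = idx(row.parent)
                fpar[k, 0] = row.length
                continue
            if isinstance(row.angle, tuple):
                ang_ring[k] = (ring_id[row.angle[1]], row.angle[2])
            else:
                ang_const[k] = float(row.angle)
            fpar[k, 0] = row.length
            if row.dihedral_ref is None:
                code[k] = OP_ANGLE3
                refs[k, 0] = idx(row.parent)
                refs[k, 1] = idx(row.angle_ref)
                continue
            code[k] = OP_PLACE
            refs[k, 0] = idx(row.dihedral_ref)
            refs[k, 1] = idx(row.angle_ref)
            refs[k, 2] = idx(row.parent)
            kind = row.dihedral[0]
            if kind == "fixed":
                dmode[k] = D_FIXED
                doff[k] = float(row.dihedral[1])
            elif kind == "torsion":
                dmode[k] = D_TORSION
                dref[k, 0] = tor_id[row.dihedral[1]]
                doff[k] = float(row.dihedral[2])
            elif kind == "ring":
                dmode[k] = D_RING
                dref[k] = (ring_id[row.dihedral[1]], row.dihedral[2])
            else:  # relative
                dmode[k] = D_REL
                dref[k, 0] = row_of_atom_name[row.dihedral[1]]
                doff[k] = float(row.dihedral[2])
        elif isinstance(row, BisectorRow):
            code[k] = OP_BIS
            refs[k, 0] = idx(row.center)
            refs[k, 1] = idx(row.ref1)
            refs[k, 2] = idx(row.ref2)
            fpar[k, 0] = row.length
            fpar[k, 1] = float(row.side)
            ang_const[k] = math.cos(math.radians(row.target_angle))
        else:  # TripodRow
            code[k] = OP_TRIPOD
            refs[k, 0] = idx(row.center)
            refs[k, 1:4] = [idx(r) for r in row.refs]
            fpar[k, 0] = row.length

    return {
        "code": code,
        "refs": refs,
        "fpar": fpar,
        "ang_ring": ang_ring,
        "ang_const": ang_const,
        "dmode": dmode,
        "dref": dref,
        "doff": doff,
        "atom_of_row": atom_of_row,
        "ring_tor": ring_tor,
        "ring_ang": ring_ang,
        "tor_names": tor_names,
        "ring_names": ring_names,
    }


@njit(cache=True, fastmath=False)
def _run_program(
    code, refs, fpar, ang_ring, ang_const, dmode, dref, doff, atom_of_row,
    ring_tor, ring_ang, torvals, ringidx, coords, dihcache,
):
    n = coords.shape[0]
    deg = math.pi / 180.0
    nrows = code.shape[0]
    for k in range(nrows):
        op = code[k]
        i = atom_of_row[k]
        if op == OP_ORIGIN:
            continue
        if op == OP_BOND:
            ip = refs[k, 0]
            L = fpar[k, 0]
            for m in range(n):
                coords[m, i, 0] = coords[m, ip, 0] + L
                coords[m, i, 1] = coords[m, ip, 1]
                coords[m, i, 2] = coords[m, ip, 2]
            continue
        if op == OP_ANGLE3:
            ip = refs[k, 0]
            ib = refs[k, 1]
            L = fpar[k, 0]
            for m in range(n):
                if ang_ring[k, 0] >= 0:
                    ang = ring_ang[ang_ring[k, 0], ringidx[ang_ring[k, 0], m], ang_ring[k, 1]]
                else:
                    ang = ang_const[k]
                th = ang * deg
                ux = coords[m, ib, 0] - coords[m, ip, 0]
                uy = coords[m, ib, 1] - coords[m, ip, 1]
                uz = coords[m, ib, 2] - coords[m, ip, 2]
                nv = math.sqrt(ux * ux + uy * uy + uz * uz)
                ux /= nv
                uy /= nv
                ct = math.cos(th)
                st = math.sin(th)
                coords[m, i, 0] = coords[m, ip, 0] + L * (ux * ct - uy * st)
                coords[m, i, 1] = coords[m, ip, 1] + L * (ux * st + uy * ct)
                coords[m, i, 2] = coords[m, ip, 2]
            continue
        if op == OP_PLACE:
            ia = refs[k, 0]
            ib = refs[k, 1]
            ic = refs[k, 2]
            L = fpar[k, 0]
            for m in range(n):
                if ang_ring[k, 0] >= 0:
                    ang = ring_ang[ang_ring[k, 0], ringidx[ang_ring[k, 0], m], ang_ring[k, 1]]
                else:
                    ang = ang_const[k]
                if dmode[k] == D_FIXED:
                    tor = doff[k]
                elif dmode[k] == D_TORSION:
                    tor = torvals[m, dref[k, 0]] + doff[k]
                elif dmode[k] == D_RING:
                    tor = ring_tor[dref[k, 0], ringidx[dref[k, 0], m], dref[k, 1]]
                else:
                    tor = dihcache[dref[k, 0], m] + doff[k]
                dihcache[k, m] = tor
                theta = ang * deg
                phi = tor * deg
                bcx = coords[m, ic, 0] - coords[m, ib, 0]
                bcy = coords[m, ic, 1] - coords[m, ib, 1]
                bcz = coords[m, ic, 2] - coords[m, ib, 2]
                nb = math.sqrt(bcx * bcx + bcy * bcy + bcz * bcz)
                bcx /= nb
                bcy /= nb
                bcz /= nb
                abx = coords[m, ib, 0] - coords[m, ia, 0]
                aby = coords[m, ib, 1] - coords[m, ia, 1]
                abz = coords[m, ib, 2] - coords[m, ia, 2]
                nx = aby * bcz - abz * bcy
                ny = abz * bcx - abx * bcz
                nz = abx * bcy - aby * bcx
                nn = math.sqrt(nx * nx + ny * ny + nz * nz)
                nx /= nn
                ny /= nn
                nz /= nn
                mx = ny * bcz - nz * bcy
                my = nz * bcx - nx * bcz
                mz = nx * bcy - ny * bcx
                st = math.sin(theta)
                ct = math.cos(theta)
                cp = math.cos(phi)
                sp = math.sin(phi)
                coords[m, i, 0] = coords[m, ic, 0] + L * (-bcx * ct + mx * st * cp + nx * st * sp)
                coords[m, i, 1] = coords[m, ic, 1] + L * (-bcy * ct + my * st * cp + ny * st * sp)
                coords[m, i, 2] = coords[m, ic, 2] + L * (-bcz * ct + mz * st * cp + nz * st * sp)
            continue
        if op == OP_BIS:
            ic = refs[k, 0]
            i1 = refs[k, 1]
            i2 = refs[k, 2]
            L = fpar[k, 0]
            side = fpar[k, 1]
            cos_t = ang_const[k]
            for m in range(n):
                u1x = coords[m, i1, 0] - coords[m, ic, 0]
                u1y = coords[m, i1, 1] - coords[m, ic, 1]
                u1z = coords[m, i1, 2] - coords[m, ic, 2]
                nv = math.sqrt(u1x * u1x + u1y * u1y + u1z * u1z)
                u1x /= nv
                u1y /= nv
                u1z /= nv
                u2x = coords[m, i2, 0] - coords[m, ic, 0]
                u2y = coords[m, i2, 1] - coords[m, ic, 1]
                u2z = coords[m, i2, 2] - coords[m, ic, 2]
                nv = math.sqrt(u2x * u2x + u2y * u2y + u2z * u2z)
                u2x /= nv
                u2y /= nv
                u2z /= nv
                bx = -(u1x + u2x)
                by = -(u1y + u2y)
                bz = -(u1z + u2z)
                nv = math.sqrt(bx * bx + by * by + bz * bz)
                bx /= nv
                by /= nv
                bz /= nv
                cx = u1y * u2z - u1z * u2y
                cy = u1z * u2x - u1x * u2z
                cz = u1x * u2y - u1y * u2x
                nv = math.sqrt(cx * cx + cy * cy + cz * cz)
                cx /= nv
                cy /= nv
                cz /= nv
                dot = u1x * u2x + u1y * u2y + u1z * u2z
                if dot > 1.0:
                    dot = 1.0
                if dot < -1.0:
                    dot = -1.0
                alpha = 0.5 * math.acos(dot)
                cw = -cos_t / math.cos(alpha)
                if cw > 1.0:
                    cw = 1.0
                if cw < -1.0:
                    cw = -1.0
                w = math.acos(cw)
                coords[m, i, 0] = coords[m, ic, 0] + L * (bx * math.cos(w) + side * cx * math.sin(w))
                coords[m, i, 1] = coords[m, ic, 1] + L * (by * math.cos(w) + side * cy * math.sin(w))
                coords[m, i, 2] = coords[m, ic, 2] + L * (bz * math.cos(w) + side * cz * math.sin(w))
            continue
        # OP_TRIPOD
        ic = refs[k, 0]
        L = fpar[k, 0]
        for m in range(n):
            sx = 0.0
            sy = 0.0
            sz = 0.0
            for jj in range(1, 4):
                ir = refs[k, jj]
                vx = coords[m, ir, 0] - coords[m, ic, 0]
                vy = coords[m, ir, 1] - coords[m, ic, 1]
                vz = coords[m, ir, 2] - coords[m, ic, 2]
                nv = math.sqrt(vx * vx + vy * vy + vz * vz)
                sx += vx / nv
                sy += vy / nv
                sz += vz / nv
            nv = math.sqrt(sx * sx + sy * sy + sz * sz)
            coords[m, i, 0] = coords[m, ic, 0] - L * sx / nv
            coords[m, i, 1] = coords[m, ic, 1] - L * sy / nv
            coords[m, i, 2] = coords[m, ic, 2] - L * sz / nv
    return coords


def run_program(prog, torvals, ringidx, n, natoms):
    coords = np.zeros((n, natoms, 3))
    dihcache = np.zeros((prog["code"].shape[0], n))
    _run_program(
        prog["code"], prog["refs"], prog["fpar"], prog["ang_ring"],
        prog["ang_const"], prog["dmode"], prog["dref"], prog["doff"],
        prog["atom_of_row"], prog["ring_tor"], prog["ring_ang"],
        torvals, ringidx, coords, dihcache,
    )
    return coords


@njit(cache=True, fastmath=False)
def pooled_r6(X, pool, ns):
    """Pool-summed mean <r^-6> matrix over a conformer batch.

    X: (n, P, 3) proton coordinates; pool: (P,) spin-pool index per proton.
    Returns (S, dmin2): the (ns, ns) matrix and the minimal squared
    inter-proton distance encountered.
    """
    n, P, _ = X.shape
    S = np.zeros((ns, ns))
    dmin2 = 1e30
    for a in range(P):
        for b in range(a + 1, P):
            acc = 0.0
            for m in range(n):
                dx = X[m, a, 0] - X[m, b, 0]
                dy = X[m, a, 1] - X[m, b, 1]
                dz = X[m, a, 2] - X[m, b, 2]
                d2 = dx * dx + dy * dy + dz * dz
                if d2 < dmin2:
                    dmin2 = d2
                inv = 1.0 / d2
                acc += inv * inv * inv
            acc /= n
            pa = pool[a]
            pb = pool[b]
            S[pa, pb] += acc
            S[pb, pa] += acc
    return S, dmin2
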