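"""Numba inner loop of the center-based suspension model.

The kernel advances all particles with a semi-implicit Euler scheme: the
stiff Stokes-drag term is treated implicitly in the velocity update, every
other force (shear-gradient lift, buoyant weight, undisturbed-flow
acceleration, soft-sphere contacts) explicitly. Particle-particle contact
detection uses a Verlet neighbour list with an O(n^2) rebuild triggered by
accumulated displacement; at the volume fractions of this process (~0.1%)
contacts are rare outside the settled bottom layer.

Everything here is plain float64 arithmetic on preallocated arrays so the
integration is bitwise deterministic for fixed inputs.
"""

import math

import numpy as np
from numba import njit

# return codes
OK = 0
PAIR_OVERFLOW = 1
NON_FINITE = 2


@njit(cache=True, inline="always")
def _interp_node(fields, k, i, j, fx, fy):
    return (fields[k, i, j] * (1.0 - fx) * (1.0 - fy)
            + fields[k, i + 1, j] * fx * (1.0 - fy)
            + fields[k, i, j + 1] * (1.0 - fx) * fy
            + fields[k, i + 1, j + 1] * fx * fy)


@njit(cache=True, inline="always")
def _locate(rq, zq, dr, dz, nr, nz):
    xi = rq / dr
    yj = zq / dz
    i = int(xi)
    j = int(yj)
    if i > nr - 2:
        i = nr - 2
    if i < 0:
        i = 0
    if j > nz - 2:
        j = nz - 2
    if j < 0:
        j = 0
    fx = xi - i
    fy = yj - j
    if fx < 0.0:
        fx = 0.0
    if fx > 1.0:
        fx = 1.0
    if fy < 0.0:
        fy = 0.0
    if fy > 1.0:
        fy = 1.0
    return i, j, fx, fy


@njit(cache=True)
def _fluid_at(fields, x, y, z, dr, dz, nr, nz, rmax, zmax, out9):
    """Interpolate the 9 stacked fields and rotate to Cartesian at (x,y,z).

    out9 receives: u (0:3), vorticity (3:6), convective acceleration (6:9),
    all in Cartesian components.
    """
    r = math.sqrt(x * x + y * y)
    rq = r if r < rmax else rmax
    zq = z
    if zq < 0.0:
        zq = 0.0
    elif zq > zmax:
        zq = zmax
    i, j, fx, fy = _locate(rq, zq, dr, dz, nr, nz)
    if r > 1e-300:
        c = x / r
        s = y / r
    else:
        c = 1.0
        s = 0.0
    for blk in range(3):
        vr = _interp_node(fields, 3 * blk + 0, i, j, fx, fy)
        vt = _interp_node(fields, 3 * blk + 1, i, j, fx, fy)
        vz = _interp_node(fields, 3 * blk + 2, i, j, fx, fy)
        out9[3 * blk + 0] = vr * c - vt * s
        out9[3 * blk + 1] = vr * s + vt * c
        out9[3 * blk + 2] = vz


@njit(cache=True)
def simulate_kernel(pos, vel, radius, density, fields,
                    dr, dz, rw, height,
                    mu, rhof, g, kn, zeta, kwall,
                    use_fluid, use_lift, use_contacts, use_gravity,
                    dt, nsteps, sample_every,
                    out_t, out_pos, out_vel, out_ufl,
                    pair_i, pair_j):
    n = pos.shape[0]
    nr = fields.shape[1]
    nz = fields.shape[2]
    rmax = rw * (1.0 - 1e-12)

    vol = np.empty(n)
    mass = np.empty(n)
    tauv = np.empty(n)
    for a in range(n):
        vol[a] = 4.0 / 3.0 * math.pi * radius[a] ** 3
        mass[a] = density[a] * vol[a]
        tauv[a] = mass[a] / (6.0 * math.pi * mu * radius[a])
    nu = mu / rhof

    skin = 2.0 * radius.max()
    npairs = 0
    acc_disp = 1e30  # force an initial neighbour-list build
    fc = np.zeros((n, 3))
    f9 = np.empty(9)

    # initial sample
    out_t[0] = 0.0
    for a in range(n):
        for d in range(3):
            out_pos[0, a, d] = pos[a, d]
            out_vel[0, a, d] = vel[a, d]
        if use_fluid:
            _fluid_at(fields, pos[a, 0], pos[a, 1], pos[a, 2],
                      dr, dz, nr, nz, rmax, height, f9)
            for d in range(3):
                out_ufl[0, a, d] = f9[d]
        else:
            for d in range(3):
                out_ufl[0, a, d] = 0.0

    rec = 0
    for step in range(nsteps):
        # ---- neighbour list ----
        if use_contacts and n > 1 and acc_disp > 0.5 * skin:
            npairs = 0
            for a in range(n - 1):
                for b in range(a + 1, n):
                    cut = radius[a] + radius[b] + skin
                    ddx = pos[a, 0] - pos[b, 0]
                    ddy = pos[a, 1] - pos[b, 1]
                    ddz = pos[a, 2] - pos[b, 2]
                    if ddx * ddx + ddy * ddy + ddz * ddz < cut * cut:
                        if npairs >= pair_i.shape[0]:
                            return PAIR_OVERFLOW
                        pair_i[npairs] = a
                        pair_j[npairs] = b
                        npairs += 1
            acc_disp = 0.0

        # ---- contact forces ----
        for a in range(n):
            fc[a, 0] = 0.0
            fc[a, 1] = 0.0
            fc[a, 2] = 0.0
        if use_contacts:
            for q in range(npairs):
                a = pair_i[q]
                b = pair_j[q]
                ddx = pos[a, 0] - pos[b, 0]
                ddy = pos[a, 1] - pos[b, 1]
                ddz = pos[a, 2] - pos[b, 2]
                sumr = radius[a] + radius[b]
                d2 = ddx * ddx + ddy * ddy + ddz * ddz
                if d2 < sumr * sumr and d2 > 1e-300:
                    dist = math.sqrt(d2)
                    h = sumr - dist
                    nx = ddx / dist
                    ny = ddy / dist
                    nzc = ddz / dist
                    vreln = ((vel[a, 0] - vel[b, 0]) * nx
                             + (vel[a, 1] - vel[b, 1]) * ny
                             + (vel[a, 2] - vel[b, 2]) * nzc)
                    meff = mass[a] * mass[b] / (mass[a] + mass[b])
                    cdamp = 2.0 * zeta * math.sqrt(kn * meff)
                    fmag = kn * h - cdamp * vreln
                    if fmag > 0.0:
                        fc[a, 0] += fmag * nx
                        fc[a, 1] += fmag * ny
                        fc[a, 2] += fmag * nzc
                        fc[b, 0] -= fmag * nx
                        fc[b, 1] -= fmag * ny
                        fc[b, 2] -= fmag * nzc
            for a in range(n):
                x = pos[a, 0]
                y = pos[a, 1]
                zp = pos[a, 2]
                cw = 2.0 * zeta * math.sqrt(kwall * mass[a])
                if zp < radius[a]:
                    fmag = kwall * (radius[a] - zp) - cw * vel[a, 2]
                    if fmag > 0.0:
                        fc[a, 2] += fmag
                if zp > height - radius[a]:
                    fmag = kwall * (zp - (height - radius[a])) + cw * vel[a, 2]
                    if fmag > 0.0:
                        fc[a, 2] -= fmag
                r = math.sqrt(x * x + y * y)
                if r > rw - radius[a] and r > 1e-300:
                    vr = (x * vel[a, 0] + y * vel[a, 1]) / r
                    fmag = kwall * (r - (rw - radius[a])) + cw * vr
                    if fmag > 0.0:
                        fc[a, 0] -= fmag * x / r
                        fc[a, 1] -= fmag * y / r

        # ---- advance particles ----
        vmax2 = 0.0
        for a in range(n):
            fx = fc[a, 0]
            fy = fc[a, 1]
            fz = fc[a, 2]
            if use_gravity:
                fz -= (density[a] - rhof) * vol[a] * g
            ux = 0.0
            uy = 0.0
            uz = 0.0
            if use_fluid:
                _fluid_at(fields, pos[a, 0], pos[a, 1], pos[a, 2],
                          dr, dz, nr, nz, rmax, height, f9)
                ux = f9[0]
                uy = f9[1]
                uz = f9[2]
                # undisturbed-flow (pressure-gradient) force rho_f V Du/Dt
                fx += rhof * vol[a] * f9[6]
                fy += rhof * vol[a] * f9[7]
                fz += rhof * vol[a] * f9[8]
                if use_lift:
                    sx = ux - vel[a, 0]
                    sy = uy - vel[a, 1]
                    sz = uz - vel[a, 2]
                    wx = f9[3]
                    wy = f9[4]
                    wz = f9[5]
                    wmag = math.sqrt(wx * wx + wy * wy + wz * wz)
                    smag = math.sqrt(sx * sx + sy * sy + sz * sz)
                    if wmag > 1e-12 and smag > 1e-14:
                        res = 2.0 * radius[a] * smag * rhof / mu
                        beta = radius[a] * wmag / smag
                        if beta > 1.0:
                            beta = 1.0
                        sb = math.sqrt(beta)
                        cmei = ((1.0 - 0.3314 * sb) * math.exp(-res / 10.0)
                                + 0.3314 * sb)
                        coef = (6.46 * cmei * mu * radius[a] ** 2
                                / math.sqrt(nu * wmag))
                        fx += coef * (sy * wz - sz * wy)
                        fy += coef * (sz * wx - sx * wz)
                        fz += coef * (sx * wy - sy * wx)

            if use_fluid:
                adt = dt / tauv[a]
                denom = 1.0 + adt
                vel[a, 0] = (vel[a, 0] + dt * fx / mass[a] + adt * ux) / denom
                vel[a, 1] = (vel[a, 1] + dt * fy / mass[a] + adt * uy) / denom
                vel[a, 2] = (vel[a, 2] + dt * fz / mass[a] + adt * uz) / denom
            else:
                vel[a, 0] += dt * fx / mass[a]
                vel[a, 1] += dt * fy / mass[a]
                vel[a, 2] += dt * fz / mass[a]

            pos[a, 0] += dt * vel[a, 0]
            pos[a, 1] += dt * vel[a, 1]
            pos[a, 2] += dt * vel[a, 2]

            # hard containment of the particle center (wall springs do the
            # soft work; this is the integrity backstop)
            if pos[a, 2] < 0.0:
                pos[a, 2] = 0.0
                if vel[a, 2] < 0.0:
                    vel[a, 2] = 0.0
            elif pos[a, 2] > height:
                pos[a, 2] = height
                if vel[a, 2] > 0.0:
                    vel[a, 2] = 0.0
            r = math.sqrt(pos[a, 0] ** 2 + pos[a, 1] ** 2)
            if r > rw and r > 1e-300:
                scale = rw / r
                pos[a, 0] *= scale
                pos[a, 1] *= scale
                vr = (pos[a, 0] * vel[a, 0] + pos[a, 1] * vel[a, 1]) / rw
                if vr > 0.0:
                    vel[a, 0] -= vr * pos[a, 0] / rw
                    vel[a, 1] -= vr * pos[a, 1] / rw

            v2 = (vel[a, 0] ** 2 + vel[a, 1] ** 2 + vel[a, 2] ** 2)
            if v2 > vmax2:
                vmax2 = v2
            if not (math.isfinite(pos[a, 0]) and math.isfinite(pos[a, 1])
                    and math.isfinite(pos[a, 2])):
                return NON_FINITE
        acc_disp += math.sqrt(vmax2) * dt

        # ---- sampling ----
        if (step + 1) % sample_every == 0:
            rec += 1
            out_t[rec] = (step + 1) * dt
            for a in range(n):
                for d in range(3):
                    out_pos[rec, a, d] = pos[a, d]
                    out_vel[rec, a, d] = vel[a, d]
                if use_fluid:
                    _fluid_at(fields, pos[a, 0], pos[a, 1], pos[a, 2],
                              dr, dz, nr, nz, rmax, height, f9)
                    for d in range(3):
                        out_ufl[rec, a, d] = f9[d]
                else:
                    for d in range(3):
                        out_ufl[rec, a, d] = 0.0
    return OK
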