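"""JIT-compiled inner loop of the Brownian pulling integrator.

Kept separate so the public dynamics module stays readable; the kernel is
pure numerics over contiguous arrays and mirrors NonbondedWorkspace.forces
exactly (truncated Coulomb + 12-6 LJ, distance clamp, force evaluated at
the clamp distance inside it).
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False, fastmath=False)
def integrate_interval(pos, rec, qq, sigma, eps4, cutoff, clamp,
                       k, v_nm_ps, dt, n_steps, direction, pulled,
                       gamma, rigid, noise, max_step, t0, x0, anchor0):
    """Euler-Maruyama overdamped integration of one pulling interval.

    The dummy (spring anchor) starts at anchor0 and advances at v along
    ``direction``; the spring force is the full vector k (dummy - pulled),
    so carrying anchor0 across intervals keeps the force continuous at
    direction changes while letting extension accumulate until rupture.

    noise is the pre-scaled random increment array: shape (n_steps, 3) in
    rigid mode, (n_steps, n_ligand, 3) in flexible mode (zeros at T = 0).
    Per-step displacements are capped at max_step (per atom), which tames
    core-overlap forces without affecting resolved dynamics.

    Returns (times, forces, displacements, final_pos, max_drift, ok).
    forces are the spring-force projection on ``direction`` evaluated at the
    start of each step (the force that acted over the recorded displacement
    increment).
    """
    nl = pos.shape[0]
    m = rec.shape[0]
    cutoff2 = cutoff * cutoff
    gamma_eff = gamma * nl if rigid else gamma

    times = np.empty(n_steps)
    forces = np.empty(n_steps)
    disps = np.empty(n_steps)
    f = np.zeros((nl, 3))
    x_p0 = pos[pulled].copy()
    com0 = np.zeros(3)
    for a in range(nl):
        for c in range(3):
            com0[c] += pos[a, c]
    for c in range(3):
        com0[c] /= nl
    max_drift = 0.0
    ok = True

    for i in range(n_steps):
        t_local = i * dt
        # nonbonded forces on each ligand atom
        for a in range(nl):
            f[a, 0] = 0.0
            f[a, 1] = 0.0
            f[a, 2] = 0.0
            for b in range(m):
                dx = pos[a, 0] - rec[b, 0]
                dy = pos[a, 1] - rec[b, 1]
                dz = pos[a, 2] - rec[b, 2]
                r2 = dx * dx + dy * dy + dz * dz
                if r2 <= cutoff2 and r2 > 1e-24:
                    r = np.sqrt(r2)
                    re = r if r > clamp else clamp
                    s6 = (sigma[a, b] / re) ** 6
                    mag = (qq[a, b] / (re * re)
                           + 6.0 * eps4[a, b] / re * (2.0 * s6 * s6 - s6)) / re
                    f[a, 0] += mag * dx
                    f[a, 1] += mag * dy
                    f[a, 2] += mag * dz
        # spring: dummy advances from anchor0 along the pulling direction
        fvx = k * (anchor0[0] + v_nm_ps * t_local * direction[0] - pos[pulled, 0])
        fvy = k * (anchor0[1] + v_nm_ps * t_local * direction[1] - pos[pulled, 1])
        fvz = k * (anchor0[2] + v_nm_ps * t_local * direction[2] - pos[pulled, 2])
        fs = fvx * direction[0] + fvy * direction[1] + fvz * direction[2]

        if rigid:
            gx = fvx
            gy = fvy
            gz = fvz
            for a in range(nl):
                gx += f[a, 0]
                gy += f[a, 1]
                gz += f[a, 2]
            sx = gx / gamma_eff * dt + noise[i, 0]
            sy = gy / gamma_eff * dt + noise[i, 1]
            sz = gz / gamma_eff * dt + noise[i, 2]
            sn = np.sqrt(sx * sx + sy * sy + sz * sz)
            if not np.isfinite(sn):
                ok = False
                break
            if sn > max_step:
                sc = max_step / sn
                sx *= sc
                sy *= sc
                sz *= sc
            for a in range(nl):
                pos[a, 0] += sx
                pos[a, 1] += sy
                pos[a, 2] += sz
        else:
            for a in range(nl):
                gx = f[a, 0]
                gy = f[a, 1]
                gz = f[a, 2]
                if a == pulled:
                    gx += fvx
                    gy += fvy
                    gz += fvz
                sx = gx / gamma * dt + noise[i, a * 3 + 0]
                sy = gy / gamma * dt + noise[i, a * 3 + 1]
                sz = gz / gamma * dt + noise[i, a * 3 + 2]
                sn = np.sqrt(sx * sx + sy * sy + sz * sz)
                if not np.isfinite(sn):
                    ok = False
                    break
                if sn > max_step:
                    sc = max_step / sn
                    sx *= sc
                    sy *= sc
                    sz *= sc
                pos[a, 0] += sx
                pos[a, 1] += sy
                pos[a, 2] += sz
            if not ok:
                break

        # sample i covers the step ending at t_new: displacement is the
        # end-of-step value, the force is the one that acted during the step
        # (pre-step evaluation; keeps the work sum unbiased under noise)
        t_new = t_local + dt
        xproj_new = ((pos[pulled, 0] - x_p0[0]) * direction[0]
                     + (pos[pulled, 1] - x_p0[1]) * direction[1]
                     + (pos[pulled, 2] - x_p0[2]) * direction[2])
        times[i] = t0 + t_new
        forces[i] = fs
        disps[i] = x0 + xproj_new

        cx = 0.0
        cy = 0.0
        cz = 0.0
        for a in range(nl):
            cx += pos[a, 0]
            cy += pos[a, 1]
            cz += pos[a, 2]
        cx = cx / nl - com0[0]
        cy = cy / nl - com0[1]
        cz = cz / nl - com0[2]
        drift = np.sqrt(cx * cx + cy * cy + cz * cz)
        if drift > max_drift:
            max_drift = drift

    return times, forces, disps, pos, max_drift, ok
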