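"""Numba inner loops for the rigid-body Brownian dynamics engine.

Everything here works on plain float64/int64 arrays; the friendly container
types live in :mod:`nanostargel.dynamics` and :mod:`nanostargel.potentials`.
Pair interactions: WCA between CORE/ARM beads of different stars, Morse
between patch sites, intramolecular pairs excluded.  Minimum image in a
cubic periodic box.
"""

from __future__ import annotations

import numpy as np
from numba import njit

WCA_CUT = 2.0 ** (1.0 / 6.0)
OVERLAP_R2 = 0.25  # (0.5 sigma)^2


@njit(cache=True, inline="always")
def _quat_mat(q, R):
    w, x, y, z = q[0], q[1], q[2], q[3]
    R[0, 0] = 1.0 - 2.0 * (y * y + z * z)
    R[0, 1] = 2.0 * (x * y - w * z)
    R[0, 2] = 2.0 * (x * z + w * y)
    R[1, 0] = 2.0 * (x * y + w * z)
    R[1, 1] = 1.0 - 2.0 * (x * x + z * z)
    R[1, 2] = 2.0 * (y * z - w * x)
    R[2, 0] = 2.0 * (x * z - w * y)
    R[2, 1] = 2.0 * (y * z + w * x)
    R[2, 2] = 1.0 - 2.0 * (x * x + y * y)


@njit(cache=True)
def build_beads(centers, quats, tpl, out):
    """World-frame bead positions: centers + R(q) · template."""
    n = centers.shape[0]
    nb = tpl.shape[0]
    R = np.empty((3, 3))
    for i in range(n):
        _quat_mat(quats[i], R)
        for b in range(nb):
            for a in range(3):
                out[i * nb + b, a] = (
                    centers[i, a]
                    + R[a, 0] * tpl[b, 0]
                    + R[a, 1] * tpl[b, 1]
                    + R[a, 2] * tpl[b, 2]
                )


@njit(cache=True)
def forces_bruteforce(
    pos, types, mol, box_L, eps_rep, sigma, eps_m, a_m, r0_m, rcut_patch, morse_shift
):
    """O(M²) forces/energy/virial over all bead pairs. Returns per-bead forces."""
    m = pos.shape[0]
    forces = np.zeros((m, 3))
    virial = np.zeros((3, 3))
    energy = 0.0
    n_overlap = 0
    wca_cut2 = (WCA_CUT * sigma) ** 2
    morse_cut2 = rcut_patch * rcut_patch
    for i in range(m):
        for j in range(i + 1, m):
            if mol[i] == mol[j]:
                continue
            ti, tj = types[i], types[j]
            is_patch = ti == 2 and tj == 2
            if (ti == 2) != (tj == 2):
                continue  # patch-(core/arm) cross pairs do not interact
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            dx -= box_L * np.rint(dx / box_L)
            dy -= box_L * np.rint(dy / box_L)
            dz -= box_L * np.rint(dz / box_L)
            r2 = dx * dx + dy * dy + dz * dz
            if is_patch:
                if r2 >= morse_cut2:
                    continue
                r = np.sqrt(r2)
                ex = np.exp(-a_m * (r - r0_m))
                omx = 1.0 - ex
                energy += eps_m * (omx * omx - 1.0) - morse_shift
                fmag = -2.0 * eps_m * a_m * omx * ex / r  # F_i = fmag * dr
            else:
                if r2 >= wca_cut2:
                    continue
                if r2 < OVERLAP_R2:
                    n_overlap += 1
                sr2 = sigma * sigma / r2
                sr6 = sr2 * sr2 * sr2
                energy += 4.0 * eps_rep * (sr6 * sr6 - sr6) + eps_rep
                fmag = 24.0 * eps_rep * (2.0 * sr6 * sr6 - sr6) / r2
            fx = fmag * dx
            fy = fmag * dy
            fz = fmag * dz
            forces[i, 0] += fx
            forces[i, 1] += fy
            forces[i, 2] += fz
            forces[j, 0] -= fx
            forces[j, 1] -= fy
            forces[j, 2] -= fz
            virial[0, 0] += dx * fx
            virial[0, 1] += dx * fy
            virial[0, 2] += dx * fz
            virial[1, 0] += dy * fx
            virial[1, 1] += dy * fy
            virial[1, 2] += dy * fz
            virial[2, 0] += dz * fx
            virial[2, 1] += dz * fy
            virial[2, 2] += dz * fz
    return forces, energy, virial, n_overlap


@njit(cache=True)
def _build_pairs(pos, types, mol, box_L, r_list_wca, r_list_patch, pairs, kinds):
    """Verlet pair list over eligible bead pairs; returns the pair count."""
    m = pos.shape[0]
    rw2 = r_list_wca * r_list_wca
    rp2 = r_list_patch * r_list_patch
    cap = pairs.shape[0]
    np_pairs = 0
    for i in range(m):
        ti = types[i]
        for j in range(i + 1, m):
            if mol[i] == mol[j]:
                continue
            tj = types[j]
            if (ti == 2) != (tj == 2):
                continue
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            dx -= box_L * np.rint(dx / box_L)
            dy -= box_L * np.rint(dy / box_L)
            dz -= box_L * np.rint(dz / box_L)
            r2 = dx * dx + dy * dy + dz * dz
            if ti == 2:
                if r2 < rp2:
                    if np_pairs >= cap:
                        return -1
                    pairs[np_pairs, 0] = i
                    pairs[np_pairs, 1] = j
                    kinds[np_pairs] = 1
                    np_pairs += 1
            else:
                if r2 < rw2:
                    if np_pairs >= cap:
                        return -1
                    pairs[np_pairs, 0] = i
                    pairs[np_pairs, 1] = j
                    kinds[np_pairs] = 0
                    np_pairs += 1
    return np_pairs


@njit(cache=True)
def _pair_forces(
    pos, pairs, kinds, n_pairs, box_L,
    eps_rep, sigma, eps_m, a_m, r0_m, rcut_patch, morse_shift,
    forces, virial,
):
    """Forces over a Verlet pair list.  Returns (energy, n_contacts, n_overlap)."""
    forces[:] = 0.0
    virial[:] = 0.0
    energy = 0.0
    n_contacts = 0
    n_overlap = 0
    wca_cut2 = (WCA_CUT * sigma) ** 2
    morse_cut2 = rcut_patch * rcut_patch
    for k in range(n_pairs):
        i = pairs[k, 0]
        j = pairs[k, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= box_L * np.rint(dx / box_L)
        dy -= box_L * np.rint(dy / box_L)
        dz -= box_L * np.rint(dz / box_L)
        r2 = dx * dx + dy * dy + dz * dz
        if kinds[k] == 1:
            if r2 >= morse_cut2:
                continue
            n_contacts += 1
            r = np.sqrt(r2)
            ex = np.exp(-a_m * (r - r0_m))
            omx = 1.0 - ex
            energy += eps_m * (omx * omx - 1.0) - morse_shift
            fmag = -2.0 * eps_m * a_m * omx * ex / r
        else:
            if r2 >= wca_cut2:
                continue
            if r2 < OVERLAP_R2:
                n_overlap += 1
            sr2 = sigma * sigma / r2
            sr6 = sr2 * sr2 * sr2
            energy += 4.0 * eps_rep * (sr6 * sr6 - sr6) + eps_rep
            fmag = 24.0 * eps_rep * (2.0 * sr6 * sr6 - sr6) / r2
        fx = fmag * dx
        fy = fmag * dy
        fz = fmag * dz
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
        virial[0, 1] += dx * fy
        virial[0, 2] += dx * fz
        virial[1, 2] += dy * fz
        virial[0, 0] += dx * fx
        virial[1, 1] += dy * fy
        virial[2, 2] += dz * fz
    return energy, n_contacts, n_overlap


@njit(cache=True)
def bd_chunk(
    centers, quats, images, tpl, tpl_types, box_L, T, dt, D_t, D_r,
    noise,
    eps_rep, sigma, eps_m, a_m, r0_m, rcut_patch, morse_shift,
    skin, disp_cap, max_halvings,
    sample_every, step0,
    samp_step, samp_E, samp_P, samp_Nc,
):
    """Advance ``noise.shape[0]`` Euler–Maruyama steps of overdamped rigid-body BD.

    Mutates centers/quats/images in place.  Observables (energy, off-diagonal
    virial stress ·V, raw patch contact count) are written into the ``samp_*``
    buffers whenever the global step index is a multiple of ``sample_every``.
    Returns (n_samples, n_rejected_steps, n_rebuilds, nan_step) where
    nan_step >= 0 flags a non-finite force at that step.
    """
    n_steps = noise.shape[0]
    n = centers.shape[0]
    nb = tpl.shape[0]
    m = n * nb
    mol = np.empty(m, dtype=np.int64)
    types = np.empty(m, dtype=np.int64)
    for i in range(n):
        for b in range(nb):
            mol[i * nb + b] = i
            types[i * nb + b] = tpl_types[b]
    lever = 0.0
    for b in range(nb):
        l = np.sqrt(tpl[b, 0] ** 2 + tpl[b, 1] ** 2 + tpl[b, 2] ** 2)
        if l > lever:
            lever = l

    pos = np.empty((m, 3))
    forces = np.empty((m, 3))
    virial = np.empty((3, 3))
    max_pairs = m * 64
    pairs = np.empty((max_pairs, 2), dtype=np.int64)
    kinds = np.empty(max_pairs, dtype=np.int64)
    r_list_wca = WCA_CUT * sigma + skin
    r_list_patch = rcut_patch + skin
    ref_centers = centers.copy()
    ref_quats = quats.copy()

    star_F = np.empty((n, 3))
    star_T = np.empty((n, 3))
    disp = np.empty((n, 3))
    rot = np.empty((n, 3))
    R = np.empty((3, 3))

    n_pairs = -1
    n_samples = 0
    n_rejected = 0
    n_rebuilds = 0

    for istep in range(n_steps):
        # rebuild the Verlet list when any star may have drifted by skin/2
        need = n_pairs < 0
        if not need:
            half_skin = 0.5 * skin
            for i in range(n):
                dx = centers[i, 0] - ref_centers[i, 0]
                dy = centers[i, 1] - ref_centers[i, 1]
                dz = centers[i, 2] - ref_centers[i, 2]
                dx -= box_L * np.rint(dx / box_L)
                dy -= box_L * np.rint(dy / box_L)
                dz -= box_L * np.rint(dz / box_L)
                qd = (
                    quats[i, 0] * ref_quats[i, 0]
                    + quats[i, 1] * ref_quats[i, 1]
                    + quats[i, 2] * ref_quats[i, 2]
                    + quats[i, 3] * ref_quats[i, 3]
                )
                if qd < 0.0:
                    qd = -qd
                if qd > 1.0:
                    qd = 1.0
                ang = 2.0 * np.arccos(qd)
                drift = np.sqrt(dx * dx + dy * dy + dz * dz) + lever * ang
                if drift > half_skin:
                    need = True
                    break
        build_beads(centers, quats, tpl, pos)
        if need:
            n_pairs = _build_pairs(
                pos, types, mol, box_L, r_list_wca, r_list_patch, pairs, kinds
            )
            if n_pairs < 0:
                return n_samples, n_rejected, n_rebuilds, istep  # overflow: abort
            ref_centers[:] = centers
            ref_quats[:] = quats
            n_rebuilds += 1

        energy, n_contacts, _ = _pair_forces(
            pos, pairs, kinds, n_pairs, box_L,
            eps_rep, sigma, eps_m, a_m, r0_m, rcut_patch, morse_shift,
            forces, virial,
        )
        if not np.isfinite(energy):
            return n_samples, n_rejected, n_rebuilds, istep

        gstep = step0 + istep
        if sample_every > 0 and gstep % sample_every == 0:
            samp_step[n_samples] = gstep
            samp_E[n_samples] = energy
            samp_P[n_samples, 0] = virial[0, 1]
            samp_P[n_samples, 1] = virial[0, 2]
            samp_P[n_samples, 2] = virial[1, 2]
            samp_Nc[n_samples] = n_contacts
            n_samples += 1

        # rigid-body force and torque
        for i in range(n):
            fx = 0.0
            fy = 0.0
            fz = 0.0
            tx = 0.0
            ty = 0.0
            tz = 0.0
            _quat_mat(quats[i], R)
            for b in range(nb):
                k = i * nb + b
                bx = forces[k, 0]
                by = forces[k, 1]
                bz = forces[k, 2]
                fx += bx
                fy += by
                fz += bz
                ox = R[0, 0] * tpl[b, 0] + R[0, 1] * tpl[b, 1] + R[0, 2] * tpl[b, 2]
                oy = R[1, 0] * tpl[b, 0] + R[1, 1] * tpl[b, 1] + R[1, 2] * tpl[b, 2]
                oz = R[2, 0] * tpl[b, 0] + R[2, 1] * tpl[b, 1] + R[2, 2] * tpl[b, 2]
                tx += oy * bz - oz * by
                ty += oz * bx - ox * bz
                tz += ox * by - oy * bx
            star_F[i, 0] = fx
            star_F[i, 1] = fy
            star_F[i, 2] = fz
            star_T[i, 0] = tx
            star_T[i, 1] = ty
            star_T[i, 2] = tz

        # Euler-Maruyama with per-step dt halving when a move exceeds the cap
        scale = 1.0
        h = 0
        while True:
            dtp = dt * scale
            ct = D_t / T * dtp
            cr = D_r / T * dtp
            st = np.sqrt(2.0 * D_t * dtp)
            sr = np.sqrt(2.0 * D_r * dtp)
            maxmove = 0.0
            for i in range(n):
                mv = 0.0
                for a in range(3):
                    disp[i, a] = ct * star_F[i, a] + st * noise[istep, i, a]
                    rot[i, a] = cr * star_T[i, a] + sr * noise[istep, i, 3 + a]
                dmag = np.sqrt(disp[i, 0] ** 2 + disp[i, 1] ** 2 + disp[i, 2] ** 2)
                rmag = np.sqrt(rot[i, 0] ** 2 + rot[i, 1] ** 2 + rot[i, 2] ** 2)
                mv = dmag + lever * rmag
                if mv > maxmove:
                    maxmove = mv
            if maxmove <= disp_cap or h >= max_halvings:
                break
            scale *= 0.5
            h += 1
        if h > 0:
            n_rejected += 1

        for i in range(n):
            for a in range(3):
                c = centers[i, a] + disp[i, a]
                shift = np.floor(c / box_L)
                centers[i, a] = c - shift * box_L
                images[i, a] += np.int64(shift)
            ang = np.sqrt(rot[i, 0] ** 2 + rot[i, 1] ** 2 + rot[i, 2] ** 2)
            if ang > 1e-300:
                ax = rot[i, 0] / ang
                ay = rot[i, 1] / ang
                az = rot[i, 2] / ang
                ch = np.cos(0.5 * ang)
                sh = np.sin(0.5 * ang)
                qw, qx, qy, qz = quats[i, 0], quats[i, 1], quats[i, 2], quats[i, 3]
                nw = ch * qw - sh * (ax * qx + ay * qy + az * qz)
                nx = ch * qx + sh * (ax * qw + ay * qz - az * qy)
                ny = ch * qy + sh * (ay * qw + az * qx - ax * qz)
                nz = ch * qz + sh * (az * qw + ax * qy - ay * qx)
                norm = np.sqrt(nw * nw + nx * nx + ny * ny + nz * nz)
                quats[i, 0] = nw / norm
                quats[i, 1] = nx / norm
                quats[i, 2] = ny / norm
                quats[i, 3] = nz / norm

    return n_samples, n_rejected, n_rebuilds, -1


@njit(cache=True)
def metadynamics_double_well(
    n_steps, dt, barrier, wall_k, wall_x, seed,
    stride, w0, delta, bias_deltaT, T,
    g_centers, g_heights,
):
    """Overdamped 1D metadynamics in U(x) = barrier · (x² − 1)².

    Gaussians of width ``delta`` are deposited every ``stride`` steps; with
    ``bias_deltaT > 0`` heights follow the well-tempered rule.  Harmonic
    walls of stiffness ``wall_k`` act beyond |x| > wall_x.  The bias force is
    evaluated by linear interpolation of dU_G/dx on a dense grid (updated at
    each deposit), so the cost per step is independent of the deposit count.
    Returns the number of deposits (centers/heights written into the
    buffers).
    """
    np.random.seed(seed)
    x = -1.0
    n_g = 0
    inv2d2 = 1.0 / (2.0 * delta * delta)
    lo = -wall_x - 1.0
    hi = wall_x + 1.0
    ng_grid = 2048
    dg = (hi - lo) / (ng_grid - 1)
    ug_grid = np.zeros(ng_grid)       # U_G on the grid
    fg_grid = np.zeros(ng_grid)       # dU_G/dx on the grid
    for step in range(n_steps):
        # forces: double well + walls + interpolated bias
        f = -4.0 * barrier * x * (x * x - 1.0)
        if x > wall_x:
            f -= wall_k * (x - wall_x)
        elif x < -wall_x:
            f -= wall_k * (x + wall_x)
        gx = (x - lo) / dg
        gi = int(gx)
        if gi < 0:
            gi = 0
        elif gi > ng_grid - 2:
            gi = ng_grid - 2
        wfrac = gx - gi
        f -= fg_grid[gi] * (1.0 - wfrac) + fg_grid[gi + 1] * wfrac
        x += f / T * dt + np.sqrt(2.0 * dt) * np.random.normal()
        if (step + 1) % stride == 0:
            gx = (x - lo) / dg
            gi = min(max(int(gx), 0), ng_grid - 2)
            wfrac = gx - gi
            ug = ug_grid[gi] * (1.0 - wfrac) + ug_grid[gi + 1] * wfrac
            h = w0
            if bias_deltaT > 0.0:
                h = w0 * np.exp(-ug / bias_deltaT)
            g_centers[n_g] = x
            g_heights[n_g] = h
            n_g += 1
            for k in range(ng_grid):
                xk = lo + k * dg
                dxk = xk - x
                e = h * np.exp(-dxk * dxk * inv2d2)
                ug_grid[k] += e
                fg_grid[k] += -dxk * 2.0 * inv2d2 * e  # dU_G/dx has sign -(x-c)... stored as dU/dx
            if n_g >= g_centers.shape[0]:
                break
    return n_g
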