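"""Numba-compiled integration kernels.

These kernels implement exactly the same arithmetic as the reference numpy
stepper in ``integrators`` (one shared eight-step leapfrog procedure); the
reference path is the readable specification, this module is the fast path
used for nanosecond-scale runs.  Agreement between the two is covered by
tests.

State arrays are modified in place so that a run can be continued segment by
segment (replica exchange advances replicas this way).  Per-step Gaussian
draws happen in a fixed atom-major, component-minor order; a run is
deterministic under its seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .constants import KB, KCAL_TO_INTERNAL

# mode codes shared with integrators.py
MODE_MD, MODE_LD, MODE_SGMD, MODE_SGLD, MODE_GLE = 0, 1, 2, 3, 4
# potential codes
POT_HARMONIC, POT_SDW, POT_LJ = 0, 1, 2

PP_GUARD = 1e-12
ETA_GUARD = 1e-12


@njit(cache=False)
def _energy_forces(pot_id, pp, box, r, f):
    """Energy (kcal/mol) and forces (kcal/mol/A) into ``f``."""
    n = r.shape[0]
    for i in range(n):
        f[i, 0] = 0.0
        f[i, 1] = 0.0
        f[i, 2] = 0.0
    e = 0.0
    if pot_id == POT_HARMONIC:
        k = pp[0]
        for i in range(n):
            e += 0.5 * k * (r[i, 0] ** 2 + r[i, 1] ** 2 + r[i, 2] ** 2)
            f[i, 0] = -k * r[i, 0]
            f[i, 1] = -k * r[i, 1]
            f[i, 2] = -k * r[i, 2]
    elif pot_id == POT_SDW:
        a, b, c, y0 = pp[0], pp[1], pp[2], pp[3]
        for i in range(n):
            x, y, z = r[i, 0], r[i, 1], r[i, 2]
            e += a * y * y * (y * y - 2.0 * y0 * y0) + b * (y + y0) ** 2 \
                + c * (x * x + z * z)
            f[i, 0] = -2.0 * c * x
            f[i, 1] = -(4.0 * a * y ** 3 - 4.0 * a * y0 * y0 * y
                        + 2.0 * b * (y + y0))
            f[i, 2] = -2.0 * c * z
    else:
        eps, sig, rc = pp[0], pp[1], pp[2]
        rc2 = rc * rc
        sr6c = (sig * sig / rc2) ** 3
        ushift = 4.0 * eps * (sr6c * sr6c - sr6c)
        for i in range(n - 1):
            for j in range(i + 1, n):
                dx = r[i, 0] - r[j, 0]
                dy = r[i, 1] - r[j, 1]
                dz = r[i, 2] - r[j, 2]
                dx -= box * np.floor(dx / box + 0.5)
                dy -= box * np.floor(dy / box + 0.5)
                dz -= box * np.floor(dz / box + 0.5)
                r2 = dx * dx + dy * dy + dz * dz
                if r2 < rc2:
                    sr2 = sig * sig / r2
                    sr6 = sr2 * sr2 * sr2
                    e += 4.0 * eps * (sr6 * sr6 - sr6) - ushift
                    w = 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / r2
                    f[i, 0] += w * dx
                    f[i, 1] += w * dy
                    f[i, 2] += w * dz
                    f[j, 0] -= w * dx
                    f[j, 1] -= w * dy
                    f[j, 2] -= w * dz
    return e


@njit(cache=False)
def run_kernel(
    pot_id,
    pot_params,
    box,
    masses,
    mode,
    dt,
    t_L,
    t_avg,
    lam,
    mu,
    gamma,
    nu,
    temperature,
    n_steps,
    record_every,
    traj_every,
    seed,
    noise,
    eta_enabled,
    r,
    v,
    r_avg,
    r_avg2,
    p_avg_prev,
    f_avg,
    g_avg,
    fp_acc,
    pp_acc,
    R_avg,
    acc8,
    scalars,
):
    """Advance the system ``n_steps`` leapfrog steps in place.

    scalars holds [t, E_avg, E_avg2, E_p_last]; acc8 holds the t_avg-filtered
    numerators/denominators of the four frequency-separated factors.
    Returns (records, traj_positions, traj_velocities, status); status != 0
    flags a non-finite energy (integration aborted at that step).
    """
    n = r.shape[0]
    delta = dt / t_L
    delta_avg = dt / t_avg
    n_rec = n_steps // record_every if record_every > 0 else 0
    n_traj = n_steps // traj_every if traj_every > 0 else 0
    rec = np.zeros((n_rec, 10))
    traj_r = np.zeros((n_traj, n, 3))
    traj_v = np.zeros((n_traj, n, 3))
    irec = 0
    itraj = 0
    status = 0

    if seed >= 0:
        np.random.seed(seed)

    noisy = (mode == MODE_LD or mode == MODE_SGLD or mode == MODE_GLE) and gamma > 0.0
    kT_int = KB * temperature * KCAL_TO_INTERNAL
    sig_r = np.zeros(n)
    for i in range(n):
        sig_r[i] = np.sqrt(2.0 * gamma * masses[i] * kT_int / dt)

    f_kcal = np.zeros((n, 3))
    f_tot = np.zeros((n, 3))
    f_int = np.zeros((n, 3))
    g = np.zeros((n, 3))
    p_lf = np.zeros((n, 3))
    p_full = np.zeros((n, 3))
    F_lf = np.zeros((n, 3))
    F_lf2 = np.zeros((n, 3))
    have_noise = noise.shape[0] > 0
    ndf = 3.0 * n

    t = scalars[0]
    E_avg = scalars[1]
    E_avg2 = scalars[2]

    for step in range(n_steps):
        # (1) energy and forces at r(t)
        E_p = _energy_forces(pot_id, pot_params, box, r, f_kcal)
        if not np.isfinite(E_p):
            status = 1
            break
        for i in range(n):
            for c in range(3):
                f_int[i, c] = f_kcal[i, c] * KCAL_TO_INTERNAL
                f_tot[i, c] = f_int[i, c]
        if noisy:
            for i in range(n):
                for c in range(3):
                    if have_noise:
                        z = noise[step, i, c]
                    else:
                        z = np.random.normal(0.0, 1.0)
                    Ric = sig_r[i] * z
                    if mode == MODE_GLE:
                        # colored noise R - nu*R_avg with the local average
                        # taken over strictly past draws (unbiased placement)
                        f_tot[i, c] += Ric - nu * R_avg[i, c]
                        R_avg[i, c] = (1.0 - delta) * R_avg[i, c] + delta * Ric
                    else:
                        f_tot[i, c] += Ric

        # (2) local averages of energy and position; derived low-freq state
        E_avg = (1.0 - delta) * E_avg + delta * E_p
        E_avg2 = (1.0 - delta) * E_avg2 + delta * E_avg
        for i in range(n):
            for c in range(3):
                r_avg[i, c] = (1.0 - delta) * r_avg[i, c] + delta * r[i, c]
                r_avg2[i, c] = (1.0 - delta) * r_avg2[i, c] + delta * r_avg[i, c]
                plf = (masses[i] / t_L) * (r[i, c] - r_avg[i, c])
                p_lf[i, c] = plf
                p_full[i, c] = p_avg_prev[i, c] + (t_L / dt) * (plf - p_avg_prev[i, c])
                F_lf[i, c] = (p_full[i, c] - plf) / t_L
                F_lf2[i, c] = (masses[i] / t_L ** 2) * (
                    r[i, c] - 2.0 * r_avg[i, c] + r_avg2[i, c]
                )
                p_avg_prev[i, c] = plf

        # (3) apparent friction constants
        for i in range(n):
            fp_i = 0.0
            pp_i = 0.0
            for c in range(3):
                fp_i += (F_lf[i, c] - F_lf2[i, c]) * p_lf[i, c]
                pp_i += p_lf[i, c] * p_lf[i, c]
            fp_acc[i] = (1.0 - delta_avg) * fp_acc[i] + delta_avg * fp_i
            pp_acc[i] = (1.0 - delta_avg) * pp_acc[i] + delta_avg * pp_i

        # (4) guiding force
        if mode == MODE_SGMD or mode == MODE_SGLD:
            for i in range(n):
                xi = -fp_acc[i] / pp_acc[i] if pp_acc[i] > PP_GUARD else 0.0
                for c in range(3):
                    g[i, c] = mu * (F_lf[i, c] - F_lf2[i, c]) + lam * xi * p_lf[i, c]
        elif mode == MODE_GLE:
            for i in range(n):
                for c in range(3):
                    g[i, c] = lam * gamma * p_lf[i, c]
        else:
            for i in range(n):
                for c in range(3):
                    g[i, c] = 0.0

        # (5)-(7) conservation scaling, velocity and position updates
        ke_int = 0.0
        tlf_sum = 0.0
        for i in range(n):
            eta_i = 0.0
            if eta_enabled and (mode == MODE_SGMD or mode == MODE_SGLD):
                gp0 = 0.0
                p0sq = 0.0
                for c in range(3):
                    mv = masses[i] * v[i, c]
                    p0c = mv + (f_tot[i, c] + g[i, c] - gamma * mv) * (dt / 2.0)
                    gp0 += g[i, c] * p0c
                    p0sq += p0c * p0c
                denom = 2.0 * p0sq - gp0 * dt
                if gp0 != 0.0 and np.abs(denom) > ETA_GUARD:
                    eta_i = (2.0 + gamma * dt) * gp0 / denom
            aa = (gamma + eta_i) * dt / 2.0
            plf2 = 0.0
            for c in range(3):
                v_new = ((1.0 - aa) / (1.0 + aa)) * v[i, c] \
                    + (f_tot[i, c] + g[i, c]) * dt / (masses[i] * (1.0 + aa))
                ke_int += 0.25 * masses[i] * (v[i, c] ** 2 + v_new ** 2)
                v[i, c] = v_new
                r[i, c] += v_new * dt
                plf2 += p_lf[i, c] * p_lf[i, c]
            tlf_sum += plf2 / masses[i]
        t += dt

        # frequency-separated factor accumulators (t_avg filtered)
        n_llf = 0.0
        d_llf = 0.0
        n_lhf = 0.0
        d_lhf = 0.0
        n_clf = 0.0
        d_clf = 0.0
        n_chf = 0.0
        d_chf = 0.0
        for i in range(n):
            for c in range(3):
                f_avg[i, c] = (1.0 - delta) * f_avg[i, c] + delta * f_int[i, c]
                g_avg[i, c] = (1.0 - delta) * g_avg[i, c] + delta * g[i, c]
                fa = f_avg[i, c]
                ga = g_avg[i, c]
                pa = p_lf[i, c]
                n_llf += (fa + ga - gamma * pa) * fa
                d_llf += fa * fa
                fh = f_int[i, c] - fa
                gh = g[i, c] - ga
                ph = p_full[i, c] - pa
                n_lhf += (fh + gh - gamma * ph) * fh
                d_lhf += fh * fh
                n_clf += ga * gamma * pa
                d_clf += gamma * gamma * pa * pa
                n_chf += gamma * gh * ph
                d_chf += gamma * gamma * ph * ph
        acc8[0] = (1.0 - delta_avg) * acc8[0] + delta_avg * n_llf
        acc8[1] = (1.0 - delta_avg) * acc8[1] + delta_avg * d_llf
        acc8[2] = (1.0 - delta_avg) * acc8[2] + delta_avg * n_lhf
        acc8[3] = (1.0 - delta_avg) * acc8[3] + delta_avg * d_lhf
        acc8[4] = (1.0 - delta_avg) * acc8[4] + delta_avg * n_clf
        acc8[5] = (1.0 - delta_avg) * acc8[5] + delta_avg * d_clf
        acc8[6] = (1.0 - delta_avg) * acc8[6] + delta_avg * n_chf
        acc8[7] = (1.0 - delta_avg) * acc8[7] + delta_avg * d_chf

        scalars[3] = E_p
        if record_every > 0 and (step + 1) % record_every == 0 and irec < n_rec:
            rec[irec, 0] = t
            rec[irec, 1] = E_p
            rec[irec, 2] = E_avg
            rec[irec, 3] = E_avg2
            rec[irec, 4] = ke_int / KCAL_TO_INTERNAL
            rec[irec, 5] = tlf_sum / (ndf * KB * KCAL_TO_INTERNAL)
            rec[irec, 6] = acc8[0] / acc8[1] if np.abs(acc8[1]) > PP_GUARD else 1.0
            rec[irec, 7] = acc8[2] / acc8[3] if np.abs(acc8[3]) > PP_GUARD else 1.0
            rec[irec, 8] = 1.0 - acc8[4] / acc8[5] if np.abs(acc8[5]) > PP_GUARD else 1.0
            rec[irec, 9] = 1.0 - acc8[6] / acc8[7] if np.abs(acc8[7]) > PP_GUARD else 1.0
            irec += 1
        if traj_every > 0 and (step + 1) % traj_every == 0 and itraj < n_traj:
            for i in range(n):
                for c in range(3):
                    traj_r[itraj, i, c] = r[i, c]
                    traj_v[itraj, i, c] = v[i, c]
            itraj += 1

    scalars[0] = t
    scalars[1] = E_avg
    scalars[2] = E_avg2
    return rec[:irec], traj_r[:itraj], traj_v[:itraj], status
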