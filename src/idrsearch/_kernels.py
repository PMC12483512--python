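"""Numba kernels: Brownian-dynamics search, point-searcher reference walks,
and the Metropolis sampler used as an independent equilibrium oracle.

Everything here works in simulation units: lengths in bp, energies in k_BT,
time in t0 = bp^2/D with D = 1 the diffusion coefficient of one site.
Randomness is controlled by an explicit integer seed per call
(``np.random.seed`` inside the jitted function), so runs are bit-reproducible.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# hard cap on any single pair force (k_BT/bp); overlapping sites closer than
# ~1e-6 bp would otherwise stall the adaptive time step
F_WCA_CAP = 1.0e3


# ---------------------------------------------------------------------------
# inline RNG: xorshift128+ with Marsaglia-polar normals.  numba's built-in
# normal generator costs ~75 ns per draw, which dominates the Langevin step;
# this one is ~6x faster.  State is a length-4 float64-free array:
# state[0:2] uint64 xorshift state, cache[0] flag, cache[1] spare normal.
# ---------------------------------------------------------------------------


@njit(cache=True, inline="always")
def _xs_u01(state):
    s0 = state[0]
    s1 = state[1]
    r = s0 + s1
    x = s0 ^ (s0 << np.uint64(23))
    state[0] = s1
    state[1] = (
        x ^ s1 ^ (x >> np.uint64(17)) ^ (s1 >> np.uint64(26))
    )
    return (r >> np.uint64(11)) * 1.1102230246251565e-16  # 2^-53


@njit(cache=True)
def _rng_init(seed):
    state = np.empty(2, dtype=np.uint64)
    z = np.uint64(seed) + np.uint64(0x9E3779B97F4A7C15)
    for i in range(2):
        z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
        z = z ^ (z >> np.uint64(31))
        state[i] = z | np.uint64(1)
        z = z + np.uint64(0x9E3779B97F4A7C15)
    return state


@njit(cache=True, fastmath=True, inline="always")
def _randn(state, cache):
    if cache[0] > 0.5:
        cache[0] = 0.0
        return cache[1]
    while True:
        u = 2.0 * _xs_u01(state) - 1.0
        v = 2.0 * _xs_u01(state) - 1.0
        s = u * u + v * v
        if 0.0 < s < 1.0:
            break
    fac = np.sqrt(-2.0 * np.log(s) / s)
    cache[0] = 1.0
    cache[1] = v * fac
    return u * fac


@njit(cache=True)
def nearest_target_dist(pos, tgt):
    """Per-site distance to the nearest target."""
    n = pos.shape[0]
    m = tgt.shape[0]
    out = np.empty(n)
    for i in range(n):
        best = 1.0e300
        for j in range(m):
            d0 = pos[i, 0] - tgt[j, 0]
            d1 = pos[i, 1] - tgt[j, 1]
            d2 = pos[i, 2] - tgt[j, 2]
            r2 = d0 * d0 + d1 * d1 + d2 * d2
            if r2 < best:
                best = r2
        out[i] = np.sqrt(best)
    return out


@njit(cache=True)
def min_antenna_dist(pos, half_l):
    """Minimum over sites of the distance to the antenna segment
    {x=y=0, |z| <= L/2}."""
    n = pos.shape[0]
    best = 1.0e300
    for i in range(n):
        dxy2 = pos[i, 0] * pos[i, 0] + pos[i, 1] * pos[i, 1]
        dz = abs(pos[i, 2]) - half_l
        if dz < 0.0:
            dz = 0.0
        d2 = dxy2 + dz * dz
        if d2 < best:
            best = d2
    return np.sqrt(best)


@njit(cache=True)
def chain_forces(pos, l0, e_b, w_d, sigma, tgt, use_wca):
    """Force on every site: harmonic springs (k = 3/l0^2), Gaussian wells of
    depth e_b at every target, and (optionally) capped WCA repulsion between
    all site pairs.  Returns (forces, max_norm, min_target_dist, n_capped)."""
    n = pos.shape[0]
    m = tgt.shape[0]
    f = np.zeros((n, 3))
    k = 3.0 / (l0 * l0)
    for i in range(n - 1):
        for c in range(3):
            dr = pos[i + 1, c] - pos[i, c]
            f[i, c] += k * dr
            f[i + 1, c] -= k * dr
    w2 = w_d * w_d
    cut2 = 81.0 * w2  # beyond 9 w_d the well force is < 1e-17 E_B
    min_td2 = 1.0e300
    for i in range(n):
        for j in range(m):
            d0 = pos[i, 0] - tgt[j, 0]
            d1 = pos[i, 1] - tgt[j, 1]
            d2 = pos[i, 2] - tgt[j, 2]
            r2 = d0 * d0 + d1 * d1 + d2 * d2
            if r2 < min_td2:
                min_td2 = r2
            if r2 < cut2:
                g = e_b * np.exp(-r2 / (2.0 * w2)) / w2
                f[i, 0] -= g * d0
                f[i, 1] -= g * d1
                f[i, 2] -= g * d2
    n_capped = 0
    if use_wca:
        s2ref = sigma * sigma
        for i in range(n):
            for j in range(i + 1, n):
                d0 = pos[i, 0] - pos[j, 0]
                d1 = pos[i, 1] - pos[j, 1]
                d2 = pos[i, 2] - pos[j, 2]
                r2 = d0 * d0 + d1 * d1 + d2 * d2
                if r2 < s2ref and r2 > 0.0:
                    s2 = s2ref / r2
                    s6 = s2 * s2 * s2
                    coef = 12.0 * (s6 * s6 - s6) / r2
                    fmag2 = coef * coef * r2
                    if fmag2 > F_WCA_CAP * F_WCA_CAP:
                        coef = F_WCA_CAP / np.sqrt(r2)
                        n_capped += 1
                    f[i, 0] += coef * d0
                    f[i, 1] += coef * d1
                    f[i, 2] += coef * d2
                    f[j, 0] -= coef * d0
                    f[j, 1] -= coef * d1
                    f[j, 2] -= coef * d2
    fmax = 0.0
    for i in range(n):
        fn = np.sqrt(f[i, 0] ** 2 + f[i, 1] ** 2 + f[i, 2] ** 2)
        if fn > fmax:
            fmax = fn
    return f, fmax, np.sqrt(min_td2), n_capped


@njit(cache=True)
def _reflect_sphere(pos, R):
    """Mirror a site back inside the reflecting sphere of radius R."""
    n = pos.shape[0]
    for i in range(n):
        r = np.sqrt(pos[i, 0] ** 2 + pos[i, 1] ** 2 + pos[i, 2] ** 2)
        if r > R:
            scale = (2.0 * R - r) / r
            if scale < 0.0:  # pathological overshoot; clamp to the centre side
                scale = 0.0
            pos[i, 0] *= scale
            pos[i, 1] *= scale
            pos[i, 2] *= scale
    return pos


@njit(cache=True, fastmath=True)
def _site_forces_z(pos, tz, d, l0, e_b, w_d, sigma, use_wca, f):
    """Forces for an equal-spaced antenna along z (targets at x=y=0,
    z in the sorted array tz with spacing d).  Wells are summed over an
    index window (contributions beyond 9 w_d are < 1e-17 E_B).
    Returns (fmax, min_target_dist2, n_capped)."""
    n = pos.shape[0]
    m = tz.shape[0]
    z0 = tz[0]
    k = 3.0 / (l0 * l0)
    for i in range(n):
        for c in range(3):
            f[i, c] = 0.0
    for i in range(n - 1):
        for c in range(3):
            dr = pos[i + 1, c] - pos[i, c]
            f[i, c] += k * dr
            f[i + 1, c] -= k * dr
    w2 = w_d * w_d
    wcut = 9.0 * w_d
    cut2 = wcut * wcut
    min_td2 = 1.0e300
    for i in range(n):
        dxy2 = pos[i, 0] * pos[i, 0] + pos[i, 1] * pos[i, 1]
        zi = pos[i, 2]
        jc = int(np.floor((zi - z0) / d + 0.5))
        if jc < 0:
            jc = 0
        if jc > m - 1:
            jc = m - 1
        dzc = zi - tz[jc]
        td2 = dxy2 + dzc * dzc
        if td2 < min_td2:
            min_td2 = td2
        if dxy2 < cut2:
            jw = int(wcut / d) + 1
            jlo = jc - jw
            if jlo < 0:
                jlo = 0
            jhi = jc + jw
            if jhi > m - 1:
                jhi = m - 1
            for j in range(jlo, jhi + 1):
                dz = zi - tz[j]
                r2 = dxy2 + dz * dz
                if r2 < cut2:
                    g = e_b * np.exp(-r2 / (2.0 * w2)) / w2
                    f[i, 0] -= g * pos[i, 0]
                    f[i, 1] -= g * pos[i, 1]
                    f[i, 2] -= g * dz
    n_capped = 0
    if use_wca:
        s2ref = sigma * sigma
        for i in range(n):
            for j in range(i + 1, n):
                d0 = pos[i, 0] - pos[j, 0]
                d1 = pos[i, 1] - pos[j, 1]
                d2 = pos[i, 2] - pos[j, 2]
                r2 = d0 * d0 + d1 * d1 + d2 * d2
                if r2 < s2ref and r2 > 0.0:
                    s2 = s2ref / r2
                    s6 = s2 * s2 * s2
                    coef = 12.0 * (s6 * s6 - s6) / r2
                    if coef * coef * r2 > F_WCA_CAP * F_WCA_CAP:
                        coef = F_WCA_CAP / np.sqrt(r2)
                        n_capped += 1
                    f[i, 0] += coef * d0
                    f[i, 1] += coef * d1
                    f[i, 2] += coef * d2
                    f[j, 0] -= coef * d0
                    f[j, 1] -= coef * d1
                    f[j, 2] -= coef * d2
    fmax2 = 0.0
    for i in range(n):
        fn2 = f[i, 0] ** 2 + f[i, 1] ** 2 + f[i, 2] ** 2
        if fn2 > fmax2:
            fmax2 = fn2
    return np.sqrt(fmax2), min_td2, n_capped


@njit(cache=True)
def _nearest_tz_dist(pos, tz, d):
    """Per-site distance to the nearest on-axis target."""
    n = pos.shape[0]
    m = tz.shape[0]
    z0 = tz[0]
    out = np.empty(n)
    for i in range(n):
        dxy2 = pos[i, 0] * pos[i, 0] + pos[i, 1] * pos[i, 1]
        jc = int(np.floor((pos[i, 2] - z0) / d + 0.5))
        if jc < 0:
            jc = 0
        if jc > m - 1:
            jc = m - 1
        dz = pos[i, 2] - tz[jc]
        out[i] = np.sqrt(dxy2 + dz * dz)
    return out


@njit(cache=True, fastmath=True)
def search_kernel(
    pos,
    tz,
    d,
    R,
    a,
    L,
    l0,
    e_b,
    w_d,
    sigma,
    far_th,
    dt0,
    max_time,
    tau_relax,
    sample_dt,
    max_samples,
    seed,
    absorb,
    use_wca,
):
    """One first-passage search of the chain for the central DBD target.

    The DBD site is chain index 0; ``tz`` holds the sorted z coordinates of
    all targets (DBD target at 0).  Near the antenna (closest site within
    ``far_th``) full per-site Euler-Maruyama updates run with the adaptive
    time step ``dt = dt0 * min(1, 1/max|f|)``; far away the TF translates
    as a rigid body with diffusion coefficient 1/n_sites and a time step
    sized so the rms displacement is ``far_th/5``.  Reflecting sphere of
    radius R; absorbing DBD target of radius ``a`` at the origin (if
    ``absorb``).

    Returns (t_total, t_first_attach, n_rounds, time_attached, terminated,
    n_samples, samp_sitedist, samp_comz, samp_attached, n_capped_total).
    terminated: 0 = absorbed, 1 = hit max_time.
    """
    state = _rng_init(seed)
    cache = np.zeros(2)
    n = pos.shape[0]
    half_l = 0.5 * L
    d_com = 1.0 / n
    dt_far = (far_th / 5.0) ** 2 / (6.0 * d_com)
    sig_far = np.sqrt(2.0 * d_com * dt_far)

    t = 0.0
    first_attach = -1.0
    n_rounds = 0
    time_attached = 0.0
    attached = False
    t_all_far = 0.0
    terminated = 1
    n_capped_total = 0

    do_sample = sample_dt > 0.0 and max_samples > 0
    samp_sitedist = np.zeros((max_samples if do_sample else 1,
                              n if do_sample else 1), dtype=np.float32)
    samp_comz = np.zeros(max_samples if do_sample else 1, dtype=np.float32)
    samp_att = np.zeros(max_samples if do_sample else 1, dtype=np.uint8)
    n_samples = 0
    next_sample = 0.0

    attach_r2 = 4.0 * w_d * w_d
    f = np.zeros((n, 3))

    while t < max_time:
        if do_sample and t >= next_sample and n_samples < max_samples:
            td = _nearest_tz_dist(pos, tz, d)
            zsum = 0.0
            for i in range(n):
                samp_sitedist[n_samples, i] = td[i]
                zsum += pos[i, 2]
            samp_comz[n_samples] = zsum / n
            samp_att[n_samples] = 1 if attached else 0
            n_samples += 1
            next_sample += sample_dt

        dmin = min_antenna_dist(pos, half_l)
        if dmin >= far_th:
            # rigid-body far-field move
            com0 = 0.0
            com1 = 0.0
            com2 = 0.0
            for i in range(n):
                com0 += pos[i, 0]
                com1 += pos[i, 1]
                com2 += pos[i, 2]
            com0 /= n
            com1 /= n
            com2 /= n
            r_ext = 0.0
            for i in range(n):
                e0 = pos[i, 0] - com0
                e1 = pos[i, 1] - com1
                e2 = pos[i, 2] - com2
                rr = e0 * e0 + e1 * e1 + e2 * e2
                if rr > r_ext:
                    r_ext = rr
            r_ext = np.sqrt(r_ext)
            r_eff = R - r_ext
            if r_eff < far_th:
                r_eff = far_th
            nx = com0 + sig_far * _randn(state, cache)
            ny = com1 + sig_far * _randn(state, cache)
            nz = com2 + sig_far * _randn(state, cache)
            rn = np.sqrt(nx * nx + ny * ny + nz * nz)
            if rn > r_eff:
                scale = (2.0 * r_eff - rn) / rn
                if scale < 0.0:
                    scale = 0.0
                nx *= scale
                ny *= scale
                nz *= scale
            dx = nx - com0
            dy = ny - com1
            dz = nz - com2
            for i in range(n):
                pos[i, 0] += dx
                pos[i, 1] += dy
                pos[i, 2] += dz
            t += dt_far
            if attached:
                t_all_far += dt_far
                time_attached += dt_far
                if t_all_far > tau_relax:
                    attached = False
                    time_attached -= t_all_far  # excursion was a detachment
                    t_all_far = 0.0
        else:
            fmax, min_td2, n_capped = _site_forces_z(
                pos, tz, d, l0, e_b, w_d, sigma, use_wca, f
            )
            n_capped_total += n_capped
            dt = dt0
            if fmax > 1.0:
                dt = dt0 / fmax
            amp = np.sqrt(2.0 * dt)
            for i in range(n):
                pos[i, 0] += f[i, 0] * dt + amp * _randn(state, cache)
                pos[i, 1] += f[i, 1] * dt + amp * _randn(state, cache)
                pos[i, 2] += f[i, 2] * dt + amp * _randn(state, cache)
            _reflect_sphere(pos, R)
            t += dt
            if min_td2 < attach_r2:
                if not attached:
                    attached = True
                    n_rounds += 1
                    if first_attach < 0.0:
                        first_attach = t
                t_all_far = 0.0
                time_attached += dt
            elif attached:
                time_attached += dt
                dmin2 = min_antenna_dist(pos, half_l)
                if dmin2 >= far_th:
                    t_all_far += dt
                    if t_all_far > tau_relax:
                        attached = False
                        time_attached -= t_all_far
                        t_all_far = 0.0
                else:
                    t_all_far = 0.0
            if absorb:
                r2_dbd = (
                    pos[0, 0] ** 2 + pos[0, 1] ** 2 + pos[0, 2] ** 2
                )
                if r2_dbd < a * a:
                    terminated = 0
                    break

    return (
        t,
        first_attach,
        n_rounds,
        time_attached,
        terminated,
        n_samples,
        samp_sitedist,
        samp_comz,
        samp_att,
        n_capped_total,
    )


@njit(cache=True, fastmath=True)
def point_mfpt_kernel(R, mode, a, L, rc, step_frac, n_runs, max_time, seed):
    """First-passage times of a single diffusing point to a central absorber.

    mode 0: absorbing sphere of radius ``a`` at the centre.
    mode 1: absorbing cylinder (radius ``rc``, length ``L`` along z).
    Distance-adaptive stepping: rms step = clip(step_frac * distance,
    floor, R/6), with floor = 0.25 * (a or rc).  Uniform start in the sphere.
    """
    state = _rng_init(seed)
    cache = np.zeros(2)
    times = np.empty(n_runs)
    floor = 0.25 * (a if mode == 0 else rc)
    cap = R / 6.0
    half_l = 0.5 * L
    for run in range(n_runs):
        # uniform start in the sphere, outside the absorber
        while True:
            x = (2.0 * _xs_u01(state) - 1.0) * R
            y = (2.0 * _xs_u01(state) - 1.0) * R
            z = (2.0 * _xs_u01(state) - 1.0) * R
            if x * x + y * y + z * z > R * R:
                continue
            if mode == 0:
                if x * x + y * y + z * z > a * a:
                    break
            else:
                dxy = np.sqrt(x * x + y * y)
                dz = abs(z) - half_l
                if dz < 0.0:
                    dz = 0.0
                inside = dxy <= rc and dz <= 0.0
                if not inside:
                    break
        t = 0.0
        while t < max_time:
            if mode == 0:
                dist = np.sqrt(x * x + y * y + z * z) - a
            else:
                dxy = np.sqrt(x * x + y * y) - rc
                if dxy < 0.0:
                    dxy = 0.0
                dz = abs(z) - half_l
                if dz < 0.0:
                    dz = 0.0
                dist = np.sqrt(dxy * dxy + dz * dz)
            if dist <= 0.0:
                break
            srms = step_frac * dist
            if srms < floor:
                srms = floor
            if srms > cap:
                srms = cap
            dt = srms * srms / 6.0
            amp = np.sqrt(2.0 * dt)
            x += amp * _randn(state, cache)
            y += amp * _randn(state, cache)
            z += amp * _randn(state, cache)
            r = np.sqrt(x * x + y * y + z * z)
            if r > R:
                scale = (2.0 * R - r) / r
                if scale < 0.0:
                    scale = 0.0
                x *= scale
                y *= scale
                z *= scale
            t += dt
            if mode == 0:
                if x * x + y * y + z * z < a * a:
                    break
            else:
                dxy = np.sqrt(x * x + y * y)
                dz = abs(z)
                if dxy <= rc and dz <= half_l:
                    break
        times[run] = t
    return times


@njit(cache=True)
def metropolis_kernel(
    n_b,
    l0,
    e_b,
    e_dbd,
    r1,
    box,
    tgt,
    n_sweeps,
    n_burn,
    seed,
    n_batches,
):
    """Metropolis sampling of the continuous bead-spring TF in a periodic box.

    Sites: index 0 is the DBD, 1..n_b the IDR.  Hamiltonian: harmonic bonds
    with stiffness 3/l0^2 plus square wells of radius ``r1``: the DBD target
    (row 0 of ``tgt``) binds only the DBD site at depth ``e_dbd``; every IDR
    target binds at most one IDR site at depth ``e_b`` (a target inside
    which at least one IDR site sits contributes -e_b once, matching the
    injective configuration counting).  Moves: single-site Gaussian
    displacements, whole-chain teleports (uniform in the box) and
    whole-chain local shifts; all symmetric, plain Metropolis.

    Returns (occupancy fractions per sector [free, idr_only, tf],
    per-batch P_TF means, acceptance fraction).
    """
    np.random.seed(seed)
    n = n_b + 1
    m = tgt.shape[0]  # includes DBD target as row 0
    pos = np.empty((n, 3))
    for c in range(3):
        pos[0, c] = box * np.random.random()
    sb = l0 / np.sqrt(3.0)
    for i in range(1, n):
        for c in range(3):
            pos[i, c] = pos[i - 1, c] + sb * np.random.standard_normal()

    k = 3.0 / (l0 * l0)
    r1sq = r1 * r1

    def _energy(p):
        u = 0.0
        for i in range(n - 1):
            for c in range(3):
                dr = p[i + 1, c] - p[i, c]
                u += 0.5 * k * dr * dr
        # DBD well
        d0 = p[0, 0] - tgt[0, 0]
        d0 -= box * np.floor(d0 / box + 0.5)
        d1 = p[0, 1] - tgt[0, 1]
        d1 -= box * np.floor(d1 / box + 0.5)
        d2 = p[0, 2] - tgt[0, 2]
        d2 -= box * np.floor(d2 / box + 0.5)
        dbd_in = d0 * d0 + d1 * d1 + d2 * d2 < r1sq
        if dbd_in:
            u -= e_dbd
        # saturating IDR wells
        for j in range(1, m):
            occ = False
            for i in range(1, n):
                d0 = p[i, 0] - tgt[j, 0]
                d0 -= box * np.floor(d0 / box + 0.5)
                d1 = p[i, 1] - tgt[j, 1]
                d1 -= box * np.floor(d1 / box + 0.5)
                d2 = p[i, 2] - tgt[j, 2]
                d2 -= box * np.floor(d2 / box + 0.5)
                if d0 * d0 + d1 * d1 + d2 * d2 < r1sq:
                    occ = True
                    break
            if occ:
                u -= e_b
        return u

    def _sector(p):
        # 0 free, 1 idr-only, 2 dbd-bound (TF)
        d0 = p[0, 0] - tgt[0, 0]
        d0 -= box * np.floor(d0 / box + 0.5)
        d1 = p[0, 1] - tgt[0, 1]
        d1 -= box * np.floor(d1 / box + 0.5)
        d2 = p[0, 2] - tgt[0, 2]
        d2 -= box * np.floor(d2 / box + 0.5)
        if d0 * d0 + d1 * d1 + d2 * d2 < r1sq:
            return 2
        for j in range(1, m):
            for i in range(1, n):
                d0 = p[i, 0] - tgt[j, 0]
                d0 -= box * np.floor(d0 / box + 0.5)
                d1 = p[i, 1] - tgt[j, 1]
                d1 -= box * np.floor(d1 / box + 0.5)
                d2 = p[i, 2] - tgt[j, 2]
                d2 -= box * np.floor(d2 / box + 0.5)
                if d0 * d0 + d1 * d1 + d2 * d2 < r1sq:
                    return 1
        return 0

    u = _energy(pos)
    trial = np.empty((n, 3))
    sig_loc = 0.5 * l0
    accepted = 0
    attempted = 0
    counts = np.zeros(3)
    batch_tf = np.zeros(n_batches)
    batch_n = np.zeros(n_batches)
    sweep_per_batch = max(n_sweeps // n_batches, 1)

    for sweep in range(n_burn + n_sweeps):
        # local single-site moves
        for i in range(n):
            for ii in range(n):
                for c in range(3):
                    trial[ii, c] = pos[ii, c]
            for c in range(3):
                trial[i, c] = pos[i, c] + sig_loc * np.random.standard_normal()
            u_new = _energy(trial)
            attempted += 1
            if u_new <= u or np.random.random() < np.exp(u - u_new):
                for c in range(3):
                    pos[i, c] = trial[i, c]
                u = u_new
                accepted += 1
        # whole-chain teleport
        for c in range(3):
            shift = box * np.random.random() - pos[0, c]
            for i in range(n):
                trial[i, c] = pos[i, c] + shift
        u_new = _energy(trial)
        attempted += 1
        if u_new <= u or np.random.random() < np.exp(u - u_new):
            for i in range(n):
                for c in range(3):
                    pos[i, c] = trial[i, c]
            u = u_new
            accepted += 1
        # whole-chain local shift
        for c in range(3):
            shift = l0 * np.random.standard_normal()
            for i in range(n):
                trial[i, c] = pos[i, c] + shift
        u_new = _energy(trial)
        attempted += 1
        if u_new <= u or np.random.random() < np.exp(u - u_new):
            for i in range(n):
                for c in range(3):
                    pos[i, c] = trial[i, c]
            u = u_new
            accepted += 1

        if sweep >= n_burn:
            s = _sector(pos)
            counts[s] += 1.0
            b = (sweep - n_burn) // sweep_per_batch
            if b >= n_batches:
                b = n_batches - 1
            batch_tf[b] += 1.0 if s == 2 else 0.0
            batch_n[b] += 1.0

    fracs = counts / counts.sum()
    for b in range(n_batches):
        if batch_n[b] > 0:
            batch_tf[b] /= batch_n[b]
    return fracs, batch_tf, accepted / attempted
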