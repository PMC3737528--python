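"""Numba kernels for closure-preserving Monte Carlo of circular chains.

The ring is represented by its ordered unit segment tangents ``u[0..n-1]``;
vertex ``v`` sits between segments ``v-1`` and ``v``, and joint ``k`` (the
bend angle ``theta_k``) lives at vertex ``k`` between segments ``k-1`` and
``k`` (cyclic).  A crankshaft move rotates the block of segments
``u[v1..v2-1]`` rigidly about the axis through vertices ``v1`` and ``v2``
(the chord), which changes only the two boundary joints and preserves ring
closure exactly: the block's tangent sum is parallel to the rotation axis.

Joint potentials are passed as per-joint parameter arrays with family codes
0 = quadratic, 1 = linear (the ``g`` slot holds alpha), 2 = kinkable/nick
(plateau ``h`` up to ``tc`` with a harmonic wall beyond, taken as the
minimum against the harmonic stack branch).
"""

import math

import numpy as np
from numba import njit


@njit(cache=True, inline="always")
def _joint_energy(fam, g, h, tc, gw, theta):
    if fam == 1:
        return g * theta
    e = 0.5 * g * theta * theta
    if fam == 2:
        ex = theta - tc
        if ex < 0.0:
            ex = 0.0
        ek = h + 0.5 * gw * ex * ex
        if ek < e:
            e = ek
    return e


@njit(cache=True, inline="always")
def _is_kinked(fam, g, h, tc, gw, theta):
    if fam != 2:
        return False
    ex = theta - tc
    if ex < 0.0:
        ex = 0.0
    return h + 0.5 * gw * ex * ex < 0.5 * g * theta * theta


@njit(cache=True)
def grow_chain_ends_trig(ct, st, cp, sp):
    """Grow linear chains from precomputed joint trig values.

    ``ct, st, cp, sp`` have shape (n_samples, m): cos/sin of the joint
    bend angles and azimuths, drawn outside (vectorised numpy is faster
    at RNG + trig than per-scalar libm calls).  Chains start along +z;
    returns end displacements (excluding the initial segment, in segment
    units) and end tangents.
    """
    n_samples, m = ct.shape
    x_out = np.empty((n_samples, 3))
    w_out = np.empty((n_samples, 3))
    for s in range(n_samples):
        tx = 0.0
        ty = 0.0
        tz = 1.0
        xx = 0.0
        xy = 0.0
        xz = 0.0
        for k in range(m):
            if abs(tx) < 0.9:
                e1x = 0.0
                e1y = tz
                e1z = -ty
            else:
                e1x = -tz
                e1y = 0.0
                e1z = tx
            norm = math.sqrt(e1x * e1x + e1y * e1y + e1z * e1z)
            e1x /= norm
            e1y /= norm
            e1z /= norm
            e2x = ty * e1z - tz * e1y
            e2y = tz * e1x - tx * e1z
            e2z = tx * e1y - ty * e1x
            a = ct[s, k]
            b = st[s, k]
            c = cp[s, k]
            d = sp[s, k]
            tx = tx * a + (e1x * c + e2x * d) * b
            ty = ty * a + (e1y * c + e2y * d) * b
            tz = tz * a + (e1z * c + e2z * d) * b
            nrm = math.sqrt(tx * tx + ty * ty + tz * tz)
            tx /= nrm
            ty /= nrm
            tz /= nrm
            xx += tx
            xy += ty
            xz += tz
        x_out[s, 0] = xx
        x_out[s, 1] = xy
        x_out[s, 2] = xz
        w_out[s, 0] = tx
        w_out[s, 1] = ty
        w_out[s, 2] = tz
    return x_out, w_out


@njit(cache=True)
def grow_chain_ends(cdf_theta, cdf_tables, joint_table, n_samples, seed):
    """Grow linear chains joint by joint; return end displacements and tangents.

    Chains start along +z.  ``cdf_tables`` holds one tabulated joint-angle
    CDF per distinct potential (rows), evaluated on the common grid
    ``cdf_theta``; ``joint_table[k]`` selects the row for joint k.  The
    displacement excludes the initial segment and is in segment-length
    units.  Inverse-CDF lookup by binary search; azimuths uniform.
    """
    np.random.seed(seed)
    m = joint_table.shape[0]
    ng = cdf_theta.shape[0]
    x_out = np.empty((n_samples, 3))
    w_out = np.empty((n_samples, 3))
    for s in range(n_samples):
        tx = 0.0
        ty = 0.0
        tz = 1.0
        xx = 0.0
        xy = 0.0
        xz = 0.0
        for k in range(m):
            row = joint_table[k]
            u = np.random.random()
            lo = 0
            hi = ng - 1
            while hi - lo > 1:
                mid = (lo + hi) // 2
                if cdf_tables[row, mid] < u:
                    lo = mid
                else:
                    hi = mid
            c0 = cdf_tables[row, lo]
            c1 = cdf_tables[row, hi]
            frac = (u - c0) / (c1 - c0) if c1 > c0 else 0.0
            theta = cdf_theta[lo] + frac * (cdf_theta[hi] - cdf_theta[lo])
            phi = 2.0 * math.pi * np.random.random()

            # orthonormal frame perpendicular to t
            if abs(tx) < 0.9:
                e1x = 0.0
                e1y = tz
                e1z = -ty
            else:
                e1x = -tz
                e1y = 0.0
                e1z = tx
            norm = math.sqrt(e1x * e1x + e1y * e1y + e1z * e1z)
            e1x /= norm
            e1y /= norm
            e1z /= norm
            e2x = ty * e1z - tz * e1y
            e2y = tz * e1x - tx * e1z
            e2z = tx * e1y - ty * e1x
            st = math.sin(theta)
            ct = math.cos(theta)
            cp = math.cos(phi)
            sp = math.sin(phi)
            tx = tx * ct + (e1x * cp + e2x * sp) * st
            ty = ty * ct + (e1y * cp + e2y * sp) * st
            tz = tz * ct + (e1z * cp + e2z * sp) * st
            nrm = math.sqrt(tx * tx + ty * ty + tz * tz)
            tx /= nrm
            ty /= nrm
            tz /= nrm
            xx += tx
            xy += ty
            xz += tz
        x_out[s, 0] = xx
        x_out[s, 1] = xy
        x_out[s, 2] = xz
        w_out[s, 0] = tx
        w_out[s, 1] = ty
        w_out[s, 2] = tz
    return x_out, w_out


@njit(cache=True, inline="always")
def _angle(ux, uy, uz, vx, vy, vz):
    c = ux * vx + uy * vy + uz * vz
    if c > 1.0:
        c = 1.0
    elif c < -1.0:
        c = -1.0
    return math.acos(c)


@njit(cache=True)
def _theta_at(u, k):
    n = u.shape[0]
    i = (k - 1) % n
    return _angle(u[i, 0], u[i, 1], u[i, 2], u[k, 0], u[k, 1], u[k, 2])


@njit(cache=True)
def _repair(u):
    """Renormalise tangents and squeeze out floating-point closure drift."""
    n = u.shape[0]
    for _ in range(3):
        sx = 0.0
        sy = 0.0
        sz = 0.0
        for i in range(n):
            norm = math.sqrt(u[i, 0] ** 2 + u[i, 1] ** 2 + u[i, 2] ** 2)
            u[i, 0] /= norm
            u[i, 1] /= norm
            u[i, 2] /= norm
            sx += u[i, 0]
            sy += u[i, 1]
            sz += u[i, 2]
        for i in range(n):
            u[i, 0] -= sx / n
            u[i, 1] -= sy / n
            u[i, 2] -= sz / n


@njit(cache=True)
def _total_energy(u, fam, g, h, tc, gw):
    n = u.shape[0]
    e = 0.0
    for k in range(n):
        e += _joint_energy(fam[k], g[k], h[k], tc[k], gw[k], _theta_at(u, k))
    return e


@njit(cache=True)
def _count_kinks(u, fam, g, h, tc, gw):
    n = u.shape[0]
    c = 0
    for k in range(n):
        if _is_kinked(fam[k], g[k], h[k], tc[k], gw[k], _theta_at(u, k)):
            c += 1
    return c


@njit(cache=True)
def _sweep(u, fam, g, h, tc, gw, nu, delta, wild_frac, target_joint, target_frac, stats):
    """One sweep (n attempted crankshaft moves) on a single replica.

    ``stats`` accumulates (tuned attempts, tuned accepts, attempts, accepts).
    """
    n = u.shape[0]
    for _ in range(n):
        # --- pick pivot vertices v1, v2 with block length in [2, n-2]
        if target_joint >= 0 and np.random.random() < target_frac:
            v1 = target_joint
        else:
            v1 = np.random.randint(n)
        m = 2 + np.random.randint(n - 3)
        if m > n // 2:
            v1 = (v1 + m) % n
            m = n - m
        v2 = (v1 + m) % n

        wild = np.random.random() < wild_frac
        if wild:
            phi = (2.0 * np.random.random() - 1.0) * math.pi
        else:
            phi = (2.0 * np.random.random() - 1.0) * delta
            stats[0] += 1
        stats[2] += 1

        # --- axis = chord between the pivots = sum of block tangents
        ax = 0.0
        ay = 0.0
        az = 0.0
        for t in range(m):
            i = (v1 + t) % n
            ax += u[i, 0]
            ay += u[i, 1]
            az += u[i, 2]
        norm = math.sqrt(ax * ax + ay * ay + az * az)
        if norm < 1e-12:
            continue
        ax /= norm
        ay /= norm
        az /= norm

        # --- energy of the two boundary joints before the move
        e_old = _joint_energy(fam[v1], g[v1], h[v1], tc[v1], gw[v1], _theta_at(u, v1))
        e_old += _joint_energy(fam[v2], g[v2], h[v2], tc[v2], gw[v2], _theta_at(u, v2))

        cphi = math.cos(phi)
        sphi = math.sin(phi)
        # Rodrigues rotation of the block tangents about (ax, ay, az)
        for t in range(m):
            i = (v1 + t) % n
            px, py, pz = u[i, 0], u[i, 1], u[i, 2]
            dot = ax * px + ay * py + az * pz
            cx = ay * pz - az * py
            cy = az * px - ax * pz
            cz = ax * py - ay * px
            nu[t, 0] = px * cphi + cx * sphi + ax * dot * (1.0 - cphi)
            nu[t, 1] = py * cphi + cy * sphi + ay * dot * (1.0 - cphi)
            nu[t, 2] = pz * cphi + cz * sphi + az * dot * (1.0 - cphi)

        ib = (v1 - 1) % n
        ia = (v2 - 1 - v1) % n  # block-local index of segment v2-1
        th1 = _angle(u[ib, 0], u[ib, 1], u[ib, 2], nu[0, 0], nu[0, 1], nu[0, 2])
        th2 = _angle(nu[ia, 0], nu[ia, 1], nu[ia, 2], u[v2, 0], u[v2, 1], u[v2, 2])
        e_new = _joint_energy(fam[v1], g[v1], h[v1], tc[v1], gw[v1], th1)
        e_new += _joint_energy(fam[v2], g[v2], h[v2], tc[v2], gw[v2], th2)

        de = e_new - e_old
        if de <= 0.0 or np.random.random() < math.exp(-de):
            for t in range(m):
                i = (v1 + t) % n
                u[i, 0] = nu[t, 0]
                u[i, 1] = nu[t, 1]
                u[i, 2] = nu[t, 2]
            stats[3] += 1
            if not wild:
                stats[1] += 1


@njit(cache=True)
def run_crankshaft(
    us,
    fam,
    g,
    hs,
    tc,
    gw,
    n_sweeps,
    burn_sweeps,
    thin,
    delta0,
    wild_frac,
    target_joint,
    target_frac,
    monitor_joint,
    h_alt,
    record_replica,
    seed,
):
    """Metropolis crankshaft MC, optionally with replica exchange on the kink energy.

    ``us`` has shape (K, n, 3): K replicas, each a closed ring of tangents
    (modified in place).  ``hs`` has shape (K, n): per-replica kink-energy
    arrays; replica 0 is the target ensemble whose observables are
    recorded.  Kink formation crosses an energy barrier of order h at the
    branch crossover, so for h of 8-16 kT single-chain crankshaft dynamics
    toggles branches too rarely; neighbouring replicas with cheaper kinks
    exchange conformations (standard Hamiltonian replica swap, accepted
    with exp(-[E_i(x_j) + E_j(x_i) - E_i(x_i) - E_j(x_j)])) and carry
    branch flips into the target ensemble.  With K = 1 this reduces to
    plain single-chain MC.

    One sweep = n attempted moves per replica + one swap attempt per
    neighbour pair (alternating parity).  Rotation angles mix a tuned
    [-delta, delta] proposal with wild [-pi, pi] proposals.  Returns
    per-retained-sweep arrays (energy, n_kinks, monitor joint angle,
    monitor kinked flag) for replica 0, the acceptance rate, the tuned
    delta, and the count of accepted swaps involving replica 0.
    """
    np.random.seed(seed)
    K = us.shape[0]
    n = us.shape[1]
    n_keep = n_sweeps // thin
    e_out = np.empty(n_keep)
    ea_out = np.empty(n_keep)
    k_out = np.empty(n_keep, dtype=np.int64)
    th_out = np.empty(n_keep)
    kf_out = np.empty(n_keep, dtype=np.bool_)

    deltas = np.full(K, delta0)
    stats = np.zeros((K, 4), dtype=np.int64)  # tun_att, tun_acc, att, acc
    kept = 0
    swaps0 = 0
    nu = np.empty((n, 3))
    tmp = np.empty((n, 3))

    for sweep in range(burn_sweeps + n_sweeps):
        for r in range(K):
            _sweep(
                us[r],
                fam,
                g,
                hs[r],
                tc,
                gw,
                nu,
                deltas[r],
                wild_frac,
                target_joint,
                target_frac,
                stats[r],
            )

        # --- replica swaps (alternating parity)
        if K > 1:
            for r in range(sweep % 2, K - 1, 2):
                de = 0.0
                for k in range(n):
                    if fam[k] == 2:
                        t_r = _theta_at(us[r], k)
                        t_s = _theta_at(us[r + 1], k)
                        de += _joint_energy(fam[k], g[k], hs[r, k], tc[k], gw[k], t_s)
                        de += _joint_energy(fam[k], g[k], hs[r + 1, k], tc[k], gw[k], t_r)
                        de -= _joint_energy(fam[k], g[k], hs[r, k], tc[k], gw[k], t_r)
                        de -= _joint_energy(fam[k], g[k], hs[r + 1, k], tc[k], gw[k], t_s)
                if de <= 0.0 or np.random.random() < math.exp(-de):
                    tmp[:, :] = us[r]
                    us[r] = us[r + 1]
                    us[r + 1] = tmp
                    if (r == record_replica or r + 1 == record_replica) and sweep >= burn_sweeps:
                        swaps0 += 1

        # --- burn-in tuning and periodic repair
        if sweep < burn_sweeps:
            for r in range(K):
                if stats[r, 0] >= 500:
                    rate = stats[r, 1] / stats[r, 0]
                    if rate < 0.30:
                        deltas[r] *= 0.8
                    elif rate > 0.50:
                        deltas[r] = min(deltas[r] * 1.25, math.pi)
                    stats[r, 0] = 0
                    stats[r, 1] = 0
        if (sweep + 1) % 200 == 0:
            for r in range(K):
                _repair(us[r])

        if sweep >= burn_sweeps:
            s = sweep - burn_sweeps
            if (s + 1) % thin == 0 and kept < n_keep:
                rr = record_replica
                e_out[kept] = _total_energy(us[rr], fam, g, hs[rr], tc, gw)
                ea_out[kept] = _total_energy(us[rr], fam, g, h_alt, tc, gw)
                k_out[kept] = _count_kinks(us[rr], fam, g, hs[rr], tc, gw)
                mth = _theta_at(us[rr], monitor_joint)
                th_out[kept] = mth
                kf_out[kept] = _is_kinked(
                    fam[monitor_joint],
                    g[monitor_joint],
                    hs[rr, monitor_joint],
                    tc[monitor_joint],
                    gw[monitor_joint],
                    mth,
                )
                kept += 1

    for r in range(K):
        _repair(us[r])
    acc_rate = stats[record_replica, 3] / stats[record_replica, 2] if stats[record_replica, 2] > 0 else 0.0
    return (
        e_out[:kept],
        ea_out[:kept],
        k_out[:kept],
        th_out[:kept],
        kf_out[:kept],
        acc_rate,
        deltas[0],
        swaps0,
    )
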