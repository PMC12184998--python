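"""Numba-compiled Monte Carlo photon-transport core.

Everything here operates on flat arrays prepared by :mod:`rotcam.transport`:
axis-aligned boxes (crystals and optional PMT blocks), per-material linear
attenuation tables on a uniform log-energy grid, and an explicit xorshift64*
random stream so that runs are bit-reproducible for a given seed across
processes and platforms.

Physics: photoelectric absorption (full local deposit, history ends) and
incoherent Compton scattering off free electrons (Klein-Nishina angular law,
recoil energy deposited locally, photon continues).  Photons falling below
the 10 keV table floor are absorbed on the spot.
"""

from __future__ import annotations

import numpy as np
from numba import njit

ME_C2 = 511.0  # keV
E_FLOOR = 10.0  # keV; below this the photon range is negligible here
EPS = 1e-7  # cm, boundary nudge

_U64 = np.uint64


@njit(cache=True, inline="always")
def _splitmix64(x):
    x = _U64(x) + _U64(0x9E3779B97F4A7C15)
    z = x
    z = (z ^ (z >> _U64(30))) * _U64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> _U64(27))) * _U64(0x94D049BB133111EB)
    return z ^ (z >> _U64(31))


@njit(cache=True, inline="always")
def _next_u64(state):
    x = state[0]
    x ^= x >> _U64(12)
    x ^= x << _U64(25)
    x ^= x >> _U64(27)
    state[0] = x
    return x * _U64(0x2545F4914F6CDD1D)


@njit(cache=True, inline="always")
def _uniform(state):
    # 53-bit double in (0, 1)
    return (float(_next_u64(state) >> _U64(11)) + 0.5) * (1.0 / 9007199254740992.0)


@njit(cache=True)
def _seed_state(seed):
    s = np.empty(1, dtype=np.uint64)
    s[0] = _splitmix64(seed)
    if s[0] == _U64(0):
        s[0] = _U64(0xDEADBEEFCAFEF00D)
    return s


@njit(cache=True, inline="always")
def _mu_lookup(log_mu, mat, log_e, log_e0, inv_dlog, ng):
    """Log-log interpolation of a linear attenuation coefficient."""
    x = (log_e - log_e0) * inv_dlog
    if x <= 0.0:
        return np.exp(log_mu[mat, 0])
    if x >= ng - 1:
        return np.exp(log_mu[mat, ng - 1])
    i = int(x)
    f = x - i
    return np.exp(log_mu[mat, i] * (1.0 - f) + log_mu[mat, i + 1] * f)


@njit(cache=True, inline="always")
def _sample_kn_cos(state, alpha):
    """Sample cos(theta) from the Klein-Nishina angular distribution.

    Plain rejection under the constant envelope f <= 2 of
    f(c) = r^2 (r + 1/r - (1 - c^2)),  r = 1/(1 + alpha (1 - c)).
    Exact at all energies; acceptance is ~2/3 at low energy.
    """
    while True:
        c = 2.0 * _uniform(state) - 1.0
        r = 1.0 / (1.0 + alpha * (1.0 - c))
        f = r * r * (r + 1.0 / r - (1.0 - c * c))
        if 2.0 * _uniform(state) <= f:
            return c


@njit(cache=True)
def sample_kn_batch(seed, n, alpha):
    """Draw n Klein-Nishina cos(theta) samples at photon energy alpha*511 keV."""
    state = _seed_state(seed)
    out = np.empty(n)
    for i in range(n):
        out[i] = _sample_kn_cos(state, alpha)
    return out


@njit(cache=True, inline="always")
def _box_exit(lo, hi, b, p, d):
    """Distance to leave box b from an interior point (half-open slab rule)."""
    t = 1e30
    for k in range(3):
        if d[k] > 0.0:
            tk = (hi[b, k] - p[k]) / d[k]
        elif d[k] < 0.0:
            tk = (lo[b, k] - p[k]) / d[k]
        else:
            continue
        if tk < t:
            t = tk
    return t


@njit(cache=True, inline="always")
def _box_entry(lo, hi, b, p, d):
    """Entry distance into box b, or -1 if the ray misses it."""
    tmin = 0.0
    tmax = 1e30
    for k in range(3):
        if d[k] != 0.0:
            t1 = (lo[b, k] - p[k]) / d[k]
            t2 = (hi[b, k] - p[k]) / d[k]
            if t1 > t2:
                t1, t2 = t2, t1
            if t1 > tmin:
                tmin = t1
            if t2 < tmax:
                tmax = t2
        else:
            if p[k] < lo[b, k] or p[k] >= hi[b, k]:
                return -1.0
    if tmax <= tmin or tmax <= EPS:
        return -1.0
    return tmin


@njit(cache=True, inline="always")
def _inside_box(lo, hi, b, p):
    for k in range(3):
        if p[k] < lo[b, k] or p[k] >= hi[b, k]:
            return False
    return True


@njit(cache=True)
def _transport_one(
    state, pos, direction, energy,
    lo, hi, box_crystal, box_mat,
    log_mu_pe, log_mu_inc, log_e0, inv_dlog, ng,
    escape_r2, deposits, counts,
):
    """Track one photon; accumulate deposits per crystal.  Returns nothing."""
    p = pos.copy()
    d = direction.copy()
    e = energy
    nb = lo.shape[0]
    for _ in range(10000):
        inside = -1
        for b in range(nb):
            if _inside_box(lo, hi, b, p):
                inside = b
                break
        if inside >= 0:
            mat = box_mat[inside]
            log_e = np.log(e)
            mu_p = _mu_lookup(log_mu_pe, mat, log_e, log_e0, inv_dlog, ng)
            mu_i = _mu_lookup(log_mu_inc, mat, log_e, log_e0, inv_dlog, ng)
            mu_t = mu_p + mu_i
            t_exit = _box_exit(lo, hi, inside, p, d)
            s = -np.log(_uniform(state)) / mu_t
            if s >= t_exit:
                for k in range(3):
                    p[k] += d[k] * (t_exit + EPS)
                continue
            for k in range(3):
                p[k] += d[k] * s
            cry = box_crystal[inside]
            if _uniform(state) * mu_t < mu_p:
                if cry >= 0:
                    deposits[cry] += e
                    counts[cry] += 1
                return
            alpha = e / ME_C2
            c = _sample_kn_cos(state, alpha)
            e_new = e / (1.0 + alpha * (1.0 - c))
            if cry >= 0:
                deposits[cry] += e - e_new
                counts[cry] += 1
            if e_new < E_FLOOR:
                if cry >= 0:
                    deposits[cry] += e_new
                return
            e = e_new
            # rotate direction by the scattering angle, uniform azimuth
            phi = 2.0 * np.pi * _uniform(state)
            st = np.sqrt(max(0.0, 1.0 - c * c))
            # orthonormal basis around d
            if abs(d[0]) < 0.5:
                bx, by, bz = 1.0, 0.0, 0.0
            else:
                bx, by, bz = 0.0, 1.0, 0.0
            u0 = d[1] * bz - d[2] * by
            u1 = d[2] * bx - d[0] * bz
            u2 = d[0] * by - d[1] * bx
            un = np.sqrt(u0 * u0 + u1 * u1 + u2 * u2)
            u0 /= un; u1 /= un; u2 /= un
            v0 = d[1] * u2 - d[2] * u1
            v1 = d[2] * u0 - d[0] * u2
            v2 = d[0] * u1 - d[1] * u0
            cp, sp = np.cos(phi), np.sin(phi)
            d0 = c * d[0] + st * (cp * u0 + sp * v0)
            d1 = c * d[1] + st * (cp * u1 + sp * v1)
            d2 = c * d[2] + st * (cp * u2 + sp * v2)
            dn = np.sqrt(d0 * d0 + d1 * d1 + d2 * d2)
            d[0], d[1], d[2] = d0 / dn, d1 / dn, d2 / dn
        else:
            t_next = 1e30
            for b in range(nb):
                tb = _box_entry(lo, hi, b, p, d)
                if tb >= 0.0 and tb < t_next:
                    t_next = tb
            if t_next >= 1e29:
                return  # escapes to infinity
            r2 = p[0] * p[0] + p[1] * p[1] + p[2] * p[2]
            if r2 > escape_r2 and (p[0] * d[0] + p[1] * d[1] + p[2] * d[2]) > 0.0:
                return
            for k in range(3):
                p[k] += d[k] * (t_next + EPS)


@njit(cache=True)
def run_histories(
    seed, n_emit,
    src_pos, energy, cone_cos, rotate_source,
    lo, hi, box_crystal, box_mat,
    log_mu_pe, log_mu_inc, log_e0, inv_dlog, ng,
    escape_r2,
    out_rot, out_dep,
):
    """Emit ``n_emit`` photons; record histories with any crystal deposit.

    Per event: draw theta_rot ~ U[0, 360), rotate the source position forward
    by theta_rot about z, aim a direction uniformly over the spherical cap
    cos(theta) >= cone_cos around the source->origin axis (cone_cos <= -1
    means full-sphere isotropic emission), and transport.

    Returns ``(n_processed, n_recorded)``; stops early if the output buffers
    fill so the caller can keep the emission accounting exact.
    """
    state = _seed_state(seed)
    cap = out_rot.shape[0]
    m = 0
    n_done = 0
    deposits = np.zeros(6, dtype=np.float64)
    counts = np.zeros(6, dtype=np.int64)
    pos = np.empty(3, dtype=np.float64)
    d = np.empty(3, dtype=np.float64)
    for i in range(n_emit):
        if m >= cap:
            break
        if rotate_source:
            theta_rot = 360.0 * _uniform(state)
        else:
            theta_rot = 0.0
        t = np.radians(theta_rot)
        ct, s_t = np.cos(t), np.sin(t)
        pos[0] = ct * src_pos[0] - s_t * src_pos[1]
        pos[1] = s_t * src_pos[0] + ct * src_pos[1]
        pos[2] = src_pos[2]
        # aim axis: from the (rotated) source toward the origin
        an = np.sqrt(pos[0] ** 2 + pos[1] ** 2 + pos[2] ** 2)
        ax, ay, az = -pos[0] / an, -pos[1] / an, -pos[2] / an
        if cone_cos <= -1.0:
            cth = 1.0 - 2.0 * _uniform(state)
        else:
            cth = 1.0 - (1.0 - cone_cos) * _uniform(state)
        phi = 2.0 * np.pi * _uniform(state)
        sth = np.sqrt(max(0.0, 1.0 - cth * cth))
        lx, ly, lz = sth * np.cos(phi), sth * np.sin(phi), cth
        # rotate local +z onto the aim axis (Rodrigues)
        czz = az
        if czz > 1.0 - 1e-12:
            d[0], d[1], d[2] = lx, ly, lz
        elif czz < -1.0 + 1e-12:
            d[0], d[1], d[2] = lx, -ly, -lz
        else:
            kx, ky = -ay, ax  # cross(z, axis), z-component is 0
            kn = np.sqrt(kx * kx + ky * ky)
            kx /= kn; ky /= kn
            s_ang = np.sqrt(max(0.0, 1.0 - czz * czz))
            omc = 1.0 - czz
            d[0] = (czz + omc * kx * kx) * lx + (omc * kx * ky) * ly + (s_ang * ky) * lz
            d[1] = (omc * kx * ky) * lx + (czz + omc * ky * ky) * ly + (-s_ang * kx) * lz
            d[2] = (-s_ang * ky) * lx + (s_ang * kx) * ly + czz * lz
        for k in range(6):
            deposits[k] = 0.0
        _transport_one(
            state, pos, d, energy,
            lo, hi, box_crystal, box_mat,
            log_mu_pe, log_mu_inc, log_e0, inv_dlog, ng,
            escape_r2, deposits, counts,
        )
        n_done = i + 1
        hit = False
        for k in range(6):
            if deposits[k] > 0.0:
                hit = True
                break
        if hit:
            out_rot[m] = theta_rot
            for k in range(6):
                out_dep[m, k] = deposits[k]
            m += 1
    return n_done, m


@njit(cache=True)
def transport_single(
    seed, pos, direction, energy,
    lo, hi, box_crystal, box_mat,
    log_mu_pe, log_mu_inc, log_e0, inv_dlog, ng,
    escape_r2,
):
    """Track one photon from an explicit origin/direction (no rotation)."""
    state = _seed_state(seed)
    deposits = np.zeros(6, dtype=np.float64)
    counts = np.zeros(6, dtype=np.int64)
    p = pos.astype(np.float64)
    d = direction.astype(np.float64)
    _transport_one(
        state, p, d, energy,
        lo, hi, box_crystal, box_mat,
        log_mu_pe, log_mu_inc, log_e0, inv_dlog, ng,
        escape_r2, deposits, counts,
    )
    return deposits, counts
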