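"""Numba kernels for weighted-packet voxel Monte Carlo photon transport.

Variance-reduced scheme: scattering lengths are sampled from mu_s alone and
absorption is deposited continuously along each voxel traversal segment as
W * (1 - exp(-mu_a * l)) (microscopic Beer–Lambert weighting).  With
mu_s = 0 this reproduces the Beer–Lambert law exactly, which is the
validation route used by the tests.

Reproducibility: each packet owns an xorshift128+ substream seeded by
splitmix64(seed, packet index), so results are independent of execution
order.  All geometry inside the kernel is in millimetres; coefficients are
passed in mm^-1.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

U64 = np.uint64

FIELD_FULL = 0
FIELD_RECT = 1
FIELD_DISC = 2


@njit(cache=True, inline="always")
def _splitmix64(x):
    x = U64(x) + U64(0x9E3779B97F4A7C15)
    z = x
    z = (z ^ (z >> U64(30))) * U64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> U64(27))) * U64(0x94D049BB133111EB)
    return z ^ (z >> U64(31))


@njit(cache=True, inline="always")
def _rng_step(s0, s1):
    """xorshift128+ step: returns (u in [0,1), new s0, new s1)."""
    x = s0
    y = s1
    s0n = y
    x ^= x << U64(23)
    s1n = x ^ y ^ (x >> U64(17)) ^ (y >> U64(26))
    out = s1n + y
    u = float(out >> U64(11)) * (1.0 / 9007199254740992.0)
    return u, s0n, s1n


@njit(cache=True)
def hg_cosine(g, u):
    """Inverse-CDF Henyey–Greenstein scattering cosine."""
    if abs(g) < 1e-8:
        return 2.0 * u - 1.0
    t = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    c = (1.0 + g * g - t * t) / (2.0 * g)
    if c > 1.0:
        c = 1.0
    elif c < -1.0:
        c = -1.0
    return c


@njit(cache=True)
def fresnel_unpolarized(n1, n2, cos_i):
    """(reflectance, cos_t) for unpolarized light; total internal
    reflection returns (1, 0)."""
    if n1 == n2:
        return 0.0, cos_i
    s2 = (n1 / n2) * (n1 / n2) * (1.0 - cos_i * cos_i)
    if s2 >= 1.0:
        return 1.0, 0.0
    cos_t = math.sqrt(1.0 - s2)
    rs = (n1 * cos_i - n2 * cos_t) / (n1 * cos_i + n2 * cos_t)
    rp = (n1 * cos_t - n2 * cos_i) / (n1 * cos_t + n2 * cos_i)
    return 0.5 * (rs * rs + rp * rp), cos_t


@njit(cache=True, inline="always")
def _spin(ux, uy, uz, cos_t, phi):
    """Rotate the direction by scattering angle (cos_t, phi)."""
    sin_t = math.sqrt(max(0.0, 1.0 - cos_t * cos_t))
    cphi = math.cos(phi)
    sphi = math.sin(phi)
    if abs(uz) > 0.99999:
        nx = sin_t * cphi
        ny = sin_t * sphi
        nz = cos_t if uz > 0.0 else -cos_t
    else:
        den = math.sqrt(1.0 - uz * uz)
        nx = sin_t * (ux * uz * cphi - uy * sphi) / den + ux * cos_t
        ny = sin_t * (uy * uz * cphi + ux * sphi) / den + uy * cos_t
        nz = -sin_t * cphi * den + uz * cos_t
    norm = math.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / norm, ny / norm, nz / norm


@njit(cache=True)
def transport_kernel(labels, mua_mm, mus_mm, nidx, gfac, pitch,
                     n_photons, seed, fresnel_on, ambient_n,
                     field_kind, f0, f1, f2, f3,
                     roulette_w, roulette_p, dep):
    """Trace ``n_photons`` weighted packets; deposit absorbed weight in
    ``dep``.  Returns (absorbed, reflected, transmitted, roulette_net)
    total weights; roulette_net is weight destroyed minus weight created so
    that absorbed + reflected + transmitted + roulette_net = launched.
    """
    nx, ny, nz = labels.shape
    lx = nx * pitch
    ly = ny * pitch
    absorbed = 0.0
    reflected = 0.0
    transmitted = 0.0
    roulette_net = 0.0

    for ip in range(n_photons):
        h = _splitmix64(U64(seed) * U64(0x9E3779B97F4A7C15) + U64(ip))
        s0 = _splitmix64(h)
        s1 = _splitmix64(h ^ U64(0x5851F42D4C957F2D))
        if s0 == U64(0) and s1 == U64(0):
            s1 = U64(1)

        # --- launch over the beam field on the z=0 face, direction +z ---
        if field_kind == FIELD_FULL:
            u, s0, s1 = _rng_step(s0, s1)
            px = u * lx
            u, s0, s1 = _rng_step(s0, s1)
            py = u * ly
        elif field_kind == FIELD_RECT:
            u, s0, s1 = _rng_step(s0, s1)
            px = f0 + u * (f1 - f0)
            u, s0, s1 = _rng_step(s0, s1)
            py = f2 + u * (f3 - f2)
        else:  # disc centred (f0, f1), radius f2
            while True:
                u, s0, s1 = _rng_step(s0, s1)
                ax = 2.0 * u - 1.0
                u, s0, s1 = _rng_step(s0, s1)
                ay = 2.0 * u - 1.0
                if ax * ax + ay * ay <= 1.0:
                    break
            px = f0 + ax * f2
            py = f1 + ay * f2
        pz = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        ix = int(px / pitch)
        iy = int(py / pitch)
        iz = 0
        if ix >= nx:
            ix = nx - 1
        if iy >= ny:
            iy = ny - 1

        w = 1.0
        # specular reflection at the ambient->first-voxel interface
        if fresnel_on:
            n2 = nidx[labels[ix, iy, iz]]
            if n2 != ambient_n:
                r, _ = fresnel_unpolarized(ambient_n, n2, 1.0)
                u, s0, s1 = _rng_step(s0, s1)
                if u < r:
                    reflected += w
                    continue

        u, s0, s1 = _rng_step(s0, s1)
        s_left = -math.log(1.0 - u)  # dimensionless scattering depth

        alive = True
        while alive:
            lab = labels[ix, iy, iz]
            mua = mua_mm[lab]
            mus = mus_mm[lab]

            # distance to the next voxel face
            tb = 1e30
            axis = -1
            if ux > 0.0:
                t = ((ix + 1) * pitch - px) / ux
                if t < tb:
                    tb = t
                    axis = 0
            elif ux < 0.0:
                t = (ix * pitch - px) / ux
                if t < tb:
                    tb = t
                    axis = 0
            if uy > 0.0:
                t = ((iy + 1) * pitch - py) / uy
                if t < tb:
                    tb = t
                    axis = 1
            elif uy < 0.0:
                t = (iy * pitch - py) / uy
                if t < tb:
                    tb = t
                    axis = 1
            if uz > 0.0:
                t = ((iz + 1) * pitch - pz) / uz
                if t < tb:
                    tb = t
                    axis = 2
            elif uz < 0.0:
                t = (iz * pitch - pz) / uz
                if t < tb:
                    tb = t
                    axis = 2
            if tb < 0.0:
                tb = 0.0

            d_int = s_left / mus if mus > 0.0 else 1e30
            step = tb if tb < d_int else d_int

            if mua > 0.0 and step > 0.0:
                da = w * (1.0 - math.exp(-mua * step))
                dep[ix, iy, iz] += da
                absorbed += da
                w -= da

            px += ux * step
            py += uy * step
            pz += uz * step

            if d_int <= tb:
                # scattering event
                s_left = 0.0
                g = gfac[lab]
                u, s0, s1 = _rng_step(s0, s1)
                ct = hg_cosine(g, u)
                u, s0, s1 = _rng_step(s0, s1)
                ux, uy, uz = _spin(ux, uy, uz, ct, 2.0 * math.pi * u)
                u, s0, s1 = _rng_step(s0, s1)
                s_left = -math.log(1.0 - u)
            else:
                # voxel face crossing
                s_left -= mus * tb
                if s_left < 0.0:
                    s_left = 0.0
                step_dir = 1 if (ux if axis == 0 else uy if axis == 1 else uz) > 0.0 else -1
                jx, jy, jz = ix, iy, iz
                if axis == 0:
                    jx += step_dir
                elif axis == 1:
                    jy += step_dir
                else:
                    jz += step_dir
                outside = jx < 0 or jx >= nx or jy < 0 or jy >= ny or jz < 0 or jz >= nz
                n1 = nidx[lab]
                n2 = ambient_n if outside else nidx[labels[jx, jy, jz]]
                if fresnel_on and n1 != n2:
                    ci = abs(ux if axis == 0 else uy if axis == 1 else uz)
                    r, ct = fresnel_unpolarized(n1, n2, ci)
                    u, s0, s1 = _rng_step(s0, s1)
                    if u < r:
                        # reflect: flip the crossing component, stay put
                        if axis == 0:
                            ux = -ux
                        elif axis == 1:
                            uy = -uy
                        else:
                            uz = -uz
                        continue
                    # refract: scale tangential components, set normal one
                    ratio = n1 / n2
                    if axis == 0:
                        sign = 1.0 if ux > 0.0 else -1.0
                        uy *= ratio
                        uz *= ratio
                        ux = sign * ct
                    elif axis == 1:
                        sign = 1.0 if uy > 0.0 else -1.0
                        ux *= ratio
                        uz *= ratio
                        uy = sign * ct
                    else:
                        sign = 1.0 if uz > 0.0 else -1.0
                        ux *= ratio
                        uy *= ratio
                        uz = sign * ct
                    norm = math.sqrt(ux * ux + uy * uy + uz * uz)
                    ux /= norm
                    uy /= norm
                    uz /= norm
                if outside:
                    if axis == 2 and step_dir < 0:
                        reflected += w
                    else:
                        transmitted += w
                    alive = False
                    continue
                ix, iy, iz = jx, jy, jz

            # Russian roulette
            if w < roulette_w and alive:
                u, s0, s1 = _rng_step(s0, s1)
                if u < roulette_p:
                    roulette_net -= w * (1.0 / roulette_p - 1.0)
                    w /= roulette_p
                else:
                    roulette_net += w
                    alive = False

    return absorbed, reflected, transmitted, roulette_net
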