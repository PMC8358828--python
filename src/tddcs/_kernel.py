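"""Numba photon-transport kernel for layered slabs.

Random numbers come from a splitmix64 stream seeded per photon from the
global seed and the photon's global index, so results are independent
of chunking and thread count.  Absorption is never applied during
transport: packets carry unit weight and per-layer path lengths are
recorded so absorption can be applied analytically downstream.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

C0_MM_PS = 0.299792458

_SM_GAMMA = np.uint64(0x9E3779B97F4A7C15)
_SM_M1 = np.uint64(0xBF58476D1CE4E5B9)
_SM_M2 = np.uint64(0x94D049BB133111EB)
_U53 = 1.0 / 9007199254740992.0  # 2^-53

GEOM_DISK = 0
GEOM_RING = 1


@njit(inline="always", fastmath=True)
def _sm_next(state):
    """Advance a splitmix64 state; return (new_state, 64-bit output)."""
    state = state + _SM_GAMMA
    z = state
    z = (z ^ (z >> np.uint64(30))) * _SM_M1
    z = (z ^ (z >> np.uint64(27))) * _SM_M2
    z = z ^ (z >> np.uint64(31))
    return state, z


@njit(inline="always", fastmath=True)
def _u01(state):
    state, z = _sm_next(state)
    return state, float(z >> np.uint64(11)) * _U53


@njit(inline="always", fastmath=True)
def _fresnel_R(n_in, n_ext, cos_i):
    """Unpolarized Fresnel reflectance for internal incidence."""
    sin_i2 = 1.0 - cos_i * cos_i
    ratio = n_in / n_ext
    sin_t2 = ratio * ratio * sin_i2
    if sin_t2 >= 1.0:
        return 1.0  # total internal reflection
    cos_t = math.sqrt(1.0 - sin_t2)
    rs = (n_in * cos_i - n_ext * cos_t) / (n_in * cos_i + n_ext * cos_t)
    rp = (n_in * cos_t - n_ext * cos_i) / (n_in * cos_t + n_ext * cos_i)
    return 0.5 * (rs * rs + rp * rp)


@njit(inline="always", fastmath=True)
def _hg_cos(g, u):
    """Sample cos(theta) from the Henyey-Greenstein phase function."""
    if abs(g) < 1e-6:
        return 2.0 * u - 1.0
    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    return (1.0 + g * g - tmp * tmp) / (2.0 * g)


@njit(fastmath=True)
def run_chunk(
    seed,
    start_index,
    n_chunk,
    mus_mm,
    g_arr,
    n_arr,
    tops_mm,
    n_ext,
    sd_mm,
    det_radius_mm,
    geometry,
    max_tof_ps,
    L_out,
    Y_out,
    tof_out,
):
    """Trace ``n_chunk`` photons; write detected histories into the buffers.

    Returns the number of detected photons.  ``tops_mm[i]`` is the depth
    of the lower boundary of layer i (last entry inf).
    """
    n_layers = mus_mm.shape[0]
    count = 0
    big = 1e30
    Lloc = np.zeros(n_layers)
    Yloc = np.zeros(n_layers)
    # slowest medium bounds the path a photon can still travel before the
    # ToF cap; a photon deeper than that budget can never exit in time
    n_min = n_arr[0]
    for i in range(n_layers):
        if n_arr[i] < n_min:
            n_min = n_arr[i]
    for p in range(n_chunk):
        idx = np.uint64(start_index + p + 1)
        state = (np.uint64(seed) ^ (idx * np.uint64(0xA24BAED4963EE407))) + _SM_GAMMA
        state, _ = _sm_next(state)  # burn-in decorrelates nearby seeds

        x = 0.0
        y = 0.0
        z = 1e-9  # just inside the medium
        ux = 0.0
        uy = 0.0
        uz = 1.0
        layer = 0
        tof = 0.0
        for i in range(n_layers):
            Lloc[i] = 0.0
            Yloc[i] = 0.0
        alive = True
        detected = False

        while alive:
            state, u = _u01(state)
            if u <= 0.0:
                u = 1e-300
            tau = -math.log(u)
            while tau > 0.0 and alive:
                mus = mus_mm[layer]
                s_free = tau / mus
                top = tops_mm[layer]
                bot = tops_mm[layer - 1] if layer > 0 else 0.0
                if uz > 0.0:
                    d_b = (top - z) / uz
                elif uz < 0.0:
                    d_b = (bot - z) / uz
                else:
                    d_b = big
                if d_b < 0.0:
                    d_b = 0.0
                if s_free < d_b:
                    # free flight ends inside the layer: scatter
                    x += ux * s_free
                    y += uy * s_free
                    z += uz * s_free
                    Lloc[layer] += s_free
                    tof += n_arr[layer] * s_free / C0_MM_PS
                    tau = 0.0
                    if tof > max_tof_ps:
                        alive = False
                        break
                    # exact prune: needs at least z more path to reach z=0
                    if z > (max_tof_ps - tof) * C0_MM_PS / n_min:
                        alive = False
                        break
                    state, u1 = _u01(state)
                    cos_t = _hg_cos(g_arr[layer], u1)
                    if cos_t > 1.0:
                        cos_t = 1.0
                    elif cos_t < -1.0:
                        cos_t = -1.0
                    Yloc[layer] += 1.0 - cos_t
                    sin_t = math.sqrt(max(0.0, 1.0 - cos_t * cos_t))
                    # Marsaglia polar sampling of the azimuth
                    r2 = 2.0
                    va = 0.0
                    vb = 0.0
                    while r2 > 1.0 or r2 < 1e-12:
                        state, ua = _u01(state)
                        state, ub = _u01(state)
                        va = 2.0 * ua - 1.0
                        vb = 2.0 * ub - 1.0
                        r2 = va * va + vb * vb
                    cos_p = (va * va - vb * vb) / r2
                    sin_p = 2.0 * va * vb / r2
                    if abs(uz) > 0.99999:
                        ux = sin_t * cos_p
                        uy = sin_t * sin_p
                        uz = cos_t * (1.0 if uz >= 0.0 else -1.0)
                    else:
                        den = math.sqrt(1.0 - uz * uz)
                        nx = sin_t * (ux * uz * cos_p - uy * sin_p) / den + ux * cos_t
                        ny = sin_t * (uy * uz * cos_p + ux * sin_p) / den + uy * cos_t
                        nz = -sin_t * cos_p * den + uz * cos_t
                        norm = math.sqrt(nx * nx + ny * ny + nz * nz)
                        ux = nx / norm
                        uy = ny / norm
                        uz = nz / norm
                else:
                    # advance to the layer boundary
                    x += ux * d_b
                    y += uy * d_b
                    z += uz * d_b
                    Lloc[layer] += d_b
                    tof += n_arr[layer] * d_b / C0_MM_PS
                    tau -= d_b * mus
                    if tof > max_tof_ps:
                        alive = False
                        break
                    if uz < 0.0 and layer == 0:
                        # top surface: Fresnel reflect or exit
                        z = 0.0
                        cos_i = -uz
                        R = _fresnel_R(n_arr[0], n_ext, cos_i)
                        state, u3 = _u01(state)
                        if u3 < R:
                            uz = -uz
                        else:
                            alive = False
                            if geometry == GEOM_RING:
                                r = math.sqrt(x * x + y * y)
                                detected = abs(r - sd_mm) <= det_radius_mm
                            else:
                                dx = x - sd_mm
                                detected = (
                                    dx * dx + y * y
                                    <= det_radius_mm * det_radius_mm
                                )
                    else:
                        if uz > 0.0:
                            z = top
                            layer += 1
                        else:
                            z = bot
                            layer -= 1
        if detected:
            for i in range(n_layers):
                L_out[count, i] = Lloc[i]
                Y_out[count, i] = Yloc[i]
            tof_out[count] = tof
            count += 1
    return count


@njit
def sample_hg_mean_transfer(g, n, seed):
    """Monte Carlo mean of (1 - cos theta) over HG deflections."""
    state = np.uint64(seed) + _SM_GAMMA
    acc = 0.0
    for _ in range(n):
        state, u = _u01(state)
        c = _hg_cos(g, u)
        acc += 1.0 - c
    return acc / n
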