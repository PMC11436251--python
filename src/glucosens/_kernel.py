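"""Numba kernel for weighted-photon transport in plane-parallel layers.

MCML-style algorithm: dimensionless step sampling with carry-over of the
remaining optical depth across layer boundaries, weight attenuation by
the single-scattering albedo at each interaction, Henyey-Greenstein
direction sampling, unpolarized Fresnel reflection/refraction (with
total internal reflection) at every refractive-index mismatch, and
Russian roulette below a weight threshold.

The kernel runs one batch of photons sequentially with numba's internal
RNG seeded per call, so identical (seed, inputs) give bit-identical
tallies.
"""

import math

import numpy as np
from numba import njit

_CHORD_EPS = 1e-30


@njit(cache=True)
def _spin(ux, uy, uz, g, r1, r2):
    """Henyey-Greenstein deflection + uniform azimuth; returns new direction."""
    if g != 0.0:
        tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * r1)
        ct = (1.0 + g * g - tmp * tmp) / (2.0 * g)
        if ct > 1.0:
            ct = 1.0
        elif ct < -1.0:
            ct = -1.0
    else:
        ct = 2.0 * r1 - 1.0
    st = math.sqrt(max(0.0, 1.0 - ct * ct))
    phi = 2.0 * math.pi * r2
    cp = math.cos(phi)
    sp = math.sin(phi)
    if abs(uz) > 0.99999:
        nux = st * cp
        nuy = st * sp
        nuz = ct if uz >= 0.0 else -ct
    else:
        den = math.sqrt(1.0 - uz * uz)
        nux = st * (ux * uz * cp - uy * sp) / den + ux * ct
        nuy = st * (uy * uz * cp + ux * sp) / den + uy * ct
        nuz = -st * cp * den + uz * ct
    norm = math.sqrt(nux * nux + nuy * nuy + nuz * nuz)
    return nux / norm, nuy / norm, nuz / norm


@njit(cache=True)
def _fresnel(n1, n2, ci):
    """Unpolarized Fresnel reflectance and transmitted cosine.

    Returns (R, ct); ct is 0 when totally internally reflected (R = 1).
    """
    if n1 == n2:
        return 0.0, ci
    st2 = (n1 / n2) * (n1 / n2) * (1.0 - ci * ci)
    if st2 >= 1.0:
        return 1.0, 0.0
    ct = math.sqrt(1.0 - st2)
    rs = (n1 * ci - n2 * ct) / (n1 * ci + n2 * ct)
    rp = (n1 * ct - n2 * ci) / (n1 * ct + n2 * ci)
    return 0.5 * (rs * rs + rp * rp), ct


@njit(cache=True)
def run_batch(
    seed,
    n_photons,
    z_edges,      # float64[n_layers + 1], z=0 at top surface, increasing down
    mu_a,         # float64[n_layers]
    mu_s,         # float64[n_layers]
    g,            # float64[n_layers]
    n_med,        # float64[n_layers]
    n_above,
    n_below,
    ring_inner,   # float64[n_rings]
    ring_outer,   # float64[n_rings]
    roulette_threshold,
    roulette_survival,
):
    """Trace one seeded batch; returns per-ring weights and global tallies.

    Output: (ring_w, refl, trans, absorbed, specular), all raw weight
    sums over ``n_photons`` launched unit-weight photons.
    """
    np.random.seed(seed)
    n_layers = mu_a.shape[0]
    n_rings = ring_inner.shape[0]
    ring_w = np.zeros(n_rings)
    refl = 0.0
    trans = 0.0
    absorbed = 0.0
    specular = 0.0

    for _ in range(n_photons):
        w = 1.0
        # Pencil beam at the origin, straight down into the top medium.
        if n_above != n_med[0]:
            rsp = ((n_above - n_med[0]) / (n_above + n_med[0])) ** 2
            specular += rsp
            w -= rsp
        x = 0.0
        y = 0.0
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        layer = 0
        s_left = 0.0  # remaining dimensionless optical depth
        alive = True

        while alive:
            mt = mu_a[layer] + mu_s[layer]
            if s_left <= 0.0:
                s_left = -math.log(np.random.random() + _CHORD_EPS)
            # distance to the layer boundary along the flight direction
            if uz > 0.0:
                db = (z_edges[layer + 1] - z) / uz
            elif uz < 0.0:
                db = (z_edges[layer] - z) / uz
            else:
                db = 1e30
            s_phys = s_left / mt if mt > 0.0 else 1e30

            if db < s_phys:
                # hit the boundary first
                x += ux * db
                y += uy * db
                z += uz * db
                if mt > 0.0:
                    s_left -= db * mt
                going_up = uz < 0.0
                n1 = n_med[layer]
                if going_up:
                    n2 = n_above if layer == 0 else n_med[layer - 1]
                else:
                    n2 = n_below if layer == n_layers - 1 else n_med[layer + 1]
                refl_prob, ct = _fresnel(n1, n2, abs(uz))
                if refl_prob > 0.0 and np.random.random() < refl_prob:
                    uz = -uz  # internal reflection
                else:
                    # refract (directions rescaled via Snell's law)
                    if n1 != n2:
                        scale = n1 / n2
                        ux *= scale
                        uy *= scale
                        uz = ct if uz > 0.0 else -ct
                    if going_up and layer == 0:
                        # escape through the top surface: tally by exit radius
                        refl += w
                        r = math.sqrt(x * x + y * y)
                        for k in range(n_rings):
                            if ring_inner[k] <= r < ring_outer[k]:
                                ring_w[k] += w
                                break
                        alive = False
                    elif (not going_up) and layer == n_layers - 1:
                        trans += w
                        alive = False
                    else:
                        layer += -1 if going_up else 1
            else:
                # interaction inside the layer
                x += ux * s_phys
                y += uy * s_phys
                z += uz * s_phys
                s_left = 0.0
                if mt <= 0.0:
                    break  # non-interacting layer: unreachable for uz != 0
                da = w * mu_a[layer] / mt
                absorbed += da
                w -= da
                ux, uy, uz = _spin(
                    ux, uy, uz, g[layer], np.random.random(), np.random.random()
                )
                if w < roulette_threshold:
                    # unbiased termination: killed weight is compensated in
                    # expectation by the survivors' 1/p boost, so it is not
                    # tallied anywhere
                    if np.random.random() < roulette_survival:
                        w /= roulette_survival
                    else:
                        alive = False

    return ring_w, refl, trans, absorbed, specular
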