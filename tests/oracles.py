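"""Independent closed-form and numerical oracles used by the tests.

These deliberately avoid the package's own code paths: the diffusion
reflectance is the textbook steady-state dipole solution for a
semi-infinite medium, and the Mie relative-change oracle is a central
finite difference on the mu_s' = K (n_s/n_0 - 1)^2 formula evaluated
directly.
"""

import numpy as np


def diffusion_reflectance(r, mu_a, mu_s_prime):
    """Diffuse reflectance per unit area R(r) (mm^-2) for a pencil beam
    on a semi-infinite medium with a refractive-index-matched boundary.

    Steady-state diffusion approximation with an isotropic point source
    at depth z0 = 1/mu_t' and an extrapolated boundary at -2D (A = 1).
    """
    r = np.asarray(r, dtype=float)
    D = 1.0 / (3.0 * (mu_a + mu_s_prime))
    mu_eff = np.sqrt(mu_a / D)
    z0 = 1.0 / (mu_a + mu_s_prime)
    zb = 2.0 * D
    r1 = np.sqrt(r**2 + z0**2)
    r2 = np.sqrt(r**2 + (z0 + 2.0 * zb) ** 2)
    return (1.0 / (4.0 * np.pi)) * (
        z0 * (mu_eff + 1.0 / r1) * np.exp(-mu_eff * r1) / r1**2
        + (z0 + 2.0 * zb) * (mu_eff + 1.0 / r2) * np.exp(-mu_eff * r2) / r2**2
    )


def mie_relative_change_fd(K, n_s, n_0, dn0_dCg, delta=1e-7):
    """Finite-difference oracle for the relative scattering change.

    d ln(mu_s')/dn_0 * dn_0/dCg with mu_s'(n_0) = K (n_s/n_0 - 1)^2,
    central difference in n_0.
    """

    def mus_prime(n0):
        return K * (n_s / n0 - 1.0) ** 2

    dlnmus_dn0 = (np.log(mus_prime(n_0 + delta)) - np.log(mus_prime(n_0 - delta))) / (
        2.0 * delta
    )
    return dlnmus_dn0 * dn0_dCg
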