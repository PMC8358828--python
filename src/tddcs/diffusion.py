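"""Time-resolved diffusion reflectance from a semi-infinite medium.

Extrapolated-boundary solution for a pencil beam on a homogeneous
semi-infinite slab: an isotropic source at depth z0 = 1/musp' and its
negative image mirrored about the extrapolated boundary at -2*zb,
zb = 2*A*Dd with Dd = 1/(3 musp') the diffusion length and A the
internal-reflection parameter for the refractive-index mismatch
(Groenhuis form).  Used both as the forward model for recovering
homogeneous-equivalent optical properties from a TPSF and as an
independent oracle for the Monte Carlo transport.
"""

from __future__ import annotations

import math

import numpy as np

from ._kernel import C0_MM_PS

__all__ = [
    "internal_reflection_A",
    "semi_infinite_reflectance",
    "semi_infinite_reflectance_ring",
]


def internal_reflection_A(n_medium: float, n_exterior: float = 1.0) -> float:
    """Internal-reflection parameter A of the extrapolated boundary.

    Polynomial approximation (in the relative index n) of the exact
    Fresnel-averaged boundary coefficient used by time-resolved
    reflectance theory; A(1.0) = 1, A(1.4) ~ 2.95.
    """
    n = n_medium / n_exterior
    if n < 1.0:
        raise ValueError("n_medium < n_exterior is not supported")
    return (
        504.332889
        - 2641.00214 * n
        + 5923.699064 * n**2
        - 7376.355814 * n**3
        + 5507.53041 * n**4
        - 2463.357945 * n**5
        + 610.956547 * n**6
        - 64.8047 * n**7
    )


def _common(t_ps, mua_cm, musp_cm, n_medium, n_exterior):
    t = np.asarray(t_ps, dtype=float)
    mua = mua_cm / 10.0   # 1/mm
    musp = musp_cm / 10.0
    v = C0_MM_PS / n_medium  # mm/ps
    Dd = 1.0 / (3.0 * musp)  # mm
    z0 = 1.0 / musp
    zb = 2.0 * internal_reflection_A(n_medium, n_exterior) * Dd
    pos = t > 0
    tsafe = np.where(pos, t, 1.0)
    denom = 4.0 * Dd * v * tsafe  # mm^2
    axial = np.where(
        pos,
        z0 * np.exp(-(z0**2) / denom)
        + (z0 + 2.0 * zb) * np.exp(-((z0 + 2.0 * zb) ** 2) / denom),
        0.0,
    )
    pref = np.where(
        pos,
        np.power(4.0 * math.pi * Dd * v, -1.5)
        * np.power(tsafe, -2.5)
        * np.exp(-mua * v * tsafe),
        0.0,
    )
    return t, denom, axial, pref


def semi_infinite_reflectance(
    t_ps,
    rho_mm: float,
    mua_cm: float,
    musp_cm: float,
    n_medium: float = 1.4,
    n_exterior: float = 1.0,
) -> np.ndarray:
    """R(rho, t): reflectance per unit area at radial distance rho.

    Arbitrary overall scale (per launched photon, 1/mm^2/ps); shapes are
    what matters for fitting and oracle comparison.
    """
    t, denom, axial, pref = _common(t_ps, mua_cm, musp_cm, n_medium, n_exterior)
    radial = np.where(t > 0, np.exp(-(rho_mm**2) / denom), 0.0)
    return 0.5 * pref * axial * radial


def semi_infinite_reflectance_ring(
    t_ps,
    r_inner_mm: float,
    r_outer_mm: float,
    mua_cm: float,
    musp_cm: float,
    n_medium: float = 1.4,
    n_exterior: float = 1.0,
) -> np.ndarray:
    """Reflectance collected over an annulus r_inner <= r <= r_outer.

    The radial Gaussian integrates in closed form:
    int_{r1}^{r2} e^{-r^2/(4 D v t)} 2 pi r dr
      = 4 pi D v t (e^{-r1^2/(4Dvt)} - e^{-r2^2/(4Dvt)}).
    """
    t, denom, axial, pref = _common(t_ps, mua_cm, musp_cm, n_medium, n_exterior)
    radial = np.where(
        t > 0,
        math.pi
        * denom
        * (np.exp(-(r_inner_mm**2) / denom) - np.exp(-(r_outer_mm**2) / denom)),
        0.0,
    )
    return 0.5 * pref * axial * radial
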