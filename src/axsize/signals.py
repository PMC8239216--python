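"""Closed-form PGSE signal models for the three tissue compartments.

Cylinder
    Restricted diffusion inside an impermeable parallel cylinder.  The
    attenuation perpendicular to the cylinder axis uses the Gaussian phase
    distribution (GPD) approximation: a series over the positive roots of the
    derivative of the order-1 Bessel function of the first kind.  Along the
    axis diffusion is free with diffusivity ``d_par``.

Zeppelin
    Axially symmetric Gaussian tensor, ``S = exp(-b [d_perp +
    (d_par - d_perp) (g.n)^2])``, modelling the extra-axonal space.

Ball
    Isotropic Gaussian, ``S = exp(-b d_iso)``, modelling CSF.

All attenuations are relative to the b=0 signal (S = 1 at b = 0).
Diffusivities are in m^2/s, radii/diameters in meters unless a function says
otherwise.

The module also provides antipodally-symmetric Watson sampling on the sphere,
used by the phantom to model axon orientation dispersion.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import jnp_zeros

from .scheme import AcquisitionScheme

__all__ = [
    "CylinderSpec",
    "ZeppelinSpec",
    "BallSpec",
    "cylinder_signal",
    "zeppelin_signal",
    "ball_signal",
    "cylinder_attenuation",
    "gpd_attenuation_factor",
    "watson_sample",
]

#: Default intra-cylinder (and zeppelin longitudinal) diffusivity, m^2/s.
D_PARALLEL = 1.7e-9
#: Default isotropic (CSF) diffusivity, m^2/s.
D_ISO = 3.0e-9
#: Default number of Bessel-derivative roots in the GPD series.
N_ROOTS = 32


@dataclass(frozen=True)
class CylinderSpec:
    """Impermeable cylinder: diameter (m), axial diffusivity (m^2/s), axis."""

    diameter: float
    d_par: float = D_PARALLEL
    orientation: tuple = (0.0, 0.0, 1.0)

    def __post_init__(self):
        if self.diameter <= 0:
            raise ValueError("cylinder diameter must be positive")
        if self.d_par <= 0:
            raise ValueError("parallel diffusivity must be positive")


@dataclass(frozen=True)
class ZeppelinSpec:
    """Axially symmetric tensor: longitudinal/perpendicular diffusivity, axis."""

    d_par: float = D_PARALLEL
    d_perp: float = 0.5e-9
    orientation: tuple = (0.0, 0.0, 1.0)

    def __post_init__(self):
        if not 0 < self.d_perp <= self.d_par:
            raise ValueError("zeppelin requires 0 < d_perp <= d_par")


@dataclass(frozen=True)
class BallSpec:
    """Isotropic tensor with diffusivity ``d_iso`` (m^2/s)."""

    d_iso: float = D_ISO

    def __post_init__(self):
        if self.d_iso <= 0:
            raise ValueError("isotropic diffusivity must be positive")


@lru_cache(maxsize=8)
def _bessel_prime_roots(n):
    return jnp_zeros(1, n)


def gpd_attenuation_factor(radius, delta, Delta, D=D_PARALLEL, n_roots=N_ROOTS,
                           check_convergence=False, rtol=1e-6):
    """GPD series factor C with ``ln S_perp = -gamma^2 * G_perp^2 * C``.

    ``C = 2 * sum_m [2 D a_m^2 delta - 2 + 2 e^{-D a_m^2 delta}
    + 2 e^{-D a_m^2 Delta} - e^{-D a_m^2 (Delta-delta)}
    - e^{-D a_m^2 (Delta+delta)}] / (D^2 a_m^6 (R^2 a_m^2 - 1))``

    with ``a_m = beta_m / R`` and ``beta_m`` the m-th positive root of
    ``J_1'``.  Broadcasts over array ``radius``; ``delta``/``Delta`` scalars.

    With ``check_convergence`` the series is re-evaluated at ``2 n_roots``
    roots and a numerical error is raised if the two disagree beyond ``rtol``
    (relative, guarded at small factors).
    """
    radius = np.asarray(radius, dtype=float)
    if np.any(radius <= 0):
        raise ValueError("cylinder radius must be positive")

    def series(m):
        beta = _bessel_prime_roots(m)
        am = beta / radius[..., None]  # (..., m)
        a2D = D * am**2
        num = (
            2 * a2D * delta
            - 2
            + 2 * np.exp(-a2D * delta)
            + 2 * np.exp(-a2D * Delta)
            - np.exp(-a2D * (Delta - delta))
            - np.exp(-a2D * (Delta + delta))
        )
        den = D**2 * am**6 * (radius[..., None] ** 2 * am**2 - 1.0)
        return 2.0 * np.sum(num / den, axis=-1)

    c = series(n_roots)
    if check_convergence:
        c2 = series(2 * n_roots)
        scale = np.maximum(np.abs(c2), 1e-30)
        if np.any(np.abs(c - c2) / scale > rtol):
            raise FloatingPointError(
                f"GPD series not converged at {n_roots} roots (rtol {rtol})"
            )
    return c


def cylinder_attenuation(diameters, orientations, scheme: AcquisitionScheme,
                         d_par=D_PARALLEL, n_roots=N_ROOTS):
    """Vectorised cylinder attenuation for paired (diameter, orientation).

    Parameters
    ----------
    diameters : (k,) array, meters.
    orientations : (k, 3) or (3,) array of unit axes (shared if a single axis).
    scheme : AcquisitionScheme

    Returns
    -------
    (k, n_measurements) array of attenuations in (0, 1].
    """
    diameters = np.atleast_1d(np.asarray(diameters, dtype=float))
    orientations = np.asarray(orientations, dtype=float)
    if orientations.ndim == 1:
        orientations = np.broadcast_to(orientations, (len(diameters), 3))
    orientations = orientations / np.linalg.norm(orientations, axis=1, keepdims=True)
    if np.any(scheme.delta >= scheme.Delta):
        raise ValueError("scheme timings must satisfy delta < Delta")

    radii = diameters / 2.0
    gamma = scheme.gamma
    n = len(scheme)
    out = np.ones((len(diameters), n))

    cos = orientations @ scheme.directions.T  # (k, n)
    G_par2 = (scheme.G * cos) ** 2
    G_perp2 = np.maximum(scheme.G**2 - G_par2, 0.0)
    b_par = (gamma * scheme.delta) ** 2 * (scheme.Delta - scheme.delta / 3.0) * G_par2

    dw = scheme.G > 0
    # GPD factor depends on (radius, delta, Delta) only; group by timing pair
    C = np.zeros((len(diameters), n))
    for key in {(float(d), float(D)) for d, D in zip(scheme.delta[dw], scheme.Delta[dw])}:
        sel = dw & (scheme.delta == key[0]) & (scheme.Delta == key[1])
        C[:, sel] = gpd_attenuation_factor(radii, key[0], key[1], d_par, n_roots)[:, None]
    out = np.exp(-b_par * d_par) * np.exp(-(gamma**2) * G_perp2 * C)
    out[:, ~dw] = 1.0
    return out


def cylinder_signal(spec: CylinderSpec, scheme: AcquisitionScheme, n_roots=N_ROOTS):
    """Attenuation vector of a single impermeable cylinder (GPD closed form)."""
    return cylinder_attenuation(
        [spec.diameter], np.asarray(spec.orientation, dtype=float),
        scheme, d_par=spec.d_par, n_roots=n_roots,
    )[0]


def zeppelin_signal(spec: ZeppelinSpec, scheme: AcquisitionScheme):
    """Attenuation of an axially symmetric Gaussian tensor."""
    n = np.asarray(spec.orientation, dtype=float)
    n = n / np.linalg.norm(n)
    cos2 = (scheme.directions @ n) ** 2
    return np.exp(-scheme.b * (spec.d_perp + (spec.d_par - spec.d_perp) * cos2))


def ball_signal(spec: BallSpec, scheme: AcquisitionScheme):
    """Attenuation of an isotropic Gaussian compartment."""
    return np.exp(-scheme.b * spec.d_iso)


def watson_sample(mu, kappa, n, rng=None):
    """Sample ``n`` axes from a Watson distribution about ``mu``.

    The density is proportional to ``exp(kappa (mu.x)^2)`` on the sphere
    (antipodally symmetric, concentrated around +/-mu for ``kappa > 0``).
    Sampling is by rejection against the uniform sphere with envelope
    ``exp(kappa)``; ``kappa = inf`` returns copies of ``mu``.

    ``rng`` may be a seed or a ``numpy.random.Generator``.
    """
    mu = np.asarray(mu, dtype=float)
    mu = mu / np.linalg.norm(mu)
    if not (kappa > 0):
        raise ValueError("kappa must be positive (or inf)")
    rng = np.random.default_rng(rng)
    if np.isinf(kappa):
        return np.tile(mu, (n, 1))
    out = np.empty((n, 3))
    filled = 0
    while filled < n:
        m = max(4 * (n - filled), 256)
        v = rng.standard_normal((m, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        t2 = (v @ mu) ** 2
        keep = rng.random(m) < np.exp(kappa * (t2 - 1.0))
        v = v[keep]
        take = min(len(v), n - filled)
        out[filled:filled + take] = v[:take]
        filled += take
    return out
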