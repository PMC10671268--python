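"""Closed-form kinetic models and physical relations.

Every model curve used elsewhere in the package is evaluated here, in one
place: the quadratic nucleation-stage intensity rise, the second-order
growth-stage polynomial, the power-law concentration dependence that carries
the order of aggregation, the Hill dose-response of a chemical chaperone,
the shape-parameterized decay of the non-aggregated protein fraction, the
second-order linearization of monomer depletion, and the Stokes-Einstein
relation used for DLS sizing.

All functions are pure and vectorized over their first argument.
Intensities are in arbitrary instrument counts throughout; only their
ratios and concentration dependences are meaningful.
"""

from __future__ import annotations

import numpy as np

from .constants import BOLTZMANN_J_PER_K

__all__ = [
    "eval_nucleation",
    "eval_growth",
    "eval_power_law",
    "eval_hill",
    "eval_nonagg",
    "second_order_transform",
    "stokes_einstein_rh",
    "stokes_einstein_d",
    "compute_q",
]


def eval_nucleation(t, I0, K_agg, t0):
    """Intensity during the nucleation stage: ``I = I0 + K_agg*(t - t0)**2``.

    The quadratic rise reflects nuclei forming at a roughly constant rate
    while each contributes scattering that grows with time.  ``K_agg``
    (counts/s^2) measures the acceleration of aggregation; ``t0`` (s) is the
    time at which the intensity starts to rise.  For ``t <= t0`` the
    baseline ``I0`` is returned.

    Raises
    ------
    ValueError
        If ``K_agg`` is negative.
    """
    if K_agg < 0:
        raise ValueError(f"K_agg must be >= 0, got {K_agg}")
    t = np.asarray(t, dtype=float)
    dt = t - t0
    return np.where(dt > 0, I0 + K_agg * dt**2, I0)


def eval_growth(t, I0, v0, t_star, B):
    """Intensity during aggregate growth: ``I = I0 + v0*(t-t*) - B*(t-t*)**2``.

    ``v0`` (counts/s) is the initial rate of the growth stage and ``t*`` (s)
    the lag duration: the length cut off on the abscissa by the fitted
    parabola at the baseline level ``I0``.  ``B`` captures the slowing of
    growth as monomer is depleted.  Defined for ``t >= t_star`` only.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < t_star):
        raise ValueError("eval_growth is defined for t >= t_star only")
    dt = t - t_star
    return I0 + v0 * dt - B * dt**2


def eval_power_law(P0, const, b):
    """Concentration dependence of a stage rate parameter: ``const * P0**b``.

    The exponent ``b`` estimates the order of aggregation with respect to
    protein for that stage; ``P0`` is the initial protein concentration
    (mg/mL).
    """
    P0 = np.asarray(P0, dtype=float)
    if np.any(P0 <= 0):
        raise ValueError("P0 must be > 0")
    if const <= 0:
        raise ValueError("const must be > 0")
    return const * P0**b


def eval_hill(L, L_half, h):
    """Hill suppression ratio ``1 / (1 + (L/L_half)**h)``.

    Fraction of the no-chaperone value of a rate parameter remaining at
    ligand concentration ``L`` (mM).  ``L_half`` is the semi-saturation
    concentration (ratio = 0.5) and ``h`` the Hill coefficient.  Strictly
    decreasing in ``L``, with range (0, 1].
    """
    L = np.asarray(L, dtype=float)
    if np.any(L < 0):
        raise ValueError("ligand concentration must be >= 0")
    if L_half <= 0 or h <= 0:
        raise ValueError("L_half and h must be > 0")
    return 1.0 / (1.0 + (L / L_half) ** h)


def eval_nonagg(t, t_star, t_half, m):
    """Non-aggregated protein fraction versus time.

    ``gamma(t) = [1 + (2**(m-1) - 1) * (t - t*)/t_half]**(-1/(m-1))`` for
    ``t > t*`` and 1 during the lag phase.  ``t_half`` is the half-decay
    interval measured from the end of the lag period, so gamma = 0.5 at
    ``t = t* + t_half`` for every shape parameter ``m > 1``.  ``m``
    interpolates between exponential-like (m -> 1) and strongly tailed
    decays; m = 2 is exact second-order depletion.
    """
    if m <= 1:
        raise ValueError(f"shape parameter m must be > 1, got {m}")
    if t_half <= 0:
        raise ValueError("t_half must be > 0")
    t = np.asarray(t, dtype=float)
    x = np.clip((t - t_star) / t_half, 0.0, None)
    return (1.0 + (2.0 ** (m - 1.0) - 1.0) * x) ** (-1.0 / (m - 1.0))


def second_order_transform(gamma, c0):
    """Second-order reaction coordinates: ``1/c - 1/c0`` with ``c = c0*gamma``.

    For a bimolecular depletion of monomer this is a straight line in time
    with slope kII (L mol^-1 s^-1).  ``c0`` is the initial molar protein
    concentration; returns L/mol.
    """
    gamma = np.asarray(gamma, dtype=float)
    if c0 <= 0:
        raise ValueError("c0 must be > 0")
    if np.any(gamma <= 0) or np.any(gamma > 1):
        raise ValueError("gamma must lie in (0, 1]")
    return 1.0 / (c0 * gamma) - 1.0 / c0


def stokes_einstein_rh(D, T, eta):
    """Hydrodynamic radius (m) from a diffusion coefficient.

    ``Rh = kB*T / (6*pi*eta*D)`` with T in kelvin and eta in Pa s.
    """
    D = np.asarray(D, dtype=float)
    if np.any(D <= 0) or T <= 0 or eta <= 0:
        raise ValueError("D, T and eta must all be > 0")
    return BOLTZMANN_J_PER_K * T / (6.0 * np.pi * eta * D)


def stokes_einstein_d(Rh, T, eta):
    """Diffusion coefficient (m^2/s) of a sphere of hydrodynamic radius Rh (m)."""
    Rh = np.asarray(Rh, dtype=float)
    if np.any(Rh <= 0) or T <= 0 or eta <= 0:
        raise ValueError("Rh, T and eta must all be > 0")
    return BOLTZMANN_J_PER_K * T / (6.0 * np.pi * eta * Rh)


def compute_q(n, wavelength_nm, angle_deg):
    """Scattering vector magnitude ``q = 4*pi*n*sin(theta/2)/lambda`` in 1/m.

    ``n`` is the solvent refractive index, ``wavelength_nm`` the vacuum laser
    wavelength and ``angle_deg`` the scattering angle (0 < angle < 180).
    """
    if n <= 0 or wavelength_nm <= 0:
        raise ValueError("refractive index and wavelength must be > 0")
    if not 0 < angle_deg < 180:
        raise ValueError("scattering angle must lie in (0, 180) degrees")
    lam_m = wavelength_nm * 1e-9
    return 4.0 * np.pi * n * np.sin(np.deg2rad(angle_deg) / 2.0) / lam_m
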