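"""Closed-form parametrizations of the coastal plankton model.

The functions here encode the model's novel coastal biology: seasonal and
lateral turbidity, the coastal-vicinity index that scales carnivorous
grazing pressure, the resulting zooplankton closure mortality, and the
smooth-step host mortality imposed by intracellular viral infection.

Sign convention that is easy to get wrong: the sigmoid step
``sigmoid_step(x, s) = 1 / (1 + exp(s*x))`` is *decreasing* in ``x`` —
it approaches 1 for strongly negative arguments and 0 for strongly
positive ones, with value 1/2 at ``x = 0``.
"""

from __future__ import annotations

import numpy as np

from .params import CoastalParams, Environment

__all__ = [
    "sigmoid_step",
    "seasonal_eta",
    "spm_attenuation",
    "coastal_vicinity_index",
    "temperature_factor",
    "zooplankton_mortality",
    "grazing_half_saturation",
    "viral_host_mortality",
]

YEAR_DAYS = 365.0

#: exponent clamp that keeps exp() finite while saturating the sigmoid
_EXP_CLAMP = 500.0


def sigmoid_step(x, s):
    """Decreasing smooth step ``1 / (1 + exp(s*x))``.

    Equals 1/2 at ``x = 0`` for any steepness ``s >= 0``; tends to 1 as
    ``x -> -inf`` and to 0 as ``x -> +inf``.  The exponent is clamped at
    +-500 so the result saturates instead of overflowing.
    Accepts scalars or arrays.
    """
    if np.any(np.asarray(s) < 0):
        raise ValueError("steepness s must be >= 0")
    z = np.clip(np.multiply(s, x), -_EXP_CLAMP, _EXP_CLAMP)
    out = 1.0 / (1.0 + np.exp(z))
    return float(out) if np.isscalar(x) and np.isscalar(s) else out


def seasonal_eta(j, l):
    """Annual harmonic ``1/2 + 1/2 cos(2*pi/365 * (j - l))`` in [0, 1].

    Peaks (value 1) at Julian day ``j = l`` and vanishes half a year
    later; the annual mean is 1/2.
    """
    out = 0.5 + 0.5 * np.cos(2.0 * np.pi / YEAR_DAYS * (np.asarray(j, dtype=float) - l))
    return float(out) if np.isscalar(j) else out


def spm_attenuation(env: Environment, p: CoastalParams) -> float:
    """Light attenuation by suspended particulate matter, 1/m.

    Combines a constant background fraction ``alpha`` with a seasonal-
    bathymetric resuspension term (winter maximum at day ``l_turb``,
    active where ``h < h_star``) and an event-scale term driven by the
    ratio of bottom TKE dissipation to its critical value ``eps_star``::

        a_spm = a'_spm * [alpha + (1-alpha)/2 *
                          (eta_Lturb(j) * sigma_sdepth(h - h*) + eps_b/eps*)]

    Always >= ``a_spm_prime * alpha``.
    """
    if p.eps_star == 0.0:
        raise ValueError("eps_star must be nonzero")
    seasonal = seasonal_eta(env.j, p.l_turb) * sigmoid_step(env.h - p.h_star, p.s_depth)
    event = env.eps_b / p.eps_star
    return p.a_spm_prime * (p.alpha + 0.5 * (1.0 - p.alpha) * (seasonal + event))


def coastal_vicinity_index(h, s, p: CoastalParams):
    """Coastal vicinity index in [0, 1.5], decreasing in depth and salinity.

    Combines a bathymetric step around ``h_star`` with two salinity steps:
    one marking typical coastal water (threshold ``s_coast``, default
    31 PSU) and a half-weighted estuarine one (``s_est``, default 12 PSU)::

        max{ sigma_0.4(h - h*), sigma_1(s - 31) } + 1/2 sigma_1(s - 12)

    Offshore (deep, saline) water scores ~0; estuarine water approaches 1.5.
    """
    bathy = sigmoid_step(np.subtract(h, p.h_star), p.s_depth)
    coast = sigmoid_step(np.subtract(s, p.s_coast), p.s_sal)
    est = sigmoid_step(np.subtract(s, p.s_est), p.s_sal)
    out = np.maximum(bathy, coast) + 0.5 * est
    return float(out) if np.isscalar(h) and np.isscalar(s) else out


def temperature_factor(t, p: CoastalParams):
    """Q10 temperature response ``q10 ** ((t - t_ref) / 10)``; 1 at ``t_ref``."""
    out = p.q10 ** ((np.asarray(t, dtype=float) - p.t_ref) / 10.0)
    return float(out) if np.isscalar(t) else out


def zooplankton_mortality(env: Environment, z: float, p: CoastalParams,
                          vicinity: float | None = None) -> float:
    """Specific zooplankton (closure) mortality, 1/d.

    ``m_z' * f_T(t) * vicinity * (gamma*z + beta * eta_Lcarn(j)**2)`` —
    carnivory by juvenile fish and benthic filter feeders concentrated
    near the coast (vicinity index) with a pronounced late-summer peak
    (squared harmonic, maximum at day ``l_carn``) plus a density-dependent
    term that also stands in for non-predation losses.

    ``vicinity`` may be supplied to override the value computed from the
    environment (used by the uniform-carnivory scenario).
    """
    if z < 0.0:
        raise ValueError("zooplankton concentration must be >= 0")
    if vicinity is None:
        vicinity = coastal_vicinity_index(env.h, env.s, p)
    seasonal = seasonal_eta(env.j, p.l_carn) ** 2
    return p.m_z_prime * temperature_factor(env.t, p) * vicinity * (
        p.gamma * z + p.beta * seasonal)


def grazing_half_saturation(k_base: float, vicinity: float) -> float:
    """Herbivorous grazing half-saturation scaled by ``1/2 + vicinity``.

    Offshore (vicinity 0) grazers exploit patchy prey efficiently and the
    effective half-saturation halves; in estuarine water (vicinity 1.5)
    it doubles.  Result lies in ``[k_base/2, 2*k_base]``.
    """
    if k_base <= 0.0:
        raise ValueError("k_base must be > 0")
    if not 0.0 <= vicinity <= 1.5:
        raise ValueError("vicinity must lie in [0, 1.5]")
    return k_base * (0.5 + vicinity)


def viral_host_mortality(v, p: CoastalParams):
    """Host mortality imposed by intracellular virus density, 1/d.

    Smooth step ``m_vir_max * sigma_svirus(1 - v)``: increasing in ``v``,
    half the maximal rate at the critical pathogenic density ``v = 1``
    (the LD50 normalization), saturating at ``m_vir_max`` for heavy
    infection.
    """
    if np.any(np.asarray(v) < 0):
        raise ValueError("virus density must be >= 0")
    return sigmoid_step(np.subtract(1.0, v), p.s_virus) * p.m_vir_max
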