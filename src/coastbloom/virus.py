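"""Intracellular virus dynamics and lysis-flux partitioning.

The virus is tracked as a host-associated intensive density ``v``,
normalized so that ``v = 1`` is the critical pathogenic density (LD50)
at which half the host population is lost per day.  Treating infection
as an intracellular trait — a lysogenic-style simplification — avoids
the extreme host:virion ratios of explicit free-virion models.

``dv/dt = r_ads * n_rep - r_defense - r_mort`` with pluggable rate
terms: saturating adsorption on host biomass, replication limited by
host nutrient status and temperature, inducible antiviral defense
(stronger in healthy hosts), and first-order decay.
"""

from __future__ import annotations

from dataclasses import dataclass

from .params import CoastalParams

__all__ = ["ViralState", "ViralRates", "viral_rate_terms",
           "virus_derivative", "partition_lysis"]


@dataclass
class ViralState:
    """Intracellular virus density; ``v = 1`` is the lethal dose (LD50)."""

    v: float

    def __post_init__(self) -> None:
        if not self.v >= 0.0:
            raise ValueError("virus density must be finite and >= 0")


@dataclass
class ViralRates:
    """The four aggregate rate terms of the virus density equation, 1/d."""

    r_ads: float      # adsorption at the host
    n_rep: float      # replication multiplier (dimensionless)
    r_defense: float  # removal by antiviral host defense
    r_mort: float     # virus decay

    def __post_init__(self) -> None:
        for name in ("r_ads", "n_rep", "r_defense", "r_mort"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name} must be >= 0")


def viral_rate_terms(v: float, host_c: float, nut_lim: float, t: float,
                     p: CoastalParams) -> ViralRates:
    """Evaluate the configured rate forms at the current conditions.

    * ``r_ads = k_ads * host_c / (k_ads_half + host_c)`` — encounter
      saturating in host biomass; zero without hosts.
    * ``n_rep = n_rep_max * nut_lim`` — replication throttled by the
      host's nutrient status (virion synthesis draws on the host's
      intracellular N and P reserves).
    * ``r_defense = k_defense * v * nut_lim`` — inducible defense,
      stronger in nutrient-replete hosts.
    * ``r_mort = k_decay * v`` — first-order decay.

    The temperature argument ``t`` is accepted for interface stability
    of pluggable rate forms; the default forms are temperature-neutral
    (replication and defense scale together with host metabolism, so
    the Q10 factors cancel in the quotient that sets the equilibrium
    infection level).
    """
    if host_c < 0.0:
        raise ValueError("host biomass must be >= 0")
    if not 0.0 <= nut_lim <= 1.0:
        raise ValueError("nut_lim must lie in [0, 1]")
    v = max(float(v), 0.0)
    r_ads = p.k_ads * host_c / (p.k_ads_half + host_c) if host_c > 0.0 else 0.0
    n_rep = p.n_rep_max * nut_lim
    r_defense = p.k_defense * v * nut_lim
    r_mort = p.k_decay * v
    return ViralRates(r_ads=r_ads, n_rep=n_rep, r_defense=r_defense, r_mort=r_mort)


def virus_derivative(v: ViralState | float, rates: ViralRates) -> float:
    """``dv/dt = r_ads * n_rep - r_defense - r_mort`` in 1/d."""
    return rates.r_ads * rates.n_rep - rates.r_defense - rates.r_mort


def partition_lysis(lysis_flux, p: CoastalParams):
    """Split a lysis flux into (detritus, dissolved-organic) parts.

    The detritus pool receives the fraction ``f_det_lysis`` (default
    80%), the dissolved organic pool the remainder; the two parts sum to
    the input exactly.  Works per element on scalars or arrays.
    """
    import numpy as np

    arr = np.asarray(lysis_flux, dtype=float)
    if np.any(arr < 0.0):
        raise ValueError("lysis flux must be >= 0")
    det = p.f_det_lysis * arr
    dom = arr - det
    if arr.ndim == 0:
        return float(det), float(dom)
    return det, dom
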