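"""Model parameters and instantaneous physical drivers.

All parameters of the coastal plankton model live in a single
:class:`CoastalParams` container that is read from, and written back to,
a YAML file.  The canonical default set ships with the package
(``coastbloom/data/default_params.yaml``) and is echoed into every run's
output directory for provenance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

__all__ = ["CoastalParams", "Environment", "default_params_path"]


def default_params_path() -> Path:
    """Path of the canonical default parameter file shipped with the package."""
    return Path(str(resources.files("coastbloom").joinpath("data/default_params.yaml")))


@dataclass
class CoastalParams:
    """All coefficients of the coastal plankton model.

    Grouped as: turbidity parametrization, coastal-vicinity carnivory
    closure, temperature response, viral infection dynamics, and the
    fixed-stoichiometry NPZD backbone.  Units are given per field; rates
    are per day, concentrations mmol per m3.
    """

    # turbidity
    a_spm_prime: float = 2.0  # specific SPM attenuation, 1/m
    alpha: float = 0.05       # background turbidity fraction, -
    h_star: float = 20.0      # resuspension threshold depth, m
    eps_star: float = 1.0e-5  # critical bottom TKE dissipation, W/kg
    l_turb: float = 20.0      # phase day of winter turbidity maximum
    s_depth: float = 0.4      # depth sigmoid steepness, 1/m
    s_sal: float = 1.0        # salinity sigmoid steepness, 1/PSU
    s_coast: float = 31.0     # coastal salinity threshold, PSU
    s_est: float = 12.0       # estuarine salinity threshold, PSU

    # carnivory closure
    l_carn: float = 250.0     # phase day of the carnivory maximum
    m_z_prime: float = 0.025  # mortality amplitude, 1/d
    beta: float = 1.0         # seasonal amplification, -
    gamma: float = 1.5        # density dependence, m3/mmol-C

    # temperature response
    q10: float = 2.0
    t_ref: float = 10.0       # degC

    # viral infection
    s_virus: float = 4.0      # virulence step steepness, -
    m_vir_max: float = 1.0    # mortality proportionality, 1/d
    f_det_lysis: float = 0.8  # lysis fraction to detritus, -
    k_ads: float = 0.4        # adsorption rate scale, 1/d
    k_ads_half: float = 10.0  # host half-saturation, mmol-C/m3
    n_rep_max: float = 3.5    # maximal replication multiplier, -
    k_defense: float = 1.0    # defense removal scale, 1/d
    k_decay: float = 0.3      # virus decay, 1/d

    # NPZD backbone
    mu_max: float = 1.5       # 1/d
    k_din: float = 1.0        # mmol-N/m3
    k_dip: float = 0.0625     # mmol-P/m3
    i_k: float = 25.0         # W/m2
    theta_chl: float = 0.25   # mg CHL per mmol-C
    a_water: float = 0.1      # 1/m
    a_chl_shading: float = 0.02  # 1/(m mg-CHL/m3)
    q_n: float = 16.0 / 106.0  # mol-N/mol-C
    q_p: float = 1.0 / 106.0   # mol-P/mol-C
    g_max: float = 1.5        # 1/d
    k_graz_base: float = 15.0  # mmol-C/m3
    eps_assim: float = 0.3    # -
    r_zoo_basal: float = 0.05  # basal respiration/excretion, 1/d
    f_det_mort: float = 0.8   # zooplankton mortality fraction to detritus
    m_agg: float = 0.0015     # m3/(mmol-C d)
    w_det: float = 3.0        # m/d
    r_det: float = 0.05       # 1/d
    r_dom: float = 0.05       # 1/d
    r_ben: float = 0.02       # 1/d
    f_denit: float = 0.2      # -
    f_burial: float = 0.05    # -

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        """Raise ``ValueError`` on any violated parameter invariant."""
        fractions = ("alpha", "f_det_lysis", "f_det_mort", "eps_assim",
                     "f_denit", "f_burial")
        for name in fractions:
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name}={val!r} must lie in [0, 1]")
        nonneg = ("a_spm_prime", "h_star", "eps_star", "s_depth", "s_sal",
                  "m_z_prime", "beta", "gamma", "q10", "s_virus", "m_vir_max",
                  "k_ads", "k_ads_half", "n_rep_max", "k_defense", "k_decay",
                  "mu_max", "k_din", "k_dip", "i_k", "theta_chl", "a_water",
                  "a_chl_shading", "q_n", "q_p", "g_max", "k_graz_base",
                  "m_agg", "w_det", "r_det", "r_dom", "r_ben", "r_zoo_basal")
        for name in nonneg:
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name} must be >= 0")
        if not self.s_est < self.s_coast:
            raise ValueError("s_est must be below s_coast")
        for name in ("l_turb", "l_carn"):
            if not 1.0 <= getattr(self, name) <= 365.0:
                raise ValueError(f"{name} must lie in [1, 365]")
        if self.k_graz_base <= 0.0:
            raise ValueError("k_graz_base must be > 0")
        if self.f_denit + self.f_burial > 1.0:
            raise ValueError("f_denit + f_burial must not exceed 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CoastalParams":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**raw)

    @classmethod
    def default(cls) -> "CoastalParams":
        return cls.from_yaml(default_params_path())

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    def replace(self, **kwargs) -> "CoastalParams":
        return dataclasses.replace(self, **kwargs)


@dataclass
class Environment:
    """Instantaneous physical drivers at one station.

    Attributes
    ----------
    h : water column depth, m
    s : salinity, PSU
    t : temperature, degC
    i0 : surface irradiance, W/m2
    eps_b : bottom turbulent-kinetic-energy dissipation, W/kg
    j : Julian day, continuous, wrapped mod 365
    """

    h: float
    s: float
    t: float
    i0: float
    eps_b: float
    j: float

    def __post_init__(self) -> None:
        if self.h <= 0.0:
            raise ValueError("depth h must be > 0")
        if self.s < 0.0:
            raise ValueError("salinity must be >= 0")
        if self.eps_b < 0.0:
            raise ValueError("eps_b must be >= 0")
        if self.i0 < 0.0:
            raise ValueError("irradiance must be >= 0")
        self.j = float(self.j) % 365.0
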