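"""Reduced fixed-stoichiometry NPZD-DOM-benthos water-column box model.

One zero-dimensional box per station: dissolved inorganic C/N/P, one
phytoplankton and one zooplankton compartment (fixed Redfield
stoichiometry), detrital and dissolved organic C/N/P, an intracellular
virus density carried by the phytoplankton, and per-area benthic C/N/P
pools coupled through detritus sinking and first-order benthic return
(with a denitrified and a buried fraction).  Depth enters through
vertical light averaging, the benthic exchange scaling and the
turbidity/vicinity parametrizations.

Integration is fixed-step classical RK4 with positivity safeguarded by
clipping (every clipping event is logged with its magnitude).  Because
all internal transfers appear with equal and opposite signs, total C, N
and P per unit area are conserved to floating-point accuracy in a
closed configuration; external exchanges (river loads, denitrification,
burial) are accumulated alongside the state so that
:func:`mass_balance` closes budgets exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import core
from .params import CoastalParams, Environment

__all__ = [
    "EcosystemState", "Trajectory", "light_limitation",
    "nutrient_limitation", "grazing_flux", "ecosystem_derivative",
    "integrate", "mass_balance", "STATE_NAMES",
]

logger = logging.getLogger(__name__)

# state-vector layout; cumulative external-exchange trackers follow the pools
STATE_NAMES = (
    "DIC", "DIN", "DIP", "Phy", "Zoo",
    "DetC", "DetN", "DetP", "DOC", "DON", "DOP",
    "v", "BenC", "BenN", "BenP",
    "cum_denit_N", "cum_burial_C", "cum_burial_N", "cum_burial_P",
    "cum_src_N", "cum_src_P",
)
_IDX = {name: i for i, name in enumerate(STATE_NAMES)}
N_POOLS = 15          # pools subject to positivity
N_STATE = len(STATE_NAMES)


@dataclass
class EcosystemState:
    """Pelagic + benthic pools at one instant.

    Pelagic pools are volumetric (mmol/m3), benthic pools per-area
    (mmol/m2); ``v`` is the dimensionless intracellular virus density.
    """

    DIC: float = 2000.0
    DIN: float = 10.0
    DIP: float = 0.6
    Phy: float = 1.0
    Zoo: float = 0.1
    DetC: float = 1.0
    DetN: float = 16.0 / 106.0
    DetP: float = 1.0 / 106.0
    DOC: float = 1.0
    DON: float = 16.0 / 106.0
    DOP: float = 1.0 / 106.0
    v: float = 0.01
    BenC: float = 100.0
    BenN: float = 100.0 * 16.0 / 106.0
    BenP: float = 100.0 / 106.0

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            val = getattr(self, name)
            if not math.isfinite(val) or val < 0.0:
                raise ValueError(f"pool {name}={val!r} must be finite and >= 0")

    def to_array(self) -> np.ndarray:
        y = np.zeros(N_STATE)
        for name in self.__dataclass_fields__:
            y[_IDX[name]] = getattr(self, name)
        return y

    @classmethod
    def from_array(cls, y: np.ndarray) -> "EcosystemState":
        return cls(**{name: float(y[_IDX[name]]) for name in cls.__dataclass_fields__})


def light_limitation(i0: float, k_total: float, h: float, p: CoastalParams) -> float:
    """Depth-averaged light limitation fraction in [0, 1].

    Mean irradiance over the column, ``Ibar = i0 (1 - exp(-k h))/(k h)``,
    saturating as ``Ibar / (Ibar + i_k)``.
    """
    if k_total <= 0.0 or h <= 0.0:
        raise ValueError("k_total and h must be > 0")
    kh = k_total * h
    if kh < 1e-8:
        ibar = i0
    else:
        ibar = i0 * (1.0 - math.exp(-kh)) / kh
    return ibar / (ibar + p.i_k)


def nutrient_limitation(din: float, dip: float, p: CoastalParams) -> float:
    """Liebig minimum of the Monod terms for DIN and DIP."""
    din = max(din, 0.0)
    dip = max(dip, 0.0)
    return min(din / (p.k_din + din), dip / (p.k_dip + dip))


def grazing_flux(phy: float, zoo: float, vicinity: float, t: float,
                 p: CoastalParams) -> float:
    """Herbivorous grazing, mmol-C/m3/d (Holling II, vicinity-scaled K)."""
    if phy < 0.0 or zoo < 0.0:
        raise ValueError("phy and zoo must be >= 0")
    k = core.grazing_half_saturation(p.k_graz_base, vicinity)
    return p.g_max * core.temperature_factor(t, p) * phy / (k + phy) * zoo


def _rhs(y: np.ndarray, h: float, s: float, t: float, i0: float,
         eps_b: float, j: float, river_n: float, river_p: float,
         p: CoastalParams, vicinity: float | None, n_rep_factor: float,
         ) -> np.ndarray:
    """Right-hand side on the raw state vector.  Units: 1/d per pool unit."""
    (dic, din, dip, phy, zoo, det_c, det_n, det_p, doc, don, dop, v,
     ben_c, ben_n, ben_p) = (max(float(x), 0.0) for x in y[:N_POOLS])

    f_t = p.q10 ** ((t - p.t_ref) / 10.0)
    chl = p.theta_chl * phy

    # light climate: water + SPM + self-shading
    seasonal = (0.5 + 0.5 * math.cos(2.0 * math.pi / 365.0 * (j - p.l_turb)))
    z_exp = min(max(p.s_depth * (h - p.h_star), -500.0), 500.0)
    a_spm = p.a_spm_prime * (p.alpha + 0.5 * (1.0 - p.alpha) * (
        seasonal / (1.0 + math.exp(z_exp)) + eps_b / p.eps_star))
    k_total = p.a_water + a_spm + p.a_chl_shading * chl
    kh = k_total * h
    ibar = i0 if kh < 1e-8 else i0 * (1.0 - math.exp(-kh)) / kh
    f_light = ibar / (ibar + p.i_k)

    f_nut = min(din / (p.k_din + din), dip / (p.k_dip + dip))
    mu = p.mu_max * f_t * f_light * f_nut
    gpp = mu * phy

    if vicinity is None:
        zb = min(max(p.s_depth * (h - p.h_star), -500.0), 500.0)
        zc = min(max(p.s_sal * (s - p.s_coast), -500.0), 500.0)
        ze = min(max(p.s_sal * (s - p.s_est), -500.0), 500.0)
        vic = max(1.0 / (1.0 + math.exp(zb)), 1.0 / (1.0 + math.exp(zc))) \
            + 0.5 / (1.0 + math.exp(ze))
    else:
        vic = vicinity

    k_graz = p.k_graz_base * (0.5 + vic)
    graz = p.g_max * f_t * phy / (k_graz + phy) * zoo
    assim = p.eps_assim * graz
    egest = graz - assim

    zv = min(max(p.s_virus * (1.0 - v), -500.0), 500.0)
    m_vir = p.m_vir_max / (1.0 + math.exp(zv))
    lys = m_vir * phy
    agg = p.m_agg * phy * phy

    eta_c = 0.5 + 0.5 * math.cos(2.0 * math.pi / 365.0 * (j - p.l_carn))
    m_z = p.m_z_prime * f_t * vic * (p.gamma * zoo + p.beta * eta_c * eta_c)
    zoo_mort = m_z * zoo
    zoo_basal = p.r_zoo_basal * f_t * zoo  # maintenance metabolism, to inorganic

    det_to_dom = p.r_det
    sink = p.w_det / h
    remin = p.r_dom
    ben_flux_c = p.r_ben * ben_c
    ben_flux_n = p.r_ben * ben_n
    ben_flux_p = p.r_ben * ben_p

    f_dl = p.f_det_lysis
    f_dm = p.f_det_mort
    qn, qp = p.q_n, p.q_p

    det_in_c = egest + f_dl * lys + agg + f_dm * zoo_mort
    dom_in_c = (1.0 - f_dl) * lys + (1.0 - f_dm) * zoo_mort

    dy = np.zeros(N_STATE)
    dy[0] = -gpp + remin * doc + (1.0 - p.f_burial) * ben_flux_c / h + zoo_basal
    dy[1] = (-qn * gpp + remin * don + qn * zoo_basal
             + (1.0 - p.f_denit - p.f_burial) * ben_flux_n / h + river_n)
    dy[2] = (-qp * gpp + remin * dop + qp * zoo_basal
             + (1.0 - p.f_burial) * ben_flux_p / h + river_p)
    dy[3] = gpp - graz - lys - agg
    dy[4] = assim - zoo_mort - zoo_basal
    dy[5] = det_in_c - det_to_dom * det_c - sink * det_c
    dy[6] = qn * det_in_c - det_to_dom * det_n - sink * det_n
    dy[7] = qp * det_in_c - det_to_dom * det_p - sink * det_p
    dy[8] = dom_in_c + det_to_dom * det_c - remin * doc
    dy[9] = qn * dom_in_c + det_to_dom * det_n - remin * don
    dy[10] = qp * dom_in_c + det_to_dom * det_p - remin * dop

    # virus density (intensive, host-associated)
    r_ads = p.k_ads * phy / (p.k_ads_half + phy) if phy > 0.0 else 0.0
    n_rep = p.n_rep_max * f_nut * n_rep_factor
    dy[11] = r_ads * n_rep - p.k_defense * v * f_nut - p.k_decay * v

    dy[12] = p.w_det * det_c - ben_flux_c
    dy[13] = p.w_det * det_n - ben_flux_n
    dy[14] = p.w_det * det_p - ben_flux_p

    # external-exchange trackers (per-area units, mmol/m2/d)
    dy[15] = p.f_denit * ben_flux_n
    dy[16] = p.f_burial * ben_flux_c
    dy[17] = p.f_burial * ben_flux_n
    dy[18] = p.f_burial * ben_flux_p
    dy[19] = river_n * h
    dy[20] = river_p * h
    return dy


def ecosystem_derivative(state: EcosystemState | np.ndarray, env: Environment,
                         p: CoastalParams, *, river_n: float = 0.0,
                         river_p: float = 0.0, vicinity: float | None = None,
                         n_rep_factor: float = 1.0) -> np.ndarray:
    """Full right-hand side d(state)/dt for one station.

    ``vicinity`` overrides the coastal-vicinity index (uniform-carnivory
    scenario); ``n_rep_factor = 0`` switches off viral replication
    (no-virus scenario).  Raises on non-finite output, naming the
    offending term.
    """
    y = state.to_array() if isinstance(state, EcosystemState) else np.asarray(state, float)
    dy = _rhs(y, env.h, env.s, env.t, env.i0, env.eps_b, env.j,
              river_n, river_p, p, vicinity, n_rep_factor)
    if not np.all(np.isfinite(dy)):
        bad = [STATE_NAMES[i] for i in np.flatnonzero(~np.isfinite(dy))]
        raise ArithmeticError(f"non-finite derivative for {bad}")
    return dy


@dataclass
class Trajectory:
    """Stored model output at regular intervals for one station/run."""

    station_id: str
    times: np.ndarray               # days since run start
    states: np.ndarray              # (n_times, N_STATE)
    h: float
    params: CoastalParams
    scenario: str = "reference"
    clip_events: int = 0
    clip_magnitude: float = 0.0     # total mass-equivalent added by clipping

    @property
    def chl(self) -> np.ndarray:
        """Diagnostic chlorophyll, mg/m3."""
        return self.params.theta_chl * self.states[:, _IDX["Phy"]]

    def pool(self, name: str) -> np.ndarray:
        return self.states[:, _IDX[name]]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(STATE_NAMES))
        df.insert(0, "time", self.times)
        df.insert(0, "station_id", self.station_id)
        df["CHL"] = self.chl
        df["scenario"] = self.scenario
        return df


def integrate(state0: EcosystemState, forcing, dt: float, horizon: float,
              p: CoastalParams, *, scenario: str = "reference",
              vicinity: float | None = None, n_rep_factor: float = 1.0,
              output_every: float = 1.5) -> Trajectory:
    """Fixed-step RK4 integration over ``horizon`` days.

    ``forcing`` is a :class:`~coastbloom.forcing.ForcingSeries`; its
    (one-year) record is repeated periodically, which implements the
    spin-up convention of cycling year-1 forcing.  States are stored
    every ``output_every`` days (default 1.5).  Negative pools produced
    by truncation error are clipped to zero and logged.
    """
    if dt <= 0.0:
        raise ValueError("dt must be > 0")
    n_steps = int(round(horizon / dt))
    if abs(n_steps * dt - horizon) > 1e-9 * max(horizon, 1.0):
        raise ValueError("horizon must be an integer multiple of dt")
    every = int(round(output_every / dt))
    if abs(every * dt - output_every) > 1e-9:
        raise ValueError("dt must divide output_every")

    # pre-sample forcing on the half-step grid (periodic in the record)
    t_half = np.arange(2 * n_steps + 1) * (dt / 2.0)
    cols = forcing.sample(t_half)   # dict of arrays: s, t, i0, eps_b, river_n, river_p
    s_a, t_a, i0_a = cols["s"], cols["t"], cols["i0"]
    eps_a, rn_a, rp_a = cols["eps_b"], cols["river_n"], cols["river_p"]
    j_a = t_half % 365.0
    h = forcing.h

    y = state0.to_array()
    out_times = [0.0]
    out_states = [y.copy()]
    clip_events = 0
    clip_mag = 0.0

    for k in range(n_steps):
        i2 = 2 * k
        k1 = _rhs(y, h, s_a[i2], t_a[i2], i0_a[i2], eps_a[i2], j_a[i2],
                  rn_a[i2], rp_a[i2], p, vicinity, n_rep_factor)
        ym = y + 0.5 * dt * k1
        k2 = _rhs(ym, h, s_a[i2 + 1], t_a[i2 + 1], i0_a[i2 + 1], eps_a[i2 + 1],
                  j_a[i2 + 1], rn_a[i2 + 1], rp_a[i2 + 1], p, vicinity, n_rep_factor)
        ym = y + 0.5 * dt * k2
        k3 = _rhs(ym, h, s_a[i2 + 1], t_a[i2 + 1], i0_a[i2 + 1], eps_a[i2 + 1],
                  j_a[i2 + 1], rn_a[i2 + 1], rp_a[i2 + 1], p, vicinity, n_rep_factor)
        ym = y + dt * k3
        k4 = _rhs(ym, h, s_a[i2 + 2], t_a[i2 + 2], i0_a[i2 + 2], eps_a[i2 + 2],
                  j_a[i2 + 2], rn_a[i2 + 2], rp_a[i2 + 2], p, vicinity, n_rep_factor)
        y = y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)

        if not np.all(np.isfinite(y)):
            bad = [STATE_NAMES[i] for i in np.flatnonzero(~np.isfinite(y))]
            raise RuntimeError(
                f"integration unstable at step {k} (t={k * dt:.3f} d): "
                f"non-finite pools {bad}")

        neg = y[:N_POOLS] < 0.0
        if neg.any():
            mag = float(-y[:N_POOLS][neg].sum())
            if mag > 1e-12:
                clip_events += int(neg.sum())
                clip_mag += mag
                logger.debug("clipped %d negative pool(s) at step %d, total %.3e",
                             int(neg.sum()), k, mag)
            y[:N_POOLS][neg] = 0.0

        if (k + 1) % every == 0:
            out_times.append((k + 1) * dt)
            out_states.append(y.copy())

    if clip_events:
        logger.info("positivity clipping: %d events, total magnitude %.3e",
                    clip_events, clip_mag)
    return Trajectory(station_id=forcing.station_id,
                      times=np.asarray(out_times),
                      states=np.asarray(out_states), h=h, params=p,
                      scenario=scenario, clip_events=clip_events,
                      clip_magnitude=clip_mag)


def _totals(y: np.ndarray, h: float, p: CoastalParams) -> dict[str, float]:
    """Per-area elemental totals (mmol/m2) of the pelagic + benthic pools."""
    g = lambda n: float(y[_IDX[n]])
    tot_c = h * (g("DIC") + g("Phy") + g("Zoo") + g("DetC") + g("DOC")) + g("BenC")
    tot_n = h * (g("DIN") + p.q_n * (g("Phy") + g("Zoo")) + g("DetN") + g("DON")) \
        + g("BenN")
    tot_p = h * (g("DIP") + p.q_p * (g("Phy") + g("Zoo")) + g("DetP") + g("DOP")) \
        + g("BenP")
    return {"C": tot_c, "N": tot_n, "P": tot_p}


def mass_balance(traj: Trajectory) -> pd.DataFrame:
    """Per-element budget: storage change - (sources - sinks) = residual.

    Sources are the cumulated river loads; sinks are denitrification
    (N only) and burial.  Residuals are reported absolute (mmol/m2) and
    relative to the initial standing stock; clipping during integration
    is the only process that can produce a nonzero residual.
    """
    p = traj.params
    t0, t1 = _totals(traj.states[0], traj.h, p), _totals(traj.states[-1], traj.h, p)
    y0, y1 = traj.states[0], traj.states[-1]
    d = lambda n: float(y1[_IDX[n]] - y0[_IDX[n]])
    rows = []
    for elem, src, snk in (
            ("C", 0.0, d("cum_burial_C")),
            ("N", d("cum_src_N"), d("cum_denit_N") + d("cum_burial_N")),
            ("P", d("cum_src_P"), d("cum_burial_P"))):
        storage = t1[elem] - t0[elem]
        residual = storage - (src - snk)
        rows.append({"element": elem, "initial": t0[elem], "final": t1[elem],
                     "sources": src, "sinks": snk, "residual": residual,
                     "rel_residual": residual / t0[elem] if t0[elem] else np.nan})
    return pd.DataFrame(rows)
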