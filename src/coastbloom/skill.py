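"""Model-data comparison: windowed best-match pairing, log-transform
Taylor-diagram statistics, and seasonal pooling.

The matcher mirrors monitoring practice on a tidal shelf: for each
observation event the best model value within a symmetric 3-day window
is selected (minimal absolute log ratio by default), absorbing phase
lags from day-night and tidal cycles.  Second-order error statistics
(correlation, normalized standard deviation, centered RMSD) are
computed on natural-log values; the mean-normalized bias on raw values,
so it reads directly as a percentage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SkillStats", "match_observations", "taylor_statistics",
           "pool_seasonal", "season_of_day"]


@dataclass
class SkillStats:
    """Taylor-diagram coordinates of one model-data comparison.

    ``bias_norm``: (mean(model) - mean(obs)) / mean(obs);
    ``rmsd_norm``: centered RMSD / STD(obs) — the distance from the
    reference point in the Taylor diagram; ``std_norm``:
    STD(model)/STD(obs), the radial coordinate; ``corr``: Pearson
    correlation, the angular coordinate.
    """

    bias_norm: float
    rmsd_norm: float
    std_norm: float
    corr: float
    n_pairs: int
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if self.rmsd_norm < 0 or self.std_norm < 0:
            raise ValueError("rmsd_norm and std_norm must be >= 0")
        if np.isfinite(self.corr) and abs(self.corr) > 1.0 + 1e-12:
            raise ValueError("|corr| must be <= 1")

    @property
    def taylor_azimuth(self) -> float:
        """Angle in the Taylor diagram, ``arccos(corr)`` in radians."""
        return float(np.arccos(np.clip(self.corr, -1.0, 1.0)))

    @property
    def taylor_radius(self) -> float:
        return self.std_norm


def match_observations(model_times, model_values, obs_times, obs_values,
                       window: float = 3.0, mode: str = "log_ratio",
                       ) -> tuple[pd.DataFrame, int]:
    """Pair each observation with the best model value within a window.

    The window is symmetric: model outputs within ``+-window/2`` days of
    the event qualify.  ``mode='log_ratio'`` picks the candidate with
    minimal ``|log(model) - log(obs)|`` (consistent with log-transformed
    error statistics); ``mode='nearest_time'`` picks the one closest in
    time.  Events with no candidate are dropped and counted.

    Returns a DataFrame with columns ``time, obs, model`` and the number
    of dropped events.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    if mode not in ("log_ratio", "nearest_time"):
        raise ValueError("mode must be 'log_ratio' or 'nearest_time'")
    mt = np.asarray(model_times, float)
    mv = np.asarray(model_values, float)
    rows, dropped = [], 0
    half = window / 2.0
    for t_obs, v_obs in zip(np.asarray(obs_times, float),
                            np.asarray(obs_values, float)):
        lo, hi = np.searchsorted(mt, [t_obs - half, t_obs + half + 1e-12])
        cand_t, cand_v = mt[lo:hi], mv[lo:hi]
        if mode == "log_ratio":
            ok = cand_v > 0
            cand_t, cand_v = cand_t[ok], cand_v[ok]
        if cand_v.size == 0 or (mode == "log_ratio" and v_obs <= 0):
            dropped += 1
            continue
        if mode == "log_ratio":
            k = int(np.argmin(np.abs(np.log(cand_v) - np.log(v_obs))))
        else:
            k = int(np.argmin(np.abs(cand_t - t_obs)))
        rows.append({"time": t_obs, "obs": v_obs, "model": cand_v[k]})
    return pd.DataFrame(rows, columns=["time", "obs", "model"]), dropped


def taylor_statistics(model, obs, log_transform: bool = True,
                      bias_on_log: bool = False) -> SkillStats:
    """Compute Taylor-diagram skill statistics for paired values.

    With ``log_transform`` on (the default), correlation, normalized
    STD and centered RMSD are computed on natural logs and nonpositive
    pairs are excluded (and counted); the bias stays on raw values
    unless ``bias_on_log``.  The Taylor identity
    ``rmsd_c^2 = std_m^2 + std_o^2 - 2 std_m std_o corr`` holds exactly
    for the centered statistics.
    """
    m = np.asarray(model, float)
    o = np.asarray(obs, float)
    if m.shape != o.shape:
        raise ValueError("model and obs must have equal length")
    n_excluded = 0
    if log_transform:
        ok = (m > 0) & (o > 0)
        n_excluded = int((~ok).sum())
        m, o = m[ok], o[ok]
    if m.size < 2:
        raise ValueError("need at least 2 valid pairs")

    bias = (float(np.log(m).mean() - np.log(o).mean()) if bias_on_log
            else float(m.mean() - o.mean()) / float(o.mean()))

    x = np.log(m) if log_transform else m
    y = np.log(o) if log_transform else o
    std_m = float(x.std())
    std_o = float(y.std())
    if std_o == 0.0:
        raise ValueError("observations have zero variance")
    dx, dy = x - x.mean(), y - y.mean()
    rmsd_c = float(np.sqrt(np.mean((dx - dy) ** 2)))
    corr = (float(np.dot(dx, dy) / (len(dx) * std_m * std_o))
            if std_m > 0 else np.nan)
    return SkillStats(bias_norm=bias, rmsd_norm=rmsd_c / std_o,
                      std_norm=std_m / std_o, corr=corr,
                      n_pairs=int(m.size), n_excluded=n_excluded)


def season_of_day(j) -> np.ndarray:
    """Meteorological season (DJF/MAM/JJA/SON) from day-of-year."""
    j = np.asarray(j, float) % 365.0
    out = np.where(j < 59, "DJF",
                   np.where(j < 151, "MAM",
                            np.where(j < 243, "JJA",
                                     np.where(j < 334, "SON", "DJF"))))
    return out


def pool_seasonal(pairs: pd.DataFrame, log_transform: bool = True,
                  ) -> dict[str, SkillStats]:
    """Seasonally pooled skill: statistics on pooled pairs, not averaged stats.

    ``pairs`` needs columns ``time`` (days), ``model`` and ``obs``;
    events are grouped by meteorological season of their day-of-year and
    one :class:`SkillStats` computed per group.
    """
    df = pairs.assign(season=season_of_day(pairs["time"].to_numpy()))
    out = {}
    for season, grp in df.groupby("season", sort=False):
        if len(grp) >= 2:
            out[season] = taylor_statistics(grp["model"].to_numpy(),
                                            grp["obs"].to_numpy(),
                                            log_transform=log_transform)
    return out
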