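"""Run configuration and output writing.

A run is fully described by a YAML config (:class:`RunConfig`); every
output directory receives the trajectories as tidy CSV, JSON summaries,
an echo of the parameter file and the resolved config, and a log file —
enough to re-run the experiment bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .params import CoastalParams, default_params_path

__all__ = ["RunConfig", "load_config", "write_outputs", "SCHEMA_VERSION"]

SCHEMA_VERSION = "1"

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated configuration of one experiment run."""

    params_file: str = ""                 # empty: packaged defaults
    n_stations: int = 8
    h_range: tuple = (5.0, 50.0)
    s_range: tuple = (25.0, 34.0)
    scenarios: list = field(default_factory=lambda: ["reference"])
    spinup_years: int = 2
    eval_years: int = 1
    dt: float = 0.05
    output_every: float = 1.5
    seed: int = 0
    out_dir: str = "runs/out"

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        n = round(self.output_every / self.dt)
        if abs(n * self.dt - self.output_every) > 1e-9:
            raise ValueError("dt must divide the output cadence")
        if self.params_file and not Path(self.params_file).exists():
            raise FileNotFoundError(self.params_file)
        for name in self.scenarios:
            if name not in ("reference", "no_virus", "uniform_carnivory"):
                raise ValueError(f"unknown scenario {name!r}")

    def load_params(self) -> CoastalParams:
        if self.params_file:
            return CoastalParams.from_yaml(self.params_file)
        return CoastalParams.default()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["h_range"] = list(d["h_range"])
        d["s_range"] = list(d["s_range"])
        return d


def load_config(path: str | Path) -> RunConfig:
    """Read a YAML run config; unknown keys are rejected, defaults filled."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "h_range" in raw:
        raw["h_range"] = tuple(raw["h_range"])
    if "s_range" in raw:
        raw["s_range"] = tuple(raw["s_range"])
    return RunConfig(**raw)


def write_outputs(result, out_dir: str | Path, config: RunConfig | None = None,
                  summary: dict | None = None) -> Path:
    """Write an :class:`~coastbloom.experiments.ExperimentResult` to disk.

    Creates ``out_dir`` if missing; writes one tidy CSV per scenario,
    the parameter echo, the resolved config, a JSON summary stamped
    with the schema version, and forcing CSVs for provenance.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = (config.load_params() if config is not None
              else next(iter(next(iter(result.trajectories.values())).values())).params)
    params.to_yaml(out / "params_echo.yaml")
    if config is not None:
        with open(out / "config_echo.yaml", "w") as fh:
            yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
    for scenario, per_station in result.trajectories.items():
        import pandas as pd

        df = pd.concat([traj.to_dataframe() for traj in per_station.values()],
                       ignore_index=True)
        df.to_csv(out / f"trajectories_{scenario}.csv", index=False,
                  float_format="%.10g")
    for station in result.transect:
        station.to_dataframe().to_csv(out / f"forcing_{station.station_id}.csv",
                                      index=False, float_format="%.10g")
    payload = {"schema_version": SCHEMA_VERSION, "summary": summary or {}}
    with open(out / "summary.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    logger.info("wrote outputs to %s", out)
    return out
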