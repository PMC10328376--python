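"""Configuration loading, measurement-table IO and run manifests.

One stable configuration dialect (YAML) holds the full simulation
configuration; unknown keys are rejected by name so that typos never
silently fall back to defaults. Measurement tables are plain CSV in the
canonical schema ``treatment,timepoint_min,cell_length_um,
nucleus_position_um`` with an optional column mapping for externally
produced files.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, Optional

import pandas as pd
import yaml

from .params import CellConfig, KineticParams, ParameterError, SimulationConfig
from .stats import MEASUREMENT_COLUMNS

__all__ = [
    "ConfigError",
    "load_config",
    "dump_config",
    "read_measurements",
    "write_measurements",
    "RunManifest",
    "load_packaged_kinetics",
    "load_packaged_cell",
]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """A configuration file violates the schema."""


_KINETIC_KEYS = set(KineticParams.field_names())
_CELL_KEYS = {"length", "nucleus_radius", "nucleus_diffusion_coeff", "nucleus_init_frac"}
_TOP_KEYS = {
    "dt",
    "duration",
    "n_runs",
    "seed",
    "record_trajectory",
    "trajectory_stride",
    "resample_interval",
    "kinetics",
    "cell",
}


def _check_keys(mapping: dict, allowed: set, context: str, errors: list) -> None:
    for key in mapping:
        if key not in allowed:
            errors.append(f"unknown key {context}{key!r}")


def _config_from_dict(raw: dict) -> SimulationConfig:
    if not isinstance(raw, dict):
        raise ConfigError("configuration root must be a mapping")
    errors: list = []
    _check_keys(raw, _TOP_KEYS, "", errors)
    kin_raw = raw.get("kinetics", {})
    cell_raw = raw.get("cell", {})
    if not isinstance(kin_raw, dict):
        errors.append("'kinetics' must be a mapping")
        kin_raw = {}
    if not isinstance(cell_raw, dict):
        errors.append("'cell' must be a mapping")
        cell_raw = {}
    _check_keys(kin_raw, _KINETIC_KEYS, "kinetics.", errors)
    _check_keys(cell_raw, _CELL_KEYS, "cell.", errors)
    if errors:
        raise ConfigError("; ".join(errors))
    kin_full = {k: 0.0 for k in _KINETIC_KEYS}
    kin_full.update({k: float(v) for k, v in kin_raw.items()})
    try:
        kinetics = KineticParams(**kin_full)
        cell = CellConfig(**cell_raw)
        top = {k: v for k, v in raw.items() if k not in ("kinetics", "cell")}
        return SimulationConfig(kinetics=kinetics, cell=cell, **top)
    except (ParameterError, TypeError) as exc:
        raise ConfigError(str(exc)) from exc


def load_config(path) -> SimulationConfig:
    """Load and validate a YAML simulation configuration.

    Missing keys take the model defaults (dt = 0.01 s, 30 min, 500
    runs); unknown keys raise :class:`ConfigError` naming every
    offending key.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    try:
        return _config_from_dict(raw)
    except ConfigError as exc:
        raise ConfigError(f"{path}: {exc}") from None


def config_to_dict(config: SimulationConfig) -> dict:
    d = {
        "dt": config.dt,
        "duration": config.duration,
        "n_runs": config.n_runs,
        "seed": config.seed,
        "record_trajectory": config.record_trajectory,
        "trajectory_stride": config.trajectory_stride,
        "resample_interval": config.resample_interval,
        "kinetics": config.kinetics.as_dict(),
        "cell": dataclasses.asdict(config.cell),
    }
    return d


def dump_config(config: SimulationConfig, path) -> None:
    """Write a configuration (e.g. fitted kinetics) back to YAML."""
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


def load_packaged_kinetics() -> KineticParams:
    """The shipped illustrative calibrated kinetics."""
    text = resources.files("phuzsim").joinpath("data/calibrated.yaml").read_text()
    raw = yaml.safe_load(text)
    return _config_from_dict(raw).kinetics


def load_packaged_cell() -> CellConfig:
    """Cell geometry/diffusion matching the shipped calibration."""
    text = resources.files("phuzsim").joinpath("data/calibrated.yaml").read_text()
    raw = yaml.safe_load(text)
    return _config_from_dict(raw).cell


# ---------------------------------------------------------------------------
# Measurement tables
# ---------------------------------------------------------------------------


def read_measurements(
    path, column_mapping: Optional[Dict[str, str]] = None
) -> pd.DataFrame:
    """Read an S1-style measurement CSV into the canonical schema.

    ``column_mapping`` maps canonical column names to the file's column
    names for externally produced tables. Rows violating the geometry
    invariants (0 <= position <= length, length > 0) are dropped with a
    per-row log message; missing required columns raise naming them.
    """
    df = pd.read_csv(path)
    if column_mapping:
        rename = {src: dst for dst, src in column_mapping.items()}
        df = df.rename(columns=rename)
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigError(f"{path}: missing required columns {missing}")
    df = df[list(MEASUREMENT_COLUMNS)].copy()
    length = pd.to_numeric(df["cell_length_um"], errors="coerce")
    pos = pd.to_numeric(df["nucleus_position_um"], errors="coerce")
    ok = (length > 0) & (pos >= 0) & (pos <= length)
    ok = ok.fillna(False)
    for idx in df.index[~ok]:
        logger.warning(
            "%s: row %d rejected (length=%r, position=%r)",
            path, idx, df.loc[idx, "cell_length_um"], df.loc[idx, "nucleus_position_um"],
        )
    out = df[ok].reset_index(drop=True)
    out["cell_length_um"] = length[ok].to_numpy()
    out["nucleus_position_um"] = pos[ok].to_numpy()
    return out


def write_measurements(df: pd.DataFrame, path) -> None:
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigError(f"measurement table missing columns {missing}")
    df[list(MEASUREMENT_COLUMNS)].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Run manifests
# ---------------------------------------------------------------------------


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Record of one CLI invocation, sufficient to re-run it exactly."""

    subcommand: str
    config: dict
    master_seed: Optional[int] = None
    package_version: str = ""
    inputs: Dict[str, str] = field(default_factory=dict)
    outputs: Dict[str, str] = field(default_factory=dict)
    started: str = ""
    finished: str = ""

    def __post_init__(self) -> None:
        if not self.package_version:
            from . import __version__

            self.package_version = __version__
        if not self.started:
            self.started = _dt.datetime.now(_dt.timezone.utc).isoformat()

    def add_input(self, path) -> None:
        self.inputs[str(path)] = _sha256(path)

    def add_output(self, path) -> None:
        self.outputs[str(path)] = _sha256(path)

    def write(self, path) -> None:
        self.finished = _dt.datetime.now(_dt.timezone.utc).isoformat()
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")
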