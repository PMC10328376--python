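"""Phase-space sweeps of centering efficiency.

Sweeps a regular grid over two axes — cell length and/or any kinetic
parameter — running an endpoint ensemble per grid cell and recording the
fraction of nuclei that finish inside the central window of the cell.
Cells are classified as "centered" when that fraction strictly exceeds a
threshold (80% within the middle 20% by default), reproducing the
centering/non-centering phase diagram over cell length and
polymerization rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple, Union

import numpy as np
import pandas as pd

from .params import KineticParams, ParameterError, SimulationConfig
from .simulate import EndpointEnsemble, run_ensemble
from .stats import off_center_fraction

__all__ = ["AxisSpec", "SweepConfig", "SweepResult", "centering_fraction", "sweep"]

#: Axis name addressing the cell length rather than a kinetic field.
CELL_LENGTH_AXIS = "cell_length"


@dataclass(frozen=True)
class AxisSpec:
    """One sweep axis: parameter name and a regular grid over [min, max]."""

    name: str
    minimum: float
    maximum: float
    n_steps: int

    def __post_init__(self) -> None:
        valid = (CELL_LENGTH_AXIS,) + KineticParams.field_names()
        if self.name not in valid:
            raise ParameterError(
                f"unknown sweep axis {self.name!r}; expected one of {valid}"
            )
        if self.n_steps < 2:
            raise ParameterError("each axis needs n_steps >= 2")
        if not (self.maximum > self.minimum):
            raise ParameterError("axis maximum must exceed minimum")

    @property
    def values(self) -> np.ndarray:
        return np.linspace(self.minimum, self.maximum, self.n_steps)

    @classmethod
    def parse(cls, text: str) -> "AxisSpec":
        """Parse ``name:min:max:n`` (the CLI axis syntax)."""
        parts = text.split(":")
        if len(parts) != 4:
            raise ParameterError(f"axis spec must be name:min:max:n, got {text!r}")
        return cls(parts[0], float(parts[1]), float(parts[2]), int(parts[3]))


@dataclass(frozen=True)
class SweepConfig:
    """Two sweep axes plus ensemble size and classification rule."""

    axis1: AxisSpec
    axis2: AxisSpec
    runs_per_cell: int = 100
    centering_window: float = 0.2
    centered_threshold: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.runs_per_cell < 1:
            raise ParameterError("runs_per_cell must be >= 1")
        if not (0.0 < self.centering_window < 1.0):
            raise ParameterError("centering_window must lie in (0, 1)")
        if not (0.0 < self.centered_threshold < 1.0):
            raise ParameterError("centered_threshold must lie in (0, 1)")
        if self.axis1.name == self.axis2.name:
            raise ParameterError("the two sweep axes must differ")


def centering_fraction(
    ensemble: Union[EndpointEnsemble, np.ndarray], window: float = 0.2
) -> float:
    """Fraction of ensemble endpoints inside the central window
    (complement of the off-center fraction)."""
    positions = (
        ensemble.normalized_positions
        if isinstance(ensemble, EndpointEnsemble)
        else np.asarray(ensemble, dtype=float)
    )
    return 1.0 - off_center_fraction(positions, window)


@dataclass
class SweepResult:
    """Centering-fraction matrix over the sweep grid."""

    axis1: AxisSpec
    axis2: AxisSpec
    fractions: np.ndarray  # shape (axis1.n_steps, axis2.n_steps)
    centered_threshold: float

    @property
    def centered(self) -> np.ndarray:
        """Boolean classification: fraction strictly above threshold."""
        return self.fractions > self.centered_threshold

    def to_dataframe(self) -> pd.DataFrame:
        a, b = np.meshgrid(self.axis1.values, self.axis2.values, indexing="ij")
        return pd.DataFrame(
            {
                self.axis1.name: a.ravel(),
                self.axis2.name: b.ravel(),
                "centering_fraction": self.fractions.ravel(),
                "centered": self.centered.ravel(),
            }
        )

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _cell_seed(master: int, i: int, j: int) -> int:
    ss = np.random.SeedSequence(entropy=master, spawn_key=(i, j))
    return int(ss.generate_state(1, dtype=np.uint32)[0]) % (2**31)


def sweep(config: SweepConfig, sim_config: SimulationConfig) -> SweepResult:
    """Run one endpoint ensemble per grid cell and record centering.

    Axis values overwrite the corresponding field of ``sim_config`` (or
    the cell length); cell lengths on the grid are fixed, not sampled.
    Deterministic under ``config.seed``.
    """
    for ax in (config.axis1, config.axis2):
        if ax.name == CELL_LENGTH_AXIS and ax.minimum <= 2.0 * sim_config.cell.nucleus_radius:
            raise ParameterError(
                "cell-length axis values must exceed the nucleus diameter"
            )
    v1 = config.axis1.values
    v2 = config.axis2.values
    fractions = np.empty((len(v1), len(v2)))
    for i, a in enumerate(v1):
        for j, b in enumerate(v2):
            cfg = sim_config.replace(
                n_runs=config.runs_per_cell, seed=_cell_seed(config.seed, i, j)
            )
            kin = cfg.kinetics
            cell = cfg.cell
            for ax, val in ((config.axis1, a), (config.axis2, b)):
                if ax.name == CELL_LENGTH_AXIS:
                    cell = cell.replace(length=float(val))
                else:
                    kin = kin.replace(**{ax.name: float(val)})
            cfg = cfg.replace(kinetics=kin, cell=cell)
            ens = run_ensemble(cfg)
            fractions[i, j] = centering_fraction(ens, config.centering_window)
    return SweepResult(config.axis1, config.axis2, fractions, config.centered_threshold)
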