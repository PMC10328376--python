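"""Parameter containers for the PhuZ spindle model.

All lengths are in micrometres, times in seconds, speeds in um/s and
diffusion coefficients in um^2/s. Kinetic rates are described by Gaussian
(mean, sd) pairs; every per-run draw is clamped at zero from below
(speeds) or floored at one timestep (durations), since negative speeds
and instantaneous phase switches are unphysical.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "ParameterError",
    "StateError",
    "KineticParams",
    "CellConfig",
    "SimulationConfig",
    "BOLTZMANN_J_PER_K",
    "stokes_einstein_D",
    "default_kinetics",
    "default_cell",
    "default_config",
]

#: Boltzmann constant, J/K (SI 2019 exact value).
BOLTZMANN_J_PER_K = 1.380649e-23


class ParameterError(ValueError):
    """A parameter violates its physical or structural constraints."""


class StateError(ValueError):
    """A simulation state violates the model invariants."""


def stokes_einstein_D(
    radius_um: float, temperature_K: float = 310.0, viscosity_Pa_s: float = 1.0e-3
) -> float:
    """Diffusion coefficient of a sphere from the Stokes-Einstein relation.

    D = k_B T / (6 pi eta r), returned in um^2/s.

    Parameters
    ----------
    radius_um
        Stokes (hydrodynamic) radius of the sphere, um.
    temperature_K
        Absolute temperature, K. Default 310 K (37 C growth conditions).
    viscosity_Pa_s
        Dynamic viscosity of the medium, Pa s. Default is that of water;
        effective cytoplasmic viscosity for um-sized objects is far higher,
        so configurations may override the resulting D directly.
    """
    import math

    if radius_um <= 0 or temperature_K <= 0 or viscosity_Pa_s <= 0:
        raise ParameterError(
            "radius, temperature and viscosity must all be positive; got "
            f"r={radius_um}, T={temperature_K}, eta={viscosity_Pa_s}"
        )
    radius_m = radius_um * 1e-6
    d_m2_per_s = BOLTZMANN_J_PER_K * temperature_K / (6.0 * math.pi * viscosity_Pa_s * radius_m)
    return d_m2_per_s * 1e12  # m^2/s -> um^2/s


_GAUSSIAN_FIELDS = (
    "v_poly",
    "v_depoly",
    "v_cat",
    "t_cat",
    "t_rec",
)


@dataclass(frozen=True)
class KineticParams:
    """Gaussian descriptors of filament dynamic-instability kinetics.

    ``v_poly``/``v_depoly`` act continuously (net growth drift
    ``v_poly - v_depoly``); ``v_cat`` is the additional catastrophic
    depolymerization speed, non-zero only while a filament is in the
    catastrophe phase. ``t_cat`` is the growth duration before catastrophe
    and ``t_rec`` the catastrophe duration before recovery.
    """

    v_poly_mean: float
    v_poly_sd: float
    v_depoly_mean: float
    v_depoly_sd: float
    v_cat_mean: float
    v_cat_sd: float
    t_cat_mean: float
    t_cat_sd: float
    t_rec_mean: float
    t_rec_sd: float

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not (v >= 0.0):  # also rejects NaN
                raise ParameterError(f"KineticParams.{f.name} must be >= 0, got {v!r}")

    @classmethod
    def zero(cls) -> "KineticParams":
        """All rates and variances zero: a completely static spindle."""
        return cls(*([0.0] * 10))

    def replace(self, **kwargs: float) -> "KineticParams":
        return dataclasses.replace(self, **kwargs)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    @staticmethod
    def field_names() -> tuple:
        return tuple(f.name for f in dataclasses.fields(KineticParams))


@dataclass(frozen=True)
class CellConfig:
    """Geometry and nucleus transport properties of one rod-shaped cell.

    ``nucleus_radius`` is the half-length used for collision geometry and
    is configured independently from the Stokes radius that sets the
    diffusion coefficient: the two describe different physics (steric
    contact vs hydrodynamic drag).
    """

    length: float = 3.5
    nucleus_radius: float = 0.5
    nucleus_diffusion_coeff: float = field(
        default_factory=lambda: stokes_einstein_D(1.0)
    )
    nucleus_init_frac: float = 0.9

    def __post_init__(self) -> None:
        if self.nucleus_radius <= 0:
            raise ParameterError(f"nucleus_radius must be > 0, got {self.nucleus_radius}")
        if self.length <= 2.0 * self.nucleus_radius:
            raise ParameterError(
                f"cell length {self.length} must exceed the nucleus diameter "
                f"{2.0 * self.nucleus_radius} (the nucleus must fit inside the cell)"
            )
        if self.nucleus_diffusion_coeff < 0:
            raise ParameterError("nucleus_diffusion_coeff must be >= 0")
        if not (0.0 < self.nucleus_init_frac < 1.0):
            raise ParameterError(
                f"nucleus_init_frac must lie in (0, 1), got {self.nucleus_init_frac}"
            )

    def replace(self, **kwargs: float) -> "CellConfig":
        return dataclasses.replace(self, **kwargs)

    def initial_center(self) -> float:
        """Initial nucleus center, clamped so the nucleus fits in the cell."""
        c = self.nucleus_init_frac * self.length
        return min(max(c, self.nucleus_radius), self.length - self.nucleus_radius)


@dataclass(frozen=True)
class SimulationConfig:
    """Full configuration of a stochastic spindle simulation.

    Defaults follow the model's reference protocol: dt = 0.01 s, 30
    simulated minutes, 500 runs per condition.
    """

    kinetics: KineticParams
    cell: CellConfig = field(default_factory=CellConfig)
    dt: float = 0.01
    duration: float = 1800.0
    n_runs: int = 500
    seed: int = 0
    record_trajectory: bool = False
    trajectory_stride: int = 100
    resample_interval: Optional[float] = None

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ParameterError(f"dt must be > 0, got {self.dt}")
        if self.duration < 0:
            raise ParameterError(f"duration must be >= 0, got {self.duration}")
        if self.duration > 0 and self.duration < self.dt:
            raise ParameterError("duration must be >= dt (or exactly 0)")
        if self.n_runs < 1:
            raise ParameterError(f"n_runs must be >= 1, got {self.n_runs}")
        if self.trajectory_stride < 1:
            raise ParameterError("trajectory_stride must be >= 1")
        if self.resample_interval is not None and self.resample_interval <= 0:
            raise ParameterError("resample_interval must be > 0 when set")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


def default_kinetics() -> KineticParams:
    """Illustrative calibrated kinetics shipped with the package.

    Fitted by the calibration module against the package's synthetic
    control dataset so that a 3.5 um cell centers its nucleus efficiently
    within 30 min while cells a few-fold longer do not. See
    ``phuzsim/data/calibrated.yaml`` and docs/methods.md.
    """
    from .io import load_packaged_kinetics

    return load_packaged_kinetics()


def default_cell(length: float = 3.5) -> CellConfig:
    """Cell geometry with the calibrated nucleus diffusion coefficient."""
    from .io import load_packaged_cell

    return load_packaged_cell().replace(length=length)


def default_config(length: float = 3.5, **kwargs) -> SimulationConfig:
    """Reference simulation protocol with the shipped calibrated kinetics."""
    return SimulationConfig(
        kinetics=default_kinetics(), cell=default_cell(length), **kwargs
    )
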