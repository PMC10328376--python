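"""Synthetic single-cell measurement tables with known ground truth.

Emulates the deposited measurement dataset: per-treatment Gaussian
cell-length populations with nucleus positions produced either by the
simulator (``mode="simulator"``) or by a parametric mixture
(``mode="parametric"``) of a midcell-centered Gaussian and an off-center
uniform component with weight ``w``. The parametric mode exists so the
statistics and calibration stages can be tested with analytically known
off-center fractions, without the simulator in the loop.

Shipped treatment profiles are illustrative: a ~3.5 um control and
progressively elongated populations standing in for cell-wall-antibiotic
and division-inhibited conditions, with mixture weights chosen so the
control's expected off-center fraction is 24% and the strongest
beta-lactam-like condition's is 60%.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .params import CellConfig, KineticParams, ParameterError, SimulationConfig
from .simulate import run_ensemble
from .stats import MEASUREMENT_COLUMNS

__all__ = [
    "TreatmentProfile",
    "FixtureSuite",
    "mixture_weight_for_off_center",
    "expected_off_center",
    "sample_cell_lengths",
    "sample_positions_parametric",
    "generate_measurement_table",
    "default_profiles",
    "make_fixture_suite",
]

_RESAMPLE_LIMIT = 1000


def mixture_weight_for_off_center(
    target: float, center_sd: float, central_width: float = 0.2
) -> float:
    """Mixture weight w giving an expected off-center fraction.

    With the off-center uniform component fully outside the central
    window, the expected off-center fraction is
    ``w + (1 - w) * P(|N(0, sd)| > width/2)``; solve for w.
    """
    if not (0.0 < target < 1.0):
        raise ParameterError("target off-center fraction must lie in (0, 1)")
    p0 = 2.0 * norm.sf(central_width / 2.0, scale=center_sd)
    if target < p0:
        raise ParameterError(
            f"target {target} below the Gaussian component's own off-center "
            f"probability {p0:.3f}; narrow center_sd first"
        )
    return (target - p0) / (1.0 - p0)


@dataclass(frozen=True)
class TreatmentProfile:
    """One treatment condition's cell-length population and (for the
    parametric mode) its normalized-position mixture.

    ``offcenter_lo/hi`` bound the uniform component's support; with
    ``exclude_central`` the central window is cut out of it (a strictly
    off-center component), without it the component is flat across the
    interior — the shape of a division-inhibited population whose nuclei
    are uniform along the cell but excluded from the poles.
    """

    label: str
    length_mean: float
    length_sd: float
    n_cells: int = 250
    mode: str = "parametric"  # or "simulator"
    center_sd: float = 0.08
    offcenter_weight: float = 0.0
    offcenter_lo: float = 0.0
    offcenter_hi: float = 1.0
    exclude_central: bool = True
    central_width: float = 0.2
    noise_sd_um: float = 0.0
    timepoint_min: float = 30.0

    def __post_init__(self) -> None:
        if self.length_mean <= 0 or self.length_sd < 0:
            raise ParameterError("length_mean must be > 0 and length_sd >= 0")
        if self.n_cells < 1:
            raise ParameterError("n_cells must be >= 1")
        if self.mode not in ("parametric", "simulator"):
            raise ParameterError(f"unknown mode {self.mode!r}")
        if not (0.0 <= self.offcenter_weight <= 1.0):
            raise ParameterError("offcenter_weight must lie in [0, 1]")
        if not (0.0 <= self.offcenter_lo < self.offcenter_hi <= 1.0):
            raise ParameterError("need 0 <= offcenter_lo < offcenter_hi <= 1")
        if self.center_sd < 0 or self.noise_sd_um < 0:
            raise ParameterError("center_sd and noise_sd_um must be >= 0")

    def replace(self, **kwargs) -> "TreatmentProfile":
        return dataclasses.replace(self, **kwargs)


def expected_off_center(profile: TreatmentProfile) -> float:
    """Analytic expected off-center fraction of a parametric profile."""
    w = profile.offcenter_weight
    half = profile.central_width / 2.0
    if profile.center_sd > 0:
        p_gauss = 2.0 * norm.sf(half, scale=profile.center_sd)
    else:
        p_gauss = 0.0
    lo, hi = profile.offcenter_lo, profile.offcenter_hi
    if profile.exclude_central:
        p_unif = 1.0
    else:
        total = hi - lo
        inside = max(0.0, min(hi, 0.5 + half) - max(lo, 0.5 - half))
        p_unif = (total - inside) / total
    return w * p_unif + (1.0 - w) * p_gauss


def sample_cell_lengths(
    profile: TreatmentProfile,
    rng: np.random.Generator,
    min_length: float = 1.0,
) -> np.ndarray:
    """Gaussian cell lengths, rejection-resampled above ``min_length``
    (the nucleus diameter by default)."""
    n = profile.n_cells
    out = np.full(n, np.nan)
    need = np.ones(n, dtype=bool)
    for _ in range(_RESAMPLE_LIMIT):
        k = int(need.sum())
        if k == 0:
            return out
        draws = rng.normal(profile.length_mean, profile.length_sd, size=k)
        idx = np.nonzero(need)[0]
        ok = draws > min_length
        out[idx[ok]] = draws[ok]
        need[idx[ok]] = False
    raise ParameterError(
        f"profile {profile.label!r}: could not draw lengths > {min_length} um "
        f"(mean {profile.length_mean}, sd {profile.length_sd})"
    )


def _sample_uniform_component(profile: TreatmentProfile, n: int,
                              rng: np.random.Generator) -> np.ndarray:
    lo, hi = profile.offcenter_lo, profile.offcenter_hi
    half = profile.central_width / 2.0
    out = np.empty(n)
    filled = 0
    for _ in range(_RESAMPLE_LIMIT):
        if filled == n:
            return out
        draws = rng.uniform(lo, hi, size=n - filled)
        if profile.exclude_central:
            draws = draws[np.abs(draws - 0.5) > half]
        out[filled : filled + len(draws)] = draws
        filled += len(draws)
    raise ParameterError("uniform component support is degenerate")


def sample_positions_parametric(
    profile: TreatmentProfile, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Normalized nucleus positions from the two-component mixture."""
    take_unif = rng.random(n) < profile.offcenter_weight
    out = np.empty(n)
    n_u = int(take_unif.sum())
    if n_u:
        out[take_unif] = _sample_uniform_component(profile, n_u, rng)
    n_g = n - n_u
    if n_g:
        if profile.center_sd == 0:
            out[~take_unif] = 0.5
        else:
            g = np.empty(n_g)
            filled = 0
            while filled < n_g:
                draws = 0.5 + rng.normal(0.0, profile.center_sd, size=n_g - filled)
                draws = draws[(draws >= 0.0) & (draws <= 1.0)]
                g[filled : filled + len(draws)] = draws
                filled += len(draws)
            out[~take_unif] = g
    return out


def _profile_seed(seed: int, profile_index: int) -> int:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(profile_index,))
    return int(ss.generate_state(1, dtype=np.uint32)[0]) % (2**31)


def generate_measurement_table(
    profiles: Sequence[TreatmentProfile],
    kinetics: Optional[KineticParams] = None,
    sim_config: Optional[SimulationConfig] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """S1-style measurement table for a list of treatment profiles.

    Parametric profiles draw lengths and mixture positions directly; for
    simulator profiles each cell's position is the endpoint of a full
    stochastic run with its length drawn from the profile's Gaussian.
    Optional measurement noise (``noise_sd_um``) is added to positions
    and clipped back into the cell.
    """
    frames: List[pd.DataFrame] = []
    for idx, profile in enumerate(profiles):
        prof_seed = _profile_seed(seed, idx)
        rng = np.random.default_rng(prof_seed)
        if profile.mode == "simulator":
            if sim_config is None:
                raise ParameterError("simulator mode requires sim_config")
            cfg = sim_config.replace(
                n_runs=profile.n_cells,
                seed=prof_seed,
                kinetics=kinetics if kinetics is not None else sim_config.kinetics,
            )
            ens = run_ensemble(
                cfg, lambda g: g.normal(profile.length_mean, profile.length_sd)
            )
            lengths = ens.cell_lengths
            positions = ens.final_positions
        else:
            min_len = (
                2.0 * sim_config.cell.nucleus_radius if sim_config is not None else 1.0
            )
            lengths = sample_cell_lengths(profile, rng, min_length=min_len)
            positions = sample_positions_parametric(profile, profile.n_cells, rng) * lengths
        if profile.noise_sd_um > 0:
            positions = positions + rng.normal(0.0, profile.noise_sd_um, size=len(positions))
            positions = np.clip(positions, 0.0, lengths)
        frames.append(
            pd.DataFrame(
                {
                    "treatment": profile.label,
                    "timepoint_min": profile.timepoint_min,
                    "cell_length_um": lengths,
                    "nucleus_position_um": positions,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)[list(MEASUREMENT_COLUMNS)]


def default_profiles(n_cells: int = 250) -> List[TreatmentProfile]:
    """Illustrative treatment panel (documented in docs/methods.md).

    Length means/SDs are not measured values; they bracket a ~3.5 um
    control and 2-4x elongated antibiotic-like conditions. Mixture
    weights pin the control's expected off-center fraction at 24% and
    the piperacillin-like condition's at 60%; the division-inhibited
    (SulA-like) profile is uniform across the cell interior.
    """
    return [
        TreatmentProfile(
            "control", 3.5, 0.7, n_cells,
            center_sd=0.08,
            offcenter_weight=mixture_weight_for_off_center(0.24, 0.08),
        ),
        TreatmentProfile(
            "ceftazidime", 7.0, 2.0, n_cells,
            center_sd=0.12,
            offcenter_weight=mixture_weight_for_off_center(0.45, 0.12),
        ),
        TreatmentProfile(
            "piperacillin", 10.0, 3.0, n_cells,
            center_sd=0.12,
            offcenter_weight=mixture_weight_for_off_center(0.60, 0.12),
        ),
        TreatmentProfile(
            "sula_induced", 14.0, 4.0, n_cells,
            offcenter_weight=1.0,
            offcenter_lo=0.1,
            offcenter_hi=0.9,
            exclude_central=False,
        ),
    ]


@dataclass
class FixtureSuite:
    """Deterministic bundle of synthetic datasets plus ground truth."""

    table: pd.DataFrame
    manifest: Dict

    def write(self, out_dir) -> List[Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        written: List[Path] = []
        for label, grp in self.table.groupby("treatment", sort=True):
            path = out_dir / f"synthetic_{label}.csv"
            grp.to_csv(path, index=False, float_format="%.6f")
            written.append(path)
        manifest = dict(self.manifest)
        manifest["files"] = [p.name for p in written] + ["manifest.json"]
        mpath = out_dir / "manifest.json"
        mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        written.append(mpath)
        return written


def make_fixture_suite(
    seed: int = 0,
    n_cells: int = 250,
    profiles: Optional[Sequence[TreatmentProfile]] = None,
    out_dir=None,
) -> FixtureSuite:
    """Generate the canned synthetic datasets (see
    :func:`default_profiles`); byte-identical for identical seeds."""
    profiles = list(profiles) if profiles is not None else default_profiles(n_cells)
    table = generate_measurement_table(profiles, seed=seed)
    manifest = {
        "seed": seed,
        "profiles": [
            {**dataclasses.asdict(p), "expected_off_center": expected_off_center(p)}
            for p in profiles
        ],
    }
    suite = FixtureSuite(table=table, manifest=manifest)
    if out_dir is not None:
        suite.write(out_dir)
    return suite
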