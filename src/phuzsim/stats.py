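"""Single-cell nucleus-position statistics.

Works on measurement tables (one row per cell: length, nucleus position,
treatment label, timepoint) from microscopy-style data or from the
simulator, and on binned normalized-position distributions. The central
quantities are the off-center fraction (nuclei outside the middle 20% of
the cell), the length-mispositioning correlation, and the RMSD between
binned position distributions used as the calibration objective.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

from .params import ParameterError

__all__ = [
    "CellMeasurement",
    "PositionDistribution",
    "measurements_to_frame",
    "normalize_positions",
    "off_center_fraction",
    "position_histogram",
    "rmsd_between_distributions",
    "length_position_correlation",
    "treatment_summary",
]

logger = logging.getLogger(__name__)

#: Canonical measurement-table columns (S1-style schema).
MEASUREMENT_COLUMNS = (
    "treatment",
    "timepoint_min",
    "cell_length_um",
    "nucleus_position_um",
)


@dataclass(frozen=True)
class CellMeasurement:
    """One measured cell: length and nucleus position from the reference
    pole (um), with treatment label and minutes post infection."""

    cell_length: float
    nucleus_position: float
    treatment: str = ""
    timepoint_min: float = 30.0

    def __post_init__(self) -> None:
        if not (self.cell_length > 0):
            raise ParameterError(f"cell_length must be > 0, got {self.cell_length}")
        if not (0.0 <= self.nucleus_position <= self.cell_length):
            raise ParameterError(
                f"nucleus_position {self.nucleus_position} outside "
                f"[0, {self.cell_length}]"
            )


Measurements = Union[pd.DataFrame, Sequence[CellMeasurement]]


def measurements_to_frame(measurements: Measurements) -> pd.DataFrame:
    """Coerce a list of records or a canonical-schema DataFrame."""
    if isinstance(measurements, pd.DataFrame):
        missing = [c for c in MEASUREMENT_COLUMNS if c not in measurements.columns]
        if missing:
            raise ParameterError(f"measurement table missing columns: {missing}")
        return measurements
    rows = [
        (m.treatment, m.timepoint_min, m.cell_length, m.nucleus_position)
        for m in measurements
    ]
    return pd.DataFrame(rows, columns=list(MEASUREMENT_COLUMNS))


def normalize_positions(measurements: Measurements, fold: bool = False) -> np.ndarray:
    """Nucleus positions divided by cell length, in [0, 1].

    Rows with non-positive length or positions outside the cell are
    rejected with a logged warning rather than raising, mirroring how a
    measured table with a few bad rows is handled in practice. With
    ``fold=True`` positions are reflected about midcell onto [0, 0.5]
    for pole-symmetric analyses.
    """
    df = measurements_to_frame(measurements)
    if len(df) == 0:
        raise ParameterError("no measurements supplied")
    length = df["cell_length_um"].to_numpy(dtype=float)
    pos = df["nucleus_position_um"].to_numpy(dtype=float)
    ok = (length > 0) & (pos >= 0) & (pos <= length)
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning("rejected %d/%d measurement rows with invalid geometry", n_bad, len(df))
    p = pos[ok] / length[ok]
    if len(p) == 0:
        raise ParameterError("all measurement rows were rejected")
    if fold:
        p = np.minimum(p, 1.0 - p)
    return p


def off_center_fraction(
    normalized_positions: Iterable[float], central_width: float = 0.2
) -> float:
    """Fraction of nuclei outside the central window of the cell.

    A nucleus at normalized position p is off-center when
    |p - 0.5| > central_width / 2 (strict: the window boundary counts as
    centered). The default window is the middle 20% of the cell.
    """
    p = np.asarray(list(normalized_positions) if not isinstance(
        normalized_positions, np.ndarray) else normalized_positions, dtype=float)
    if p.size == 0:
        raise ParameterError("off_center_fraction requires at least one position")
    if np.any((p < 0) | (p > 1)):
        raise ParameterError("normalized positions must lie in [0, 1]")
    if not (0.0 < central_width < 1.0):
        raise ParameterError(f"central_width must lie in (0, 1), got {central_width}")
    return float(np.mean(np.abs(p - 0.5) > central_width / 2.0))


@dataclass(frozen=True)
class PositionDistribution:
    """Probability-normalized histogram of normalized nucleus positions."""

    bin_edges: np.ndarray
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        probs = np.asarray(self.probabilities, dtype=float)
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "probabilities", probs)
        if edges.ndim != 1 or probs.ndim != 1 or len(edges) != len(probs) + 1:
            raise ParameterError("need n_bins+1 edges for n_bins probabilities")
        if np.any(np.diff(edges) <= 0):
            raise ParameterError("bin edges must be strictly increasing")
        if np.any(probs < 0):
            raise ParameterError("probabilities must be >= 0")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ParameterError(f"probabilities must sum to 1, got {probs.sum()!r}")

    @property
    def n_bins(self) -> int:
        return len(self.probabilities)

    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def position_histogram(
    normalized_positions: Iterable[float], n_bins: int = 10
) -> PositionDistribution:
    """Equal-width probability histogram of normalized positions on [0, 1].

    The final bin is right-closed, so p = 1 lands in the last bin.
    """
    p = np.asarray(normalized_positions, dtype=float)
    if p.size == 0:
        raise ParameterError("position_histogram requires at least one position")
    if n_bins < 2:
        raise ParameterError(f"n_bins must be >= 2, got {n_bins}")
    if np.any((p < 0) | (p > 1)):
        raise ParameterError("normalized positions must lie in [0, 1]")
    counts, edges = np.histogram(p, bins=n_bins, range=(0.0, 1.0))
    return PositionDistribution(edges, counts / counts.sum())


def rmsd_between_distributions(a: PositionDistribution, b: PositionDistribution) -> float:
    """Root mean squared difference between two binned distributions.

    Requires identical binning; symmetric; zero iff the distributions
    are identical.
    """
    if a.n_bins != b.n_bins or not np.allclose(a.bin_edges, b.bin_edges, atol=1e-12):
        raise ParameterError("distributions must share identical bin edges")
    d = a.probabilities - b.probabilities
    return float(np.sqrt(np.mean(d * d)))


def length_position_correlation(
    measurements: Measurements, use_deviation: bool = True
) -> float:
    """Pearson correlation between cell length and nucleus positioning.

    By default the position variable is the centering deviation
    |p - 0.5| (monotone in mispositioning regardless of which pole the
    nucleus errs toward); ``use_deviation=False`` correlates against the
    raw normalized position instead.
    """
    df = measurements_to_frame(measurements)
    length_all = df["cell_length_um"].to_numpy(dtype=float)
    pos = df["nucleus_position_um"].to_numpy(dtype=float)
    ok = (length_all > 0) & (pos >= 0) & (pos <= length_all)
    length = length_all[ok]
    p = pos[ok] / length
    if len(p) < 3:
        raise ParameterError("correlation requires at least 3 valid measurements")
    y = np.abs(p - 0.5) if use_deviation else p
    if np.std(length) == 0 or np.std(y) == 0:
        raise ParameterError("correlation undefined: zero variance in lengths or positions")
    r, _ = sps.pearsonr(length, y)
    return float(r)


def treatment_summary(
    measurements: Measurements, central_width: float = 0.2
) -> pd.DataFrame:
    """Per-treatment summary: n, cell-length mean/SD, off-center fraction
    and length-deviation correlation, ordered by treatment label."""
    df = measurements_to_frame(measurements)
    if len(df) == 0:
        raise ParameterError("no measurements supplied")
    rows = []
    for label, grp in sorted(df.groupby("treatment", sort=False), key=lambda kv: str(kv[0])):
        p = normalize_positions(grp)
        lengths = grp["cell_length_um"].to_numpy(dtype=float)
        try:
            r = length_position_correlation(grp)
        except ParameterError:
            r = float("nan")
        rows.append(
            {
                "treatment": label,
                "n": len(grp),
                "cell_length_mean_um": float(np.mean(lengths)),
                "cell_length_sd_um": float(np.std(lengths, ddof=1)) if len(grp) > 1 else 0.0,
                "off_center_fraction": off_center_fraction(p, central_width),
                "length_deviation_r": r,
            }
        )
    return pd.DataFrame(rows)
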