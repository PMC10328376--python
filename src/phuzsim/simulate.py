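"""Time-stepped stochastic simulation of two opposing PhuZ filaments.

The model is one-dimensional. Two dynamically unstable filaments nucleate
at the cell poles (x = 0 and x = L) and grow toward midcell with net drift
``v_poly - v_depoly``; during a catastrophe phase the additional speed
``v_cat`` is subtracted, producing rapid shrinkage. Growth and catastrophe
durations are Gaussian draws. A spherical phage nucleus of collision
radius ``r`` starts near one pole (90% of the cell length by default),
diffuses, and is pushed by any growing filament tip that would otherwise
overlap it. If the opposite tip is already in contact with the far side
of the nucleus, the system jams: neither nucleus nor the advancing tip
moves until a catastrophe releases it.

Internally positions are stored in mirror-symmetric coordinates — the
nucleus as a signed offset ``m`` from midcell and each filament as its
grown length ``g`` measured from its own pole — so that reflecting a cell
(x -> L - x) is an exact float-level negation/role swap. The public
containers expose conventional absolute coordinates measured from the
left pole.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .params import (
    CellConfig,
    KineticParams,
    ParameterError,
    SimulationConfig,
    StateError,
    stokes_einstein_D,
)

__all__ = [
    "GROWING",
    "CATASTROPHE",
    "FilamentState",
    "SimState",
    "Trajectory",
    "RunResult",
    "EndpointEnsemble",
    "sample_speed",
    "sample_duration",
    "step",
    "run_simulation",
    "run_ensemble",
    "make_initial_state",
    "stokes_einstein_D",
]

GROWING = "growing"
CATASTROPHE = "catastrophe"

# Stream indices under a run's spawn key: left filament, right filament,
# nucleus diffusion, cell-length draw.
_STREAM_LEFT, _STREAM_RIGHT, _STREAM_DIFF, _STREAM_LENGTH = 0, 1, 2, 3

_LENGTH_RESAMPLE_LIMIT = 1000


def _stream(master_seed: int, run_index: int, which: int) -> np.random.Generator:
    """Counter-based child stream: stable under changes of n_runs."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(run_index, which))
    return np.random.Generator(np.random.Philox(ss))


def run_seed_id(master_seed: int, run_index: int) -> int:
    """A loggable 32-bit identifier of a run's seed material."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(run_index,))
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def sample_speed(mean: float, sd: float, rng: np.random.Generator) -> float:
    """One Gaussian speed draw, clamped at zero from below (um/s)."""
    if mean < 0 or sd < 0:
        raise ParameterError(f"speed mean and sd must be >= 0, got {mean}, {sd}")
    if sd == 0.0:
        return float(mean)
    return max(0.0, float(rng.normal(mean, sd)))


def sample_duration(mean: float, sd: float, dt: float, rng: np.random.Generator) -> float:
    """One Gaussian phase-duration draw, floored at one timestep (s)."""
    if mean < 0 or sd < 0:
        raise ParameterError(f"duration mean and sd must be >= 0, got {mean}, {sd}")
    draw = float(mean) if sd == 0.0 else float(rng.normal(mean, sd))
    return max(dt, draw)


# ---------------------------------------------------------------------------
# Public state containers (absolute coordinates at the surface)
# ---------------------------------------------------------------------------


@dataclass
class FilamentState:
    """One filament: its pole of origin and instantaneous kinetic state.

    ``length`` is the polymerized extent measured from the filament's own
    pole, so it is >= 0 for both filaments; the absolute tip position
    follows from the cell length (see :class:`SimState`).
    """

    origin: str  # "left" (pole at x=0) or "right" (pole at x=L)
    length: float
    phase: str = GROWING
    v_poly: float = 0.0
    v_depoly: float = 0.0
    v_cat: float = 0.0
    next_phase_change: float = 0.0

    def __post_init__(self) -> None:
        if self.origin not in ("left", "right"):
            raise StateError(f"origin must be 'left' or 'right', got {self.origin!r}")
        if self.phase not in (GROWING, CATASTROPHE):
            raise StateError(f"phase must be growing|catastrophe, got {self.phase!r}")
        if self.length < 0:
            raise StateError(f"filament length must be >= 0, got {self.length}")

    @property
    def current_speeds(self) -> Tuple[float, float, float]:
        return (self.v_poly, self.v_depoly, self.v_cat)


@dataclass
class SimState:
    """Instantaneous cell state: two filaments, nucleus, elapsed time.

    ``nucleus_offset`` is the signed offset of the nucleus center from
    midcell; ``nucleus_center`` (= L/2 + offset) is the conventional
    coordinate from the left pole.
    """

    t: float
    left: FilamentState
    right: FilamentState
    nucleus_offset: float
    cell: CellConfig

    @property
    def nucleus_center(self) -> float:
        return self.cell.length / 2.0 + self.nucleus_offset

    @property
    def left_tip(self) -> float:
        return self.left.length

    @property
    def right_tip(self) -> float:
        return self.cell.length - self.right.length

    def validate(self, tol: float = 1e-9) -> None:
        L = self.cell.length
        r = self.cell.nucleus_radius
        hr = L / 2.0 - r
        if not (abs(self.nucleus_offset) <= hr + tol):
            raise StateError(
                f"nucleus center {self.nucleus_center} outside [{r}, {L - r}]"
            )
        for fil, sign in ((self.left, 1.0), (self.right, -1.0)):
            if not (0.0 <= fil.length <= L + tol):
                raise StateError(f"{fil.origin} filament length {fil.length} outside [0, {L}]")
            gap = (hr + sign * self.nucleus_offset) - fil.length
            if gap < -tol:
                raise StateError(
                    f"{fil.origin} filament tip overlaps the nucleus by {-gap:.3g} um"
                )


def make_initial_state(config: SimulationConfig, cell_length: Optional[float] = None,
                       rng: Optional[np.random.Generator] = None) -> SimState:
    """Initial condition: fresh growing filaments at both poles, nucleus
    at ``nucleus_init_frac`` of the cell length (clamped to fit)."""
    cell = config.cell if cell_length is None else config.cell.replace(length=cell_length)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    k = config.kinetics
    hr = cell.length / 2.0 - cell.nucleus_radius
    m0 = (cell.nucleus_init_frac - 0.5) * cell.length
    m0 = min(max(m0, -hr), hr)
    fils = []
    for origin in ("left", "right"):
        vp = sample_speed(k.v_poly_mean, k.v_poly_sd, rng)
        vd = sample_speed(k.v_depoly_mean, k.v_depoly_sd, rng)
        vc = sample_speed(k.v_cat_mean, k.v_cat_sd, rng)
        tc = sample_duration(k.t_cat_mean, k.t_cat_sd, config.dt, rng)
        fils.append(FilamentState(origin, 0.0, GROWING, vp, vd, vc, tc))
    return SimState(t=0.0, left=fils[0], right=fils[1], nucleus_offset=m0, cell=cell)


# ---------------------------------------------------------------------------
# Core update rule (shared by the scalar step() and the vectorized engine)
# ---------------------------------------------------------------------------


def _advance_positions(m, g_left, g_right, d_left, d_right, hr, noise):
    """Advance nucleus offset and filament extents by one timestep.

    Pure elementwise numpy; works on scalars and arrays alike. ``d_*``
    are signed tip displacements toward midcell, ``noise`` the diffusion
    displacement of the nucleus. All float expressions are arranged to be
    exactly antisymmetric under the mirror map (m -> -m, left <-> right,
    noise -> -noise).
    """
    # proposed extents, clamped at the origin pole (a filament never
    # retracts past its own pole)
    n_left = np.maximum(g_left + d_left, 0.0)
    n_right = np.maximum(g_right + d_right, 0.0)
    # overshoot past the near nucleus face (face sits at extent hr + m for
    # the left filament, hr - m for the right one)
    over_left = np.maximum(n_left - (hr + m), 0.0)
    over_right = np.maximum(n_right - (hr - m), 0.0)
    # room the nucleus has before hitting the opposite tip (pre-step); the
    # cell wall is never more permissive because extents are >= 0
    room_left = np.maximum((hr - m) - g_right, 0.0)
    room_right = np.maximum((hr + m) - g_left, 0.0)
    push_left = np.minimum(over_left, room_left)
    push_right = np.minimum(over_right, room_right)
    m1 = m + (push_left - push_right)
    # tips never overlap the (possibly displaced) nucleus
    g1_left = np.minimum(n_left, hr + m1)
    g1_right = np.minimum(n_right, hr - m1)
    # diffusion, clamped at filament contacts and cell walls; when both
    # tips touch the nucleus the bounds coincide and the nucleus is frozen
    lo = g1_left - hr
    hi = hr - g1_right
    m2 = np.minimum(np.maximum(m1 + noise, lo), hi)
    return m2, g1_left, g1_right


def step(state: SimState, params: KineticParams, dt: float,
         rng: np.random.Generator) -> SimState:
    """Advance a single cell state by one timestep of length ``dt``.

    Order of operations: phase bookkeeping (catastrophe onset / recovery
    with fresh Gaussian draws), tip displacement, collision resolution
    with the anti-clipping push and two-sided jam rules, then clamped
    nucleus diffusion. Draw order from ``rng``: left filament events,
    right filament events, diffusion noise.
    """
    if dt <= 0:
        raise ParameterError(f"dt must be > 0, got {dt}")
    state.validate()

    cell = state.cell
    hr = cell.length / 2.0 - cell.nucleus_radius
    t = state.t

    fils = []
    for fil in (state.left, state.right):
        fil = dataclasses.replace(fil)
        if fil.next_phase_change <= t:
            if fil.phase == GROWING:
                fil.phase = CATASTROPHE
                fil.next_phase_change = t + sample_duration(
                    params.t_rec_mean, params.t_rec_sd, dt, rng
                )
            else:
                fil.phase = GROWING
                fil.v_poly = sample_speed(params.v_poly_mean, params.v_poly_sd, rng)
                fil.v_depoly = sample_speed(params.v_depoly_mean, params.v_depoly_sd, rng)
                fil.v_cat = sample_speed(params.v_cat_mean, params.v_cat_sd, rng)
                fil.next_phase_change = t + sample_duration(
                    params.t_cat_mean, params.t_cat_sd, dt, rng
                )
        fils.append(fil)
    left, right = fils

    def _disp(fil: FilamentState) -> float:
        v = fil.v_poly - fil.v_depoly
        if fil.phase == CATASTROPHE:
            v -= fil.v_cat
        return v * dt

    if cell.nucleus_diffusion_coeff > 0.0:
        noise = np.sqrt(2.0 * cell.nucleus_diffusion_coeff * dt) * rng.standard_normal()
    else:
        noise = 0.0

    m2, g_left, g_right = _advance_positions(
        state.nucleus_offset, left.length, right.length,
        _disp(left), _disp(right), hr, noise,
    )
    left.length = float(g_left)
    right.length = float(g_right)
    out = SimState(t=t + dt, left=left, right=right,
                   nucleus_offset=float(m2), cell=cell)
    out.validate()
    return out


# ---------------------------------------------------------------------------
# Vectorized ensemble engine
# ---------------------------------------------------------------------------


class _FilamentBatch:
    """Struct-of-arrays state of one filament family across runs."""

    __slots__ = ("vp", "vd", "vc", "cat", "next_change", "g", "gens")

    def __init__(self, n: int, gens: List[np.random.Generator]):
        self.vp = np.zeros(n)
        self.vd = np.zeros(n)
        self.vc = np.zeros(n)
        self.cat = np.zeros(n, dtype=bool)
        self.next_change = np.zeros(n)
        self.g = np.zeros(n)
        self.gens = gens

    def initial_draws(self, k: KineticParams, dt: float) -> None:
        for i, gen in enumerate(self.gens):
            self.vp[i] = sample_speed(k.v_poly_mean, k.v_poly_sd, gen)
            self.vd[i] = sample_speed(k.v_depoly_mean, k.v_depoly_sd, gen)
            self.vc[i] = sample_speed(k.v_cat_mean, k.v_cat_sd, gen)
            self.next_change[i] = sample_duration(k.t_cat_mean, k.t_cat_sd, dt, gen)

    def update_phases(self, t: float, dt: float, k: KineticParams) -> None:
        due = self.next_change <= t
        if not due.any():
            return
        for i in np.nonzero(due)[0]:
            gen = self.gens[i]
            if self.cat[i]:
                self.cat[i] = False
                self.vp[i] = sample_speed(k.v_poly_mean, k.v_poly_sd, gen)
                self.vd[i] = sample_speed(k.v_depoly_mean, k.v_depoly_sd, gen)
                self.vc[i] = sample_speed(k.v_cat_mean, k.v_cat_sd, gen)
                self.next_change[i] = t + sample_duration(k.t_cat_mean, k.t_cat_sd, dt, gen)
            else:
                self.cat[i] = True
                self.next_change[i] = t + sample_duration(k.t_rec_mean, k.t_rec_sd, dt, gen)

    def resample_speeds(self, k: KineticParams) -> None:
        for i, gen in enumerate(self.gens):
            self.vp[i] = sample_speed(k.v_poly_mean, k.v_poly_sd, gen)
            self.vd[i] = sample_speed(k.v_depoly_mean, k.v_depoly_sd, gen)
            self.vc[i] = sample_speed(k.v_cat_mean, k.v_cat_sd, gen)

    def displacement(self, dt: float, out: np.ndarray) -> np.ndarray:
        np.subtract(self.vp, self.vd, out=out)
        np.subtract(out, self.vc, out=out, where=self.cat)
        out *= dt
        return out


@dataclass
class Trajectory:
    """Recorded time series of one simulated cell (absolute coordinates
    derived on demand from the mirror-exact internal ones)."""

    t: np.ndarray
    left_extent: np.ndarray
    right_extent: np.ndarray
    nucleus_offset: np.ndarray
    left_in_catastrophe: np.ndarray
    right_in_catastrophe: np.ndarray
    cell: CellConfig

    @property
    def left_tip(self) -> np.ndarray:
        return self.left_extent

    @property
    def right_tip(self) -> np.ndarray:
        return self.cell.length - self.right_extent

    @property
    def nucleus_center(self) -> np.ndarray:
        return self.cell.length / 2.0 + self.nucleus_offset

    def to_dataframe(self) -> pd.DataFrame:
        phase = np.array([GROWING, CATASTROPHE])
        return pd.DataFrame(
            {
                "t_s": self.t,
                "left_tip_um": self.left_tip,
                "right_tip_um": self.right_tip,
                "nucleus_center_um": self.nucleus_center,
                "left_phase": phase[self.left_in_catastrophe.astype(int)],
                "right_phase": phase[self.right_in_catastrophe.astype(int)],
            }
        )

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass
class RunResult:
    """Outcome of a single simulated cell."""

    final_state: SimState
    trajectory: Optional[Trajectory] = None


@dataclass
class EndpointEnsemble:
    """Final nucleus positions of an ensemble of simulated cells."""

    final_positions: np.ndarray  # um from the left pole
    cell_lengths: np.ndarray  # um
    normalized_positions: np.ndarray  # in [r/L, 1 - r/L]
    seed_record: np.ndarray  # per-run 32-bit seed identifiers
    master_seed: int

    def __len__(self) -> int:
        return len(self.final_positions)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "run": np.arange(len(self.final_positions)),
                "seed": self.seed_record,
                "cell_length_um": self.cell_lengths,
                "final_position_um": self.final_positions,
                "normalized_position": self.normalized_positions,
            }
        )

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


_NOISE_CHUNK = 4096


def _simulate_batch(
    config: SimulationConfig,
    lengths: np.ndarray,
    streams: Sequence[Tuple[np.random.Generator, np.random.Generator, np.random.Generator]],
    mirror: bool = False,
    record: bool = False,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, _FilamentBatch, _FilamentBatch, Optional[list]]:
    """Advance ``len(lengths)`` cells through the full simulation.

    Returns final (m, g_left, g_right) plus filament batches and, when
    ``record``, a list of per-stride snapshot tuples.
    """
    n = len(lengths)
    k = config.kinetics
    cell = config.cell
    dt = config.dt
    n_steps = config.n_steps

    hr = lengths / 2.0 - cell.nucleus_radius
    if np.any(hr <= 0):
        raise ParameterError("every cell length must exceed the nucleus diameter")

    init_frac = cell.nucleus_init_frac
    m = (init_frac - 0.5) * lengths
    if mirror:
        m = -m
    m = np.minimum(np.maximum(m, -hr), hr)

    first = _FilamentBatch(n, [s[0] for s in streams])
    second = _FilamentBatch(n, [s[1] for s in streams])
    diff_gens = [s[2] for s in streams]
    # under mirroring the "left" family consumes what was the right
    # filament's stream, and vice versa
    left, right = (second, first) if mirror else (first, second)
    first.initial_draws(k, dt)
    second.initial_draws(k, dt)

    noise_factor = np.sqrt(2.0 * cell.nucleus_diffusion_coeff * dt)
    noise_buf = np.zeros((n, 1))
    d_left = np.zeros(n)
    d_right = np.zeros(n)

    resample_every = None
    if config.resample_interval is not None:
        resample_every = max(1, int(round(config.resample_interval / dt)))

    snapshots: Optional[list] = [] if record else None
    stride = config.trajectory_stride

    def snap(step_idx: int) -> None:
        snapshots.append(
            (
                step_idx * dt,
                left.g.copy(),
                right.g.copy(),
                m.copy(),
                left.cat.copy(),
                right.cat.copy(),
            )
        )

    if record:
        snap(0)

    for s_idx in range(n_steps):
        t = s_idx * dt
        # phase bookkeeping in stream order (stable under mirroring)
        first.update_phases(t, dt, k)
        second.update_phases(t, dt, k)
        if resample_every is not None and s_idx > 0 and s_idx % resample_every == 0:
            first.resample_speeds(k)
            second.resample_speeds(k)

        left.displacement(dt, d_left)
        right.displacement(dt, d_right)

        if noise_factor > 0.0:
            j = s_idx % _NOISE_CHUNK
            if j == 0:
                width = min(_NOISE_CHUNK, n_steps - s_idx)
                if noise_buf.shape[1] != width:
                    noise_buf = np.empty((n, width))
                for i, gen in enumerate(diff_gens):
                    noise_buf[i, :] = gen.standard_normal(width)
                if mirror:
                    np.negative(noise_buf, out=noise_buf)
                noise_buf *= noise_factor
            noise = noise_buf[:, j]
        else:
            noise = 0.0

        m, g_left, g_right = _advance_positions(m, left.g, right.g, d_left, d_right, hr, noise)
        left.g = np.asarray(g_left)
        right.g = np.asarray(g_right)

        if record and ((s_idx + 1) % stride == 0 or s_idx + 1 == n_steps):
            snap(s_idx + 1)

    return m, left.g, right.g, left, right, snapshots


def _state_from_batch(config, cell, m, left_batch, right_batch, t, i=0) -> SimState:
    def fil(batch: _FilamentBatch, origin: str) -> FilamentState:
        return FilamentState(
            origin=origin,
            length=float(batch.g[i]),
            phase=CATASTROPHE if batch.cat[i] else GROWING,
            v_poly=float(batch.vp[i]),
            v_depoly=float(batch.vd[i]),
            v_cat=float(batch.vc[i]),
            next_phase_change=float(batch.next_change[i]),
        )

    return SimState(
        t=t,
        left=fil(left_batch, "left"),
        right=fil(right_batch, "right"),
        nucleus_offset=float(m[i]),
        cell=cell,
    )


def run_simulation(
    config: SimulationConfig,
    cell_length: Optional[float] = None,
    run_seed: Optional[int] = None,
    run_index: int = 0,
    mirror: bool = False,
) -> RunResult:
    """Simulate a single cell for ``config.duration`` seconds.

    ``run_seed`` defaults to ``config.seed``; together with ``run_index``
    it fully determines the trajectory. ``mirror=True`` reflects the
    initial condition (nucleus at ``1 - nucleus_init_frac``), swaps the
    filament random streams and negates the diffusion noise, producing
    the exact mirror image x -> L - x of the unmirrored run.
    """
    cell = config.cell if cell_length is None else config.cell.replace(length=cell_length)
    cfg = config.replace(cell=cell)
    seed = config.seed if run_seed is None else run_seed
    streams = (
        _stream(seed, run_index, _STREAM_LEFT),
        _stream(seed, run_index, _STREAM_RIGHT),
        _stream(seed, run_index, _STREAM_DIFF),
    )
    lengths = np.array([cell.length])
    m, gL, gR, left_b, right_b, snaps = _simulate_batch(
        cfg, lengths, [streams], mirror=mirror, record=config.record_trajectory
    )
    final = _state_from_batch(cfg, cell, m, left_b, right_b, t=config.n_steps * config.dt)
    traj = None
    if snaps is not None:
        traj = Trajectory(
            t=np.array([s[0] for s in snaps]),
            left_extent=np.array([s[1][0] for s in snaps]),
            right_extent=np.array([s[2][0] for s in snaps]),
            nucleus_offset=np.array([s[3][0] for s in snaps]),
            left_in_catastrophe=np.array([s[4][0] for s in snaps]),
            right_in_catastrophe=np.array([s[5][0] for s in snaps]),
            cell=cell,
        )
    return RunResult(final_state=final, trajectory=traj)


LengthSampler = Union[float, Callable[[np.random.Generator], float]]


def _draw_length(sampler: LengthSampler, gen: np.random.Generator, min_length: float) -> float:
    if not callable(sampler):
        L = float(sampler)
        if L <= min_length:
            raise ParameterError(
                f"cell length {L} must exceed the nucleus diameter {min_length}"
            )
        return L
    for _ in range(_LENGTH_RESAMPLE_LIMIT):
        L = float(sampler(gen))
        if L > min_length:
            return L
    raise ParameterError(
        f"cell-length sampler failed to produce a length > {min_length} um "
        f"in {_LENGTH_RESAMPLE_LIMIT} attempts"
    )


def run_ensemble(
    config: SimulationConfig,
    cell_length_sampler: Optional[LengthSampler] = None,
) -> EndpointEnsemble:
    """Run ``config.n_runs`` independent cells and collect the endpoints.

    ``cell_length_sampler`` is either a fixed length or a callable
    ``sampler(rng) -> length`` (e.g. a Gaussian treatment profile); draws
    at or below the nucleus diameter are rejected and resampled, with a
    bounded retry count. Per-run seeds derive from ``config.seed`` and
    the run index via a counter-based scheme, so run ``i`` is unchanged
    when ``n_runs`` changes.
    """
    n = config.n_runs
    cell = config.cell
    sampler = cell.length if cell_length_sampler is None else cell_length_sampler
    min_length = 2.0 * cell.nucleus_radius

    lengths = np.empty(n)
    streams = []
    for i in range(n):
        len_gen = _stream(config.seed, i, _STREAM_LENGTH)
        lengths[i] = _draw_length(sampler, len_gen, min_length)
        streams.append(
            (
                _stream(config.seed, i, _STREAM_LEFT),
                _stream(config.seed, i, _STREAM_RIGHT),
                _stream(config.seed, i, _STREAM_DIFF),
            )
        )

    m, _gL, _gR, _lb, _rb, _ = _simulate_batch(config, lengths, streams, record=False)
    centers = lengths / 2.0 + m
    seeds = np.array([run_seed_id(config.seed, i) for i in range(n)], dtype=np.uint32)
    return EndpointEnsemble(
        final_positions=centers,
        cell_lengths=lengths,
        normalized_positions=centers / lengths,
        seed_record=seeds,
        master_seed=config.seed,
    )
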