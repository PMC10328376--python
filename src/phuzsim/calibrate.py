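"""Kinetic-parameter fitting by distribution-RMSD minimization.

The objective is the RMSD between a measured binned distribution of
normalized nucleus positions and the distribution produced by endpoint
ensembles of the simulator. Free parameters (a named subset of the
kinetic fields) are fitted by a stochastic scheme: an initial phase of
random Gaussian mutations, followed by iterations that estimate the
partial derivatives of RMSD by finite differences and take bounded
downhill steps, tracking the best parameters seen. Objective noise is
tamed by averaging replicate ensembles and by common-random-number
seeding within each finite-difference pair.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.interpolate import LinearNDInterpolator

from .params import KineticParams, ParameterError, SimulationConfig
from .simulate import LengthSampler, run_ensemble
from .stats import PositionDistribution, position_histogram, rmsd_between_distributions

__all__ = [
    "ParameterVector",
    "OptimizationConfig",
    "FitResult",
    "SurfaceResult",
    "make_objective",
    "objective",
    "estimate_gradient",
    "optimize_parameters",
    "rmsd_surface",
]


@dataclass(frozen=True)
class ParameterVector:
    """Named free kinetic parameters with bounds and mutation scales.

    Every name must be a :class:`KineticParams` field; fields not listed
    stay fixed at their values in the base kinetics.
    """

    names: Tuple[str, ...]
    values: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    mutation_scales: np.ndarray

    def __post_init__(self) -> None:
        names = tuple(self.names)
        object.__setattr__(self, "names", names)
        for attr in ("values", "lower", "upper", "mutation_scales"):
            object.__setattr__(self, attr, np.asarray(getattr(self, attr), dtype=float))
        valid = set(KineticParams.field_names())
        bad = [n for n in names if n not in valid]
        if bad:
            raise ParameterError(f"unknown kinetic parameter names: {bad}")
        if len(set(names)) != len(names):
            raise ParameterError("duplicate parameter names")
        k = len(names)
        for attr in ("values", "lower", "upper", "mutation_scales"):
            if getattr(self, attr).shape != (k,):
                raise ParameterError(f"{attr} must have shape ({k},)")
        if np.any(self.lower < 0):
            raise ParameterError("lower bounds must be >= 0 (rates are non-negative)")
        if np.any(self.upper <= self.lower):
            raise ParameterError("upper bounds must exceed lower bounds")
        if np.any(self.mutation_scales <= 0):
            raise ParameterError("mutation scales must be > 0")
        if np.any((self.values < self.lower) | (self.values > self.upper)):
            raise ParameterError("values must lie within bounds")

    @classmethod
    def from_dict(
        cls,
        values: dict,
        bounds: dict,
        mutation_scales: Optional[dict] = None,
    ) -> "ParameterVector":
        names = tuple(values)
        lo = np.array([bounds[n][0] for n in names], dtype=float)
        hi = np.array([bounds[n][1] for n in names], dtype=float)
        if mutation_scales is None:
            scales = (hi - lo) / 10.0
        else:
            scales = np.array([mutation_scales[n] for n in names], dtype=float)
        return cls(names, np.array([values[n] for n in names], float), lo, hi, scales)

    def with_values(self, values: np.ndarray) -> "ParameterVector":
        return dataclasses.replace(self, values=np.asarray(values, dtype=float))

    def clip(self, values: np.ndarray) -> np.ndarray:
        return np.minimum(np.maximum(values, self.lower), self.upper)

    def apply_to(self, kinetics: KineticParams) -> KineticParams:
        return kinetics.replace(**dict(zip(self.names, (float(v) for v in self.values))))

    def as_dict(self) -> dict:
        return dict(zip(self.names, (float(v) for v in self.values)))


@dataclass(frozen=True)
class OptimizationConfig:
    """Controls of the stochastic finite-difference descent."""

    replicates_per_eval: int = 3
    max_iterations: int = 30
    n_initial_mutations: int = 8
    perturbation_scale: float = 0.25  # FD half-step, in units of mutation scale
    step_size: float = 1.0  # initial step, in units of mutation scale
    step_decay: float = 0.9
    convergence_tol: float = 0.01  # relative best-RMSD improvement ...
    convergence_window: int = 5  # ... over this many iterations
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates_per_eval < 1 or self.max_iterations < 1:
            raise ParameterError("replicates_per_eval and max_iterations must be >= 1")
        if self.n_initial_mutations < 0:
            raise ParameterError("n_initial_mutations must be >= 0")
        for attr in ("perturbation_scale", "step_size", "step_decay", "convergence_tol"):
            if getattr(self, attr) <= 0:
                raise ParameterError(f"{attr} must be > 0")
        if self.convergence_window < 1:
            raise ParameterError("convergence_window must be >= 1")


def _eval_seed(base_seed: int, counter: int) -> int:
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(counter,))
    return int(ss.generate_state(1, dtype=np.uint32)[0]) % (2**31)


def make_objective(
    measured: PositionDistribution,
    sim_config: SimulationConfig,
    length_sampler: Optional[LengthSampler] = None,
    base: Optional[ParameterVector] = None,
    replicates: int = 3,
) -> Callable[[np.ndarray, int], float]:
    """Build ``f(values, seed) -> RMSD`` around the simulator.

    Each call runs ``replicates`` independent endpoint ensembles (seeds
    derived from ``seed`` and the replicate index), histograms them at
    the measured bin edges, and averages the per-ensemble RMSD. Passing
    the same ``seed`` to two calls yields common random numbers, which
    makes finite differences of the noisy objective meaningful.
    """

    def f(values: np.ndarray, seed: int) -> float:
        kinetics = (
            base.with_values(values).apply_to(sim_config.kinetics)
            if base is not None
            else sim_config.kinetics
        )
        total = 0.0
        for rep in range(replicates):
            cfg = sim_config.replace(kinetics=kinetics, seed=_eval_seed(seed, rep))
            ens = run_ensemble(cfg, length_sampler)
            model = position_histogram(ens.normalized_positions, measured.n_bins)
            total += rmsd_between_distributions(measured, model)
        return total / replicates

    return f


def objective(
    params: ParameterVector,
    measured: PositionDistribution,
    sim_config: SimulationConfig,
    length_sampler: Optional[LengthSampler] = None,
    replicates: int = 3,
    seed: int = 0,
) -> float:
    """Mean distribution-RMSD of the model at ``params`` (see
    :func:`make_objective`)."""
    f = make_objective(measured, sim_config, length_sampler, params, replicates)
    return f(params.values, seed)


def estimate_gradient(
    func: Callable[[np.ndarray, int], float],
    point: ParameterVector,
    perturbation_scale: float = 0.25,
    seed: int = 0,
    rng: Optional[np.random.Generator] = None,
    mode: str = "central",
) -> np.ndarray:
    """Finite-difference estimate of dRMSD/dparam at ``point``.

    ``mode='central'`` perturbs each free parameter in turn by
    ``perturbation_scale * mutation_scale`` (one-sided at a bound);
    ``mode='spsa'`` uses one simultaneous random +-1 perturbation drawn
    from ``rng``. Both sides of every difference share the same seed.
    """
    x = point.values
    h = perturbation_scale * point.mutation_scales
    if mode == "spsa":
        if rng is None:
            rng = np.random.default_rng(seed)
        delta = rng.choice([-1.0, 1.0], size=len(x))
        xp = point.clip(x + h * delta)
        xm = point.clip(x - h * delta)
        df = func(xp, seed) - func(xm, seed)
        span = xp - xm
        span[span == 0] = np.inf
        return df / span * 1.0
    if mode != "central":
        raise ParameterError(f"unknown gradient mode {mode!r}")
    grad = np.empty(len(x))
    for i in range(len(x)):
        hi = min(h[i], point.upper[i] - x[i])
        lo = min(h[i], x[i] - point.lower[i])
        if hi <= 0 and lo <= 0:
            grad[i] = 0.0
            continue
        xp, xm = x.copy(), x.copy()
        xp[i] += hi
        xm[i] -= lo
        grad[i] = (func(xp, seed) - func(xm, seed)) / (hi + lo)
    return grad


@dataclass
class FitResult:
    """Best-seen parameters, their RMSD, and the optimization trace."""

    params: ParameterVector
    rmsd: float
    trace: pd.DataFrame
    converged: bool
    n_evaluations: int


def optimize_parameters(
    measured: PositionDistribution,
    init: ParameterVector,
    opt_config: OptimizationConfig,
    sim_config: SimulationConfig,
    length_sampler: Optional[LengthSampler] = None,
    func: Optional[Callable[[np.ndarray, int], float]] = None,
) -> FitResult:
    """Fit the free parameters by random mutation + estimated-gradient
    descent on the distribution RMSD.

    Phase 1 evaluates the initial point and ``n_initial_mutations``
    Gaussian mutations of it, keeping the best. Phase 2 iterates:
    finite-difference gradient (common random numbers within each pair),
    a bounded downhill step of decaying size, and best-seen tracking.
    Convergence is declared when the relative improvement of the best
    RMSD over ``convergence_window`` iterations drops below
    ``convergence_tol``. Fully reproducible from ``opt_config.seed``.

    ``func`` may replace the simulator-backed objective (e.g. with a
    deterministic surrogate); it must have signature ``f(values, seed)``.
    """
    if func is None:
        func = make_objective(
            measured, sim_config, length_sampler, init, opt_config.replicates_per_eval
        )
    rng = np.random.default_rng(opt_config.seed)
    n_evals = 0

    def ev(values: np.ndarray, seed: int) -> float:
        nonlocal n_evals
        n_evals += 1
        return func(values, seed)

    # Phase 1: random mutations around the initial guess
    candidates = [init.values]
    for _ in range(opt_config.n_initial_mutations):
        mut = init.values + rng.normal(0.0, init.mutation_scales)
        candidates.append(init.clip(mut))
    scores = [ev(c, _eval_seed(opt_config.seed, 10_000 + i)) for i, c in enumerate(candidates)]
    best_i = int(np.argmin(scores))
    x_best = np.array(candidates[best_i])
    f_best = scores[best_i]
    x_cur, f_cur = x_best.copy(), f_best

    rows = [{"iter": 0, "rmsd": f_best, **dict(zip(init.names, x_best))}]
    history = [f_best]
    converged = False

    step = opt_config.step_size
    for it in range(1, opt_config.max_iterations + 1):
        pair_seed = _eval_seed(opt_config.seed, 20_000 + it)
        grad = estimate_gradient(
            ev, init.with_values(x_cur), opt_config.perturbation_scale, seed=pair_seed
        )
        u = grad * init.mutation_scales  # gradient in scale units
        norm = float(np.linalg.norm(u))
        if norm > 0:
            direction = -u / norm * init.mutation_scales
            accepted = False
            trial_step = step
            for _ in range(3):
                x_try = init.clip(x_cur + trial_step * direction)
                f_try = ev(x_try, _eval_seed(opt_config.seed, 30_000 + it))
                if f_try < f_cur:
                    x_cur, f_cur = x_try, f_try
                    accepted = True
                    break
                trial_step *= 0.5
            if not accepted:
                # random mutation fallback keeps the search moving
                x_try = init.clip(x_cur + rng.normal(0.0, step * init.mutation_scales))
                f_try = ev(x_try, _eval_seed(opt_config.seed, 40_000 + it))
                if f_try < f_cur:
                    x_cur, f_cur = x_try, f_try
        if f_cur < f_best:
            x_best, f_best = x_cur.copy(), f_cur
        history.append(f_best)
        rows.append({"iter": it, "rmsd": f_best, **dict(zip(init.names, x_best))})
        step *= opt_config.step_decay
        w = opt_config.convergence_window
        if len(history) > w:
            past = history[-1 - w]
            if past > 0 and (past - history[-1]) / past < opt_config.convergence_tol:
                converged = True
                break

    return FitResult(
        params=init.with_values(x_best),
        rmsd=float(f_best),
        trace=pd.DataFrame(rows),
        converged=converged,
        n_evaluations=n_evals,
    )


@dataclass
class SurfaceResult:
    """Randomly sampled objective surface over two parameters with a
    linear interpolator over the scatter."""

    param_x: str
    param_y: str
    points: np.ndarray  # (n, 2)
    values: np.ndarray  # (n,)

    def interpolator(self) -> LinearNDInterpolator:
        return LinearNDInterpolator(self.points, self.values)

    def to_grid(self, nx: int = 50, ny: int = 50):
        xs = np.linspace(self.points[:, 0].min(), self.points[:, 0].max(), nx)
        ys = np.linspace(self.points[:, 1].min(), self.points[:, 1].max(), ny)
        gx, gy = np.meshgrid(xs, ys, indexing="ij")
        return xs, ys, self.interpolator()(gx, gy)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {self.param_x: self.points[:, 0], self.param_y: self.points[:, 1],
             "rmsd": self.values}
        )


def rmsd_surface(
    param_x: str,
    param_y: str,
    bounds_x: Tuple[float, float],
    bounds_y: Tuple[float, float],
    measured: Optional[PositionDistribution] = None,
    sim_config: Optional[SimulationConfig] = None,
    length_sampler: Optional[LengthSampler] = None,
    n_points: int = 200,
    replicates: int = 1,
    seed: int = 0,
    func: Optional[Callable[[np.ndarray, int], float]] = None,
) -> SurfaceResult:
    """Sample the RMSD surface at ``n_points`` random (x, y) parameter
    pairs for linear interpolation.

    All other kinetic parameters stay at their ``sim_config`` values.
    ``func(values, seed)`` may replace the simulator objective.
    """
    if bounds_x[1] <= bounds_x[0] or bounds_y[1] <= bounds_y[0]:
        raise ParameterError("degenerate parameter bounds")
    if n_points < 4:
        raise ParameterError("n_points must be >= 4 for interpolation")
    if func is None:
        if measured is None or sim_config is None:
            raise ParameterError("measured and sim_config are required without func")
        base = ParameterVector.from_dict(
            {param_x: bounds_x[0], param_y: bounds_y[0]},
            {param_x: bounds_x, param_y: bounds_y},
        )
        # from_dict starts at the lower bounds; only values passed to f matter
        func = make_objective(measured, sim_config, length_sampler, base, replicates)
    rng = np.random.default_rng(seed)
    xs = rng.uniform(bounds_x[0], bounds_x[1], size=n_points)
    ys = rng.uniform(bounds_y[0], bounds_y[1], size=n_points)
    vals = np.empty(n_points)
    for i in range(n_points):
        vals[i] = func(np.array([xs[i], ys[i]]), _eval_seed(seed, i))
    return SurfaceResult(param_x, param_y, np.column_stack([xs, ys]), vals)
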