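# Methods

## The model

`phuzsim` simulates, in one spatial dimension, how the tubulin-like PhuZ
spindle of nucleus-forming jumbo phages positions the phage nucleus in a
rod-shaped host cell. Two filaments nucleate at the cell poles (x = 0 and
x = L) and undergo dynamic instability. The tip of a filament moves with

    dx/dt = v_poly − v_depoly − v_cat,

where `v_cat` is non-zero only while the filament is in its catastrophe
phase. A filament grows for a stochastic interval (`t_cat` draw), then
switches to catastrophe; a recovery interval (`t_rec` draw) later it
resumes growth with freshly sampled speeds. Every kinetic quantity is a
Gaussian (mean, SD) pair; speed draws are clamped at zero from below and
interval draws are floored at one timestep, since negative speeds and
instantaneous phase flips are unphysical. A filament never retracts past
its own pole.

The phage nucleus is a sphere of collision radius `r` (default 0.5 um)
whose center starts at 90% of the cell length — the DNA is injected at a
pole, and the nascent nucleus forms there. Each step the nucleus
receives a Brownian displacement `sqrt(2 D dt) N(0,1)`. When a growing
tip would overlap the nucleus, the overshoot is transferred to the
nucleus (an anti-clipping push); if the opposite tip is already in
contact with the far face, the system *jams* — neither the nucleus nor
the advancing tip moves — until a catastrophe releases it. Diffusion is
clamped so the nucleus can pass through neither a touching tip nor the
cell poles.

### Update rule and coordinates

Within a timestep the order of operations is: phase bookkeeping, tip
displacement, collision resolution, then clamped diffusion. Both
filaments are resolved **simultaneously against the pre-step state**:
each filament's push is limited by the room the nucleus has before
contacting the *pre-step* opposite tip, and the nucleus moves by the
difference of the two allowed pushes. A sequential left-then-right
update would be an equally valid discretization, but it breaks the exact
mirror symmetry of the model; with the simultaneous rule, reflecting the
initial condition, swapping the two filaments' random streams and
negating the diffusion noise yields the reflected trajectory *to the
bit* (the test suite asserts float equality). To make that possible the
implementation stores the nucleus as a signed offset from midcell and
each filament as its polymerized extent from its own pole, so that the
mirror map is a pure negation/role swap; every floating-point expression
in the update is arranged to be exactly antisymmetric under that map.
At dt = 0.01 s the behavioural difference between the sequential and
simultaneous rules is far below the stochastic variability.

The reference protocol follows the model's standard conditions:
dt = 0.01 s, 30 simulated minutes, 500 runs per condition, with per-run
random streams derived from the master seed by a counter-based scheme
(run *i* is unchanged when the ensemble size changes). Three independent
streams per run — left filament, right filament, nucleus diffusion —
support the mirror construction above.

## Parameters

| parameter | units | default | role |
|---|---|---|---|
| `v_poly_mean/sd` | um/s | 0.045 / 0.005 | polymerization speed |
| `v_depoly_mean/sd` | um/s | 0.015 / 0.002 | continuous depolymerization |
| `v_cat_mean/sd` | um/s | 0.4 / 0.05 | catastrophic shrinkage speed |
| `t_cat_mean/sd` | s | 50 / 3 | growth interval before catastrophe |
| `t_rec_mean/sd` | s | 8 / 3 | catastrophe interval before recovery |
| `nucleus_radius` | um | 0.5 | collision half-length |
| `nucleus_diffusion_coeff` | um^2/s | 1e-4 | nucleus mobility |
| `nucleus_init_frac` | – | 0.9 | initial center, fraction of L |
| `dt`, `duration`, `n_runs` | s, s, – | 0.01, 1800, 500 | protocol |

The shipped kinetics (`phuzsim/data/calibrated.yaml`) are **illustrative
calibrated values**, produced with the package's own calibration and
sweep machinery, not published measurements. They were chosen so that a
3.5 um cell — the typical untreated host — centers its nucleus
efficiently within 30 minutes while cells two- to four-fold longer do
not, which is the qualitative behaviour the model exists to study. The
working point has a simple reading: the polymerized reach per growth
phase, `(v_poly − v_depoly)·t_cat ≈ 1.5 um`, just exceeds the 1.25 um
pole-to-nucleus-face distance of a 3.5 um cell. A filament therefore
reaches the nucleus and pushes it for a short interval before
catastrophe; alternating pushes from the two poles settle the nucleus
where both filaments can just reach — midcell. In longer cells the
reach falls short, the far filament rarely arrives, and the nucleus
parks roughly one reach-length from the pole that can still push it:
centering collapses. Catastrophes at `v_cat·t_rec ≈ 3 um` fully reset a
filament, which is what makes the reach (rather than accumulated
length) the controlling quantity. With these defaults the fraction of
500 endpoints inside the central 20% falls from ≈0.82 at 3.5 um to
≈0.64, ≈0.08 and ≈0.00 at 7, 10 and 14 um.

**Collision radius vs Stokes radius.** The 1 um Stokes radius enters
only the diffusion coefficient; the collision half-length is an
independent 0.5 um (a nucleus spanning the full cell width of a
~1 um-wide rod, described in 1D). Both are configurable.

**Diffusion coefficient.** `stokes_einstein_D(r, T, eta)` evaluates
D = k_B T / (6 pi eta r) (0.227 um^2/s for a 1 um sphere in water at
310 K). Water viscosity is far too low for a chromosome-scale particle
in crowded cytoplasm, where effective viscosities for um-scale objects
are thousands of times higher; the calibrated configuration therefore
sets D = 1e-4 um^2/s (effective viscosity ~2 Pa s) directly. D is a
plain config field, so any Stokes-Einstein evaluation can be
substituted.

**Speed re-sampling.** Speeds are re-sampled at every phase change.
The event-driven reading of "positions are updated if the random time
sampling associated with their movement has passed" can be emulated
with the optional `resample_interval`, which re-samples all speeds at a
fixed period; the default (phase changes only) is the simplest scheme
consistent with dynamic instability.

## Position statistics

Measured or simulated cells are tables of (treatment, timepoint, cell
length, nucleus position). Positions are normalized by cell length; a
cell is *off-center* when |p − 0.5| > w/2 with w = 0.2 (the middle 20%
of the cell), using a strict inequality so the window boundary counts
as centered — the boundary convention is not standardized, and the
choice is exposed. Distributions are equal-width probability histograms
on [0, 1] (default 10 bins; the bin count matters to the calibration
objective and is configurable). The distribution distance is the RMSD
across bins. The length–mispositioning correlation is the Pearson r
between cell length and the centering deviation |p − 0.5| by default
(monotone in mispositioning regardless of which pole the nucleus errs
toward); raw-position correlation is available via a flag. When the
reference pole of a measured table is unknown, fold-invariant
statistics (off-center fraction, deviation correlation) are unaffected.

## Calibration

Free kinetic parameters (any named subset of the kinetic fields, with
non-negative bounds and per-parameter mutation scales) are fitted by
minimizing the RMSD between a measured position histogram and the
model's, formalized as stochastic finite-difference descent: an initial
phase of random Gaussian mutations keeps the best scoring candidate,
then each iteration estimates the partial derivatives of RMSD by
central differences (one-sided at bounds; a simultaneous-perturbation
mode is available), takes a bounded downhill step of decaying size, and
tracks the best parameters seen. Objective noise is handled by
averaging replicate ensembles (default 3) and by common-random-number
seeding within each finite-difference pair. Convergence is declared
when the best RMSD improves by less than 1% over 5 iterations. The
best-seen trace is non-increasing by construction and the whole fit is
reproducible from its seed.

Two numerical facts about this objective are worth knowing. First,
parameter pairs with equal net growth `v_poly − v_depoly` produce
identical net-speed distributions (up to the negligible effect of
clamping speed draws at zero), so the polymerization/depolymerization
surface contains an exactly degenerate low-RMSD valley; fitting both
simultaneously from endpoint data alone cannot resolve it. Second, the
endpoint distribution of a well-centered short cell is insensitive to
*increases* of the polymerized reach (the jam rule caps overshoot), so
recovery experiments are run on elongated (7 um) cells, where the
parking position responds to the reach in both directions. The
RMSD surface utility samples 200 random parameter pairs and linearly
interpolates them, matching the procedure used for the published
surface plots.

## Phase-space sweeps

The sweep module evaluates a regular grid over two axes (cell length
and/or kinetic parameters), runs an ensemble per grid cell
(default 100 runs — scaled from the 500-run reference protocol to keep
grids affordable, and configurable back up), and records the centering
fraction, classifying a cell as centered when the fraction strictly
exceeds 80%. Random-sampling + interpolation surfaces reuse the
calibration utility.

## Synthetic data

The generator emulates the deposited single-cell measurement dataset.
Each treatment profile draws Gaussian cell lengths
(rejection-resampled above the nucleus diameter) and produces nucleus
positions either from the simulator itself (ground truth = the kinetic
parameters) or from a parametric mixture: with weight w, a uniform
off-center component, otherwise a Gaussian centered at midcell. The
mixture weight for a target off-center fraction is computed in closed
form. The default panel is *illustrative* — the per-treatment length
means are not published numbers: a 3.5 ± 0.7 um control, 7 ± 2 um and
10 ± 3 um beta-lactam-like elongated conditions, and a 14 ± 4 um
division-inhibited condition whose positions are uniform across the
cell interior with the poles excluded. Control and piperacillin-like
mixture weights pin the expected off-center fractions at 24% and 60%.
Optional Gaussian measurement noise (um) can be added to positions.

What the parametric tables deliberately do not emulate: measurement
pipelines (segmentation error, pole ambiguity), multiple nuclei per
cell, infection-rate count data, or any time course — each table is one
timepoint. Tests passing on these tables show the statistics and
calibration machinery are correct, not that the biological profiles
are accurate.

## Numerical choices and edge cases

- Gaussian speed draws are clamped at 0 (censored, not conditionally
  resampled); interval draws are floored at dt.
- The initial nucleus center `0.9 L` is clamped into `[r, L − r]`; in
  cells shorter than 5 r this means the nucleus starts in contact with
  the far pole.
- Phase-change comparisons use `next_change <= t` at the step's start;
  both filaments start growing with a fresh catastrophe clock at t = 0.
- Equality at the off-center window boundary counts as centered; the
  centered classification in sweeps is strictly greater-than.
- Histogram final bin is right-closed so p = 1 is counted.
- Cell-length samplers are rejection-resampled above the nucleus
  diameter with a bounded retry count (1000), then error.
- All lengths are um and times s internally; the CLI accepts minutes
  for durations.

## Problem sizes used in the test suite

Behavioural tests run the reference protocol (dt = 0.01 s, 30 min,
500 runs) for the centering-window checks. Calibration tests use
shortened ensembles (dt = 0.05 s, 450–600 s) — the centering process
equilibrates within the first few push cycles (~100 s), and halving dt
from 0.02 to 0.01 changes ensemble centering fractions by less than
the between-seed spread, so the shortened settings probe the same
dynamics at a fraction of the cost.

## Known limitations

- Strictly 1D: no excluded volume, no filament bundling, no nucleus
  rotation or capsid trafficking, no treadmilling, no explicit GTP
  hydrolysis chemistry.
- Catastrophe timing is length-independent; there is no force-dependent
  catastrophe or rescue.
- The fitted/shipped kinetics are a documented working point, not
  measurements; any quantitative use should re-fit against real
  measured tables with `phuzsim fit`.
- The RMSD objective uses endpoint distributions only and therefore
  cannot identify parameters that trade off into identical endpoint
  statistics (the net-growth valley above).
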