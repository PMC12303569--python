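# Methods

This note documents the model, the simulation and training procedures, the
statistics, and the numerical and design choices behind `placenet`. It is
the package's account of its own science; every number quoted here is
computed by the test suite or by `scripts/acceptance.py`, not asserted.

## Model

The model is a normative account of hippocampal place-cell formation and
remapping: a recurrent network is required to reconstruct its position
while path-integrating, and position is read out of its output population
by a fixed, place-cell-inspired decoder rather than by trainable readout
coordinates.

A one-layer vanilla RNN with `N_g = 500` rectified units and no biases
receives, at each step, a Cartesian velocity `v_t` and a constant six-entry
one-hot context signal `c` identifying the current arena:

    g_{t+1} = [W_R g_t + W_I cat(v_t, c)]_+ ,
    p_t     = [W_p g_t]_+ ,                      N_p = 100 output units.

The decoder assigns each output unit a center — the activity-weighted mean
of the positions visited along the trajectory,

    mu_i = sum_t p_i(t) x_t / max(eps, sum_t p_i(t)),

and decodes position as the activity-weighted mean of the centers,

    x_hat_t = sum_i p_i(t) mu_i / max(eps, sum_i p_i(t)),

with `eps = 1e-8` guarding zero division (an all-silent population decodes
to the origin). Centers are computed per trajectory, over all of its
timesteps, inside the gradient graph: "non-trainable" means the decoder has
no learnable parameters, not that gradients stop at it. A
`stop_gradient_centers` switch provides the detached variant. The decoder
is acausal within a trajectory by construction (the center expectations
run over the full trajectory); this is deliberate — it is the trajectory-
level definition of the center, not a filtering scheme.

The objective is

    S = E_t[ |x_t - x_hat_t|^2 + lambda |g_t|_1 / N_g ],   lambda = 10.

The L1 'energy' term is normalized by `N_g`. Rationale: with 500 units and
activities of order one, a raw 1-norm at `lambda = 10` would be two to
three orders of magnitude larger than a squared decoding error bounded by
the arena size, and the regularizer would dominate the task entirely. The
per-unit mean keeps the two terms commensurate while preserving the
sparsity pressure; `LossConfig(normalize_l1=False)` restores the raw form.

### Gradients

No autodiff framework is used: `backward_trajectory` implements
reverse-mode differentiation by hand — through the two guarded quotients of
the decoder (including the path through `mu`, whose numerator and
denominator both depend on every timestep's activity) and through time in
the RNN. The `max(eps, ·)` guards use the one-sided subgradient active at
the evaluation point, and ReLU kinks use the conventional 0 subgradient at
0. The implementation is validated against central finite differences on a
5-recurrent/3-output-unit network over 20 steps (relative error under
1e-4 in the acceptance suite; in practice ~1e-6 at double precision).

Training uses single precision; analysis oracles and finite-difference
checks run in double precision.

## Arenas

Six arenas, each with a unique context index: square (0), large square
(1), rectangle (2), circle (3), square with a thin central dividing wall
(4), square with a central hole (5). Dimensions are a package choice (the
task only fixes the shapes): the reference square is 2.2 × 2.2 arena units
centered at the origin, the large square scales it by 1.5, the rectangle
halves the y-extent, the circle has radius 1.1, the dividing wall runs
from the top wall's midpoint to the arena center, and the hole is a
centered square with one-third the side length. At this scale the speed
process (Rayleigh sigma = 0.5, dt = 0.1) crosses the arena in roughly 35
steps, so a 250–500-step trajectory samples the geometry well. All
dimensions live in one constructor and can be overridden by building
`Environment` objects directly.

Interior tests use horizontal ray casting with odd/even crossing parity.
The thin dividing wall is stored as two superimposed segments: crossing it
changes the parity count by two, leaving inside/outside labels unaffected,
while collision tests still detect it. The hole's loop is stored once, so
parity correctly labels the hole's interior as outside. Rays that would
pass exactly through a wall vertex are broken by a deterministic 1e-9
jitter of the query ordinate. Boundary-grazing steps count as collisions,
which keeps simulated positions strictly interior.

`arc_inside_fraction` — the fraction of a circle's circumference inside
the arena, needed by Ripley's edge correction — uses 720 equally spaced
boundary samples (<0.5° resolution) and is floored at 1/720 so the
correction weights stay finite.

## Trajectory simulation

Speeds are Rayleigh(sigma = 0.5); headings are von Mises centered on the
previous heading with concentration kappa = 4; positions advance by
forward Euler with dt = 0.1. A step that would cross a wall has its
*heading* resampled (up to 100 times) until the step is allowed; speeds
are never resampled, which produces smooth paths that turn away from
boundaries. If the resample budget is exhausted (acute corners), the
heading is reversed and the speed repeatedly halved until the step fits —
a geometrically terminating escape that never freezes the walker. The
initial heading is uniform on [0, 2pi). Stored velocities are the realized
displacement divided by dt, i.e. what the walker actually did, and
positions are re-quantized to `pos + vel*dt` so the Euler identity holds
bit-exactly in the stored arrays.

The full dataset holds 15000 trajectories of 500 steps, 80/20
train/validation, balanced across the six arenas within each split.
Trajectories are grouped into chains of 10 for stateful replay; the
arena changes at random from one trajectory of a chain to the next
(balanced assignments are permuted before chunking). Chains are fixed at
build time; epoch shuffling permutes chains only.

## Training

Each trajectory is one truncated-BPTT segment: the recurrent state is
carried (detached) across the 10 trajectories of a chain and reset to zero
at chain boundaries, so the network starts every chain with no positional
information and must relocalize from boundary interactions. One Adam
update (lr 1e-4, default moments) is taken per trajectory; minibatches are
lanes of chains replayed in parallel. Gradient clipping is off; the
identity initialization of `W_R` is the stated mitigation for exploding
gradients. A non-finite loss aborts with a diagnostic.

Validation mirrors training statefulness (chains of 10, zero reset,
frozen weights). Reported errors are mean Euclidean distances between true
and decoded positions including the uninformed initial timesteps; the
per-timestep curve aggregates by position within a trajectory.

### Desk-scale preset

The full configuration (100 epochs, N_g = 500, six arenas, 15000×500
samples) is an hours-long CPU run. The test suite and the acceptance
script use a reduced preset: N_g = 128, N_p = 64, all six arenas, 1200
trajectories of 250 steps. Keeping the complete arena set matters: global
remapping is driven by context-signal inhibition orthogonalizing the
per-arena representations, and a miniature with only two contexts learns
visibly partial remapping (cross-context ratemap correlations remain above
the shuffled null), whereas the six-context miniature reproduces the
full signature. At this scale an epoch holds very few minibatches, so what
must be preserved is the number of gradient updates, not the epoch count:
the preset uses batch 16 and 300 epochs, i.e. 18000 updates — comparable
to the full run's ~23400 — at identical floating-point cost per epoch
(~6.5 minutes single-threaded in total). Validation is evaluated every
fifth epoch and at the last one.

Near convergence the recurrent matrix must sit at marginal stability
(path integration is integration), and constant-learning-rate updates can
overshoot into a regime where the forward states explode over the
2500-step stateful chains. The preset therefore anneals the learning rate
linearly to 10% over the final third of training, which in practice
removes the overshoots entirely and lets the network settle into a
globally stable solution. As a second line of defense the trainer
checkpoints at epoch boundaries; on a non-finite loss it restores the
previous epoch and halves the learning rate (the full-scale default keeps
the abort-with-diagnostic contract instead).

The preset exists to let the qualitative signatures — error reduction over
training, within-trajectory error decay, global remapping, post-noise
attractor recovery at moderate noise — emerge in minutes; it does not
reproduce the full model's quantitative error floor.

## Experiments (frozen weights)

All protocols run with frozen parameters and freshly simulated paths.

- **Remapping (A→B→A')**: square → square-with-wall → square, recurrent
  state carried across transfers, start position re-sampled per segment.
  Condition ratemaps aggregate 500 distinct 800-step runs.
- **Geometric manipulations**: wall coordinates are transformed about the
  arena center (x or x+y elongation ×2/×3, hole removal, circle
  expansion); trajectories are re-simulated in the transformed arena while
  the familiar context signal is fed.
- **Noise injection**: at step tau = 400 of 800-step runs (1000 runs),
  the recurrent state becomes `[g + chi]_+`, chi ~ N(0, sigma^2),
  sigma in {0, 0.01, 0.1, 1}. The noise RNG is independent of the
  trajectory RNG. Velocity ablation zeroes the velocity input from tau
  onward (context intact) to rule out boundary-interaction error
  correction as the sole recovery mechanism.
- **Context mismatch**: simulate in geometry A while feeding context B.

### Attractor recovery at desk scale

Noise-injection runs on the trained preset reproduce the dip-and-recover
population-vector signature at both moderate (sigma = 0.1) and strong
(sigma = 1.0, tens of times the per-unit activity scale) perturbations,
with recovery to ~100% of the pre-injection plateau — the learned
representation is an approximate attractor. Convergence matters here:
under-converged models (constant learning rate, or a fraction of the
preset's updates) recover from sigma = 0.1 but are only locally stable —
a sigma = 1.0 kick pushes the state out of the attractor basin, where the
super-unit eigenvalues of the learned recurrent matrix let it grow
without bound. The annealed preset does not exhibit this.

The aggregated remapping ratemaps exclude the first 100 steps of each
800-step segment: after a transfer the carried recurrent state needs a
settling period before the representation reflects the new condition,
and condition ratemaps are meant to capture the settled representation —
the same reasoning as the burn-in for long single runs.

## Statistics

- **Ratemaps**: occupancy-normalized mean activity on a 16×16 grid over
  the arena bounding box (15×15 for experimental-style maps); unvisited
  bins are NaN, never zero. A 500-step burn-in is discarded for single
  long runs; aggregated short runs use none.
- **Smoothing**: Gaussian kernel (sigma = 1 pixel) with NaN-aware
  renormalization — the zero-filled map and the defined-bin mask are both
  blurred and their ratio taken, which fills unvisited bins from their
  neighbors and leaves fully isolated regions undefined.
- **Spatial correlation**: Pearson over jointly defined bins, maximized
  over ratemap rotations {0, 90, 180, 270}° (square grids; {0, 180}° for
  rectangular ones); fewer than 3 joint bins gives NaN. The shuffled null
  pairs every active unit with every *other* active unit across
  conditions. Ties in the rotation maximum keep the first maximizing
  rotation in listing order.
- **Rate overlap / difference**: min/max and (a−b)/(a+b) of condition
  mean rates; shuffled nulls use 1000 random pairings. "Active" means any
  strictly positive activity sample in the condition.
- **PV correlation**: Pearson between stacked flattened smoothed unit
  ratemaps; the time-resolved variant builds one ratemap stack per
  timepoint from trial-aggregated states and correlates all timepoint
  pairs, restricted to bins defined at every timepoint.
- **Spatial information**: S = sum_i p_i (f_i/fbar) log2(f_i/fbar) with
  occupancy p_i over visited bins and fbar the occupancy-weighted mean
  rate. This is the standard bits-per-activity form; it is 0 for uniform
  maps and log2(M) for a one-hot map over M equally occupied bins.
  High-SI unit selection keeps units strictly above the per-arena
  percentile (2.5th for inclusion filters, 75th for field-center
  decoding) in every arena considered.
- **Ripley's K/H**: K(R) = |Omega|/(N(N−1)) × sum over ordered pairs
  within R of the symmetric edge correction f(x,y) = (k(x,y)+k(y,x))/2,
  where k is the reciprocal arc-inside fraction; H(R) = sqrt(K/pi) − R.
  Fifty radii, log-spaced from 1e-8 to a quarter of the domain diagonal.
  The uniform baseline resamples point sets on the centers of a 15×15
  grid (matching experimental ratemap resolution) and reports mean ± 2 SD
  of H over 100 samplings.
- **KDE**: Gaussian kernels, bandwidth 0.2 in the units of the supplied
  points, evaluated on a 64×64 grid.
- **PCA / weight diagnostics**: explained-variance fractions of the state
  covariance; eigenvalue spectrum of W_R; Pearson correlations between
  the six context columns of W_I and their negative-weight fractions.

## What the synthetic data does and does not emulate

The simulator reproduces the statistical structure the model is trained
on: semi-smooth foraging with Rayleigh speeds and von Mises heading
persistence, wall avoidance, uniform starts, and multi-arena context
switches. It does not emulate real rodent behavior beyond this — no speed
modulation near walls, no head-direction dynamics, no landmark or sensory
input, no inter-animal variability. Passing tests therefore demonstrate
properties of the model under its training distribution, not claims about
biological trajectories; the Ripley/KDE pipeline accepts external field
centers precisely so that real data can be analyzed with the same code.

## Numerical choices and degenerate inputs

- eps = 1e-8 in both decoder quotients; silent units decode to (0, 0) and
  are excluded from analyses by the activity filters.
- Ratemap argmax ties resolve to the first bin in scan order.
- A uniform map smooths to itself exactly (ratio renormalization), and an
  all-NaN map is an error rather than a silent zero map.
- Rate overlap/difference reject units silent in both conditions; the
  analysis layer filters such units before calling them.
- `simulate` re-quantizes positions so stored velocity and position arrays
  satisfy forward-Euler consistency exactly in float64 (1e-6 in the
  float32 dataset containers).

## Known limitations

- The hand-rolled backward pass supports exactly the published
  architecture (one recurrent layer, linear rectified readout, this
  decoder); architectural variants require extending it.
- At desk scale, some quantitative results (e.g. the full model's
  validation error floor near 0.15) are out of reach; the package treats
  them as full-scale runs, reproducible via the CLI with the default
  configuration.
- The rotation-searched spatial correlation is only defined for square or
  axis-aligned rectangular grids.
- Ripley's correction uses angular sampling (720 points) rather than
  exact circular-arc clipping; agreement with an exact geometric oracle
  is ~1% at the radii used, which is well inside the baseline envelope
  width.
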