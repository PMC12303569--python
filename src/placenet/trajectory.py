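"""Constrained random-walk trajectory simulation and dataset assembly.

Foraging paths are generated step by step: speeds are Rayleigh(sigma)
draws, headings are von Mises draws centered on the previous heading
(concentration kappa), and positions advance by forward Euler with step
``dt``. When a proposed step would cross a wall, the *heading* is redrawn
until an allowed step is found — step sizes are never resampled — which
yields smooth paths that turn away from boundaries.

Datasets group trajectories into chains of ``chain_length`` (default 10):
during stateful training the recurrent state is carried across the
trajectories of a chain and reset to zero at chain boundaries. Each
trajectory in a chain is placed in an independently random environment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from .geometry import (
    ENV_NAMES,
    N_CONTEXTS,
    Environment,
    make_environment,
    point_inside,
    sample_uniform,
    segment_hits_wall_batch,
)


@dataclass
class SimulatorConfig:
    """Random-walk parameters.

    sigma_step : Rayleigh scale of the per-step speed (arena units / time).
    kappa : von Mises concentration of the heading about its previous value.
    dt : forward-Euler integration step.
    max_heading_resamples : collision resample budget before the escape rule
        (heading reversal with halved speed) kicks in.
    """

    sigma_step: float = 0.5
    kappa: float = 4.0
    dt: float = 0.1
    max_heading_resamples: int = 100

    def __post_init__(self):
        if self.sigma_step <= 0 or self.dt <= 0 or self.kappa < 0:
            raise ValueError("invalid simulator configuration")


@dataclass
class Trajectory:
    """One simulated path: T positions, T velocities, and its context."""

    env_name: str
    positions: np.ndarray  # (T, 2)
    velocities: np.ndarray  # (T, 2); velocities[t] moves positions[t] -> next
    context: np.ndarray  # (6,)
    dt: float


def step(pos, heading, cfg: SimulatorConfig, env: Environment, rng: np.random.Generator):
    """Advance a single walker by one step; returns (new_pos, new_heading, velocity).

    The speed is drawn once; on collision only the heading is redrawn, up to
    ``cfg.max_heading_resamples`` times, after which the heading is reversed
    and the speed halved (repeatedly, so the step always terminates strictly
    inside the arena).
    """
    new_pos, new_heading, vel = _step_batch(
        np.asarray(pos, dtype=float)[None],
        np.asarray([heading], dtype=float),
        cfg,
        env,
        rng,
    )
    return new_pos[0], float(new_heading[0]), vel[0]


def _step_batch(pos, heading, cfg, env, rng):
    """Vectorized step for (n, 2) walkers; see :func:`step`."""
    n = len(pos)
    speed = rng.rayleigh(cfg.sigma_step, n)
    prop = rng.vonmises(heading, cfg.kappa)
    new = pos + (speed * cfg.dt)[:, None] * np.stack([np.cos(prop), np.sin(prop)], axis=1)
    hits = segment_hits_wall_batch(pos, new, env)
    tries = 0
    while hits.any() and tries < cfg.max_heading_resamples:
        idx = np.flatnonzero(hits)
        prop[idx] = rng.vonmises(heading[idx], cfg.kappa)
        new[idx] = pos[idx] + (speed[idx] * cfg.dt)[:, None] * np.stack(
            [np.cos(prop[idx]), np.sin(prop[idx])], axis=1
        )
        hits[idx] = segment_hits_wall_batch(pos[idx], new[idx], env)
        tries += 1
    # escape rule for walkers stuck in tight corners: reverse and shrink
    while hits.any():
        idx = np.flatnonzero(hits)
        prop[idx] = np.mod(prop[idx] + np.pi, 2 * np.pi)
        speed[idx] *= 0.5
        new[idx] = pos[idx] + (speed[idx] * cfg.dt)[:, None] * np.stack(
            [np.cos(prop[idx]), np.sin(prop[idx])], axis=1
        )
        hits[idx] = segment_hits_wall_batch(pos[idx], new[idx], env)
        if speed.max() < 1e-12:  # pragma: no cover - geometric safeguard
            new[idx] = pos[idx]
            break
    vel = (new - pos) / cfg.dt
    # re-quantize so pos + vel*dt reproduces the stored position bit-exactly
    new = pos + vel * cfg.dt
    return new, prop, vel


def simulate(
    env: Environment,
    T: int,
    cfg: SimulatorConfig | None = None,
    rng: np.random.Generator | None = None,
    start=None,
) -> Trajectory:
    """Simulate one trajectory of ``T`` positions inside ``env``.

    The start (and the initial heading, uniform on [0, 2pi)) are drawn at
    random unless ``start`` is given. ``velocities[t]`` is the realized
    displacement over ``dt``, so ``positions[t+1] = positions[t] +
    velocities[t] * dt`` holds exactly for t < T-1.
    """
    batch = simulate_batch(env, 1, T, cfg, rng, starts=None if start is None else np.asarray(start)[None])
    return Trajectory(env.name, batch[0][0], batch[1][0], env.context_vector(), (cfg or SimulatorConfig()).dt)


def simulate_batch(
    env: Environment,
    n: int,
    T: int,
    cfg: SimulatorConfig | None = None,
    rng: np.random.Generator | None = None,
    starts: np.ndarray | None = None,
):
    """Simulate ``n`` independent trajectories in lockstep.

    Returns ``(positions, velocities)`` with shapes (n, T, 2). Internally
    T steps are taken from the start so every stored velocity corresponds
    to a realized displacement.
    """
    if T < 2:
        raise ValueError("T must be >= 2")
    cfg = cfg or SimulatorConfig()
    rng = rng if rng is not None else np.random.default_rng()
    if starts is None:
        pos = sample_uniform(env, n, rng)
    else:
        pos = np.array(starts, dtype=float).reshape(n, 2)
        if not point_inside(pos, env).all():
            raise ValueError("start position outside environment")
    heading = rng.uniform(0.0, 2.0 * np.pi, n)
    positions = np.empty((n, T, 2))
    velocities = np.empty((n, T, 2))
    for t in range(T):
        positions[:, t] = pos
        pos, heading, vel = _step_batch(pos, heading, cfg, env, rng)
        velocities[:, t] = vel
    return positions, velocities


# ---------------------------------------------------------------------------
# datasets


@dataclass
class Dataset:
    """Precomputed trajectory dataset grouped into stateful chains.

    Arrays are indexed by trajectory; ``chains[c]`` lists the trajectory
    indices of chain ``c`` in replay order, and ``train_chain`` flags the
    training split (the rest is validation).
    """

    positions: np.ndarray  # (n_traj, T, 2) float32
    velocities: np.ndarray  # (n_traj, T, 2) float32
    context_index: np.ndarray  # (n_traj,) int16
    chains: np.ndarray  # (n_chains, chain_length) int32
    train_chain: np.ndarray  # (n_chains,) bool
    dt: float = 0.1
    env_names: tuple = field(default_factory=lambda: ENV_NAMES)

    @property
    def T(self) -> int:
        return self.positions.shape[1]

    @property
    def chain_length(self) -> int:
        return self.chains.shape[1]

    def contexts_onehot(self, idx) -> np.ndarray:
        out = np.zeros((len(idx), N_CONTEXTS), dtype=self.positions.dtype)
        out[np.arange(len(idx)), self.context_index[idx]] = 1.0
        return out

    def chain_ids(self, train: bool) -> np.ndarray:
        return np.flatnonzero(self.train_chain if train else ~self.train_chain)

    def save(self, path) -> None:
        with h5py.File(path, "w") as fh:
            for k in ("positions", "velocities", "context_index", "chains", "train_chain"):
                fh.create_dataset(k, data=getattr(self, k))
            fh.attrs["dt"] = self.dt
            fh.attrs["env_names"] = ",".join(self.env_names)

    @classmethod
    def load(cls, path) -> "Dataset":
        with h5py.File(path, "r") as fh:
            return cls(
                positions=fh["positions"][:],
                velocities=fh["velocities"][:],
                context_index=fh["context_index"][:],
                chains=fh["chains"][:],
                train_chain=fh["train_chain"][:].astype(bool),
                dt=float(fh.attrs["dt"]),
                env_names=tuple(str(fh.attrs["env_names"]).split(",")),
            )


def build_dataset(
    envs: list | None = None,
    n_total: int = 15000,
    T: int = 500,
    split: float = 0.8,
    rng: np.random.Generator | None = None,
    cfg: SimulatorConfig | None = None,
    chain_length: int = 10,
) -> Dataset:
    """Assemble a balanced, chained train/validation dataset.

    Both splits contain an equal number of trajectories per environment;
    environment assignments are randomly permuted before chunking into
    chains, so the environment switches at random between consecutive
    trajectories of a chain. Defaults reproduce the full study dataset
    (15000 trajectories of 500 steps, 80/20 split over six arenas).
    """
    envs = envs if envs is not None else [make_environment(n) for n in ENV_NAMES]
    rng = rng if rng is not None else np.random.default_rng()
    cfg = cfg or SimulatorConfig()
    n_env = len(envs)
    n_train = int(round(n_total * split))
    n_val = n_total - n_train
    if n_total % n_env:
        raise ValueError(f"n_total={n_total} not divisible by the number of environments ({n_env})")
    if n_train % chain_length or n_val % chain_length:
        raise ValueError("split sizes must be divisible by the chain length")
    if n_train % n_env or n_val % n_env:
        raise ValueError("split sizes must be divisible by the number of environments")

    env_assign = np.concatenate(
        [rng.permutation(np.repeat(np.arange(n_env), n // n_env)) for n in (n_train, n_val)]
    )
    train_flag = np.concatenate([np.ones(n_train, bool), np.zeros(n_val, bool)])

    positions = np.empty((n_total, T, 2), dtype=np.float32)
    velocities = np.empty((n_total, T, 2), dtype=np.float32)
    context_index = np.empty(n_total, dtype=np.int16)
    for e, env in enumerate(envs):
        idx = np.flatnonzero(env_assign == e)
        P, V = simulate_batch(env, len(idx), T, cfg, rng)
        positions[idx] = P.astype(np.float32)
        velocities[idx] = V.astype(np.float32)
        context_index[idx] = env.context_index

    chains = np.arange(n_total, dtype=np.int32).reshape(-1, chain_length)
    train_chain = train_flag[chains[:, 0]]
    return Dataset(positions, velocities, context_index, chains, train_chain, cfg.dt,
                   tuple(e.name for e in envs))


def save_trajectory_csv(path, traj: Trajectory) -> None:
    """Write a trajectory as CSV with columns t, x, y, vx, vy."""
    T = len(traj.positions)
    table = np.column_stack([np.arange(T), traj.positions, traj.velocities])
    np.savetxt(path, table, delimiter=",", header="t,x,y,vx,vy", comments="")
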