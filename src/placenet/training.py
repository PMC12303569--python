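"""Stateful multi-environment training and decoding-error evaluation.

Chains of ten trajectories are replayed with the recurrent state carried
from the end of one trajectory into the next (the environment typically
changes at the boundary) and reset to zero at chain boundaries. Gradients
are truncated at trajectory boundaries: each trajectory yields one Adam
update of the objective. Epoch shuffling permutes chains only, so every
epoch replays the same precomputed chains.

The full-study configuration (100 epochs, batch 64, learning rate 1e-4,
N_g=500, N_p=100, six arenas, 15000 trajectories of 500 steps) takes hours
on a single CPU; :func:`TrainConfig.scaled` provides the desk-scale preset
(N_g=128, N_p=64, two arenas, 1200 trajectories of 250 steps, 25 epochs)
used throughout the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import LossConfig, NetworkParams, backward_trajectory, forward_trajectory, init_params
from .trajectory import Dataset


@dataclass
class TrainConfig:
    epochs: int = 100
    batch_size: int = 64
    lr: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-8
    chain_length: int = 10
    seed: int = 0
    n_g: int = 500
    n_p: int = 100
    #: evaluate the validation split every this many epochs (always at the end)
    val_every: int = 1
    #: clip the global gradient norm at this value (None = off, the full-scale
    #: default; the identity initialization is the primary mitigation there)
    clip_norm: float | None = None
    #: on a non-finite loss, restore the last epoch checkpoint and halve the
    #: learning rate instead of aborting (the path-integration solution sits
    #: near marginal recurrent stability, so aggressive training can overshoot)
    recover_on_divergence: bool = False
    #: anneal the learning rate linearly to 10% over the last third of the
    #: epochs; reduces end-of-training instability near marginal stability
    lr_tail_decay: bool = False
    loss: LossConfig = field(default_factory=LossConfig)

    def __post_init__(self):
        if min(self.epochs, self.batch_size, self.chain_length, self.n_g, self.n_p) <= 0:
            raise ValueError("all sizes must be positive")
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")

    @classmethod
    def scaled(cls, seed: int = 0, **kw) -> "TrainConfig":
        """Reduced preset for desk-scale runs.

        Network and data sizes shrink (N_g=128, N_p=64; the matching dataset
        keeps all six arenas at 1200 trajectories of 250 steps), and the
        batch shrinks to 16 with 300 epochs so the number of gradient
        updates (18000) approaches the full run's (~23400) — one epoch of
        the small dataset holds few minibatches, so matching updates, not
        epochs, is what preserves the training regime. Divergence recovery
        is on: near convergence the recurrent matrix sits at marginal
        stability and an update can overshoot into state explosion; the
        loop then restores the last epoch and halves the learning rate.
        """
        kw.setdefault("epochs", 300)
        kw.setdefault("batch_size", 16)
        kw.setdefault("val_every", 5)
        kw.setdefault("recover_on_divergence", True)
        kw.setdefault("lr_tail_decay", True)
        return cls(n_g=128, n_p=64, seed=seed, **kw)


@dataclass
class TrainLog:
    """Per-epoch error curves plus final per-environment/-timestep tables."""

    train_error: np.ndarray  # (epochs,) mean Euclidean decoding error
    val_error: np.ndarray  # (epochs,)
    per_env_error: dict  # env name -> float (final validation)
    per_timestep_error: np.ndarray  # (T,) final validation, by within-trajectory time

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": np.arange(len(self.train_error)),
                "train_error": self.train_error,
                "val_error": self.val_error,
            }
        )

    def save(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


class Adam:
    """Adaptive-moment optimizer over a dict of parameter arrays."""

    def __init__(self, shapes: dict, lr: float, beta1=0.9, beta2=0.999, eps=1e-8, dtype=np.float32):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros(s, dtype=dtype) for k, s in shapes.items()}
        self.v = {k: np.zeros(s, dtype=dtype) for k, s in shapes.items()}

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= self.lr * (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)


def _batch_arrays(dataset: Dataset, traj_idx: np.ndarray, dtype):
    X = dataset.positions[traj_idx].astype(dtype, copy=False)
    V = dataset.velocities[traj_idx].astype(dtype, copy=False)
    C = dataset.contexts_onehot(traj_idx).astype(dtype, copy=False)
    return V, C, X


def mean_euclidean_error(X: np.ndarray, X_hat: np.ndarray) -> float:
    return float(np.sqrt(((X - X_hat) ** 2).sum(axis=-1)).mean())


def train(dataset: Dataset, params: NetworkParams | None = None, cfg: TrainConfig | None = None,
          verbose: bool = False):
    """Optimize the network on the dataset's training chains.

    Returns ``(trained params, TrainLog)``. The reported train error is the
    mean Euclidean decoding error accumulated while the weights evolve; the
    validation error is a stateful evaluation with frozen weights after
    each epoch. Aborts on a non-finite loss.
    """
    cfg = cfg or TrainConfig()
    rng = np.random.default_rng(cfg.seed)
    if params is None:
        params = init_params(cfg.n_g, cfg.n_p, rng=rng)
    dtype = params.W_R.dtype
    if dataset.chain_length != cfg.chain_length:
        raise ValueError("dataset chain length does not match the configuration")

    pdict = {"W_R": params.W_R, "W_I": params.W_I, "W_p": params.W_p}
    opt = Adam({k: v.shape for k, v in pdict.items()}, cfg.lr, cfg.beta1, cfg.beta2,
               cfg.adam_eps, dtype=dtype)
    train_chains = dataset.chain_ids(train=True)
    tr_err = np.empty(cfg.epochs)
    va_err = np.empty(cfg.epochs)

    def snapshot():
        return (
            {k: v.copy() for k, v in pdict.items()},
            {k: v.copy() for k, v in opt.m.items()},
            {k: v.copy() for k, v in opt.v.items()},
            opt.t,
        )

    backup = snapshot()
    epoch = 0
    n_recoveries = 0
    recovery_scale = 1.0
    while epoch < cfg.epochs:
        sched = 1.0
        if cfg.lr_tail_decay:
            tail_start = 2 * cfg.epochs // 3
            if epoch >= tail_start:
                frac = (epoch - tail_start) / max(1, cfg.epochs - tail_start)
                sched = 1.0 - 0.9 * frac
        opt.lr = cfg.lr * sched * recovery_scale
        order = rng.permutation(train_chains)
        err_sum, err_n = 0.0, 0
        diverged = False
        for b0 in range(0, len(order), cfg.batch_size):
            chain_batch = dataset.chains[order[b0 : b0 + cfg.batch_size]]
            B = len(chain_batch)
            g = np.zeros((B, params.n_g), dtype=dtype)
            for k in range(dataset.chain_length):
                V, C, X = _batch_arrays(dataset, chain_batch[:, k], dtype)
                fwd, grads = backward_trajectory(params, V, C, X, g0=g, cfg=cfg.loss)
                if not np.isfinite(fwd["loss"]):
                    if not cfg.recover_on_divergence or n_recoveries >= 12:
                        raise FloatingPointError(
                            f"non-finite loss at epoch {epoch}, chain step {k}: {fwd['loss']}"
                        )
                    diverged = True
                    break
                if cfg.clip_norm is not None:
                    gn = np.sqrt(sum(float((g_ * g_).sum()) for g_ in grads.values()))
                    if gn > cfg.clip_norm:
                        scale = np.float32(cfg.clip_norm / gn)
                        grads = {k_: g_ * scale for k_, g_ in grads.items()}
                opt.step(pdict, grads)
                g = fwd["G"][:, -1]  # carried, detached state
                err_sum += mean_euclidean_error(X, fwd["X_hat"]) * B
                err_n += B
            if diverged:
                break
        if diverged:
            # overshoot past marginal recurrent stability: back up one epoch
            # and continue more cautiously
            n_recoveries += 1
            saved_p, saved_m, saved_v, saved_t = backup
            for k_ in pdict:
                pdict[k_][...] = saved_p[k_]
                opt.m[k_][...] = saved_m[k_]
                opt.v[k_][...] = saved_v[k_]
            opt.t = saved_t
            recovery_scale *= 0.5
            if verbose:
                print(f"epoch {epoch:3d}  diverged; restored checkpoint, "
                      f"lr scale -> {recovery_scale:.3f}")
            continue
        tr_err[epoch] = err_sum / err_n
        if (epoch + 1) % cfg.val_every == 0 or epoch == cfg.epochs - 1:
            va_err[epoch] = evaluate(params, dataset, train=False, cfg=cfg)["error"]
        else:  # carry the latest evaluation forward to keep the log dense
            va_err[epoch] = va_err[epoch - 1] if epoch else np.nan
        if verbose:
            print(f"epoch {epoch:3d}  train {tr_err[epoch]:.4f}  val {va_err[epoch]:.4f}")
        backup = snapshot()
        epoch += 1

    report = evaluate(params, dataset, train=False, cfg=cfg)
    log = TrainLog(tr_err, va_err, report["per_env"], report["per_timestep"])
    return params, log


def evaluate(params: NetworkParams, dataset: Dataset, train: bool = False,
             cfg: TrainConfig | None = None, batch_size: int | None = None) -> dict:
    """Stateful decoding-error report on one split of a dataset.

    Chains are replayed exactly as in training (zero state at chain start,
    carried between trajectories) with frozen weights. Returns the overall
    mean Euclidean error, a per-environment breakdown, and the error by
    within-trajectory timestep (averaged over all trajectories, so t=0
    reflects starts with no or stale positional information).
    """
    cfg = cfg or TrainConfig()
    bs = batch_size or cfg.batch_size
    dtype = params.W_R.dtype
    chains = dataset.chain_ids(train=train)
    T = dataset.T
    per_t = np.zeros(T)
    per_env_sum: dict = {}
    per_env_n: dict = {}
    n_traj = 0
    for b0 in range(0, len(chains), bs):
        chain_batch = dataset.chains[chains[b0 : b0 + bs]]
        B = len(chain_batch)
        g = np.zeros((B, params.n_g), dtype=dtype)
        for k in range(dataset.chain_length):
            idx = chain_batch[:, k]
            V, C, X = _batch_arrays(dataset, idx, dtype)
            fwd = forward_trajectory(params, V, C, X, g0=g, cfg=cfg.loss)
            g = fwd["G"][:, -1]
            d = np.sqrt(((X - fwd["X_hat"]) ** 2).sum(axis=-1))  # (B, T)
            per_t += d.sum(axis=0)
            n_traj += B
            for e in np.unique(dataset.context_index[idx]):
                sel = dataset.context_index[idx] == e
                name = _env_name(dataset, e)
                per_env_sum[name] = per_env_sum.get(name, 0.0) + float(d[sel].mean() * sel.sum())
                per_env_n[name] = per_env_n.get(name, 0) + int(sel.sum())
    per_t /= max(n_traj, 1)
    per_env = {k: per_env_sum[k] / per_env_n[k] for k in per_env_sum}
    return {"error": float(per_t.mean()), "per_env": per_env, "per_timestep": per_t}


def _env_name(dataset: Dataset, context_index: int) -> str:
    from .geometry import ENV_NAMES

    return ENV_NAMES[int(context_index)]


def untrained_baseline(dataset: Dataset, cfg: TrainConfig) -> dict:
    """Evaluation report of a freshly initialized (identity W_R) network."""
    rng = np.random.default_rng(cfg.seed)
    params = init_params(cfg.n_g, cfg.n_p, rng=rng)
    return evaluate(params, dataset, train=False, cfg=cfg)
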