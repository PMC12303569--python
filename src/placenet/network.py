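"""Recurrent path-integration network with a fixed center-of-mass decoder.

The model is a one-layer vanilla RNN with rectified units and no biases:

    g_{t+1} = [W_R g_t + W_I cat(v_t, c)]_+        (recurrent layer, N_g units)
    p_t     = [W_p g_t]_+                          (output layer, N_p units)

Position is never predicted directly. Instead, each output unit is assigned
a center — the activity-weighted time-average of the trajectory positions,

    mu_i = sum_t p_i(t) x_t / max(eps, sum_t p_i(t)),

and the decoded position is the activity-weighted average of those centers,

    x_hat_t = sum_i p_i(t) mu_i / max(eps, sum_i p_i(t)).

The decoder has no trainable parameters but is differentiable end to end;
the training objective is the mean squared decoding error plus an L1
'energy' penalty on the recurrent state,

    S = E_t[ |x_t - x_hat_t|^2 + lambda |g_t|_1 / N_g ].

The L1 norm is normalized per unit so that the penalty stays commensurate
with a squared error of order one (a switch restores the raw 1-norm).

Because no autodiff framework is used, :func:`backward_trajectory`
implements reverse-mode gradients through the decoder (including the flow
through mu) and backpropagation through time; it is validated against
central finite differences in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

N_VELOCITY = 2
N_CONTEXT = 6
N_INPUT = N_VELOCITY + N_CONTEXT

try:  # the sequential recurrences dominate training time; JIT them if possible
    import numba

    @numba.njit(cache=True)
    def _forward_recurrence(g0, WRT, drive, G):
        B, T, N = G.shape
        g = g0.copy()
        G[:, 0] = g
        for t in range(1, T):
            a = np.dot(g, WRT) + drive[:, t - 1]
            g = a * (a > 0)  # dtype-preserving rectification
            G[:, t] = g

    @numba.njit(cache=True)
    def _backward_recurrence(dG, G, W_R, dA):
        B, T, N = G.shape
        carry = np.zeros((B, N), dtype=G.dtype)
        for t in range(T - 1, 0, -1):
            da = (dG[:, t] + carry) * (G[:, t] > 0)
            dA[:, t] = da
            carry = np.dot(da, W_R)

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a standard dependency
    _HAVE_NUMBA = False


@dataclass
class LossConfig:
    """Objective hyperparameters: L1 coefficient and zero-division guard."""

    lambda_l1: float = 10.0
    epsilon: float = 1e-8
    #: divide |g|_1 by N_g (keeps the penalty commensurate with the MSE)
    normalize_l1: bool = True
    #: compute unit centers outside the gradient graph
    stop_gradient_centers: bool = False

    def __post_init__(self):
        if self.lambda_l1 < 0:
            raise ValueError("lambda_l1 must be >= 0")


@dataclass
class NetworkParams:
    """Weight matrices of the model (no biases).

    ``W_R`` (N_g, N_g) recurrent, ``W_I`` (N_g, 8) input (2 velocity + 6
    context channels), ``W_p`` (N_p, N_g) readout.
    """

    W_R: np.ndarray
    W_I: np.ndarray
    W_p: np.ndarray

    def __post_init__(self):
        ng = self.W_R.shape[0]
        if self.W_R.shape != (ng, ng) or self.W_I.shape[0] != ng or self.W_p.shape[1] != ng:
            raise ValueError("inconsistent parameter shapes")

    @property
    def n_g(self) -> int:
        return self.W_R.shape[0]

    @property
    def n_p(self) -> int:
        return self.W_p.shape[0]

    def copy(self) -> "NetworkParams":
        return NetworkParams(self.W_R.copy(), self.W_I.copy(), self.W_p.copy())

    def astype(self, dtype) -> "NetworkParams":
        return NetworkParams(
            self.W_R.astype(dtype), self.W_I.astype(dtype), self.W_p.astype(dtype)
        )

    def save(self, path, meta: dict | None = None) -> None:
        """Write weights as an .npz container with a JSON sidecar."""
        np.savez(path, W_R=self.W_R, W_I=self.W_I, W_p=self.W_p)
        side = {"n_g": self.n_g, "n_p": self.n_p, "n_input": self.W_I.shape[1]}
        side.update(meta or {})
        with open(str(path) + ".json", "w") as fh:
            json.dump(side, fh, indent=1)

    @classmethod
    def load(cls, path) -> "NetworkParams":
        with np.load(path) as fh:
            return cls(fh["W_R"], fh["W_I"], fh["W_p"])


def init_params(
    n_g: int = 500,
    n_p: int = 100,
    n_input: int = N_INPUT,
    rng: np.random.Generator | None = None,
    dtype=np.float32,
) -> NetworkParams:
    """Fresh parameters: identity recurrent matrix (mitigates exploding and
    vanishing gradients over the long sequences used in training) and
    feedforward weights uniform in (-k, k) with k = 1/sqrt(fan-in)."""
    rng = rng if rng is not None else np.random.default_rng()
    k_i = 1.0 / np.sqrt(n_input)
    k_p = 1.0 / np.sqrt(n_g)
    return NetworkParams(
        W_R=np.eye(n_g, dtype=dtype),
        W_I=rng.uniform(-k_i, k_i, size=(n_g, n_input)).astype(dtype),
        W_p=rng.uniform(-k_p, k_p, size=(n_p, n_g)).astype(dtype),
    )


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def rnn_step(g: np.ndarray, v: np.ndarray, c: np.ndarray, params: NetworkParams) -> np.ndarray:
    """One recurrent update g' = [W_R g + W_I cat(v, c)]_+ (single state)."""
    g = np.asarray(g)
    i = np.concatenate([np.asarray(v), np.asarray(c)])
    if g.shape != (params.n_g,) or i.shape != (params.W_I.shape[1],):
        raise ValueError("shape mismatch in rnn_step")
    return relu(params.W_R @ g + params.W_I @ i)


def readout(g: np.ndarray, params: NetworkParams) -> np.ndarray:
    """Output activity p = [W_p g]_+."""
    g = np.asarray(g)
    if g.shape[-1] != params.n_g:
        raise ValueError("shape mismatch in readout")
    return relu(g @ params.W_p.T)


def decode_centers(P: np.ndarray, X: np.ndarray, epsilon: float = 1e-8) -> np.ndarray:
    """Activity-weighted center of each output unit.

    ``P`` is (T, N_p) activity, ``X`` is (T, 2) positions; returns (N_p, 2).
    The time-expectations in numerator and denominator share the 1/T factor,
    so sums are used. Units that are silent over the whole trajectory get
    the guard center (0, 0).
    """
    P = np.asarray(P)
    X = np.asarray(X)
    num = P.T @ X  # (N_p, 2)
    den = np.maximum(epsilon, P.sum(axis=0))[:, None]
    return num / den


def decode_position(p: np.ndarray, mu: np.ndarray, epsilon: float = 1e-8) -> np.ndarray:
    """Center-of-mass position estimate from one activity vector.

    Accepts (N_p,) or (T, N_p) activity; returns (2,) or (T, 2).
    """
    p = np.asarray(p)
    mu = np.asarray(mu)
    single = p.ndim == 1
    P = np.atleast_2d(p)
    num = P @ mu  # (T, 2)
    den = np.maximum(epsilon, P.sum(axis=1))[:, None]
    out = num / den
    return out[0] if single else out


def objective(X: np.ndarray, X_hat: np.ndarray, G: np.ndarray, cfg: LossConfig | None = None) -> float:
    """Mean squared decoding error plus the L1 state penalty.

    Arrays may be (T, ...) or batched (B, T, ...); the reduction is the mean
    over time (and batch) of the squared Euclidean error, plus lambda times
    the mean over time of the (optionally per-unit-normalized) 1-norm of g.
    """
    cfg = cfg or LossConfig()
    X = np.asarray(X)
    X_hat = np.asarray(X_hat)
    G = np.asarray(G)
    if X.shape != X_hat.shape:
        raise ValueError("shape mismatch between targets and estimates")
    mse = float(((X - X_hat) ** 2).sum(axis=-1).mean())
    l1 = float(np.abs(G).sum(axis=-1).mean())
    if cfg.normalize_l1:
        l1 /= G.shape[-1]
    return mse + cfg.lambda_l1 * l1


# ---------------------------------------------------------------------------
# batched rollout and hand-derived gradients


def rollout(
    params: NetworkParams,
    V: np.ndarray,
    C: np.ndarray,
    g0: np.ndarray | None = None,
    noise_hook=None,
):
    """Roll the recurrent layer over a batch of input sequences.

    ``V`` is (B, T, 2) velocities, ``C`` is (B, 6) constant context (or
    (B, T, 6) if time varying), ``g0`` the (B, N_g) initial state (zeros by
    default: no positional information at the start). Returns ``(G, P)``
    with G (B, T, N_g) where ``G[:, 0] = g0`` — state t >= 1 integrates
    velocities v_0..v_{t-1} and therefore encodes position x_t — and the
    output activity P (B, T, N_p).

    ``noise_hook(t, g) -> g`` may perturb the state right after step t is
    produced (used by the noise-injection experiments).
    """
    B, T, _ = V.shape
    dtype = params.W_R.dtype
    if g0 is None:
        g0 = np.zeros((B, params.n_g), dtype=dtype)
    C = np.asarray(C, dtype=dtype)
    Ct = np.broadcast_to(C[:, None, :], (B, T, C.shape[-1])) if C.ndim == 2 else C
    G = np.empty((B, T, params.n_g), dtype=dtype)
    g = np.asarray(g0, dtype=dtype)
    if noise_hook is not None:
        g = noise_hook(0, g)
    G[:, 0] = g
    WRT = np.ascontiguousarray(params.W_R.T)
    # input drive is state-independent: project all timesteps in one matmul
    inputs = np.concatenate([V, Ct], axis=2).astype(dtype, copy=False)
    drive = inputs.reshape(B * T, -1) @ params.W_I.T
    drive = drive.reshape(B, T, params.n_g)
    if noise_hook is None and _HAVE_NUMBA:
        _forward_recurrence(np.ascontiguousarray(g), WRT, drive, G)
    else:
        for t in range(1, T):
            g = relu(g @ WRT + drive[:, t - 1])
            if noise_hook is not None:
                g = noise_hook(t, g)
            G[:, t] = g
    P = relu(G.reshape(B * T, -1) @ params.W_p.T).reshape(B, T, params.n_p)
    return G, P


def forward_trajectory(
    params: NetworkParams,
    V: np.ndarray,
    C: np.ndarray,
    X: np.ndarray,
    g0: np.ndarray | None = None,
    cfg: LossConfig | None = None,
):
    """Full forward pass: rollout, per-trajectory centers, decoded positions,
    and the objective.

    ``X`` is (B, T, 2) true positions. Centers are estimated from the same
    trajectory's activity (per batch element, over all T steps). Returns a
    dict with G, P, mu (B, N_p, 2), X_hat (B, T, 2) and the scalar loss.
    """
    cfg = cfg or LossConfig()
    X = np.asarray(X, dtype=params.W_R.dtype)
    G, P = rollout(params, np.asarray(V, dtype=params.W_R.dtype), C, g0)
    eps = cfg.epsilon
    Pt = P.transpose(0, 2, 1)  # (B, N_p, T)
    num_mu = Pt @ X  # (B, N_p, 2)
    den_mu = np.maximum(eps, P.sum(axis=1))  # (B, N_p)
    mu = num_mu / den_mu[:, :, None]
    num_x = P @ mu  # (B, T, 2)
    den_x = np.maximum(eps, P.sum(axis=2))  # (B, T)
    X_hat = num_x / den_x[:, :, None]
    loss = objective(X, X_hat, G, cfg)
    return {"G": G, "P": P, "mu": mu, "X_hat": X_hat, "loss": loss}


def backward_trajectory(
    params: NetworkParams,
    V: np.ndarray,
    C: np.ndarray,
    X: np.ndarray,
    g0: np.ndarray | None = None,
    cfg: LossConfig | None = None,
):
    """Forward pass plus reverse-mode gradients of the loss w.r.t. weights.

    Returns ``(fwd, grads)`` where ``grads`` maps {"W_R", "W_I", "W_p"} to
    arrays of the parameter shapes. The decoder is differentiated exactly:
    the loss gradient flows both directly through p_t in x_hat_t and through
    the trajectory-wide centers mu (unless ``cfg.stop_gradient_centers``).
    The max(eps, .) guards use the subgradient that is active on each side.
    """
    cfg = cfg or LossConfig()
    dtype = params.W_R.dtype
    V = np.asarray(V, dtype=dtype)
    X = np.asarray(X, dtype=dtype)
    fwd = forward_trajectory(params, V, C, X, g0, cfg)
    G, P, mu, X_hat = fwd["G"], fwd["P"], fwd["mu"], fwd["X_hat"]
    B, T, _ = X.shape
    eps = cfg.epsilon

    den_x = np.maximum(eps, P.sum(axis=2))  # (B, T)
    act_x = (P.sum(axis=2) > eps).astype(dtype)
    den_mu = np.maximum(eps, P.sum(axis=1))  # (B, N_p)
    act_mu = (P.sum(axis=1) > eps).astype(dtype)

    # dL/dx_hat: mean over batch and time of squared Euclidean error
    E = (2.0 / (B * T)) * (X_hat - X)  # (B, T, 2)
    Ed = E / den_x[:, :, None]

    # direct route: x_hat_t depends on p_t both in numerator and denominator
    dP = Ed @ mu.transpose(0, 2, 1) - ((Ed * X_hat).sum(axis=2) * act_x)[:, :, None]
    if not cfg.stop_gradient_centers:
        # route through the centers: dL/dmu then dmu/dP
        dMu = P.transpose(0, 2, 1) @ Ed  # (B, N_p, 2)
        dMu_d = dMu / den_mu[:, :, None]
        dP += X @ dMu_d.transpose(0, 2, 1) - ((dMu_d * mu).sum(axis=2) * act_mu)[:, None, :]

    mask_p = (P > 0).astype(dtype)
    dPre_p = dP * mask_p  # (B, T, N_p)
    dW_p = dPre_p.reshape(-1, params.n_p).T @ G.reshape(-1, params.n_g)
    dG = dPre_p @ params.W_p  # (B, T, N_g)

    # L1 penalty on the (non-negative) recurrent state
    l1_coef = cfg.lambda_l1 / (B * T)
    if cfg.normalize_l1:
        l1_coef /= params.n_g
    dG += l1_coef * (G > 0)

    Ct = np.broadcast_to(
        np.asarray(C, dtype=dtype)[:, None, :], (B, T, np.asarray(C).shape[-1])
    ) if np.asarray(C).ndim == 2 else np.asarray(C, dtype=dtype)
    inputs = np.concatenate([V, Ct], axis=2)  # (B, T, 8); input t-1 feeds state t

    # sequential part: pre-activation gradients da_t, back through time
    dA = np.zeros((B, T, params.n_g), dtype=dtype)
    if _HAVE_NUMBA:
        _backward_recurrence(np.ascontiguousarray(dG), G, params.W_R, dA)
    else:
        carry = np.zeros((B, params.n_g), dtype=dtype)
        for t in range(T - 1, 0, -1):
            da = (dG[:, t] + carry) * (G[:, t] > 0)
            dA[:, t] = da
            carry = da @ params.W_R
    # weight updates batch over all timesteps at once
    dA2 = dA[:, 1:].reshape(-1, params.n_g)
    dW_R = dA2.T @ G[:, :-1].reshape(-1, params.n_g)
    dW_I = dA2.T @ inputs[:, :-1].reshape(-1, inputs.shape[-1])
    # G[:, 0] is the (detached) initial state: its gradient is dropped.
    return fwd, {"W_R": dW_R, "W_I": dW_I, "W_p": dW_p}
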