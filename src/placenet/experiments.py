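"""Frozen-weight protocols probing the trained network.

All runners leave the parameters untouched (the frozen-weights contract is
asserted in the test suite): they simulate fresh trajectories, roll the
network, and hand back everything needed for ratemaps and population-vector
analyses.

The canonical remapping protocol runs square (A) → square with a central
dividing wall (B) → square again (A'), carrying the recurrent state across
the environment boundaries while re-sampling the start position in each
segment, exactly like moving an animal between recording boxes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np

from .geometry import Environment, make_environment
from .network import N_CONTEXT, NetworkParams, relu, rollout
from .trajectory import SimulatorConfig, simulate_batch


@dataclass
class EpisodeSpec:
    """Ordered multi-environment visit: (env name, context override, steps).

    ``context_override`` of None feeds each segment's own context one-hot.
    """

    segments: list  # of (env_name, context_override or None, duration)
    carry_state: bool = True

    def __post_init__(self):
        for _, _, dur in self.segments:
            if dur < 1:
                raise ValueError("segment durations must be >= 1")


@dataclass
class Manipulation:
    """Geometric deformation of a familiar arena (context kept)."""

    kind: str  # elongate_x | elongate_xy | fill_hole | expand_circle
    factor: int = 2

    def __post_init__(self):
        if self.kind not in ("elongate_x", "elongate_xy", "fill_hole", "expand_circle"):
            raise ValueError(f"unknown manipulation {self.kind!r}")
        if self.factor not in (1, 2, 3):
            raise ValueError("factor must be 1, 2 or 3")


@dataclass
class NoiseSpec:
    """Noise-injection protocol parameters."""

    sigma: float = 1.0
    tau: int = 400
    T: int = 800
    n_traj: int = 1000
    env_name: str = "square"

    def __post_init__(self):
        if not 0 <= self.tau < self.T:
            raise ValueError("tau must lie within the trajectory")


def _context_matrix(n: int, index: int, dtype) -> np.ndarray:
    C = np.zeros((n, N_CONTEXT), dtype=dtype)
    C[:, index] = 1.0
    return C


def run_episode(params: NetworkParams, spec: EpisodeSpec, n_traj: int = 500,
                sim_cfg: SimulatorConfig | None = None,
                rng: np.random.Generator | None = None) -> list:
    """Roll the frozen network across an ordered sequence of environments.

    Each of the ``n_traj`` parallel runs visits every segment; the start
    position is re-sampled uniformly per segment and the recurrent state is
    carried across segment boundaries (zero at the very start, or always
    zero with ``carry_state=False``). Returns one dict per segment with
    keys ``env``, ``positions`` (n, T, 2), ``G``, ``P``.
    """
    sim_cfg = sim_cfg or SimulatorConfig()
    rng = rng if rng is not None else np.random.default_rng()
    dtype = params.W_R.dtype
    g = np.zeros((n_traj, params.n_g), dtype=dtype)
    out = []
    for env_name, ctx_override, T in spec.segments:
        env = env_name if isinstance(env_name, Environment) else make_environment(env_name)
        idx = env.context_index if ctx_override is None else int(ctx_override)
        X, V = simulate_batch(env, n_traj, T, sim_cfg, rng)
        G, P = rollout(params, V.astype(dtype), _context_matrix(n_traj, idx, dtype), g0=g)
        g = G[:, -1] if spec.carry_state else np.zeros_like(g)
        out.append({"env": env, "context_index": idx, "positions": X, "G": G, "P": P})
    return out


def remap_protocol(params: NetworkParams, n_traj: int = 500, T: int = 800,
                   env_a: str = "square", env_b: str = "square_wall",
                   rng: np.random.Generator | None = None) -> list:
    """The A → B → A' remapping run aggregated over short trajectories."""
    spec = EpisodeSpec([(env_a, None, T), (env_b, None, T), (env_a, None, T)])
    return run_episode(params, spec, n_traj=n_traj, rng=rng)


def apply_manipulation(base_env: Environment, manip: Manipulation) -> Environment:
    """Deformed copy of an arena (walls transformed about the arena center).

    The returned environment keeps the base context index, so feeding its
    context vector realizes the familiar-context condition.
    """
    c = base_env.center if base_env.is_circle else base_env.bounding_box.mean(axis=0)
    if manip.kind == "expand_circle":
        if not base_env.is_circle:
            raise ValueError("expand_circle requires the circular arena")
        return dc_replace(base_env, radius=base_env.radius * manip.factor)
    if base_env.is_circle:
        raise ValueError(f"{manip.kind} is incompatible with the circular arena")
    if manip.kind == "fill_hole":
        if not len(base_env.hole_loops):
            raise ValueError("fill_hole requires an arena with a hole")
        return dc_replace(base_env, inner_walls=np.zeros((0, 2, 2)), hole_loops=())
    scale = np.array([manip.factor, manip.factor if manip.kind == "elongate_xy" else 1.0])

    def tf(seg):
        return (seg - c) * scale[None, None, :] + c

    return dc_replace(
        base_env,
        outer_walls=tf(base_env.outer_walls),
        inner_walls=tf(base_env.inner_walls) if len(base_env.inner_walls) else base_env.inner_walls,
        hole_loops=tuple(tf(np.asarray(h)) for h in base_env.hole_loops),
    )


def run_manipulation(params: NetworkParams, base_env: Environment, manip: Manipulation,
                     n_traj: int = 100, T: int = 800,
                     sim_cfg: SimulatorConfig | None = None,
                     rng: np.random.Generator | None = None) -> dict:
    """Run the frozen network in a deformed arena with the familiar context.

    Trajectories are re-simulated in the transformed geometry (not warped);
    the context one-hot stays that of the base arena. Returns positions,
    states, and the transformed environment for ratemap construction.
    """
    env = apply_manipulation(base_env, manip)
    sim_cfg = sim_cfg or SimulatorConfig()
    rng = rng if rng is not None else np.random.default_rng()
    dtype = params.W_R.dtype
    X, V = simulate_batch(env, n_traj, T, sim_cfg, rng)
    C = _context_matrix(n_traj, base_env.context_index, dtype)
    G, P = rollout(params, V.astype(dtype), C)
    return {"env": env, "positions": X, "G": G, "P": P}


def run_noise_injection(params: NetworkParams, spec: NoiseSpec,
                        rng: np.random.Generator | None = None,
                        noise_rng: np.random.Generator | None = None,
                        ablate_velocity: bool = False,
                        sim_cfg: SimulatorConfig | None = None) -> dict:
    """Inject rectified Gaussian noise into the recurrent state mid-run.

    At step ``tau`` the state becomes [g + chi]_+ with chi ~ N(0, sigma^2)
    i.i.d.; the run then continues normally. The trajectory RNG and the
    noise RNG are independent so noise realizations can be varied at fixed
    paths. With ``ablate_velocity`` the velocity inputs are zeroed from
    ``tau`` onward (context intact), removing boundary interactions from
    the recovery.
    """
    sim_cfg = sim_cfg or SimulatorConfig()
    rng = rng if rng is not None else np.random.default_rng()
    noise_rng = noise_rng if noise_rng is not None else np.random.default_rng()
    env = make_environment(spec.env_name)
    dtype = params.W_R.dtype
    X, V = simulate_batch(env, spec.n_traj, spec.T, sim_cfg, rng)
    V_in = V.astype(dtype)
    if ablate_velocity:
        V_in = V_in.copy()
        V_in[:, spec.tau :, :] = 0.0
    chi = (
        noise_rng.normal(0.0, spec.sigma, size=(spec.n_traj, params.n_g)).astype(dtype)
        if spec.sigma > 0
        else None
    )

    def hook(t, g):
        if t == spec.tau and chi is not None:
            return relu(g + chi)
        return g

    C = _context_matrix(spec.n_traj, env.context_index, dtype)
    G, P = rollout(params, V_in, C, noise_hook=hook)
    return {"env": env, "positions": X, "G": G, "P": P, "tau": spec.tau}


def run_velocity_ablation(params: NetworkParams, spec: NoiseSpec,
                          rng: np.random.Generator | None = None,
                          noise_rng: np.random.Generator | None = None,
                          sim_cfg: SimulatorConfig | None = None) -> dict:
    """Noise injection with velocities zeroed from the injection step on."""
    return run_noise_injection(params, spec, rng, noise_rng, ablate_velocity=True, sim_cfg=sim_cfg)


def remap_signature(params: NetworkParams, rng: np.random.Generator, n_traj: int = 500,
                    T: int = 800, env_a: str = "square", env_b: str = "square_wall",
                    bins: int = 16, settle_steps: int = 100) -> dict:
    """Global-remapping signature of the A → B → A' protocol.

    Builds aggregated output-unit ratemaps per condition, computes per-unit
    spatial correlations for the same-context pair (A, A') and the
    cross-context pair (A, B), and compares both against the shuffled
    (unit-mispaired) null. Under global remapping the A–A' correlations of
    most active units exceed the null's 95th percentile while the A–B
    distribution is indistinguishable from the null.

    The first ``settle_steps`` of every segment are excluded from the
    aggregated ratemaps: after a transfer the carried state needs time to
    re-localize, and condition ratemaps should reflect the settled
    representation (the same reasoning behind the burn-in used for long
    single runs).

    Returns the correlation distributions, the shuffled null and its 95th
    percentile, the fraction of active units whose A–A' correlation exceeds
    that percentile, and the two-sample KS p-value of A–B against the null.
    """
    from scipy.stats import ks_2samp

    from .analysis import compute_ratemap, shuffled_null, spatial_correlation

    segs = remap_protocol(params, n_traj=n_traj, T=T, env_a=env_a, env_b=env_b, rng=rng)
    grids = []
    active = []
    for seg in segs:
        P = seg["P"][:, settle_steps:].reshape(-1, params.n_p)
        X = seg["positions"][:, settle_steps:].reshape(-1, 2)
        active.append(P.max(axis=0) > 0)
        grids.append(
            [compute_ratemap(P[:, u], X, seg["env"], bins=bins).grid for u in range(params.n_p)]
        )
    act_aa = active[0] & active[2]
    act_ab = active[0] & active[1]
    corr_aa = np.array(
        [spatial_correlation(grids[0][u], grids[2][u]) for u in np.flatnonzero(act_aa)]
    )
    corr_ab = np.array(
        [spatial_correlation(grids[0][u], grids[1][u]) for u in np.flatnonzero(act_ab)]
    )
    null = shuffled_null(
        [grids[0][u] for u in np.flatnonzero(active[0])],
        [grids[1][u] for u in np.flatnonzero(active[1])],
        mode="correlation",
    )
    corr_aa = corr_aa[~np.isnan(corr_aa)]
    corr_ab = corr_ab[~np.isnan(corr_ab)]
    frac_above = float((corr_aa > null["p95"]).mean()) if len(corr_aa) else np.nan
    ks_p = float(ks_2samp(corr_ab, null["values"]).pvalue) if len(corr_ab) else np.nan
    return {
        "corr_aa": corr_aa,
        "corr_ab": corr_ab,
        "null": null["values"],
        "null_p95": null["p95"],
        "frac_aa_above_null95": frac_above,
        "ks_p_ab_vs_null": ks_p,
    }


def noise_recovery(params: NetworkParams, rng: np.random.Generator,
                   noise_rng: np.random.Generator, sigma: float = 1.0,
                   spec: NoiseSpec | None = None, layer: str = "P",
                   bins: int = 16) -> dict:
    """Population-vector account of a noise-injection run.

    Computes the time-by-time PV correlation matrix of the chosen layer,
    then summarizes recovery relative to the pre-injection plateau: the
    plateau is the mean off-diagonal correlation within the last quarter
    before injection, the dip the minimum correlation of those reference
    times against the 50 steps after injection, and the late value their
    correlation with the final eighth of the run.
    """
    from .analysis import pv_time_correlation

    spec = spec or NoiseSpec(sigma=sigma)
    spec = dc_replace(spec, sigma=sigma)
    res = run_noise_injection(params, spec, rng, noise_rng)
    M = pv_time_correlation(res[layer], res["positions"], res["env"], bins=bins)
    tau, T = spec.tau, spec.T
    ref = slice(max(0, tau - tau // 4), tau)
    block = M[ref, ref]
    off = ~np.eye(block.shape[0], dtype=bool)
    plateau = float(block[off].mean())
    dip = float(M[ref, tau : min(T, tau + 50)].mean(axis=0).min())
    late = float(M[ref, T - T // 8 :].mean())
    return {
        "pv_matrix": M,
        "plateau": plateau,
        "dip": dip,
        "late": late,
        "recovery_ratio": late / plateau if plateau > 0 else np.nan,
        "tau": tau,
    }


def run_context_mismatch(params: NetworkParams, geometry_env: Environment,
                         context_env: Environment, n_traj: int = 100, T: int = 800,
                         sim_cfg: SimulatorConfig | None = None,
                         rng: np.random.Generator | None = None) -> dict:
    """Simulate in one geometry while feeding another arena's context."""
    spec = EpisodeSpec([(geometry_env, context_env.context_index, T)])
    (seg,) = run_episode(params, spec, n_traj=n_traj, sim_cfg=sim_cfg, rng=rng)
    return seg
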