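"""Ratemap and point-pattern statistics for the learned representations.

Covers everything used to characterize the model's units and their
remapping: occupancy-normalized ratemaps with NaN-aware Gaussian smoothing,
per-unit spatial correlations with rotation search and shuffled nulls,
rate overlap/difference, population-vector (PV) correlations, Skaggs
spatial information, PCA spectra, weight diagnostics, and edge-corrected
Ripley's K/H with kernel density estimates for field-center clustering.

The Ripley pipeline accepts generic 2-D point sets and either an
:class:`~placenet.geometry.Environment` or a plain rectangle as the domain,
so externally recorded field centers (e.g. place fields from a 75x75 cm
box) can be analyzed from a 2-column CSV without code changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.decomposition import PCA
from sklearn.neighbors import KernelDensity

from .geometry import Environment, arc_inside_fraction
from .network import NetworkParams, N_VELOCITY


@dataclass
class Ratemap:
    """Binned, occupancy-normalized mean activity of one unit.

    ``grid`` holds the mean rate per bin with NaN marking unvisited bins
    (never zero); ``occupancy`` the per-bin visit counts; ``edges_x`` /
    ``edges_y`` the bin edges tied to the arena bounding box.
    """

    grid: np.ndarray
    occupancy: np.ndarray
    edges_x: np.ndarray
    edges_y: np.ndarray

    @property
    def visited(self) -> np.ndarray:
        return ~np.isnan(self.grid)

    @property
    def mean_rate(self) -> float:
        """Occupancy-weighted mean rate over visited bins."""
        occ = self.occupancy[self.visited]
        return float((self.grid[self.visited] * occ).sum() / occ.sum())

    def bin_centers(self):
        cx = 0.5 * (self.edges_x[:-1] + self.edges_x[1:])
        cy = 0.5 * (self.edges_y[:-1] + self.edges_y[1:])
        return cx, cy


def _domain_box(domain) -> np.ndarray:
    if isinstance(domain, Environment):
        return domain.bounding_box
    return np.asarray(domain, dtype=float).reshape(2, 2)


def compute_ratemap(activity, positions, env, bins: int = 16, burn_in: int = 0) -> Ratemap:
    """Occupancy-normalized ratemap of one unit.

    ``activity`` is the per-sample rate (any shape flattening to n),
    ``positions`` the matching (n, 2) locations. ``burn_in`` samples are
    discarded from the front (use 500 for single long runs so that only the
    steady-state behavior enters; 0 for aggregated short runs).
    """
    a = np.asarray(activity, dtype=float).reshape(-1)
    x = np.asarray(positions, dtype=float).reshape(-1, 2)
    if len(a) != len(x):
        raise ValueError("activity and positions are not aligned")
    a, x = a[burn_in:], x[burn_in:]
    if len(a) == 0:
        raise ValueError("no samples left after burn-in")
    (lo_x, lo_y), (hi_x, hi_y) = _domain_box(env)
    ex = np.linspace(lo_x, hi_x, bins + 1)
    ey = np.linspace(lo_y, hi_y, bins + 1)
    ix = np.clip(np.searchsorted(ex, x[:, 0], side="right") - 1, 0, bins - 1)
    iy = np.clip(np.searchsorted(ey, x[:, 1], side="right") - 1, 0, bins - 1)
    occ = np.zeros((bins, bins))
    tot = np.zeros((bins, bins))
    np.add.at(occ, (ix, iy), 1.0)
    np.add.at(tot, (ix, iy), a)
    with np.errstate(invalid="ignore"):
        grid = np.where(occ > 0, tot / np.maximum(occ, 1), np.nan)
    return Ratemap(grid, occ, ex, ey)


def smooth_grid(grid: np.ndarray, sigma_px: float = 1.0) -> np.ndarray:
    """NaN-aware Gaussian smoothing of one or many stacked maps.

    Unvisited (NaN) bins are filled from neighbors by a renormalized
    kernel: the zero-filled data and the defined-bin mask are both blurred
    and their ratio taken. The last two axes are the spatial ones. Bins
    with no defined neighbor mass remain NaN.
    """
    grid = np.asarray(grid, dtype=float)
    if np.isnan(grid).all():
        raise ValueError("cannot smooth an all-undefined map")
    mask = (~np.isnan(grid)).astype(float)
    filled = np.where(mask > 0, grid, 0.0)
    sig = (0,) * (grid.ndim - 2) + (sigma_px, sigma_px)
    num = ndimage.gaussian_filter(filled, sigma=sig, mode="constant", truncate=4.0)
    den = ndimage.gaussian_filter(mask, sigma=sig, mode="constant", truncate=4.0)
    with np.errstate(invalid="ignore"):
        out = np.where(den > 1e-12, num / np.maximum(den, 1e-300), np.nan)
    return out


def smooth_ratemap(rm: Ratemap, sigma_px: float = 1.0) -> Ratemap:
    """Return a smoothed copy of a ratemap (see :func:`smooth_grid`)."""
    return Ratemap(smooth_grid(rm.grid, sigma_px), rm.occupancy, rm.edges_x, rm.edges_y)


# ---------------------------------------------------------------------------
# remapping measures


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    ok = ~(np.isnan(a) | np.isnan(b))
    if ok.sum() < 3:
        return np.nan
    a, b = a[ok], b[ok]
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def spatial_correlation(grid_a: np.ndarray, grid_b: np.ndarray, try_rotations: bool = True) -> float:
    """Maximal Pearson correlation of two ratemap grids over rigid rotations.

    Rotations of 0/90/180/270 degrees are searched for square grids (0/180
    for rectangular ones); only jointly defined bins enter each Pearson
    correlation. Returns NaN when fewer than 3 bins are jointly defined.
    """
    grid_a = np.asarray(grid_a, dtype=float)
    grid_b = np.asarray(grid_b, dtype=float)
    if grid_a.shape != grid_b.shape:
        raise ValueError("ratemap shapes differ")
    if not try_rotations:
        rots = (0,)
    elif grid_a.shape[0] == grid_a.shape[1]:
        rots = (0, 1, 2, 3)
    else:
        rots = (0, 2)
    vals = [_pearson(np.rot90(grid_a, k).ravel(), grid_b.ravel()) for k in rots]
    vals = [v for v in vals if not np.isnan(v)]
    return max(vals) if vals else np.nan


def rate_overlap(mean_a: float, mean_b: float) -> float:
    """Mean rate in the least active condition over the most active one."""
    hi = max(mean_a, mean_b)
    if hi <= 0:
        raise ValueError("rate overlap requires a unit active in at least one condition")
    return min(mean_a, mean_b) / hi


def rate_difference(mean_a: float, mean_b: float) -> float:
    """Signed normalized rate contrast (a - b) / (a + b)."""
    s = mean_a + mean_b
    if s <= 0:
        raise ValueError("rate difference requires a unit active in at least one condition")
    return (mean_a - mean_b) / s


def shuffled_null(units_a, units_b, mode: str = "correlation", n_pairings: int = 1000,
                  rng: np.random.Generator | None = None, try_rotations: bool = True) -> dict:
    """Shuffled baseline distribution for a remapping measure.

    ``correlation`` mode pairs every unit in ``units_a`` (list of ratemap
    grids) with every *other* unit in ``units_b`` across environments;
    rate modes (``overlap``/``difference``, inputs are per-unit mean rates)
    use ``n_pairings`` random pairings. Returns the distribution and its
    95th percentile.
    """
    if mode == "correlation":
        vals = [
            spatial_correlation(ga, gb, try_rotations)
            for i, ga in enumerate(units_a)
            for j, gb in enumerate(units_b)
            if i != j
        ]
        vals = np.asarray([v for v in vals if not np.isnan(v)])
    elif mode in ("overlap", "difference"):
        rng = rng if rng is not None else np.random.default_rng()
        a = np.asarray(units_a, dtype=float)
        b = np.asarray(units_b, dtype=float)
        fn = rate_overlap if mode == "overlap" else rate_difference
        vals = np.empty(n_pairings)
        for k in range(n_pairings):
            i = rng.integers(len(a))
            j = rng.integers(len(b))
            while j == i and len(b) > 1:
                j = rng.integers(len(b))
            vals[k] = fn(a[i], b[j])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return {"values": vals, "p95": float(np.percentile(vals, 95)) if len(vals) else np.nan}


def pv_correlation(stack_a: np.ndarray, stack_b: np.ndarray) -> float:
    """Pearson correlation between two stacked ratemap population vectors.

    Each stack is (n_units, Nx, Ny) (or already flat); smoothing should be
    applied beforehand and the stacking order must match. Only entries
    defined in both stacks are used.
    """
    return _pearson(np.asarray(stack_a, float).ravel(), np.asarray(stack_b, float).ravel())


def pv_time_correlation(P: np.ndarray, X: np.ndarray, env, bins: int = 16,
                        sigma_px: float = 1.0, active_only: bool = True) -> np.ndarray:
    """Time-by-time PV correlation matrix from trial-aggregated states.

    ``P`` is (n_traj, T, n_units) activity and ``X`` (n_traj, T, 2) the
    matching positions. For each timepoint a ratemap per unit is built by
    binning the n_traj samples at that time, smoothed, stacked, and the
    Pearson correlation between every pair of timepoints returned as a
    (T, T) matrix. Only bins defined at every timepoint (and, with
    ``active_only``, units with nonzero activity somewhere) enter.
    """
    n, T, U = P.shape
    (lo_x, lo_y), (hi_x, hi_y) = _domain_box(env)
    ex = np.linspace(lo_x, hi_x, bins + 1)
    ey = np.linspace(lo_y, hi_y, bins + 1)
    ix = np.clip(np.searchsorted(ex, X[..., 0], side="right") - 1, 0, bins - 1)
    iy = np.clip(np.searchsorted(ey, X[..., 1], side="right") - 1, 0, bins - 1)
    flat = ix * bins + iy  # (n, T)
    maps = np.zeros((T, U, bins * bins))
    occ = np.zeros((T, bins * bins))
    for t in range(T):
        np.add.at(occ[t], flat[:, t], 1.0)
        np.add.at(maps[t].T, flat[:, t], P[:, t, :])
    with np.errstate(invalid="ignore"):
        maps = np.where(occ[:, None, :] > 0, maps / np.maximum(occ[:, None, :], 1), np.nan)
    if active_only:
        used = np.nansum(maps, axis=(0, 2)) > 0
        maps = maps[:, used, :]
    sm = smooth_grid(maps.reshape(T, -1, bins, bins), sigma_px).reshape(T, -1)
    defined = ~np.isnan(sm).any(axis=0)
    sm = sm[:, defined]
    sm = sm - sm.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(sm, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    sm /= norm
    return sm @ sm.T


# ---------------------------------------------------------------------------
# spatial information and unit selection


def spatial_information(rm: Ratemap) -> float:
    """Skaggs spatial information (bits per unit activity).

    S = sum_i p_i (f_i / fbar) log2(f_i / fbar) with occupancy p_i
    normalized over visited bins and fbar the occupancy-weighted mean rate;
    zero-rate bins contribute 0, and an everywhere-silent map scores 0.
    """
    vis = rm.visited
    occ = rm.occupancy[vis]
    f = rm.grid[vis]
    p = occ / occ.sum()
    fbar = float((p * f).sum())
    if fbar <= 0:
        return 0.0
    ratio = f / fbar
    pos = ratio > 0
    return float((p[pos] * ratio[pos] * np.log2(ratio[pos])).sum())


def high_si_units(si_per_env: np.ndarray, percentile: float = 2.5) -> np.ndarray:
    """Indices of units above the per-environment SI percentile in *every*
    environment.

    ``si_per_env`` is (n_units, n_envs); NaN entries (undefined maps)
    disqualify a unit.
    """
    si = np.atleast_2d(np.asarray(si_per_env, dtype=float))
    if si.ndim != 2:
        raise ValueError("expected (n_units, n_envs)")
    keep = np.ones(si.shape[0], dtype=bool)
    for e in range(si.shape[1]):
        col = si[:, e]
        ok = ~np.isnan(col)
        if percentile <= 0:
            keep &= ok
            continue
        thr = np.percentile(col[ok], percentile) if ok.any() else np.inf
        keep &= ok & (col > thr)
    return np.flatnonzero(keep)


# ---------------------------------------------------------------------------
# population geometry diagnostics


def pca_spectrum(states: np.ndarray, cum_threshold: float = 0.9) -> dict:
    """Explained-variance fractions of the state covariance.

    Returns fractions, their cumulative sum, and the number of components
    needed to pass ``cum_threshold`` cumulative explained variance.
    """
    states = np.asarray(states, dtype=float)
    if states.shape[0] < 2:
        raise ValueError("need at least two samples")
    frac = PCA().fit(states).explained_variance_ratio_
    cum = np.cumsum(frac)
    n_comp = int(np.searchsorted(cum, cum_threshold) + 1)
    return {"fractions": frac, "cumulative": cum, "n_components": n_comp}


def weight_diagnostics(params: NetworkParams) -> dict:
    """Spectrum of W_R, context-column correlations, and sign summary.

    Returns the complex eigenvalues of the recurrent matrix, the 6x6
    Pearson correlation matrix between the context columns of the input
    weights, and the fraction of negative weights per context channel.
    """
    eig = np.linalg.eigvals(np.asarray(params.W_R, dtype=float))
    ctx = np.asarray(params.W_I, dtype=float)[:, N_VELOCITY:]
    corr = np.corrcoef(ctx.T)
    neg_frac = (ctx < 0).mean(axis=0)
    return {"eigenvalues": eig, "context_correlations": corr, "context_negative_fraction": neg_frac}


# ---------------------------------------------------------------------------
# Ripley's K / H and field-center clustering


def _domain_area(domain) -> float:
    if isinstance(domain, Environment):
        return domain.area
    (lo_x, lo_y), (hi_x, hi_y) = _domain_box(domain)
    return float((hi_x - lo_x) * (hi_y - lo_y))


def _arc_fraction(points: np.ndarray, radii: np.ndarray, domain) -> np.ndarray:
    if isinstance(domain, Environment):
        return arc_inside_fraction(points, radii, domain)
    # rectangle domain: reuse the same angular-sampling estimate
    (lo_x, lo_y), (hi_x, hi_y) = _domain_box(domain)
    n_s = 720
    theta = np.linspace(0, 2 * np.pi, n_s, endpoint=False)
    ring = np.stack([np.cos(theta), np.sin(theta)], axis=1)
    pts = points[:, None, :] + radii[:, None, None] * ring[None, :, :]
    inside = (
        (pts[..., 0] >= lo_x) & (pts[..., 0] <= hi_x) & (pts[..., 1] >= lo_y) & (pts[..., 1] <= hi_y)
    )
    return np.maximum(inside.mean(axis=1), 1.0 / n_s)


def default_radii(domain, n_radii: int = 50) -> np.ndarray:
    """Log-spaced radii from 1e-8 to a quarter of the domain diagonal."""
    (lo_x, lo_y), (hi_x, hi_y) = _domain_box(domain)
    rmax = 0.25 * float(np.hypot(hi_x - lo_x, hi_y - lo_y))
    return np.geomspace(1e-8, rmax, n_radii)


def ripleys_K(points: np.ndarray, domain, radii: np.ndarray | None = None) -> np.ndarray:
    """Edge-corrected Ripley's K.

    K(R) = |Omega| / (N (N-1)) * sum over ordered pairs x != y of
    1{|x-y| < R} f(x, y), with the symmetric boundary correction
    f(x, y) = (k(x,y) + k(y,x)) / 2 and k(x, y) the reciprocal of the
    fraction of the circle about x through y that lies inside the domain.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    N = len(pts)
    if N < 2:
        raise ValueError("Ripley's K needs at least two points")
    radii = default_radii(domain) if radii is None else np.asarray(radii, dtype=float)
    iu, ju = np.triu_indices(N, k=1)
    d = np.linalg.norm(pts[iu] - pts[ju], axis=1)
    k_xy = 1.0 / _arc_fraction(pts[iu], d, domain)
    k_yx = 1.0 / _arc_fraction(pts[ju], d, domain)
    f = 0.5 * (k_xy + k_yx)
    area = _domain_area(domain)
    # each unordered pair contributes twice (x,y) and (y,x) with equal f
    K = np.array([(f[d < R]).sum() * 2.0 for R in radii])
    return area / (N * (N - 1)) * K


def ripleys_H(K: np.ndarray, radii: np.ndarray) -> np.ndarray:
    """Variance-stabilized, centered transform H(R) = sqrt(K/pi) - R."""
    return np.sqrt(np.asarray(K, dtype=float) / np.pi) - np.asarray(radii, dtype=float)


@dataclass
class RipleyResult:
    radii: np.ndarray
    K: np.ndarray
    H: np.ndarray
    baseline_mean: np.ndarray | None = None
    baseline_2sd: np.ndarray | None = None


def uniform_baseline(domain, n_points: int, radii: np.ndarray,
                     rng: np.random.Generator, n_sets: int = 100, grid: int | None = 15) -> dict:
    """Mean +/- 2 SD envelope of H under uniform resampling.

    Points are sampled uniformly on the centers of a ``grid`` x ``grid``
    discretization of the domain bounding box (matching ratemap
    resolution); with ``grid=None`` they are sampled continuously.
    """
    (lo_x, lo_y), (hi_x, hi_y) = _domain_box(domain)
    Hs = np.empty((n_sets, len(radii)))
    for s in range(n_sets):
        if grid is None:
            pts = rng.uniform((lo_x, lo_y), (hi_x, hi_y), size=(n_points, 2))
        else:
            cx = lo_x + (hi_x - lo_x) * (rng.integers(0, grid, n_points) + 0.5) / grid
            cy = lo_y + (hi_y - lo_y) * (rng.integers(0, grid, n_points) + 0.5) / grid
            pts = np.column_stack([cx, cy])
        Hs[s] = ripleys_H(ripleys_K(pts, domain, radii), radii)
    return {"mean": Hs.mean(axis=0), "sd2": 2.0 * Hs.std(axis=0), "all": Hs}


def ripley_analysis(points: np.ndarray, domain, radii: np.ndarray | None = None,
                    rng: np.random.Generator | None = None, n_sets: int = 100,
                    grid: int | None = 15) -> RipleyResult:
    """Full K/H computation with a uniform-resampling envelope."""
    radii = default_radii(domain) if radii is None else radii
    K = ripleys_K(points, domain, radii)
    H = ripleys_H(K, radii)
    base_mean = base_2sd = None
    if rng is not None:
        base = uniform_baseline(domain, len(np.atleast_2d(points)), radii, rng, n_sets, grid)
        base_mean, base_2sd = base["mean"], base["sd2"]
    return RipleyResult(radii, K, H, base_mean, base_2sd)


def field_centers_from_ratemaps(smoothed_grids: np.ndarray, edges_x: np.ndarray,
                                edges_y: np.ndarray, si: np.ndarray | None = None,
                                si_percentile: float = 75.0) -> np.ndarray:
    """Field center of each map: the bin-center of the maximum firing bin.

    ``smoothed_grids`` is (n_units, Nx, Ny); with ``si`` given, only units
    above the ``si_percentile`` of spatial information are kept. Argmax
    ties resolve to the first bin in scan order.
    """
    grids = np.asarray(smoothed_grids, dtype=float)
    keep = np.arange(len(grids))
    if si is not None:
        si = np.asarray(si, dtype=float)
        thr = np.percentile(si[~np.isnan(si)], si_percentile)
        keep = np.flatnonzero(~np.isnan(si) & (si > thr))
    cx = 0.5 * (edges_x[:-1] + edges_x[1:])
    cy = 0.5 * (edges_y[:-1] + edges_y[1:])
    centers = []
    for g in grids[keep]:
        flat = np.where(np.isnan(g), -np.inf, g).ravel()
        ix, iy = np.unravel_index(int(np.argmax(flat)), g.shape)
        centers.append((cx[ix], cy[iy]))
    return np.asarray(centers).reshape(-1, 2)


def kde(points: np.ndarray, domain, bandwidth: float = 0.2, grid: int = 64) -> dict:
    """Gaussian kernel density estimate of point locations on a grid.

    The bandwidth is in the units of the supplied points; the density is
    evaluated on a ``grid`` x ``grid`` lattice over the domain bounding box
    and integrates to ~1 for points far from the domain edge.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    (lo_x, lo_y), (hi_x, hi_y) = _domain_box(domain)
    gx = np.linspace(lo_x, hi_x, grid)
    gy = np.linspace(lo_y, hi_y, grid)
    XX, YY = np.meshgrid(gx, gy, indexing="ij")
    est = KernelDensity(bandwidth=bandwidth, kernel="gaussian").fit(pts)
    dens = np.exp(est.score_samples(np.column_stack([XX.ravel(), YY.ravel()]))).reshape(grid, grid)
    return {"density": dens, "x": gx, "y": gy}


def decoded_center_aggregation(params: NetworkParams, env, n_traj: int = 100, T: int = 30000,
                               rng: np.random.Generator | None = None,
                               sim_cfg=None, unit_subset: np.ndarray | None = None,
                               epsilon: float = 1e-8) -> np.ndarray:
    """Per-unit clouds of decoded centers over independent long trajectories.

    Runs the frozen network on ``n_traj`` trajectories of ``T`` steps in
    ``env`` and decodes every output unit's center once per trajectory.
    Returns (n_units_kept, n_traj, 2); restrict with ``unit_subset`` (e.g.
    the high-spatial-information units).
    """
    from .network import decode_centers, rollout
    from .trajectory import SimulatorConfig, simulate_batch

    rng = rng if rng is not None else np.random.default_rng()
    sim_cfg = sim_cfg or SimulatorConfig()
    keep = np.arange(params.n_p) if unit_subset is None else np.asarray(unit_subset)
    out = np.empty((len(keep), n_traj, 2))
    C = np.tile(env.context_vector(), (1, 1))
    chunk = max(1, min(n_traj, int(2e6 // T)))
    done = 0
    while done < n_traj:
        b = min(chunk, n_traj - done)
        X, V = simulate_batch(env, b, T, sim_cfg, rng)
        _, P = rollout(params, V.astype(params.W_R.dtype), np.repeat(C, b, axis=0))
        for j in range(b):
            mu = decode_centers(P[j], X[j], epsilon)
            out[:, done + j, :] = mu[keep]
        done += b
    return out


# ---------------------------------------------------------------------------
# convenience: per-unit ratemaps + SI for a whole run


def ratemaps_for_run(P: np.ndarray, X: np.ndarray, env, bins: int = 16,
                     burn_in: int = 0, smooth_sigma: float | None = None):
    """Per-unit ratemaps (and SI) for one run.

    ``P`` may be (T, n_units) or (n_traj, T, n_units) with matching ``X``;
    aggregated runs are flattened. Returns ``(list of Ratemap, si array)``.
    """
    P = np.asarray(P)
    X = np.asarray(X)
    if P.ndim == 3:
        P = P.reshape(-1, P.shape[-1])
        X = X.reshape(-1, 2)
    maps = []
    si = np.empty(P.shape[1])
    for u in range(P.shape[1]):
        rm = compute_ratemap(P[:, u], X, env, bins=bins, burn_in=burn_in)
        si[u] = spatial_information(rm)
        if smooth_sigma is not None:
            rm = smooth_ratemap(rm, smooth_sigma)
        maps.append(rm)
    return maps, si


def export_grid_csv(path, grid: np.ndarray) -> None:
    """Write a 2-D grid (ratemap or density) as a CSV matrix."""
    np.savetxt(path, np.asarray(grid, dtype=float), delimiter=",")
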