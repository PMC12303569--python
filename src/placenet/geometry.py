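"""Arena geometries for simulated foraging.

Six stock arenas (square, large square, rectangle, circle, square with a
thin central dividing wall, square with a central hole), each identified by
a unique one-hot context index. Arenas are represented as sets of wall
segments; point-in-arena queries use horizontal ray casting (odd crossing
count = inside), step-validity queries use segment/segment intersection,
and uniform interior sampling uses rejection from the bounding box.

The thin dividing wall is stored as two superimposed segments so that ray
casting parity is unaffected by it (crossing it adds two intersections)
while collision tests still see it. The hole of ``square_hole`` is an
extended object: its loop is stored once, so ray parity correctly labels
the hole interior as outside.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

ENV_NAMES = ("square", "large_square", "rectangle", "circle", "square_wall", "square_hole")
N_CONTEXTS = len(ENV_NAMES)

#: Side length of the reference square arena (arena units).
SQUARE_SIDE = 2.2

_VERTEX_JITTER = 1e-9


@dataclass
class Environment:
    """A 2-D arena bounded by wall segments (or a circle).

    Parameters
    ----------
    name : str
        Label of the arena.
    context_index : int
        Index of the one-hot context signal identifying this arena, in
        ``[0, 6)``.
    outer_walls : ndarray, shape (n, 2, 2)
        Ordered outer wall segments forming a closed loop (ignored for the
        circular arena).
    inner_walls : ndarray, shape (m, 2, 2)
        Interior walls: hole loops (stored once) and thin dividing walls
        (stored as two superimposed copies).
    is_circle : bool
        Circular arena flag; ``center``/``radius`` define the boundary.
    """

    name: str
    context_index: int
    outer_walls: np.ndarray
    inner_walls: np.ndarray = field(default_factory=lambda: np.zeros((0, 2, 2)))
    is_circle: bool = False
    center: np.ndarray = field(default_factory=lambda: np.zeros(2))
    radius: float = 0.0
    #: hole loops (subset of inner_walls) used for area computation
    hole_loops: tuple = ()

    def __post_init__(self):
        self.outer_walls = np.asarray(self.outer_walls, dtype=float).reshape(-1, 2, 2)
        self.inner_walls = np.asarray(self.inner_walls, dtype=float).reshape(-1, 2, 2)
        self.center = np.asarray(self.center, dtype=float)
        if not self.is_circle and len(self.outer_walls):
            first = self.outer_walls[0, 0]
            last = self.outer_walls[-1, 1]
            if not np.allclose(first, last):
                raise ValueError("outer walls must form a closed loop")

    # -- basic descriptors -------------------------------------------------

    @property
    def walls(self) -> np.ndarray:
        """All wall segments, shape (n_walls, 2, 2)."""
        if self.is_circle:
            return self.inner_walls
        if len(self.inner_walls):
            return np.concatenate([self.outer_walls, self.inner_walls])
        return self.outer_walls

    @property
    def bounding_box(self) -> np.ndarray:
        """Axis-aligned ``[[xmin, ymin], [xmax, ymax]]``."""
        if self.is_circle:
            lo = self.center - self.radius
            hi = self.center + self.radius
            return np.array([lo, hi])
        pts = self.walls.reshape(-1, 2)
        return np.array([pts.min(axis=0), pts.max(axis=0)])

    @property
    def area(self) -> float:
        """Interior area |Ω| (holes subtracted, thin walls have none)."""
        if self.is_circle:
            return float(np.pi * self.radius**2)
        a = _loop_area(self.outer_walls)
        for loop in self.hole_loops:
            a -= _loop_area(np.asarray(loop))
        return a

    def context_vector(self, n: int = N_CONTEXTS) -> np.ndarray:
        c = np.zeros(n)
        c[self.context_index] = 1.0
        return c

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "context_index": self.context_index,
            "outer_walls": self.outer_walls.tolist(),
            "inner_walls": self.inner_walls.tolist(),
            "is_circle": self.is_circle,
            "center": self.center.tolist(),
            "radius": self.radius,
            "hole_loops": [np.asarray(h).tolist() for h in self.hole_loops],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Environment":
        return cls(
            name=d["name"],
            context_index=int(d["context_index"]),
            outer_walls=np.asarray(d["outer_walls"]).reshape(-1, 2, 2),
            inner_walls=np.asarray(d["inner_walls"]).reshape(-1, 2, 2),
            is_circle=bool(d["is_circle"]),
            center=np.asarray(d["center"]),
            radius=float(d["radius"]),
            hole_loops=tuple(np.asarray(h) for h in d.get("hole_loops", [])),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "Environment":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _loop_area(segments: np.ndarray) -> float:
    """Shoelace area of a closed loop given as consecutive segments."""
    pts = segments[:, 0, :]
    x, y = pts[:, 0], pts[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


def _rect_loop(cx: float, cy: float, w: float, h: float) -> np.ndarray:
    """Closed rectangular loop of 4 segments, centered at (cx, cy)."""
    x0, x1 = cx - w / 2.0, cx + w / 2.0
    y0, y1 = cy - h / 2.0, cy + h / 2.0
    corners = np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1], [x0, y0]])
    return np.stack([corners[:-1], corners[1:]], axis=1)


def make_environment(name: str) -> Environment:
    """Build one of the six stock arenas by name.

    Dimensions: the reference square is 2.2 x 2.2 centered at the origin;
    the large square is 1.5x that, the rectangle halves the y extent, the
    circle has radius 1.1, the dividing wall spans from the top wall to the
    arena center, and the hole is a centered 0.73 x 0.73 square.
    """
    s = SQUARE_SIDE
    if name == "square":
        return Environment("square", 0, _rect_loop(0, 0, s, s))
    if name == "large_square":
        return Environment("large_square", 1, _rect_loop(0, 0, 1.5 * s, 1.5 * s))
    if name == "rectangle":
        return Environment("rectangle", 2, _rect_loop(0, 0, s, s / 2.0))
    if name == "circle":
        return Environment(
            "circle", 3, np.zeros((0, 2, 2)), is_circle=True, center=np.zeros(2), radius=s / 2.0
        )
    if name == "square_wall":
        wall = np.array([[[0.0, s / 2.0], [0.0, 0.0]]])
        # superimposed copy: keeps ray-casting parity unchanged
        return Environment(
            "square_wall", 4, _rect_loop(0, 0, s, s), np.concatenate([wall, wall])
        )
    if name == "square_hole":
        hole = _rect_loop(0, 0, s / 3.0, s / 3.0)
        return Environment(
            "square_hole", 5, _rect_loop(0, 0, s, s), hole, hole_loops=(hole,)
        )
    raise ValueError(f"unknown environment name: {name!r}")


def all_environments() -> list:
    return [make_environment(n) for n in ENV_NAMES]


# ---------------------------------------------------------------------------
# predicates


def point_inside(p, env: Environment) -> np.ndarray:
    """Horizontal-ray-casting inside test; accepts a point or an (n, 2) array.

    A point is inside iff a +x ray crosses the wall set an odd number of
    times (circle: radius test). Boundary points count as inside for the
    circle; for polygons a 1e-9 y-jitter is applied whenever the ray would
    pass exactly through a wall vertex, removing degenerate parity counts.
    Returns a boolean scalar for a single point, else a boolean array.
    """
    pts = np.asarray(p, dtype=float)
    scalar = pts.ndim == 1
    pts = np.atleast_2d(pts)
    if env.is_circle:
        d2 = ((pts - env.center) ** 2).sum(axis=1)
        out = d2 <= env.radius**2 * (1 + 1e-12)
        return bool(out[0]) if scalar else out

    walls = env.walls  # (w, 2, 2)
    y1 = walls[:, 0, 1]
    y2 = walls[:, 1, 1]
    py = pts[:, 1].copy()
    vy = np.unique(walls[:, :, 1])
    hit_vertex = np.isin(py, vy)
    py[hit_vertex] += _VERTEX_JITTER
    px = pts[:, 0]

    # crossing iff wall straddles the ray's y and the intersection is right of p
    straddle = (y1[None, :] > py[:, None]) != (y2[None, :] > py[:, None])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (py[:, None] - y1[None, :]) / (y2[None, :] - y1[None, :])
    xint = walls[None, :, 0, 0] + t * (walls[None, :, 1, 0] - walls[None, :, 0, 0])
    crossings = (straddle & (xint > px[:, None])).sum(axis=1)
    out = (crossings % 2) == 1
    return bool(out[0]) if scalar else out


def _orient(a, b, c):
    """Signed orientation of triple(s) a→b→c (broadcasting)."""
    return (b[..., 0] - a[..., 0]) * (c[..., 1] - a[..., 1]) - (
        b[..., 1] - a[..., 1]
    ) * (c[..., 0] - a[..., 0])


def segments_intersect(a, b, c, d) -> np.ndarray:
    """Whether segments a-b and c-d intersect (touching counts), broadcasting."""
    d1 = _orient(c, d, a)
    d2 = _orient(c, d, b)
    d3 = _orient(a, b, c)
    d4 = _orient(a, b, d)
    proper = ((d1 > 0) != (d2 > 0)) & ((d3 > 0) != (d4 > 0)) & (d1 != 0) & (d2 != 0) & (d3 != 0) & (d4 != 0)

    def on_seg(p, q, r):
        return (
            (np.minimum(p[..., 0], q[..., 0]) <= r[..., 0])
            & (r[..., 0] <= np.maximum(p[..., 0], q[..., 0]))
            & (np.minimum(p[..., 1], q[..., 1]) <= r[..., 1])
            & (r[..., 1] <= np.maximum(p[..., 1], q[..., 1]))
        )

    touch = (
        ((d1 == 0) & on_seg(c, d, a))
        | ((d2 == 0) & on_seg(c, d, b))
        | ((d3 == 0) & on_seg(a, b, c))
        | ((d4 == 0) & on_seg(a, b, d))
    )
    return proper | touch


def segment_hits_wall(a, b, env: Environment) -> bool:
    """True iff the step segment a→b crosses (or touches) any arena wall.

    For the circular arena the farthest point of a segment from the center
    is an endpoint, so with ``a`` inside the step exits iff ``b`` is outside.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if env.is_circle:
        hit_walls = False
        if len(env.inner_walls):
            hit_walls = bool(
                segments_intersect(
                    a[None], b[None], env.inner_walls[:, 0], env.inner_walls[:, 1]
                ).any()
            )
        return hit_walls or ((b - env.center) ** 2).sum() > env.radius**2
    walls = env.walls
    return bool(segments_intersect(a[None], b[None], walls[:, 0], walls[:, 1]).any())


def segment_hits_wall_batch(a: np.ndarray, b: np.ndarray, env: Environment) -> np.ndarray:
    """Vectorized ``segment_hits_wall`` over (n, 2) start/end arrays."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if env.is_circle:
        out = ((b - env.center) ** 2).sum(axis=1) > env.radius**2
        if len(env.inner_walls):
            w = env.inner_walls
            out = out | segments_intersect(
                a[:, None, :], b[:, None, :], w[None, :, 0, :], w[None, :, 1, :]
            ).any(axis=1)
        return out
    w = env.walls
    return segments_intersect(
        a[:, None, :], b[:, None, :], w[None, :, 0, :], w[None, :, 1, :]
    ).any(axis=1)


# ---------------------------------------------------------------------------
# sampling and boundary arcs


def sample_uniform(env: Environment, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` points uniformly from the arena interior by rejection.

    Candidates are drawn uniformly from the smallest covering rectangle and
    kept when the ray-casting inside test accepts them.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = env.bounding_box
    out = np.empty((n, 2))
    filled = 0
    while filled < n:
        m = max(2 * (n - filled), 64)
        cand = rng.uniform(lo, hi, size=(m, 2))
        good = cand[point_inside(cand, env)]
        take = min(len(good), n - filled)
        out[filled : filled + take] = good[:take]
        filled += take
    return out


def arc_inside_fraction(x, r, env: Environment, n_samples: int = 720):
    """Fraction of the circle of radius ``r`` about ``x`` lying inside the arena.

    Estimated by ``n_samples`` equally spaced boundary points (<0.5 degree
    resolution at the default). Floored at ``1/n_samples`` so the Ripley
    edge-correction weights 1/fraction stay finite. ``x`` may be (2,) or
    (n, 2) with scalar-or-(n,) ``r``.
    """
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 1
    x = np.atleast_2d(x)
    r = np.broadcast_to(np.asarray(r, dtype=float), (len(x),))
    theta = np.linspace(0.0, 2.0 * np.pi, n_samples, endpoint=False)
    ring = np.stack([np.cos(theta), np.sin(theta)], axis=1)  # (s, 2)
    pts = x[:, None, :] + r[:, None, None] * ring[None, :, :]  # (n, s, 2)
    inside = point_inside(pts.reshape(-1, 2), env).reshape(len(x), n_samples)
    frac = np.maximum(inside.mean(axis=1), 1.0 / n_samples)
    return float(frac[0]) if scalar else frac


# ---------------------------------------------------------------------------
# point-set IO


def save_points(path, points: np.ndarray, header: bool = True) -> None:
    """Write an (n, 2) point set as 2-column CSV."""
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    hdr = "x,y" if header else ""
    np.savetxt(path, points, delimiter=",", header=hdr, comments="")


def load_points(path) -> np.ndarray:
    """Read a 2-column (x, y) CSV, with or without a header line."""
    with open(path) as fh:
        first = fh.readline()
    skip = 0
    try:
        [float(v) for v in first.strip().split(",")[:2]]
    except ValueError:
        skip = 1
    return np.loadtxt(path, delimiter=",", skiprows=skip, usecols=(0, 1)).reshape(-1, 2)
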