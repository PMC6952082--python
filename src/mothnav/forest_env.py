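"""Virtual forests, fog-limited perception range, and the one-step reward field.

A forest is a set of disc-shaped obstacles ("trees") in the plane.  Forests are
either loaded from delimited text files or generated procedurally as periodic
artificial forests: a 4n x 3n metre elementary cell with a single tree at
cell coordinate (1, 1), tiled indefinitely in all directions.  Tree density is
then 1/(12 n^2) trees per square metre.

The one-step reward is a function of position only.  It is assembled from a
univariate polynomial profile f applied to the distance of each tree scaled by
that tree's size: negative very close to a tree (collision risk), positive in
an annulus around it (cover from predators), and zero far away.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

__all__ = [
    "Forest",
    "RewardParams",
    "RewardField",
    "make_artificial_forest",
    "reward_polynomial",
    "reward_field",
    "visibility_range",
    "VISIBILITY_CONSTANT",
    "DEFAULT_FOG",
    "MEAN_TREE_SIZE",
]

#: Product of fog level and perception distance (metres); chosen so that the
#: standard evaluation fog of 6.66 yields a perception range of 20 m.
VISIBILITY_CONSTANT = 133.2

#: Fog level used for all policy evaluation runs (the same value appears in
#: the source data capture).  Reported variously as 6.6/6.66/6.67; a single
#: configuration value is used for all of them.
DEFAULT_FOG = 6.66

#: Mean tree size (metres) of the experimental forest; used as the default
#: tree size of artificial forests.
MEAN_TREE_SIZE = 0.0811


def visibility_range(fog_level: float, c_vis: float = VISIBILITY_CONSTANT) -> float:
    """Maximum distance (m) at which a tree contributes to perception.

    Reciprocal in the fog level (qualitatively matching contrast
    attenuation); ``fog_level == 0`` means unlimited visibility.
    """
    if fog_level < 0:
        raise ValueError(f"fog_level must be >= 0, got {fog_level}")
    if fog_level == 0:
        return math.inf
    return c_vis / fog_level


@dataclass(frozen=True)
class Forest:
    """A set of disc obstacles, optionally periodic.

    Parameters
    ----------
    trees
        Array of shape (M, 3): columns are center x, center y, size, all in
        metres.  ``size`` is stored as the quantity divided into distance in
        the reward sum (by default the tree diameter).
    bounds
        (width, height) of the world rectangle in metres.
    periodic_cell
        If set, ``(cell_width, cell_height)``: the listed trees all lie in one
        elementary cell and perception/reward queries tile the cell in all
        directions.
    size_is_diameter
        Whether the size column holds diameters (default) or radii; controls
        the physical radius used for visual projection.
    """

    trees: np.ndarray
    bounds: tuple[float, float]
    periodic_cell: tuple[float, float] | None = None
    size_is_diameter: bool = True

    def __post_init__(self) -> None:
        trees = np.atleast_2d(np.asarray(self.trees, dtype=float))
        if trees.size == 0:
            trees = trees.reshape(0, 3)
        if trees.shape[1] != 3:
            raise ValueError("trees must have columns (x, y, size)")
        if np.any(trees[:, 2] <= 0):
            raise ValueError("tree sizes must be strictly positive")
        object.__setattr__(self, "trees", trees)
        if self.periodic_cell is not None:
            cw, ch = self.periodic_cell
            if cw <= 0 or ch <= 0:
                raise ValueError("periodic cell dimensions must be positive")
            inside = (
                (trees[:, 0] >= 0)
                & (trees[:, 0] <= cw)
                & (trees[:, 1] >= 0)
                & (trees[:, 1] <= ch)
            )
            if not np.all(inside):
                raise ValueError("periodic forests require all trees inside one cell")

    @property
    def n_trees(self) -> int:
        return self.trees.shape[0]

    @property
    def radii(self) -> np.ndarray:
        """Physical tree radii in metres (for visual projection)."""
        sizes = self.trees[:, 2]
        return sizes / 2.0 if self.size_is_diameter else sizes

    def tiled_trees(self, margin: float, min_rings: int = 1) -> np.ndarray:
        """Materialized tree array covering the bounds plus ``margin`` metres.

        For a periodic forest the elementary cell is replicated in enough
        rings to cover the margin (at least ``min_rings``); for a bounded
        forest the stored trees are returned as-is.
        """
        if self.periodic_cell is None:
            return self.trees
        cw, ch = self.periodic_cell
        if not math.isfinite(margin):
            raise ValueError("cannot tile a periodic forest to infinite margin; "
                             "pass a finite perception/reward range")
        rings_x = max(min_rings, int(math.ceil(margin / cw)))
        rings_y = max(min_rings, int(math.ceil(margin / ch)))
        nx = max(1, int(math.ceil(self.bounds[0] / cw)))
        ny = max(1, int(math.ceil(self.bounds[1] / ch)))
        reps = []
        for i in range(-rings_x, nx + rings_x):
            for j in range(-rings_y, ny + rings_y):
                shifted = self.trees.copy()
                shifted[:, 0] += i * cw
                shifted[:, 1] += j * ch
                reps.append(shifted)
        return np.concatenate(reps, axis=0)

    # ------------------------------------------------------------------ I/O
    def to_file(self, path: str | Path) -> None:
        lines = [f"# bounds {self.bounds[0]} {self.bounds[1]}"]
        if self.periodic_cell is not None:
            lines.append(f"# periodic_cell {self.periodic_cell[0]} {self.periodic_cell[1]}")
        lines.append(f"# size_is_diameter {int(self.size_is_diameter)}")
        lines.append("x,y,size")
        for x, y, s in self.trees:
            lines.append(f"{float(x)!r},{float(y)!r},{float(s)!r}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "Forest":
        bounds: tuple[float, float] | None = None
        cell: tuple[float, float] | None = None
        size_is_diameter = True
        body: list[str] = []
        for line in Path(path).read_text().splitlines():
            if line.startswith("#"):
                parts = line[1:].split()
                if parts and parts[0] == "bounds":
                    bounds = (float(parts[1]), float(parts[2]))
                elif parts and parts[0] == "periodic_cell":
                    cell = (float(parts[1]), float(parts[2]))
                elif parts and parts[0] == "size_is_diameter":
                    size_is_diameter = bool(int(parts[1]))
            elif line.strip():
                body.append(line)
        arr = np.loadtxt(io.StringIO("\n".join(body[1:])), delimiter=",", ndmin=2)
        if bounds is None:
            if arr.size:
                bounds = (float(arr[:, 0].max()), float(arr[:, 1].max()))
            else:
                bounds = (1.0, 1.0)
        return cls(arr, bounds, cell, size_is_diameter)


def make_artificial_forest(
    n: int,
    tree_size: float = MEAN_TREE_SIZE,
    tiles: int = 1,
    size_is_diameter: bool = True,
) -> Forest:
    """Periodic forest built from a 4n x 3n metre elementary cell.

    One tree of size ``tree_size`` is planted at cell coordinate (1, 1) and
    the cell tiles the plane, giving tree density 1/(12 n^2) per square
    metre.  ``tiles`` sets the minimum number of replica rings materialized
    around the cell when perception or reward queries need physical trees;
    the ring count is extended automatically to cover the query margin.
    """
    if n < 1 or int(n) != n:
        raise ValueError(f"n must be a positive integer, got {n}")
    if tree_size <= 0:
        raise ValueError(f"tree_size must be positive, got {tree_size}")
    cell = (4.0 * n, 3.0 * n)
    forest = Forest(
        np.array([[1.0, 1.0, float(tree_size)]]),
        bounds=cell,
        periodic_cell=cell,
        size_is_diameter=size_is_diameter,
    )
    object.__setattr__(forest, "_min_tile_rings", int(tiles))
    return forest


# ---------------------------------------------------------------------------
# One-step reward
# ---------------------------------------------------------------------------

#: Cutoff in the scaled-distance profile: gamma = beta / sin(pi/72).
GAMMA_SIN_ARG = math.pi / 72


@dataclass(frozen=True)
class RewardParams:
    """Parameters of the scaled-distance reward profile f.

    ``alpha`` is the scaled distance at which the profile crosses zero (inside
    it the reward is negative, modelling collision risk), ``peak`` (P) is the
    profile value at the midpoint (alpha + gamma)/2, and ``gamma``, derived as
    beta / sin(pi/72), is the scaled distance beyond which the profile
    vanishes.
    """

    alpha: float = 1.0
    beta: float = 1.0
    peak: float = 43.5
    gamma: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.gamma is None:
            object.__setattr__(self, "gamma", self.beta / math.sin(GAMMA_SIN_ARG))
        if not (0 < self.alpha < self.gamma):
            raise ValueError(
                f"need 0 < alpha < gamma, got alpha={self.alpha}, gamma={self.gamma}"
            )
        if self.peak <= 0:
            raise ValueError(f"peak must be positive, got {self.peak}")


def reward_polynomial(params: RewardParams) -> Callable[[np.ndarray], np.ndarray]:
    """Construct the univariate reward profile f on [0, inf).

    The four boundary constraints

        f(0) = -0.1,  f(alpha) = 0,  f((alpha+gamma)/2) = peak,  f(gamma) = 0

    are interpolated by the unique cubic through those points, and f is set
    identically to 0 for s >= gamma.  The expected sign structure (f <= 0 on
    [0, alpha], f >= 0 on [alpha, gamma]) is verified numerically on a
    10^4-point grid at construction time; violations raise ``ValueError``.
    """
    a, g, p = params.alpha, params.gamma, params.peak
    mid = 0.5 * (a + g)
    nodes = np.array([0.0, a, mid, g])
    if len(np.unique(nodes)) != 4:
        raise ValueError("degenerate constraint system (coincident nodes)")
    vals = np.array([-0.1, 0.0, p, 0.0])
    # Vandermonde solve for the cubic coefficients (highest degree first).
    coeffs = np.linalg.solve(np.vander(nodes, 4), vals)
    poly = np.polynomial.Polynomial(coeffs[::-1])

    s_chk = np.linspace(0.0, g, 10_000)
    v_chk = poly(s_chk)
    tol = 1e-9 * max(1.0, p)
    if np.any(v_chk[s_chk <= a] > tol) or np.any(v_chk[s_chk >= a] < -tol):
        raise ValueError(
            "reward profile violates its sign conditions for "
            f"alpha={a}, beta={params.beta}, peak={p}"
        )

    def f(s: np.ndarray | float) -> np.ndarray | float:
        s_arr = np.asarray(s, dtype=float)
        out = np.where(s_arr < g, poly(s_arr), 0.0)
        if np.isscalar(s) or s_arr.ndim == 0:
            return float(out)
        return out

    return f


@dataclass(frozen=True)
class RewardField:
    """Normalized one-step reward sampled on a planar grid.

    ``values[iy, ix]`` is the reward at the grid point with index (ix, iy);
    after normalization the values lie in [-0.1, 1].  The reward depends on
    position only, never on heading.
    """

    values: np.ndarray
    xs: np.ndarray
    ys: np.ndarray

    def export(self, path: str | Path) -> None:
        """Delimited text dump ``x,y,reward`` (one grid point per row)."""
        xx, yy = np.meshgrid(self.xs, self.ys)
        arr = np.column_stack([xx.ravel(), yy.ravel(), self.values.ravel()])
        header = "x,y,reward"
        np.savetxt(path, arr, delimiter=",", header=header, comments="")


def _normalize(raw: np.ndarray) -> np.ndarray:
    """Piecewise-affine rescale of the raw reward into [-0.1, 1].

    Negative values are scaled by 0.1/|min| so the floor is exactly -0.1,
    positive values by 1/max so the cap is exactly 1, and zero stays zero.
    This preserves the sign structure (approach trees vs avoid collision); a
    single affine map would shift the zero set.
    """
    out = np.zeros_like(raw)
    mn = raw.min() if raw.size else 0.0
    mx = raw.max() if raw.size else 0.0
    if mn < 0:
        neg = raw < 0
        out[neg] = raw[neg] * (0.1 / abs(mn))
    if mx > 0:
        pos = raw > 0
        out[pos] = raw[pos] / mx
    return out


def raw_reward_at(
    forest: Forest,
    x: np.ndarray,
    y: np.ndarray,
    params: RewardParams,
) -> np.ndarray:
    """Un-normalized reward: sum over trees of f(distance / tree size)."""
    f = reward_polynomial(params)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    scalar_input = x.ndim == 0 and y.ndim == 0
    x, y = np.atleast_1d(x), np.atleast_1d(y)
    if forest.periodic_cell is not None:
        # Fold queries into the elementary cell: the field is periodic by
        # construction, and the materialized replicas surround that cell.
        x = x % forest.periodic_cell[0]
        y = y % forest.periodic_cell[1]
    out = np.zeros(np.broadcast(x, y).shape, dtype=float)
    if forest.n_trees == 0:
        return float(out[0]) if scalar_input else out
    sizes_all = forest.trees[:, 2]
    margin = params.gamma * float(sizes_all.max())
    min_rings = getattr(forest, "_min_tile_rings", 1)
    trees = forest.tiled_trees(margin, min_rings=min_rings)
    # Chunk over trees to bound memory on heavily tiled forests.
    for start in range(0, trees.shape[0], 1024):
        chunk = trees[start : start + 1024]
        d = np.hypot(
            x[..., None] - chunk[None, :, 0], y[..., None] - chunk[None, :, 1]
        )
        s = d / chunk[:, 2]
        out += f(s).sum(axis=-1)
    return float(out[0]) if scalar_input else out


def reward_field(
    forest: Forest,
    grid,
    params: RewardParams,
) -> RewardField:
    """Normalized reward field over the planar part of ``grid``.

    ``grid`` must expose nx, ny, cell_dx, cell_dy and origin (a GridSpec
    qualifies).  Grid points at a tree center simply evaluate f at distance
    zero (-0.1 per tree); they are not an error.
    """
    xs = grid.origin[0] + (np.arange(grid.nx) + 0.5) * grid.cell_dx
    ys = grid.origin[1] + (np.arange(grid.ny) + 0.5) * grid.cell_dy
    xx, yy = np.meshgrid(xs, ys)
    raw = raw_reward_at(forest, xx, yy, params)
    return RewardField(_normalize(raw), xs, ys)
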