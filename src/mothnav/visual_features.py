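"""Per-action visual features: obstacle spatial density, optical flow,
control history and turning energy.

The field of view is the pi/2 arc centred on the current heading, split into
2m+1 equal segments, one per candidate action.  Each tree within the
fog-limited perception range projects to an angular interval (half-angle
arcsin(r/d) for a disc of radius r at distance d); projections narrower than
the eye's angular resolution are discarded, the remaining intervals are
unioned, and the obstacle spatial density (OSD) of a segment is the fraction
of its width covered by that union.  Thresholded variants binarize the
coverage, and a 1-D gradient-based optical-flow estimate compares the OSD
signals of two consecutive steps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .forest_env import DEFAULT_FOG, Forest, visibility_range
from .mdp_core import ActionSpace

__all__ = [
    "FEATURE_NAMES",
    "FeatureScaler",
    "osd",
    "osd_table",
    "osd_threshold",
    "optical_flow",
    "history_feature",
    "energy_feature",
    "feature_matrix",
    "feature_vector",
]

#: Canonical feature order; Table-style weight files follow it.
FEATURE_NAMES = ("osd", "osd0", "osd05", "of", "history", "energy")

FOV_HALF = math.pi / 4
DEFAULT_ANGULAR_RESOLUTION = 0.01  # radians


def _tree_geometry(forest: Forest, fog_level: float):
    """Distances/bearings/half-angles of every (materialized) tree.

    Returns callables' inputs precomputed per tree; positions of query points
    are supplied later.  Trees are tiled to cover the perception range for
    periodic forests.
    """
    rng_vis = visibility_range(fog_level)
    margin = rng_vis if math.isfinite(rng_vis) else 0.0
    if forest.periodic_cell is not None and not math.isfinite(rng_vis):
        raise ValueError("periodic forests need a finite perception range (fog > 0)")
    trees = forest.tiled_trees(margin) if forest.periodic_cell is not None else forest.trees
    radii = trees[:, 2] / 2.0 if forest.size_is_diameter else trees[:, 2]
    return trees[:, 0], trees[:, 1], radii, rng_vis


def _union_coverage(lo: np.ndarray, hi: np.ndarray, m: int) -> np.ndarray:
    """Per-segment union coverage from per-tree angular intervals.

    ``lo``/``hi`` have shape (..., T), pre-sorted ascending in ``lo`` along
    the last axis; empty intervals may carry lo=+inf.  Returns coverage in
    [0, 1] with shape (..., 2m+1).
    """
    n_actions = 2 * m + 1
    edges = np.linspace(-FOV_HALF, FOV_HALF, n_actions + 1)
    width = edges[1] - edges[0]
    out = np.empty(lo.shape[:-1] + (n_actions,), dtype=float)
    for j in range(n_actions):
        lo_c = np.maximum(lo, edges[j])
        hi_c = np.minimum(hi, edges[j + 1])
        # Sweep: subtract the part already covered by earlier intervals.
        run = np.maximum.accumulate(hi_c, axis=-1)
        prev = np.concatenate(
            [np.full(lo.shape[:-1] + (1,), -np.inf), run[..., :-1]], axis=-1
        )
        contrib = np.clip(hi_c - np.maximum(lo_c, prev), 0.0, None)
        out[..., j] = contrib.sum(axis=-1) / width
    return np.clip(out, 0.0, 1.0)


def _osd_points(
    x: np.ndarray,
    y: np.ndarray,
    heading: np.ndarray,
    forest: Forest,
    fog_level: float,
    m: int,
    angular_resolution: float,
) -> np.ndarray:
    """OSD for broadcastable arrays of poses; shape (..., 2m+1)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if forest.periodic_cell is not None:
        x = x % forest.periodic_cell[0]
        y = y % forest.periodic_cell[1]
    heading = np.asarray(heading, float)
    shape = np.broadcast(x, y, heading).shape
    n_actions = 2 * m + 1
    if forest.n_trees == 0:
        return np.zeros(shape + (n_actions,))
    tx, ty, tr, rng_vis = _tree_geometry(forest, fog_level)
    dx = tx[None, :] - x.reshape(-1, 1)
    dy = ty[None, :] - y.reshape(-1, 1)
    d = np.hypot(dx, dy)
    with np.errstate(invalid="ignore", divide="ignore"):
        delta = np.arcsin(np.clip(tr[None, :] / np.maximum(d, 1e-300), 0.0, 1.0))
    bear = np.arctan2(dy, dx)
    inside = d <= tr[None, :]  # agent inside a tree: full coverage
    visible = (d <= rng_vis) & (2 * delta >= angular_resolution) & ~inside
    rel = bear - heading.reshape(-1, 1)
    rel = (rel + math.pi) % (2 * math.pi) - math.pi
    lo = np.where(visible, rel - delta, np.inf)
    hi = np.where(visible, rel + delta, -np.inf)
    order = np.argsort(lo, axis=-1)
    lo = np.take_along_axis(lo, order, axis=-1)
    hi = np.take_along_axis(hi, order, axis=-1)
    cov = _union_coverage(lo, hi, m)
    cov[inside.any(axis=-1)] = 1.0
    return cov.reshape(shape + (n_actions,))


def osd(
    x: float,
    y: float,
    heading: float,
    forest: Forest,
    fog_level: float = DEFAULT_FOG,
    m: int = 2,
    angular_resolution: float = DEFAULT_ANGULAR_RESOLUTION,
) -> np.ndarray:
    """Per-segment obstacle spatial density of a single pose, in [0, 1]^(2m+1)."""
    return _osd_points(
        np.asarray(x), np.asarray(y), np.asarray(heading), forest, fog_level, m, angular_resolution
    )


def osd_table(
    forest: Forest,
    grid,
    fog_level: float = DEFAULT_FOG,
    m: int = 2,
    angular_resolution: float = DEFAULT_ANGULAR_RESOLUTION,
) -> np.ndarray:
    """OSD precomputed for every (cell, heading) of a GridSpec.

    Returns an array of shape (ny, nx, n_headings, 2m+1) (float32 to keep
    large periodic tables small).  The per-heading loop reuses the
    heading-independent tree geometry.
    """
    xs = grid.origin[0] + (np.arange(grid.nx) + 0.5) * grid.cell_dx
    ys = grid.origin[1] + (np.arange(grid.ny) + 0.5) * grid.cell_dy
    xx, yy = np.meshgrid(xs, ys)
    n_actions = 2 * m + 1
    out = np.zeros((grid.ny, grid.nx, grid.n_headings, n_actions), dtype=np.float32)
    if forest.n_trees == 0:
        return out
    tx, ty, tr, rng_vis = _tree_geometry(forest, fog_level)
    px, py = xx.ravel(), yy.ravel()
    dx = tx[None, :] - px[:, None]
    dy = ty[None, :] - py[:, None]
    d = np.hypot(dx, dy)
    delta = np.arcsin(np.clip(tr[None, :] / np.maximum(d, 1e-300), 0.0, 1.0))
    bear = np.arctan2(dy, dx)
    inside = (d <= tr[None, :]).any(axis=-1)
    base_visible = (d <= rng_vis) & (2 * delta >= angular_resolution) & (d > tr[None, :])
    for h in range(grid.n_headings):
        w = h * grid.heading_quantum
        rel = (bear - w + math.pi) % (2 * math.pi) - math.pi
        vis = base_visible & (np.abs(rel) <= FOV_HALF + delta)
        lo = np.where(vis, rel - delta, np.inf)
        hi = np.where(vis, rel + delta, -np.inf)
        order = np.argsort(lo, axis=-1)
        lo = np.take_along_axis(lo, order, axis=-1)
        hi = np.take_along_axis(hi, order, axis=-1)
        cov = _union_coverage(lo, hi, m)
        cov[inside] = 1.0
        out[:, :, h, :] = cov.reshape(grid.ny, grid.nx, n_actions)
    return out


def osd_threshold(coverage: np.ndarray, p: float) -> np.ndarray:
    """Binary feature: 1 where strictly more than a fraction p is covered."""
    return (np.asarray(coverage) > p).astype(float)


def optical_flow(f_prev: np.ndarray, f_curr: np.ndarray) -> np.ndarray:
    """1-D gradient-based optical-flow estimate between consecutive signals.

    s(u) = (f_prev(u) - f_curr(u)) / (f_prev(u+1) - f_prev(u)) with the last
    entry copied from its neighbour (no forward difference there).  A zero
    spatial gradient means no measurable flow: those entries are 0.
    """
    f_prev = np.asarray(f_prev, float)
    f_curr = np.asarray(f_curr, float)
    if f_prev.shape != f_curr.shape:
        raise ValueError("signal length mismatch")
    n = f_prev.shape[-1]
    s = np.zeros_like(f_prev)
    if n < 2:
        return s
    num = f_prev[..., :-1] - f_curr[..., :-1]
    den = f_prev[..., 1:] - f_prev[..., :-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(den != 0, num / np.where(den == 0, 1.0, den), 0.0)
    s[..., :-1] = ratio
    s[..., -1] = s[..., -2]
    return s


def history_feature(history: Sequence[int], actions: ActionSpace) -> float:
    """Mean signed heading offset of the last q actions (radians).

    This is the state part of the control-history feature; the per-action
    feature is the deviation |offset(u) - mean|, so that a negative weight
    expresses a preference for flying smoothly (choosing the turn closest
    to the recent ones).  A feature constant across candidate actions would
    cancel in the softmax and its weight could never be identified from
    demonstrations.
    """
    if len(history) == 0:
        raise ValueError("empty control history")
    offs = actions.offsets
    return float(np.mean([offs[a] for a in history]))


def energy_feature(action: int, actions: ActionSpace) -> float:
    """Turning effort of an action: |commanded heading change| (radians).

    Straight flight costs nothing; the proportionality constant is absorbed
    into the policy weight.
    """
    return float(abs(actions.offsets[action]))


def feature_matrix(
    cov_curr: np.ndarray,
    cov_prev: np.ndarray | None,
    history: Sequence[int],
    actions: ActionSpace,
) -> np.ndarray:
    """Stack the six features for every candidate action: shape (2m+1, 6).

    Columns follow :data:`FEATURE_NAMES`.  At episode start (``cov_prev is
    None``) the optical-flow column is zero.
    """
    cov_curr = np.asarray(cov_curr, float)
    a = actions.n_actions
    if cov_curr.shape != (a,):
        raise ValueError("coverage length does not match the action space")
    of = np.zeros(a) if cov_prev is None else optical_flow(np.asarray(cov_prev, float), cov_curr)
    hist = history_feature(history, actions) if len(history) else 0.0
    phi = np.empty((a, len(FEATURE_NAMES)))
    phi[:, 0] = cov_curr
    phi[:, 1] = osd_threshold(cov_curr, 0.0)
    phi[:, 2] = osd_threshold(cov_curr, 0.5)
    phi[:, 3] = of
    phi[:, 4] = np.abs(actions.offsets - hist)  # deviation from recent controls
    phi[:, 5] = np.abs(actions.offsets)
    return phi


def feature_vector(
    cov_curr: np.ndarray,
    cov_prev: np.ndarray | None,
    history: Sequence[int],
    action: int,
    actions: ActionSpace,
) -> np.ndarray:
    """Feature row phi(x, u) of a single candidate action."""
    return feature_matrix(cov_curr, cov_prev, history, actions)[action]


@dataclass
class FeatureScaler:
    """Location/scale normalization fitted once on a training set.

    Location is the feature mean and scale the standard deviation; features
    with no variance keep scale 1 so the transform stays invertible.
    """

    mean: np.ndarray | None = None
    scale: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "FeatureScaler":
        X2 = np.asarray(X, float).reshape(-1, X.shape[-1])
        self.mean = X2.mean(axis=0)
        sd = X2.std(axis=0)
        self.scale = np.where(sd > 0, sd, 1.0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mean is None:
            raise ValueError("scaler is not fitted")
        return (np.asarray(X, float) - self.mean) / self.scale

    def inverse_transform(self, X: np.ndarray) -> np.ndarray:
        if self.mean is None:
            raise ValueError("scaler is not fitted")
        return np.asarray(X, float) * self.scale + self.mean
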