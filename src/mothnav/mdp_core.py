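"""Finite-MDP discretization of the unicycle kinematics.

The agent flies at constant speed v in the plane; its only control is the
heading change applied at each step.  State = (planar cell, heading bin,
last-q-actions history); action = one of 2m+1 desired headings spanning a
pi/2 arc centred on the current heading.  Continuous endpoints are snapped
stochastically onto the grid (bilinear overlap weights in the plane, nearest
bin in heading), which is what turns the deterministic kinematics into a
probabilistic transition model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "GridSpec",
    "ActionSpace",
    "MdpConfig",
    "AgentState",
    "count_states",
    "unicycle_step",
    "bilinear_weights",
    "transition_sample",
    "simulate",
]


@dataclass(frozen=True)
class GridSpec:
    """Discretization of (x, y, omega).

    ``n_headings`` heading bins of width 2*pi/n_headings (default 72, i.e.
    5-degree bins); planar cells of size cell_dx x cell_dy anchored at
    ``origin`` (lower-left corner of cell (0, 0)).
    """

    nx: int
    ny: int
    n_headings: int = 72
    cell_dx: float = 0.25
    cell_dy: float = 0.25
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if min(self.nx, self.ny, self.n_headings) < 1:
            raise ValueError("grid dimensions must be positive")
        if self.cell_dx <= 0 or self.cell_dy <= 0:
            raise ValueError("cell sizes must be positive")

    @property
    def heading_quantum(self) -> float:
        return 2 * math.pi / self.n_headings

    @property
    def n_states(self) -> int:
        return self.nx * self.ny * self.n_headings

    def cell_center(self, ix: int | np.ndarray, iy: int | np.ndarray):
        x = self.origin[0] + (np.asarray(ix) + 0.5) * self.cell_dx
        y = self.origin[1] + (np.asarray(iy) + 0.5) * self.cell_dy
        return x, y

    def heading_angle(self, ih: int | np.ndarray):
        return np.asarray(ih) * self.heading_quantum

    @classmethod
    def for_forest(cls, forest, cell: float = 0.25, n_headings: int = 72) -> "GridSpec":
        """Grid covering the forest bounds with square cells of side ``cell``."""
        nx = max(1, round(forest.bounds[0] / cell))
        ny = max(1, round(forest.bounds[1] / cell))
        return cls(nx, ny, n_headings, cell, cell, (0.0, 0.0))


def count_states(grid: GridSpec) -> int:
    """Number of un-augmented MDP states, nx * ny * n_headings."""
    return grid.n_states


@dataclass(frozen=True)
class ActionSpace:
    """2m+1 actions; action j commands heading change offsets[j].

    The offsets cover the pi/2 visual arc symmetrically, so the extreme
    actions are +/- pi/4 and action m (0-based) flies straight.
    """

    m: int = 2

    def __post_init__(self) -> None:
        if self.m < 0:
            raise ValueError("m must be >= 0")
        offs = (
            np.zeros(1)
            if self.m == 0
            else np.linspace(-math.pi / 4, math.pi / 4, 2 * self.m + 1)
        )
        offs.setflags(write=False)
        object.__setattr__(self, "_offsets", offs)

    @property
    def n_actions(self) -> int:
        return 2 * self.m + 1

    @property
    def straight(self) -> int:
        return self.m

    @property
    def offsets(self) -> np.ndarray:
        return self._offsets


@dataclass(frozen=True)
class MdpConfig:
    """Kinematic constants: constant speed v (m/s), MDP time step dt (s),
    and control-history length q (number of past actions kept in the state).

    The default step of 0.25 s at 2 m/s travels 0.5 m, about two planar
    cells at the default 0.25 m pitch.
    """

    speed: float = 2.0
    dt: float = 0.25
    q: int = 1
    midpoint: bool = False  # integrate along the half-turned heading instead

    def __post_init__(self) -> None:
        if self.speed <= 0 or self.dt <= 0:
            raise ValueError("speed and dt must be positive")
        if self.q < 0:
            raise ValueError("q must be >= 0")


@dataclass(frozen=True)
class AgentState:
    """Discrete MDP state: cell indices, heading bin, last-q action history.

    ``history[-1]`` is the most recent action; at episode start the history
    is padded with the straight action.
    """

    ix: int
    iy: int
    ih: int
    history: tuple[int, ...] = ()


def unicycle_step(
    pose: tuple[float, float, float],
    offset: float,
    cfg: MdpConfig,
) -> tuple[float, float, float]:
    """Advance a continuous pose one step.

    The commanded heading change is applied instantaneously at the start of
    the step (the action names the *desired next heading*), then the agent
    translates speed*dt along the new heading.  With ``cfg.midpoint`` the
    translation instead follows the average of old and new headings.
    """
    x, y, w = pose
    w_new = w + offset
    w_move = w + 0.5 * offset if cfg.midpoint else w_new
    d = cfg.speed * cfg.dt
    return (x + d * math.cos(w_move), y + d * math.sin(w_move), w_new)


def bilinear_weights(fx: float, fy: float) -> list[tuple[int, int, float]]:
    """Snap weights of a continuous point onto the 4 nearest cell centers.

    ``fx, fy`` are fractional cell coordinates of the point relative to cell
    centers (i.e. point_x/dx - 0.5).  Returns (di, dj, w) triples relative to
    floor(fx), floor(fy) with weights summing to 1.
    """
    ix0, iy0 = math.floor(fx), math.floor(fy)
    tx, ty = fx - ix0, fy - iy0
    out = []
    for di, wx in ((0, 1 - tx), (1, tx)):
        for dj, wy in ((0, 1 - ty), (1, ty)):
            w = wx * wy
            if w > 0:
                out.append((ix0 + di, iy0 + dj, w))
    return out


def _snap_heading(ih: int, offset: float, grid: GridSpec) -> int:
    # Round the *offset* in bin units (half-to-even keeps left/right turns
    # symmetric), then wrap.
    db = int(np.rint(offset / grid.heading_quantum))
    return (ih + db) % grid.n_headings


def _wrap_or_reflect(i: int, n: int, periodic: bool) -> int:
    if periodic:
        return i % n
    while not 0 <= i < n:
        if i < 0:
            i = -i - 1
        else:
            i = 2 * n - i - 1
    return i


def transition_sample(
    state: AgentState,
    action: int,
    grid: GridSpec,
    actions: ActionSpace,
    cfg: MdpConfig,
    rng: np.random.Generator,
    periodic: bool = True,
) -> AgentState:
    """Sample the next discrete state.

    The cell-center pose is advanced by :func:`unicycle_step`, the planar
    endpoint is snapped stochastically with bilinear overlap weights, and the
    heading goes to the nearest bin.  Endpoints beyond the bounds wrap for
    periodic forests and reflect for bounded ones.  The action is appended to
    the history (oldest entry dropped).
    """
    if not 0 <= action < actions.n_actions:
        raise ValueError(f"action {action} outside 0..{actions.n_actions - 1}")
    offset = actions.offsets[action]
    cx, cy = grid.cell_center(state.ix, state.iy)
    x, y, _ = unicycle_step((float(cx), float(cy), grid.heading_angle(state.ih)), offset, cfg)
    fx = (x - grid.origin[0]) / grid.cell_dx - 0.5
    fy = (y - grid.origin[1]) / grid.cell_dy - 0.5
    cand = bilinear_weights(fx, fy)
    probs = np.array([w for _, _, w in cand])
    k = rng.choice(len(cand), p=probs / probs.sum())
    ix, iy, _ = cand[k]
    ix = _wrap_or_reflect(ix, grid.nx, periodic)
    iy = _wrap_or_reflect(iy, grid.ny, periodic)
    ih = _snap_heading(state.ih, offset, grid)
    hist = (state.history + (action,))[-cfg.q :] if cfg.q > 0 else ()
    return AgentState(int(ix), int(iy), ih, hist)


def simulate(
    policy: Callable[[AgentState, np.random.Generator], int],
    reward_of: Callable[[AgentState], float],
    start: AgentState,
    K: int,
    rng: np.random.Generator,
    grid: GridSpec,
    actions: ActionSpace,
    cfg: MdpConfig,
    periodic: bool = True,
) -> tuple[list[tuple[AgentState, int, float]], float]:
    """Roll the chain K steps; returns the trajectory and running avg reward.

    ``policy`` maps (state, rng) to an action index; ``reward_of`` gives the
    one-step reward of the *current* state (rewards depend on position only).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    traj: list[tuple[AgentState, int, float]] = []
    s = start
    total = 0.0
    for _ in range(K):
        a = int(policy(s, rng))
        if not 0 <= a < actions.n_actions:
            raise ValueError(f"policy returned out-of-range action {a}")
        g = float(reward_of(s))
        traj.append((s, a, g))
        total += g
        s = transition_sample(s, a, grid, actions, cfg, rng, periodic)
    return traj, total / K


def export_trajectory(
    traj: Sequence[tuple[AgentState, int, float]],
    path,
    grid: GridSpec,
    cfg: MdpConfig,
) -> None:
    """Delimited-text trajectory dump ``t,x,y,heading,action,reward``."""
    rows = []
    for k, (s, a, g) in enumerate(traj):
        x, y = grid.cell_center(s.ix, s.iy)
        w = float(grid.heading_angle(s.ih)) % (2 * math.pi)
        rows.append(f"{k * cfg.dt},{float(x)},{float(y)},{w},{a},{g}")
    with open(path, "w") as fh:
        fh.write("t,x,y,heading,action,reward\n")
        fh.write("\n".join(rows) + "\n")
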