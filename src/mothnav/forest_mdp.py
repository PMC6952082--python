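"""Table-driven composition of forest + grid + features into a fast MDP.

Feature evaluation dominates the cost of simulating the chain, so
:class:`ForestMdp` precomputes the obstacle-spatial-density table for every
(cell, heading), the reward per cell, and the snapping stencil per
(heading, action) — the bilinear weights depend only on the fractional part
of the displacement, which is identical for every cell of a uniform grid.
Stepping the chain then reduces to table lookups, which is what makes the
actor-critic restarts and stationary-chain construction tractable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .forest_env import DEFAULT_FOG, Forest, RewardParams, reward_field
from .mdp_core import ActionSpace, GridSpec, MdpConfig, unicycle_step
from .visual_features import (
    DEFAULT_ANGULAR_RESOLUTION,
    feature_matrix,
    osd_table,
)
from .boltzmann_policy import PolicyParams, action_probabilities, as_raw_weights

__all__ = ["Observation", "ForestMdp"]


@dataclass(frozen=True)
class Observation:
    """Simulation state: grid indices, action history, and the previous
    grid state (needed to evaluate optical flow)."""

    ix: int
    iy: int
    ih: int
    history: tuple[int, ...]
    prev: tuple[int, int, int] | None = None


class ForestMdp:
    """The full navigation MDP over a concrete forest.

    Exposes the environment protocol used by the actor-critic and the
    evaluators: ``reset(rng)``, ``step(obs, action, rng)``, ``phi(obs)``
    and ``reward(obs)``.
    """

    def __init__(
        self,
        forest: Forest,
        grid: GridSpec | None = None,
        actions: ActionSpace = ActionSpace(2),
        cfg: MdpConfig = MdpConfig(),
        reward_params: RewardParams = RewardParams(),
        fog_level: float = DEFAULT_FOG,
        angular_resolution: float = DEFAULT_ANGULAR_RESOLUTION,
    ) -> None:
        self.forest = forest
        self.grid = grid or GridSpec.for_forest(forest)
        self.actions = actions
        self.cfg = cfg
        self.reward_params = reward_params
        self.fog_level = fog_level
        self.periodic = forest.periodic_cell is not None

        self.field = reward_field(forest, self.grid, reward_params)
        self.reward_cells = self.field.values  # (ny, nx)
        self.osd = osd_table(forest, self.grid, fog_level, actions.m, angular_resolution)
        self._build_kinematics()

    # ------------------------------------------------------------ kinematics
    def _build_kinematics(self) -> None:
        g, acts, cfg = self.grid, self.actions, self.cfg
        H, A = g.n_headings, acts.n_actions
        quantum = g.heading_quantum
        # Heading-bin change per action (round half to even keeps turns
        # left/right symmetric).
        self.dheading = np.rint(acts.offsets / quantum).astype(int)
        # Per (heading, action): the 4-point bilinear stencil of the planar
        # endpoint, shared by every cell.
        self.stencil_ij = np.zeros((H, A, 4, 2), dtype=np.int64)
        self.stencil_w = np.zeros((H, A, 4), dtype=float)
        for h in range(H):
            for a in range(A):
                x, y, _ = unicycle_step((0.0, 0.0, h * quantum), acts.offsets[a], cfg)
                fx, fy = x / g.cell_dx, y / g.cell_dy
                ix0, iy0 = math.floor(fx), math.floor(fy)
                tx, ty = fx - ix0, fy - iy0
                k = 0
                for di, wx in ((0, 1 - tx), (1, tx)):
                    for dj, wy in ((0, 1 - ty), (1, ty)):
                        self.stencil_ij[h, a, k] = (ix0 + di, iy0 + dj)
                        self.stencil_w[h, a, k] = wx * wy
                        k += 1
        self.stencil_cum = np.cumsum(self.stencil_w, axis=-1)

    # -------------------------------------------------------------- protocol
    def reset(self, rng: np.random.Generator) -> Observation:
        """Uniform random cell and heading; straight-padded history."""
        ix = int(rng.integers(self.grid.nx))
        iy = int(rng.integers(self.grid.ny))
        ih = int(rng.integers(self.grid.n_headings))
        hist = (self.actions.straight,) * self.cfg.q
        return Observation(ix, iy, ih, hist, None)

    def reward(self, obs: Observation) -> float:
        return float(self.reward_cells[obs.iy, obs.ix])

    def phi(self, obs: Observation) -> np.ndarray:
        """Feature matrix (2m+1, 6) of the observation."""
        cov = self.osd[obs.iy, obs.ix, obs.ih]
        cov_prev = None
        if obs.prev is not None:
            pix, piy, pih = obs.prev
            cov_prev = self.osd[piy, pix, pih]
        return feature_matrix(cov, cov_prev, obs.history, self.actions)

    def _snap_planar(self, ix: int, iy: int) -> tuple[int, int]:
        nx, ny = self.grid.nx, self.grid.ny
        if self.periodic:
            return ix % nx, iy % ny
        while not 0 <= ix < nx:
            ix = -ix - 1 if ix < 0 else 2 * nx - ix - 1
        while not 0 <= iy < ny:
            iy = -iy - 1 if iy < 0 else 2 * ny - iy - 1
        return ix, iy

    def step(
        self, obs: Observation, action: int, rng: np.random.Generator
    ) -> tuple[Observation, float]:
        """One transition; returns (next observation, reward of ``obs``)."""
        g = self.reward(obs)
        cum = self.stencil_cum[obs.ih, action]
        k = int(np.searchsorted(cum, rng.random() * cum[-1], side="right"))
        k = min(k, 3)
        di, dj = self.stencil_ij[obs.ih, action, k]
        ix, iy = self._snap_planar(obs.ix + int(di), obs.iy + int(dj))
        ih = (obs.ih + int(self.dheading[action])) % self.grid.n_headings
        hist = (obs.history + (action,))[-self.cfg.q :] if self.cfg.q > 0 else ()
        return Observation(ix, iy, ih, hist, (obs.ix, obs.iy, obs.ih)), g

    # ------------------------------------------------------------ simulation
    def simulate_policy(
        self,
        theta: PolicyParams | np.ndarray,
        K: int,
        rng: np.random.Generator,
        start: Observation | None = None,
        collect: bool = False,
    ):
        """Roll the chain K steps under a Boltzmann policy.

        Returns ``(average_reward, info)`` where ``info`` carries the action
        frequency histogram, a batch-means standard error of the reward mean
        (the chain is autocorrelated, so the iid formula would be
        optimistic), and — with ``collect`` — the visited
        (ix, iy, ih, action) rows.
        """
        w = as_raw_weights(theta)
        obs = start if start is not None else self.reset(rng)
        counts = np.zeros(self.actions.n_actions, dtype=np.int64)
        rows = [] if collect else None
        rewards = np.empty(K)
        for k in range(K):
            p = action_probabilities(w, self.phi(obs))
            a = int(rng.choice(p.shape[0], p=p))
            counts[a] += 1
            if collect:
                rows.append((obs.ix, obs.iy, obs.ih, a))
            obs, g = self.step(obs, a, rng)
            rewards[k] = g
        mean = float(rewards.mean())
        n_batches = min(50, K)
        batch = rewards[: (K // n_batches) * n_batches].reshape(n_batches, -1).mean(axis=1)
        stderr = float(batch.std(ddof=1) / math.sqrt(n_batches)) if n_batches > 1 else float("nan")
        info = {"action_counts": counts, "stderr": stderr, "rows": rows}
        return mean, info
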