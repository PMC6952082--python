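"""Synthetic demonstration data with the statistical structure the
regression assumes.

A known-parameter Boltzmann policy is simulated in a forest; each MDP step
is upsampled into a fixed-rate (60 Hz-style) continuous log of
(t, x, y, heading, control), optionally jittered in position.  The inverse
operation re-discretizes such logs onto the grid, infers the commanded
heading change between kept samples, recomputes the per-action features and
yields the (state, action) observation set the regression consumes — the
stand-in for real torque-meter recordings, and the substrate of the
end-to-end parameter-recovery (identifiability) check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from pathlib import Path

from .boltzmann_policy import PolicyParams, action_probabilities, as_raw_weights
from .forest_mdp import ForestMdp, Observation
from .policy_regression import ObservationSet

__all__ = ["TrajectoryLog", "generate_demonstrations", "discretize_log"]

DEFAULT_RATE = 60.0  # Hz


@dataclass
class TrajectoryLog:
    """Fixed-rate continuous flight log.

    Columns: time (s, strictly increasing at ``rate``), planar position (m),
    heading (rad, in [0, 2pi)), and the control (the commanded heading
    change of the step the sample belongs to, rad).
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    heading: np.ndarray
    control: np.ndarray
    rate: float = DEFAULT_RATE
    animal_id: str = "sim"
    trial_id: str = "0"
    fog_level: float | None = None

    def __post_init__(self) -> None:
        n = len(self.t)
        for name in ("x", "y", "heading", "control"):
            if len(getattr(self, name)) != n:
                raise ValueError("log columns must have equal length")
        if n > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("time must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)

    def to_file(self, path: str | Path) -> None:
        lines = [
            f"# rate {self.rate}",
            f"# animal {self.animal_id}",
            f"# trial {self.trial_id}",
        ]
        if self.fog_level is not None:
            lines.append(f"# fog {self.fog_level}")
        lines.append("t,x,y,heading,control")
        for row in zip(self.t, self.x, self.y, self.heading, self.control):
            lines.append(",".join(repr(float(v)) for v in row))
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "TrajectoryLog":
        meta = {"rate": DEFAULT_RATE, "animal": "sim", "trial": "0", "fog": None}
        rows = []
        header_seen = False
        for line in Path(path).read_text().splitlines():
            if line.startswith("#"):
                parts = line[1:].split()
                if len(parts) == 2 and parts[0] in meta:
                    meta[parts[0]] = parts[1]
            elif line.strip():
                if not header_seen:
                    header_seen = True
                    continue
                rows.append([float(v) for v in line.split(",")])
        arr = np.asarray(rows, float).reshape(-1, 5)
        return cls(
            arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3], arr[:, 4],
            rate=float(meta["rate"]),
            animal_id=str(meta["animal"]),
            trial_id=str(meta["trial"]),
            fog_level=None if meta["fog"] is None else float(meta["fog"]),
        )


def generate_demonstrations(
    theta_true: PolicyParams,
    mdp: ForestMdp,
    n_trials: int,
    steps_per_trial: int,
    rng: np.random.Generator,
    rate: float = DEFAULT_RATE,
    jitter: float = 0.0,
) -> tuple[list[TrajectoryLog], ObservationSet]:
    """Simulate the MDP under theta_true and log at a fixed rate.

    Returns the continuous logs (one per trial; ``rate`` frames per second,
    linearly interpolated inside each MDP step, with optional isotropic
    Gaussian positional jitter of standard deviation ``jitter`` metres) and
    the exact ground-truth observation set containing each decision's full
    per-action feature matrix and the chosen action.
    """
    frames = rate * mdp.cfg.dt
    if abs(frames - round(frames)) > 1e-9 or frames < 1:
        raise ValueError("rate * dt must be a positive integer (frames per MDP step)")
    frames = int(round(frames))
    w = as_raw_weights(theta_true)
    g = mdp.grid
    all_phis, all_actions, all_src = [], [], []
    logs = []
    for trial in range(n_trials):
        obs = mdp.reset(rng)
        ts, xs, ys, hs, cs = [], [], [], [], []
        for k in range(steps_per_trial):
            phis = mdp.phi(obs)
            p = action_probabilities(w, phis)
            a = int(rng.choice(p.shape[0], p=p))
            all_phis.append(phis)
            all_actions.append(a)
            all_src.append(trial)
            obs_next, _ = mdp.step(obs, a, rng)
            # Upsample the step: heading turns at the step start, then the
            # position interpolates linearly between the two cell centers.
            x0, y0 = g.cell_center(obs.ix, obs.iy)
            x1, y1 = g.cell_center(obs_next.ix, obs_next.iy)
            w0 = float(g.heading_angle(obs.ih)) % (2 * math.pi)
            for j in range(frames):
                frac = j / frames
                ts.append((k * frames + j) / rate)
                xs.append(float(x0) + frac * (float(x1) - float(x0)))
                ys.append(float(y0) + frac * (float(y1) - float(y0)))
                hs.append(w0)
                cs.append(float(mdp.actions.offsets[a]))
            obs = obs_next
        # Terminal frame: the pose after the last step, so that the last
        # action remains inferable from the log.
        xT, yT = g.cell_center(obs.ix, obs.iy)
        ts.append(steps_per_trial * frames / rate)
        xs.append(float(xT))
        ys.append(float(yT))
        hs.append(float(g.heading_angle(obs.ih)) % (2 * math.pi))
        cs.append(0.0)
        xs = np.asarray(xs)
        ys = np.asarray(ys)
        if jitter > 0:
            xs = xs + rng.normal(0.0, jitter, xs.shape)
            ys = ys + rng.normal(0.0, jitter, ys.shape)
        logs.append(
            TrajectoryLog(
                np.asarray(ts), xs, ys, np.asarray(hs), np.asarray(cs),
                rate=rate, animal_id="sim", trial_id=str(trial),
                fog_level=mdp.fog_level,
            )
        )
    data = ObservationSet(
        np.asarray(all_phis), np.asarray(all_actions), theta_true.feature_names,
        sources=np.asarray(all_src),
    )
    return logs, data


@dataclass
class DiscretizationReport:
    """Bookkeeping of a log discretization."""

    n_kept: int = 0
    n_clamped: int = 0
    mean_snap_distance: float = 0.0


def discretize_log(
    log: TrajectoryLog,
    mdp: ForestMdp,
    subsample: int,
) -> tuple[ObservationSet, DiscretizationReport]:
    """Reduce a continuous log to an observation set on the MDP grid.

    Every ``subsample``-th frame is kept, poses snap to the nearest grid
    state, and the action is inferred as the heading change to the next kept
    frame quantized to the nearest commanded offset (changes outside the
    +-pi/4 arc clamp to the extreme action and are counted).  Features are
    recomputed per candidate action exactly as during policy execution, with
    the optical flow fed by the previous kept frame's snapped state.
    """
    if subsample < 1:
        raise ValueError("subsample must be >= 1")
    frames_per_step = log.rate * mdp.cfg.dt
    g, acts = mdp.grid, mdp.actions
    idx = np.arange(0, len(log), subsample)
    if idx.size < 2:
        raise ValueError("log too short for this subsample factor")
    xs, ys, hs = log.x[idx], log.y[idx], log.heading[idx]

    ix = np.clip(np.floor((xs - g.origin[0]) / g.cell_dx).astype(int), 0, g.nx - 1)
    iy = np.clip(np.floor((ys - g.origin[1]) / g.cell_dy).astype(int), 0, g.ny - 1)
    ih = np.mod(np.rint(hs / g.heading_quantum).astype(int), g.n_headings)
    cx, cy = g.cell_center(ix, iy)
    snap_d = np.hypot(xs - cx, ys - cy)

    dh = np.diff(hs)
    dh = (dh + math.pi) % (2 * math.pi) - math.pi
    offsets = acts.offsets
    inferred = np.abs(dh[:, None] - offsets[None, :]).argmin(axis=1)
    clamped = int(np.sum((dh < offsets[0] - 1e-12) | (dh > offsets[-1] + 1e-12)))

    phis, actions_out = [], []
    hist = (acts.straight,) * mdp.cfg.q
    prev = None
    for k in range(idx.size - 1):
        obs = Observation(int(ix[k]), int(iy[k]), int(ih[k]), hist, prev)
        phis.append(mdp.phi(obs))
        a = int(inferred[k])
        actions_out.append(a)
        prev = (int(ix[k]), int(iy[k]), int(ih[k]))
        hist = (hist + (a,))[-mdp.cfg.q:] if mdp.cfg.q > 0 else ()
    data = ObservationSet(np.asarray(phis), np.asarray(actions_out))
    report = DiscretizationReport(
        n_kept=int(idx.size),
        n_clamped=clamped,
        mean_snap_distance=float(snap_d.mean()),
    )
    return data, report
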