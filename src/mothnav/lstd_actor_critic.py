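"""Average-reward LSTD actor-critic policy refinement.

The critic tracks the average-reward estimate a, an eligibility trace z of
visited feature vectors, and least-squares statistics (A, b) whose solve
gives the critic weights r.  The actor ascends the average reward along the
score function, with the step clipped through Gamma(r) = min(1, D/||r||).
Step sizes: zeta_k = 1/k for the critic and eta_k = c/(k ln k) for the
actor (started at k = 2, where the schedule is first defined).

A single run is a local stochastic-gradient search; the multi-restart
protocol reruns it from independent seeds, ranks runs by the critic's final
average-reward estimate, re-simulates the top candidates and returns the
winner.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .boltzmann_policy import PolicyParams, action_probabilities, as_raw_weights

__all__ = [
    "ACState",
    "ACConfig",
    "critic_update",
    "actor_update",
    "run_actor_critic",
    "multi_restart",
]


@dataclass
class ACState:
    """Critic/actor internals at step k."""

    a: float
    z: np.ndarray
    b: np.ndarray
    A: np.ndarray
    r: np.ndarray
    theta: np.ndarray
    k: int = 0

    @classmethod
    def initial(cls, theta0: np.ndarray, a0: float = 0.0) -> "ACState":
        f = theta0.shape[0]
        return cls(
            a=float(a0),
            z=np.zeros(f),
            b=np.zeros(f),
            A=np.zeros((f, f)),
            r=np.zeros(f),
            theta=np.asarray(theta0, float).copy(),
            k=0,
        )


@dataclass(frozen=True)
class ACConfig:
    """Tunables of the refinement loop.

    ``rho`` discounts the eligibility trace (close to 1), ``D`` caps the
    critic norm entering the actor step, ``c`` scales the actor step size,
    ``epsilon`` is the theta-change stopping threshold and ``a0`` the
    initial average-reward estimate (estimated from a pilot simulation of
    theta0 when None).
    """

    rho: float = 0.99
    D: float = 10.0
    c: float = 50.0
    epsilon: float = 1e-4
    a0: float | None = None
    max_steps: int = 200_000
    min_steps: int = 1000  # burn-in before the theta-change criterion applies
    check_every: int = 500  # theta-change tested between checkpoints, not per step
    actor_burn_in: int = 1000  # critic-only steps before the actor activates
    theta_bound: float = 1e6
    rcond: float = 1e-6  # relative singular-value cutoff of the critic solve
    printed_r_update: bool = False  # solve with the pre-update (A_k, b_k)
    a0_pilot_steps: int = 10_000


def _solve_r(A: np.ndarray, b: np.ndarray, rcond: float) -> np.ndarray:
    """Minimum-norm least-squares critic solve.

    With A accumulating z (phi_next - phi)' and b accumulating (g - a) z,
    the temporal-difference fixed point E[z delta] = 0 reads b + A r = 0,
    so the critic weights are r = -A^+ b (r then approximates the
    differential action values).  A is singular early on — and stays
    singular along any direction that scores every state-action pair
    equally — so the pseudo-inverse (singular values below ``rcond`` of the
    largest are dropped) both regularizes the start-up and keeps the
    irrelevant constant component of r at zero instead of letting it blow
    up against the near-null space.
    """
    sol, *_ = np.linalg.lstsq(A, -b, rcond=rcond)
    return sol


def critic_update(
    s: ACState,
    transition: tuple[np.ndarray, float, np.ndarray],
    zeta: float,
    cfg: ACConfig = ACConfig(),
) -> ACState:
    """One critic step on (phi_k, g_k, phi_{k+1}).

    The update lines are applied sequentially in their written order —
    average-reward estimate, eligibility trace, b, A, r — each line reading
    the values already updated above it (so the b recursion sees the fresh
    a and z).  With ``cfg.printed_r_update`` the critic weights are solved
    from the pre-update statistics instead; both variants converge.
    """
    phi_k, g, phi_next = transition
    a = s.a + zeta * (g - s.a)
    z = cfg.rho * s.z + phi_k
    b = s.b + zeta * ((g - a) * z - s.b)
    A = s.A + zeta * (np.outer(z, phi_next - phi_k) - s.A)
    if cfg.printed_r_update:
        r = _solve_r(s.A, s.b, cfg.rcond)
    else:
        r = _solve_r(A, b, cfg.rcond)
    return replace(s, a=a, z=z, b=b, A=A, r=r)


def gamma_clip(r: np.ndarray, D: float) -> float:
    """Gamma(r) = D/||r|| when ||r|| > D, else 1."""
    nrm = float(np.linalg.norm(r))
    return D / nrm if nrm > D else 1.0


def actor_update(
    s: ACState,
    transition: tuple[np.ndarray, np.ndarray],
    eta: float,
    cfg: ACConfig = ACConfig(),
) -> ACState:
    """One actor step: theta += eta * Gamma(r) * (phi' r) * psi.

    ``transition`` supplies the feature vector whose critic value phi' r
    multiplies the score psi; the policy-gradient estimate requires both to
    be evaluated at the same state-action pair, so the main loop passes
    phi(x_{k+1}, u_{k+1}) alongside psi(x_{k+1}, u_{k+1}).
    """
    phi_q, psi = transition
    gain = eta * gamma_clip(s.r, cfg.D) * float(phi_q @ s.r)
    return replace(s, theta=s.theta + gain * psi)


def eta_schedule(k: int, c: float) -> float:
    """Actor step size c/(k ln k); undefined at k = 1, so eta_1 = eta_2."""
    kk = max(k, 2)
    return c / (kk * math.log(kk))


@dataclass
class RefineResult:
    theta: PolicyParams
    a_final: float
    steps: int
    converged: bool
    diverged: bool
    a_trace: np.ndarray = field(default_factory=lambda: np.empty(0))


def run_actor_critic(
    env,
    theta0: PolicyParams,
    cfg: ACConfig,
    rng: np.random.Generator,
    trace_every: int = 0,
) -> RefineResult:
    """Iterate state/critic/actor updates until the theta-change stopping
    criterion or the step budget.

    ``env`` must provide ``reset(rng)``, ``phi(obs) -> (A, F)`` and
    ``step(obs, action, rng) -> (obs', g)``.  The loop is fully seeded and
    reproducible; it aborts (flagging divergence) if ||theta|| exceeds the
    configured bound.
    """
    feature_names = theta0.feature_names
    a0 = cfg.a0
    if a0 is None:
        a0 = _pilot_average_reward(env, theta0, cfg.a0_pilot_steps, rng)
    theta = as_raw_weights(theta0).astype(float).copy()
    f = theta.shape[0]
    a = float(a0)
    z = np.zeros(f)
    b = np.zeros(f)
    A = np.zeros((f, f))
    r = np.zeros(f)

    obs = env.reset(rng)
    phis = env.phi(obs)
    p = action_probabilities(theta, phis)
    u = int(rng.choice(p.shape[0], p=p))
    phi_k = phis[u]

    trace: list[float] = []
    theta_checkpoint = theta.copy()
    converged = diverged = False
    k = 1
    while k <= cfg.max_steps:
        obs_next, g = env.step(obs, u, rng)
        phis_next = env.phi(obs_next)
        p_next = action_probabilities(theta, phis_next)
        u_next = int(rng.choice(p_next.shape[0], p=p_next))
        phi_next = phis_next[u_next]
        psi_next = phi_next - p_next @ phis_next

        # Actor update first, with the critic weights from *before* this
        # transition is absorbed (the printed r-index lag): r must be
        # independent of the u_{k+1} draw, or the score factor acquires a
        # bias.  The actor also waits out a critic burn-in — the early
        # least-squares statistics are rank-deficient — and its step
        # schedule counts from activation.
        if k > cfg.actor_burn_in:
            eta = eta_schedule(k - cfg.actor_burn_in, cfg.c)
            nrm = float(np.linalg.norm(r))
            gain = eta * (cfg.D / nrm if nrm > cfg.D else 1.0) * float(phi_next @ r)
            dtheta = gain * psi_next
            theta += dtheta
        else:
            dtheta = np.zeros(f)

        zeta = 1.0 / k
        a += zeta * (g - a)
        z = cfg.rho * z + phi_k
        b += zeta * ((g - a) * z - b)
        A += zeta * (np.outer(z, phi_next - phi_k) - A)
        r = _solve_r(A, b, cfg.rcond)

        if trace_every and k % trace_every == 0:
            trace.append(a)
        if float(np.linalg.norm(theta)) > cfg.theta_bound:
            diverged = True
            break
        # A single stochastic update can be arbitrarily small, so the
        # theta-change stopping rule compares checkpoints a window apart.
        if k % cfg.check_every == 0:
            if (
                k >= cfg.actor_burn_in + cfg.min_steps
                and float(np.linalg.norm(theta - theta_checkpoint)) <= cfg.epsilon
            ):
                converged = True
                break
            theta_checkpoint = theta.copy()
        obs, u, phi_k = obs_next, u_next, phi_next
        k += 1

    return RefineResult(
        theta=PolicyParams(theta, feature_names),
        a_final=a,
        steps=k,
        converged=converged,
        diverged=diverged,
        a_trace=np.asarray(trace),
    )


def _pilot_average_reward(env, theta: PolicyParams, steps: int, rng: np.random.Generator) -> float:
    """Empirical average reward of theta; initializes the critic's a."""
    obs = env.reset(rng)
    w = as_raw_weights(theta)
    total = 0.0
    for _ in range(steps):
        p = action_probabilities(w, env.phi(obs))
        a = int(rng.choice(p.shape[0], p=p))
        obs, g = env.step(obs, a, rng)
        total += g
    return total / steps


@dataclass
class RestartReport:
    best: PolicyParams
    best_sim_reward: float
    runs: list[RefineResult]
    ranked_idx: list[int]
    sim_rewards: dict[int, float]


def multi_restart(
    env,
    theta0: PolicyParams,
    n_runs: int,
    top_k: int,
    sim_steps: int,
    rng: np.random.Generator,
    cfg: ACConfig = ACConfig(),
) -> RestartReport:
    """Restart protocol: run the refinement ``n_runs`` times from distinct
    seeds, rank runs by the critic's final average-reward estimate,
    re-evaluate the ``top_k`` by independent simulation and return the
    winner.

    Diverged runs are excluded from ranking when any run survives.
    """
    if not n_runs >= top_k >= 1:
        raise ValueError("need n_runs >= top_k >= 1")
    seeds = rng.spawn(n_runs + top_k + 1)
    if cfg.a0 is None:
        # The restarts all refine the same starting policy, so its pilot
        # average-reward estimate is shared.
        a0 = _pilot_average_reward(env, theta0, cfg.a0_pilot_steps, seeds[-1])
        cfg = replace(cfg, a0=a0)
    runs = [run_actor_critic(env, theta0, cfg, seeds[i]) for i in range(n_runs)]
    ok = [i for i, res in enumerate(runs) if not res.diverged]
    pool = ok if ok else list(range(n_runs))
    ranked = sorted(pool, key=lambda i: runs[i].a_final, reverse=True)[:top_k]
    sim_rewards: dict[int, float] = {}
    for j, i in enumerate(ranked):
        reward, _ = env.simulate_policy(runs[i].theta, sim_steps, seeds[n_runs + j])
        sim_rewards[i] = reward
    winner = max(sim_rewards, key=sim_rewards.get)
    return RestartReport(
        best=runs[winner].theta,
        best_sim_reward=sim_rewards[winner],
        runs=runs,
        ranked_idx=ranked,
        sim_rewards=sim_rewards,
    )
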