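"""Shared fixtures: small forests, a visually rich demonstration MDP, and an
enumerable toy chain with a known optimal policy."""

from __future__ import annotations

import numpy as np
import pytest

from mothnav.boltzmann_policy import PolicyParams, action_probabilities
from mothnav.forest_env import make_artificial_forest
from mothnav.forest_mdp import ForestMdp
from mothnav.visual_features import FEATURE_NAMES


class ToyChain:
    """Two-state, two-action chain for exact oracles.

    Action 1 ("move") switches the state with probability 0.9, action 0
    ("stay") keeps it with probability 0.9; reward 1 in state B, 0 in A.
    Features are one-hot over (state, action), so a linear softmax policy
    can represent every deterministic policy in the limit.
    """

    p = 0.9
    n_features = 4
    feature_names = ("A_stay", "A_move", "B_stay", "B_move")

    def phi_s(self, s: int) -> np.ndarray:
        out = np.zeros((2, 4))
        out[0, 2 * s] = 1.0
        out[1, 2 * s + 1] = 1.0
        return out

    def reset(self, rng):
        return int(rng.integers(2))

    def phi(self, s):
        return self.phi_s(s)

    def step(self, s, a, rng):
        g = float(s == 1)
        switch = a == 1
        if rng.random() > self.p:
            switch = not switch
        return (1 - s if switch else s), g

    def simulate_policy(self, theta, K, rng):
        w = theta.theta if isinstance(theta, PolicyParams) else np.asarray(theta)
        s = self.reset(rng)
        total = 0.0
        for _ in range(K):
            pr = action_probabilities(w, self.phi_s(s))
            a = int(rng.choice(2, p=pr))
            s, g = self.step(s, a, rng)
            total += g
        return total / K, {}

    # ---------------------------------------------------------------- exact
    def exact_average_reward(self, p_move_A: float, p_move_B: float) -> float:
        """Closed-form average reward of the policy (pi_B of the 2-chain)."""
        qA = 0.1 + 0.8 * p_move_A  # P(A -> B)
        qB = 0.1 + 0.8 * p_move_B  # P(B -> A)
        return qA / (qA + qB)

    def exact_policy_value(self, theta) -> float:
        w = theta.theta if isinstance(theta, PolicyParams) else np.asarray(theta)
        pA = action_probabilities(w, self.phi_s(0))[1]
        pB = action_probabilities(w, self.phi_s(1))[1]
        return self.exact_average_reward(pA, pB)

    def brute_force_optimum(self) -> float:
        return max(
            self.exact_average_reward(a, b) for a in (0.0, 1.0) for b in (0.0, 1.0)
        )


@pytest.fixture(scope="session")
def toy_env():
    return ToyChain()


@pytest.fixture(scope="session")
def toy_theta0():
    return PolicyParams(np.zeros(4), ToyChain.feature_names)


@pytest.fixture(scope="session")
def rich_mdp():
    """Demonstration benchmark: a dense periodic forest (4 x 3 m cell,
    0.5 m trees) under heavy fog (perception range ~5 m), chosen so every
    visual feature varies in the data — the identifiability precondition."""
    return ForestMdp(make_artificial_forest(1, tree_size=0.5), fog_level=26.67)


@pytest.fixture(scope="session")
def forest16x12_mdp():
    """The 16 x 12 m elementary-cell artificial forest (n = 4)."""
    return ForestMdp(make_artificial_forest(4))


@pytest.fixture(scope="session")
def theta_true():
    """Ground-truth weights for recovery oracles (all six identifiable)."""
    return PolicyParams(np.array([1.0, -0.5, 0.8, 0.6, -0.7, -1.2]), FEATURE_NAMES)
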