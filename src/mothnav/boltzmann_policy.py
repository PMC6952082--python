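"""The parameterized randomized stationary policy and its score function.

Action probabilities follow a Boltzmann (softmax) distribution over the
linear energies theta' phi(x, u): every action keeps strictly positive
probability for finite weights, which is what makes the induced Markov
chains irreducible.  The score function -- the gradient of the
log-likelihood of a chosen action -- is the quantity the actor-critic uses
to ascend the average reward.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .visual_features import FEATURE_NAMES

__all__ = [
    "PolicyParams",
    "action_probabilities",
    "sample_action",
    "score",
    "load_bundled_policy",
    "MOTH_POLICY_WEIGHTS",
    "REFINED_POLICY_WEIGHTS",
]

#: Reference weight vectors of the two bundled policies (feature order:
#: osd, osd0, osd05, of, history, energy).  The first was regressed from
#: 62,651 recorded moth state-action pairs; the second is its actor-critic
#: refinement against the constructed one-step reward.
MOTH_POLICY_WEIGHTS = (0.0, -0.0817, 0.1234, 0.7644, -1.1349, 0.7546)
REFINED_POLICY_WEIGHTS = (1.2590, 38.8491, -8.6711, 66.5153, -9.2061, 15.7742)


@dataclass(frozen=True)
class PolicyParams:
    """Weight vector theta over named features."""

    theta: np.ndarray
    feature_names: tuple[str, ...] = FEATURE_NAMES
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        theta = np.asarray(self.theta, dtype=float).ravel()
        if theta.shape[0] != len(self.feature_names):
            raise ValueError("theta length does not match feature_names")
        if not np.all(np.isfinite(theta)):
            raise ValueError("theta must be finite")
        object.__setattr__(self, "theta", theta)

    @property
    def n_features(self) -> int:
        return self.theta.shape[0]

    @property
    def effective_theta(self) -> np.ndarray:
        """Weights applied to *raw* features.

        Policies regressed on standardized features carry the per-feature
        scale in ``meta["feature_scale"]``; since the mean subtraction is
        constant across candidate actions it cancels in the softmax, so
        applying such a policy to raw features is exactly equivalent to
        using theta / scale.  Policies without a scale reference are
        raw-feature policies already.
        """
        scale = self.meta.get("feature_scale")
        if scale is None:
            return self.theta
        s = np.asarray(scale, dtype=float)
        if s.shape != self.theta.shape or np.any(s <= 0):
            raise ValueError("feature_scale must be positive, one entry per feature")
        return self.theta / s

    # ------------------------------------------------------------------ I/O
    def save(self, path: str | Path) -> None:
        doc = {
            "schema": "mothnav-policy-v1",
            "features": list(self.feature_names),
            "weights": {n: float(w) for n, w in zip(self.feature_names, self.theta)},
        }
        if self.meta:
            doc["meta"] = dict(self.meta)
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "PolicyParams":
        return cls._from_doc(yaml.safe_load(Path(path).read_text()))

    @classmethod
    def _from_doc(cls, doc: dict) -> "PolicyParams":
        if doc.get("schema") != "mothnav-policy-v1":
            raise ValueError("unrecognized policy file schema")
        names = tuple(doc["features"])
        theta = np.array([doc["weights"][n] for n in names], dtype=float)
        return cls(theta, names, doc.get("meta", {}))


def load_bundled_policy(name: str) -> PolicyParams:
    """Load one of the reference policies shipped with the package.

    ``name`` is ``"moth"`` (regressed from the flight demonstrations) or
    ``"refined"`` (actor-critic refinement of the former).  Their metadata
    records the expected average reward each attained in the experimental
    forest (0.1006 and 0.1668 respectively).
    """
    fname = f"{name}.policy"
    try:
        text = resources.files("mothnav.data").joinpath(fname).read_text()
    except FileNotFoundError as exc:  # pragma: no cover
        raise ValueError(f"no bundled policy named {name!r}") from exc
    return PolicyParams._from_doc(yaml.safe_load(text))


def as_raw_weights(theta: "PolicyParams | np.ndarray") -> np.ndarray:
    """Weight vector to apply to raw features (resolving any scale reference)."""
    if isinstance(theta, PolicyParams):
        return theta.effective_theta
    return np.asarray(theta, float)


def _logits(theta: PolicyParams | np.ndarray, phis: np.ndarray) -> np.ndarray:
    w = as_raw_weights(theta)
    phis = np.asarray(phis, float)
    if phis.ndim != 2 or phis.shape[1] != w.shape[0]:
        raise ValueError(
            f"feature matrix shape {phis.shape} incompatible with theta of length {w.shape[0]}"
        )
    return phis @ w


def action_probabilities(theta: PolicyParams | np.ndarray, phis: np.ndarray) -> np.ndarray:
    """Softmax of theta' phi(x, u) over the candidate actions.

    ``phis`` has one row per action.  Computed with the max subtracted for
    stability; probabilities are strictly positive and sum to 1.
    """
    z = _logits(theta, phis)
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


def sample_action(
    theta: PolicyParams | np.ndarray, phis: np.ndarray, rng: np.random.Generator
) -> int:
    """Draw an action index from the Boltzmann distribution."""
    p = action_probabilities(theta, phis)
    return int(rng.choice(p.shape[0], p=p))


def score(theta: PolicyParams | np.ndarray, phis: np.ndarray, action: int) -> np.ndarray:
    """Score function psi = grad_theta ln mu(u | x; theta).

    Equals phi(x, u) minus the probability-weighted feature average; its
    expectation under the policy itself is the zero vector.
    """
    p = action_probabilities(theta, phis)
    phis = np.asarray(phis, float)
    return phis[action] - p @ phis
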