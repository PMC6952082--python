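"""Sparse multinomial logistic regression of policy weights from demonstrations.

Given demonstration pairs D = {(x_i, u_i)} with the full per-action feature
matrix recorded at each decision, the weights theta of the Boltzmann policy
are estimated by minimizing the negative log-likelihood plus an l1 penalty
that selects the informative features.  The composite objective is convex;
it is solved exactly by splitting theta into positive and negative parts and
running box-constrained L-BFGS-B on the resulting smooth program.  Penalty
selection follows an 80/20 train/validation split over a log-spaced grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp, softmax

from .boltzmann_policy import PolicyParams, as_raw_weights
from .visual_features import FEATURE_NAMES

__all__ = [
    "ObservationSet",
    "FitResult",
    "CrossValidationResult",
    "nll",
    "nll_gradient",
    "nll_subgradient",
    "fit_sparse",
    "lambda_max",
    "cross_validate",
]

#: Weights with magnitude below this after optimization are snapped to zero.
SPARSITY_TOL = 1e-8


@dataclass(frozen=True)
class ObservationSet:
    """The regression dataset D.

    ``phis`` has shape (N, A, F): the feature matrix of every candidate
    action at each recorded decision; ``actions`` holds the chosen action
    indices; ``sources`` optionally tags each record with an
    (animal, trial) label so grouped splits remain possible.
    """

    phis: np.ndarray
    actions: np.ndarray
    feature_names: tuple[str, ...] = FEATURE_NAMES
    sources: np.ndarray | None = None

    def __post_init__(self) -> None:
        phis = np.asarray(self.phis, dtype=float)
        acts = np.asarray(self.actions, dtype=np.int64)
        if phis.ndim != 3:
            raise ValueError("phis must have shape (N, A, F)")
        if acts.shape != (phis.shape[0],):
            raise ValueError("actions must have one entry per record")
        if phis.shape[0] and (acts.min() < 0 or acts.max() >= phis.shape[1]):
            raise ValueError("action index out of range")
        object.__setattr__(self, "phis", phis)
        object.__setattr__(self, "actions", acts)

    def __len__(self) -> int:
        return self.phis.shape[0]

    def subset(self, idx: np.ndarray) -> "ObservationSet":
        src = self.sources[idx] if self.sources is not None else None
        return ObservationSet(self.phis[idx], self.actions[idx], self.feature_names, src)

    # ------------------------------------------------------------------ I/O
    def to_frame(self) -> pd.DataFrame:
        n, a, _ = self.phis.shape
        rec = np.repeat(np.arange(n), a)
        act = np.tile(np.arange(a), n)
        df = pd.DataFrame(self.phis.reshape(n * a, -1), columns=list(self.feature_names))
        df.insert(0, "record", rec)
        df.insert(1, "candidate_action", act)
        df["chosen"] = (act == np.repeat(self.actions, a)).astype(int)
        return df

    def to_file(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_file(cls, path: str | Path) -> "ObservationSet":
        df = pd.read_csv(path)
        names = tuple(c for c in df.columns if c not in ("record", "candidate_action", "chosen"))
        n = df["record"].nunique()
        a = df["candidate_action"].nunique()
        df = df.sort_values(["record", "candidate_action"])
        phis = df[list(names)].to_numpy().reshape(n, a, len(names))
        chosen = df[df["chosen"] == 1].sort_values("record")["candidate_action"].to_numpy()
        return cls(phis, chosen, names)


def nll(theta: np.ndarray | PolicyParams, data: ObservationSet) -> float:
    """Negative log-likelihood of the demonstrations under the policy."""
    w = as_raw_weights(theta)
    z = data.phis @ w  # (N, A)
    chosen = z[np.arange(len(data)), data.actions]
    return float(np.sum(logsumexp(z, axis=1) - chosen))


def nll_gradient(theta: np.ndarray, data: ObservationSet) -> np.ndarray:
    """Gradient of the (smooth) NLL: sum_i E_mu[phi] - phi(x_i, u_i)."""
    w = np.asarray(theta, float)
    z = data.phis @ w
    mu = softmax(z, axis=1)  # (N, A)
    expected = np.einsum("na,naf->f", mu, data.phis)
    chosen = data.phis[np.arange(len(data)), data.actions].sum(axis=0)
    return expected - chosen


def nll_subgradient(theta: np.ndarray, data: ObservationSet, lam: float) -> np.ndarray:
    """Minimum-norm subgradient of NLL + lam * ||theta||_1.

    At zero coordinates the l1 term contributes the element of
    [-lam, lam] that minimizes the subgradient norm (i.e. soft-shrinks the
    smooth gradient), so a zero vector here certifies optimality.
    """
    w = np.asarray(theta, float)
    g = nll_gradient(w, data)
    out = g + lam * np.sign(w)
    zero = w == 0
    out[zero] = np.sign(g[zero]) * np.maximum(np.abs(g[zero]) - lam, 0.0)
    return out


def lambda_max(data: ObservationSet) -> float:
    """Smallest penalty for which theta = 0 is optimal: ||grad NLL(0)||_inf."""
    return float(np.abs(nll_gradient(np.zeros(data.phis.shape[2]), data)).max())


@dataclass(frozen=True)
class FitResult:
    theta_hat: PolicyParams
    lam: float
    train_nll: float
    val_nll: float | None = None
    converged: bool = True
    n_iter: int = 0
    message: str = ""


def fit_sparse(
    data: ObservationSet,
    lam: float,
    theta0: np.ndarray | None = None,
    tol: float = 1e-12,
    max_iter: int = 2000,
) -> FitResult:
    """Minimize NLL(theta) + lam * ||theta||_1.

    The nonsmooth program is rewritten with theta = theta+ - theta-,
    theta+/- >= 0, which is smooth with simple bounds and solved by
    L-BFGS-B; the split is exact for this convex objective.  Near-zero
    coordinates are snapped to exactly zero.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if len(data) == 0:
        raise ValueError("empty observation set")
    F = data.phis.shape[2]

    def fg(v: np.ndarray):
        th = v[:F] - v[F:]
        g = nll_gradient(th, data)
        f = nll(th, data) + lam * v.sum()
        return f, np.concatenate([g + lam, -g + lam])

    x0 = np.zeros(2 * F)
    if theta0 is not None:
        th0 = np.asarray(theta0, float)
        x0[:F] = np.clip(th0, 0, None)
        x0[F:] = np.clip(-th0, 0, None)
    res = minimize(
        fg,
        x0,
        jac=True,
        method="L-BFGS-B",
        bounds=[(0, None)] * (2 * F),
        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-10},
    )
    theta = res.x[:F] - res.x[F:]
    theta[np.abs(theta) < SPARSITY_TOL] = 0.0
    params = PolicyParams(theta, data.feature_names, {"lambda": float(lam)})
    return FitResult(
        theta_hat=params,
        lam=float(lam),
        train_nll=nll(theta, data),
        converged=bool(res.success),
        n_iter=int(res.nit),
        message=str(res.message),
    )


@dataclass(frozen=True)
class CrossValidationResult:
    best_lambda: float
    best_fit: FitResult
    path: list[FitResult] = field(default_factory=list)

    def path_frame(self) -> pd.DataFrame:
        rows = []
        for fit in self.path:
            for name, w in zip(fit.theta_hat.feature_names, fit.theta_hat.theta):
                rows.append({"lambda": fit.lam, "feature": name, "weight": w})
        return pd.DataFrame(rows)


def default_lambda_grid(data: ObservationSet, n: int = 30) -> np.ndarray:
    """30 log-spaced penalties spanning [1e-5, lambda_max], descending."""
    lmax = max(lambda_max(data), 1e-4)
    return np.geomspace(lmax, 1e-5, n)


def cross_validate(
    data: ObservationSet,
    lambda_grid: Sequence[float] | None = None,
    split_fraction: float = 0.8,
    rng: np.random.Generator | None = None,
) -> CrossValidationResult:
    """Select the l1 penalty on a record-wise random train/validation split.

    Fits the regularization path on ``split_fraction`` of the records (warm
    starting along the descending grid) and returns the penalty minimizing
    validation NLL together with the whole path.
    """
    if lambda_grid is None:
        lambda_grid = default_lambda_grid(data)
    lambda_grid = np.asarray(sorted(lambda_grid, reverse=True), float)
    if lambda_grid.size == 0:
        raise ValueError("empty lambda grid")
    if not 0 < split_fraction < 1:
        raise ValueError("split_fraction must be in (0, 1)")
    rng = rng or np.random.default_rng()
    n = len(data)
    perm = rng.permutation(n)
    n_train = max(1, int(round(split_fraction * n)))
    if n_train >= n:
        raise ValueError("validation split is empty")
    train = data.subset(perm[:n_train])
    val = data.subset(perm[n_train:])

    path: list[FitResult] = []
    warm = None
    for lam in lambda_grid:
        fit = fit_sparse(train, float(lam), theta0=warm)
        warm = fit.theta_hat.theta
        fit = FitResult(
            theta_hat=fit.theta_hat,
            lam=fit.lam,
            train_nll=fit.train_nll,
            val_nll=nll(fit.theta_hat.theta, val),
            converged=fit.converged,
            n_iter=fit.n_iter,
            message=fit.message,
        )
        path.append(fit)
    best = min(path, key=lambda f: f.val_nll)
    return CrossValidationResult(best.lam, best, path)
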