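"""Sparse multinomial logistic regression: objective, subgradient, fitting,
penalty path, cross-validation, and parameter recovery."""

import math

import numpy as np
import pytest

from mothnav.policy_regression import (
    ObservationSet,
    cross_validate,
    fit_sparse,
    lambda_max,
    nll,
    nll_gradient,
    nll_subgradient,
)
from mothnav.boltzmann_policy import action_probabilities
from mothnav.synthetic_trajectories import generate_demonstrations
from mothnav.visual_features import FEATURE_NAMES


def random_dataset(rng, n=50, n_actions=5, n_features=6, theta=None):
    phis = rng.normal(0, 1, (n, n_actions, n_features))
    if theta is None:
        actions = rng.integers(0, n_actions, n)
    else:
        actions = np.array(
            [
                rng.choice(n_actions, p=action_probabilities(theta, phis[i]))
                for i in range(n)
            ]
        )
    return ObservationSet(phis, actions)


@pytest.fixture(scope="module")
def demo_data(rich_mdp, theta_true):
    """2e4 ground-truth demonstration records from the benchmark forest."""
    rng = np.random.default_rng(100)
    _, data = generate_demonstrations(theta_true, rich_mdp, 4, 5000, rng, rate=4.0)
    return data


class TestNll:
    def test_uniform_likelihood_at_zero(self):
        data = random_dataset(np.random.default_rng(0), n=37)
        assert nll(np.zeros(6), data) == pytest.approx(37 * math.log(5))

    def test_single_record_definition(self):
        rng = np.random.default_rng(1)
        data = random_dataset(rng, n=1)
        theta = rng.normal(0, 1, 6)
        p = action_probabilities(theta, data.phis[0])
        assert nll(theta, data) == pytest.approx(-math.log(p[data.actions[0]]))

    def test_matches_bruteforce_summation(self):
        rng = np.random.default_rng(2)
        data = random_dataset(rng, n=10)
        theta = rng.normal(0, 1.5, 6)
        brute = 0.0
        for i in range(10):
            z = data.phis[i] @ theta
            brute += math.log(np.exp(z).sum()) - z[data.actions[i]]
        assert nll(theta, data) == pytest.approx(brute, abs=1e-10)

    def test_convexity(self):
        rng = np.random.default_rng(3)
        data = random_dataset(rng, n=30)
        for _ in range(10):
            t1, t2 = rng.normal(0, 2, (2, 6))
            t = rng.uniform(0.1, 0.9)
            lhs = nll(t * t1 + (1 - t) * t2, data)
            rhs = t * nll(t1, data) + (1 - t) * nll(t2, data)
            assert lhs <= rhs + 1e-9


class TestSubgradient:
    def test_matches_finite_differences(self):
        rng = np.random.default_rng(4)
        data = random_dataset(rng, n=20)
        theta = rng.normal(0, 1, 6)
        grad = nll_gradient(theta, data)
        eps = 1e-6
        for j in range(6):
            e = np.zeros(6)
            e[j] = eps
            num = (nll(theta + e, data) - nll(theta - e, data)) / (2 * eps)
            assert grad[j] == pytest.approx(num, abs=1e-5 * max(1, abs(num)))

    def test_zero_penalty_reduces_to_gradient(self):
        rng = np.random.default_rng(5)
        data = random_dataset(rng, n=15)
        theta = rng.normal(0, 1, 6)
        assert np.allclose(nll_subgradient(theta, data, 0.0), nll_gradient(theta, data))

    def test_small_subgradient_at_minimizer(self):
        rng = np.random.default_rng(6)
        data = random_dataset(rng, n=200)
        lam = 0.5
        fit = fit_sparse(data, lam)
        sub = nll_subgradient(fit.theta_hat.theta, data, lam)
        assert np.linalg.norm(sub, np.inf) < 1e-3


class TestFitSparse:
    def test_dominant_penalty_zeroes_theta_exactly(self):
        rng = np.random.default_rng(7)
        data = random_dataset(rng, n=100)
        lam = lambda_max(data) * 1.01
        fit = fit_sparse(data, lam)
        assert np.all(fit.theta_hat.theta == 0.0)

    def test_null_generator_yields_near_zero_estimate(self):
        rng = np.random.default_rng(8)
        data = random_dataset(rng, n=400, theta=np.zeros(6))
        fit = fit_sparse(data, 1.0)
        assert np.linalg.norm(fit.theta_hat.theta) < 0.1

    def test_deterministic(self):
        rng = np.random.default_rng(9)
        data = random_dataset(rng, n=100)
        f1 = fit_sparse(data, 0.01)
        f2 = fit_sparse(data, 0.01)
        assert np.array_equal(f1.theta_hat.theta, f2.theta_hat.theta)

    def test_l1_norm_nonincreasing_along_path(self):
        rng = np.random.default_rng(10)
        theta_gen = rng.normal(0, 1, 6)
        data = random_dataset(rng, n=400, theta=theta_gen)
        lams = np.geomspace(1e-4, lambda_max(data), 8)
        norms = [np.abs(fit_sparse(data, lam).theta_hat.theta).sum() for lam in lams]
        # the objective is solved to ~1e-10 but near-flat directions leave
        # the weights determined only to ~1e-3: compare at that tolerance
        for a, b in zip(norms, norms[1:]):
            assert b <= a + 1e-3

    def test_parameter_recovery_from_demonstrations(self, demo_data, theta_true):
        """2e4 simulated demonstration steps identify the 6 generating
        weights to max abs error < 0.1."""
        fit = fit_sparse(demo_data, 1e-4)
        err = np.max(np.abs(fit.theta_hat.theta - theta_true.theta))
        assert err < 0.1

    def test_recovery_error_decreases_with_sample_size(self, rich_mdp, theta_true):
        """Median recovery error over 5 seeds shrinks from N=2e3 to N=2e4."""
        errs = {2000: [], 20000: []}
        for seed in range(5):
            rng = np.random.default_rng(200 + seed)
            _, data = generate_demonstrations(theta_true, rich_mdp, 1, 20000, rng, rate=4.0)
            for n in errs:
                fit = fit_sparse(data.subset(np.arange(n)), 1e-4)
                errs[n].append(np.linalg.norm(fit.theta_hat.theta - theta_true.theta))
        assert np.median(errs[20000]) < np.median(errs[2000])


class TestCrossValidate:
    def test_single_lambda_grid(self):
        rng = np.random.default_rng(11)
        data = random_dataset(rng, n=100)
        cv = cross_validate(data, [0.3], rng=np.random.default_rng(0))
        assert cv.best_lambda == 0.3

    def test_selected_lambda_minimizes_validation_nll(self):
        rng = np.random.default_rng(12)
        theta_gen = rng.normal(0, 1, 6)
        data = random_dataset(rng, n=600, theta=theta_gen)
        cv = cross_validate(data, np.geomspace(1e-4, 1.0, 6), rng=np.random.default_rng(1))
        vals = [f.val_nll for f in cv.path]
        assert cv.best_fit.val_nll == min(vals)

    def test_spurious_features_stay_zero_along_path(self):
        """Features that are identically zero in the data never acquire
        weight at any penalty."""
        rng = np.random.default_rng(13)
        theta_gen = np.array([1.0, -1.0, 0.5, 0.0])
        base = random_dataset(rng, n=500, n_features=4, theta=theta_gen)
        phis = np.concatenate([base.phis, np.zeros((500, 5, 2))], axis=2)
        data = ObservationSet(phis, base.actions, tuple("abcdef"))
        cv = cross_validate(data, np.geomspace(1e-3, 1.0, 6), rng=np.random.default_rng(2))
        for f in cv.path:
            assert np.all(f.theta_hat.theta[4:] == 0.0)

    def test_empty_grid_rejected(self):
        data = random_dataset(np.random.default_rng(14), n=20)
        with pytest.raises(ValueError):
            cross_validate(data, [], rng=np.random.default_rng(0))


class TestObservationSetIO:
    def test_file_roundtrip(self, tmp_path):
        rng = np.random.default_rng(15)
        data = random_dataset(rng, n=12)
        data = ObservationSet(data.phis, data.actions, FEATURE_NAMES)
        path = tmp_path / "obs.csv"
        data.to_file(path)
        back = ObservationSet.from_file(path)
        assert np.allclose(back.phis, data.phis)
        assert np.array_equal(back.actions, data.actions)
        assert back.feature_names == FEATURE_NAMES
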