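"""Obstacle spatial density, optical flow, history and energy features."""

import math

import numpy as np
import pytest

from mothnav.forest_env import Forest
from mothnav.mdp_core import ActionSpace
from mothnav.visual_features import (
    FEATURE_NAMES,
    FeatureScaler,
    energy_feature,
    feature_matrix,
    feature_vector,
    history_feature,
    optical_flow,
    osd,
    osd_threshold,
)

ACTIONS = ActionSpace(2)
SEG_W = math.pi / 10  # 5 segments over the pi/2 field of view


def single_tree_forest(x, y, diameter=0.2):
    return Forest(np.array([[x, y, diameter]]), bounds=(50.0, 50.0))


class TestOsd:
    def test_empty_forest(self):
        forest = Forest(np.empty((0, 3)), bounds=(10.0, 10.0))
        assert np.all(osd(5.0, 5.0, 0.0, forest) == 0.0)

    def test_tree_filling_exactly_one_segment(self):
        """A disc subtending exactly one segment's half-angle dead ahead
        covers the central segment fully and the others not at all."""
        d = 5.0
        r = d * math.sin(SEG_W / 2)
        forest = single_tree_forest(5.0 + d, 5.0, diameter=2 * r)
        cov = osd(5.0, 5.0, 0.0, forest, fog_level=1.0)
        assert cov[2] == pytest.approx(1.0, abs=1e-9)
        assert np.all(cov[[0, 1, 3, 4]] < 1e-9)

    def test_half_covered_segment_analytic(self):
        d = 8.0
        r = d * math.sin(SEG_W / 4)  # subtends half a segment width
        forest = single_tree_forest(5.0 + d, 5.0, diameter=2 * r)
        cov = osd(5.0, 5.0, 0.0, forest, fog_level=1.0)
        assert cov[2] == pytest.approx(0.5, abs=1e-9)

    def test_fog_hides_distant_tree(self):
        forest = single_tree_forest(30.0, 5.0, diameter=1.0)
        near = osd(5.0, 5.0, 0.0, forest, fog_level=1.0)  # range 133 m
        far = osd(5.0, 5.0, 0.0, forest, fog_level=10.0)  # range 13 m
        assert near.sum() > 0
        assert np.all(far == 0.0)

    def test_angular_resolution_discards_slivers(self):
        forest = single_tree_forest(25.0, 5.0, diameter=0.02)  # ~1e-3 rad
        cov = osd(5.0, 5.0, 0.0, forest, fog_level=1.0, angular_resolution=0.01)
        assert np.all(cov == 0.0)
        cov2 = osd(5.0, 5.0, 0.0, forest, fog_level=1.0, angular_resolution=1e-5)
        assert cov2.sum() > 0

    def test_rotation_equivariance(self):
        """Rotating trees and heading together leaves the coverage unchanged."""
        rng = np.random.default_rng(11)
        base = rng.uniform(-6, 6, (6, 2))
        sizes = rng.uniform(0.2, 0.8, 6)
        for ang in rng.uniform(0, 2 * math.pi, 5):
            c, s = math.cos(ang), math.sin(ang)
            rot = base @ np.array([[c, -s], [s, c]]).T
            f0 = Forest(np.column_stack([base + 20, sizes]), bounds=(40.0, 40.0))
            f1 = Forest(np.column_stack([rot + 20, sizes]), bounds=(40.0, 40.0))
            cov0 = osd(20.0, 20.0, 0.3, f0, fog_level=1.0)
            cov1 = osd(20.0, 20.0, 0.3 + ang, f1, fog_level=1.0)
            assert np.allclose(cov0, cov1, atol=1e-9)

    def test_overlapping_trees_union_not_double_counted(self):
        d = 5.0
        r = d * math.sin(SEG_W / 2)
        tree = [5.0 + d, 5.0, 2 * r]
        one = Forest(np.array([tree]), bounds=(50.0, 50.0))
        two = Forest(np.array([tree, tree]), bounds=(50.0, 50.0))
        assert np.allclose(
            osd(5.0, 5.0, 0.0, one, fog_level=1.0),
            osd(5.0, 5.0, 0.0, two, fog_level=1.0),
        )

    def test_union_bound(self):
        """Total covered angle never exceeds the sum of subtended widths."""
        rng = np.random.default_rng(4)
        pts = rng.uniform(2, 18, (8, 2))
        sizes = rng.uniform(0.3, 1.0, 8)
        forest = Forest(np.column_stack([pts, sizes]), bounds=(20.0, 20.0))
        cov = osd(10.0, 10.0, 1.0, forest, fog_level=1.0)
        covered = cov.sum() * SEG_W
        d = np.hypot(pts[:, 0] - 10, pts[:, 1] - 10)
        subtended = 2 * np.arcsin(np.clip(sizes / 2 / d, 0, 1)).sum()
        assert covered <= subtended + 1e-9


class TestThreshold:
    def test_strictly_greater(self):
        assert osd_threshold(np.array([0.6]), 0.5) == 1.0
        assert osd_threshold(np.array([0.0]), 0.0) == 0.0
        assert osd_threshold(np.array([0.3]), 0.0) == 1.0
        assert osd_threshold(np.array([0.5]), 0.5) == 0.0

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        cov = rng.uniform(0, 1, 100)
        assert np.all(osd_threshold(cov, 0.5) <= osd_threshold(cov, 0.0))


class TestOpticalFlow:
    def test_static_scene_has_no_flow(self):
        f = np.array([0.1, 0.4, 0.9, 0.2, 0.0])
        assert np.all(optical_flow(f, f) == 0.0)

    def test_unit_shift_of_ramp(self):
        f_prev = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        f_curr = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        assert np.allclose(optical_flow(f_prev, f_curr), 1.0)

    def test_constant_signal_guard(self):
        f_prev = np.full(5, 0.3)
        f_curr = np.full(5, 0.9)
        assert np.all(optical_flow(f_prev, f_curr) == 0.0)

    @pytest.mark.parametrize("shift", [-2, -1, 1, 2])
    def test_exact_shift_recovery_on_affine_signals(self, shift):
        """For strictly monotone affine signals the discrete estimator
        recovers an integer translation exactly."""
        rng = np.random.default_rng(shift + 10)
        slope = rng.uniform(0.5, 3.0) * (1 if shift % 2 else -1)
        u = np.arange(9, dtype=float)
        f_prev = slope * u + rng.uniform(-1, 1)
        f_curr = slope * (u - shift) + (f_prev[0] - slope * u[0])
        s = optical_flow(f_prev, f_curr)
        assert np.allclose(s, shift, atol=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            optical_flow(np.zeros(5), np.zeros(4))


class TestScalarFeatures:
    def test_history_examples(self):
        assert history_feature([ACTIONS.straight], ACTIONS) == 0.0
        assert history_feature([3, 1], ACTIONS) == pytest.approx(0.0)  # +/- pi/8
        assert history_feature([4, 4, 2], ACTIONS) == pytest.approx(math.pi / 6)

    def test_history_empty_rejected(self):
        with pytest.raises(ValueError):
            history_feature([], ACTIONS)

    def test_energy_zero_for_straight_and_symmetric(self):
        assert energy_feature(ACTIONS.straight, ACTIONS) == 0.0
        for j in range(ACTIONS.n_actions):
            mirror = ACTIONS.n_actions - 1 - j
            assert energy_feature(j, ACTIONS) == pytest.approx(
                energy_feature(mirror, ACTIONS)
            )
        assert energy_feature(0, ACTIONS) == pytest.approx(math.pi / 4)


class TestFeatureMatrix:
    def test_empty_forest_straight_action_all_zero(self):
        cov = np.zeros(5)
        row = feature_vector(cov, None, [ACTIONS.straight], ACTIONS.straight, ACTIONS)
        assert np.all(row == 0.0)

    def test_vector_length_matches_schema(self):
        phi = feature_matrix(np.zeros(5), None, [2], ACTIONS)
        assert phi.shape == (5, len(FEATURE_NAMES))

    def test_columns_wired_to_the_right_features(self):
        cov = np.array([0.0, 0.2, 0.7, 0.0, 1.0])
        prev = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        phi = feature_matrix(cov, prev, [4], ACTIONS)
        assert np.allclose(phi[:, 0], cov)
        assert np.allclose(phi[:, 1], [0, 1, 1, 0, 1])
        assert np.allclose(phi[:, 2], [0, 0, 1, 0, 1])
        assert np.allclose(phi[:, 3], optical_flow(prev, cov))
        # history column: deviation of each candidate offset from the mean
        # recent offset (here the last action was the extreme left, +pi/4)
        assert np.allclose(phi[:, 4], np.abs(ACTIONS.offsets - math.pi / 4))
        assert np.allclose(phi[:, 5], np.abs(ACTIONS.offsets))


class TestFeatureScaler:
    def test_roundtrip_and_standardization(self):
        rng = np.random.default_rng(8)
        X = rng.normal(2.0, 3.0, (500, 6))
        X[:, 4] = 1.0  # constant column keeps scale 1
        scaler = FeatureScaler().fit(X)
        Z = scaler.transform(X)
        assert np.allclose(Z.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(Z[:, :4].std(axis=0), 1.0, atol=1e-12)
        assert np.allclose(scaler.inverse_transform(Z), X, atol=1e-12)
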