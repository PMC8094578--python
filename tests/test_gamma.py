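"""Geometry and algebra of the class-separability (gamma) score."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import gammafs as g
from gammafs.gamma import ellipsoid_from_moments

from _naive import naive_gamma
from conftest import random_instance, two_point_class


class TestFitClassEllipsoid:
    def test_zero_variance_class(self):
        e = g.fit_class_ellipsoid(np.tile([3.0, 7.0], (5, 1)))
        assert np.allclose(e.center, [3.0, 7.0])
        assert np.allclose(e.eigenvalues, 0.0)

    def test_two_points_sample_denominator(self):
        # n-1 denominator: var of {0, 2} is 2
        e = g.fit_class_ellipsoid(np.array([[0.0, 0.0], [2.0, 0.0]]))
        assert np.allclose(e.center, [1.0, 0.0])
        assert np.allclose(sorted(e.eigenvalues, reverse=True), [2.0, 0.0])

    def test_eigenvalues_of_anisotropic_covariance(self, rng):
        # color a whitened sample so its sample covariance is exactly Sigma;
        # expected eigenvalues from the 2x2 quadratic formula
        sigma = np.array([[0.3, 0.1], [0.1, 0.9]])
        Z = rng.normal(size=(200, 2))
        Z -= Z.mean(axis=0)
        Z = Z @ np.linalg.inv(np.linalg.cholesky(np.cov(Z, rowvar=False)).T)
        X = Z @ np.linalg.cholesky(sigma).T
        e = g.fit_class_ellipsoid(X)
        tr, det = 1.2, 0.3 * 0.9 - 0.1 * 0.1
        disc = np.sqrt(tr ** 2 - 4 * det)
        expected = [(tr + disc) / 2, (tr - disc) / 2]
        assert np.allclose(e.eigenvalues, expected, atol=1e-10)
        assert np.allclose(e.covariance(), sigma, atol=1e-8)
        assert np.allclose(e.basis.T @ e.basis, np.eye(2), atol=1e-10)

    def test_errors(self):
        with pytest.raises(g.DegenerateClassError):
            g.fit_class_ellipsoid(np.array([[1.0, 2.0]]))
        with pytest.raises(g.ValidationError):
            g.fit_class_ellipsoid(np.array([[1.0, np.nan], [0.0, 1.0]]))


class TestBorderDistance:
    def test_one_dimensional_is_sd(self):
        e = ellipsoid_from_moments([0.0], [[2.25]])
        assert g.border_distance(e, [1.0]) == pytest.approx(1.5, abs=1e-12)

    def test_spherical_isotropy(self, rng):
        e = ellipsoid_from_moments(np.zeros(3), 0.49 * np.eye(3))
        for _ in range(5):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            assert g.border_distance(e, u) == pytest.approx(0.7, abs=1e-10)

    def test_axis_aligned(self):
        e = ellipsoid_from_moments([0.0, 0.0], np.diag([4.0, 1.0]))
        assert g.border_distance(e, [1.0, 0.0]) == pytest.approx(2.0, abs=1e-12)

    def test_zero_eigenvalue_limits(self):
        # no extent along the direction -> border 0; 0/0 direction skipped
        e = ellipsoid_from_moments([0.0, 0.0], np.diag([4.0, 0.0]))
        assert g.border_distance(e, [0.0, 1.0]) == 0.0
        assert g.border_distance(e, [1.0, 0.0]) == pytest.approx(2.0)

    def test_rejects_non_unit_direction(self):
        e = ellipsoid_from_moments([0.0], [[1.0]])
        with pytest.raises(g.ValidationError):
            g.border_distance(e, [0.0])
        with pytest.raises(g.ValidationError):
            g.border_distance(e, [2.0])


class TestPairwiseSeparation:
    def test_reference_scenarios_signs(self):
        # population ellipsoids from the printed parameter sets
        for which, sign in (("a", 1.0), ("b", -1.0)):
            spec = g.figure2_scenario(which)
            val = g.population_gamma(spec)
            assert np.sign(val) == sign

    def test_one_dimensional_closed_form(self):
        e1 = ellipsoid_from_moments([0.0], [[1.0]])
        e2 = ellipsoid_from_moments([10.0], [[1.0]])
        sep = g.pairwise_separation(e1, e2)
        assert sep.distance == pytest.approx(4.0, abs=1e-12)
        assert sep.alpha == pytest.approx(2.0)
        assert sep.border_1 == sep.border_2 == pytest.approx(1.0)

    def test_point_masses_raise(self):
        e = ellipsoid_from_moments([0.0, 0.0], np.zeros((2, 2)))
        e2 = ellipsoid_from_moments([1.0, 1.0], np.zeros((2, 2)))
        with pytest.raises(g.DegenerateGeometryError):
            g.pairwise_separation(e, e2)

    def test_coincident_centers_negative(self):
        e = ellipsoid_from_moments([1.0, 2.0], np.diag([1.0, 0.5]))
        sep = g.pairwise_separation(e, e)
        assert sep.distance < 0
        assert sep.mean_gap == 0.0


class TestGammaMetric:
    def test_two_classes_equals_single_pair(self, rng):
        X, y = random_instance(rng)
        res = g.gamma_metric(X, y)
        assert res.gamma == pytest.approx(
            res.pairwise[(0, 1)].distance, abs=1e-15)

    def test_three_class_one_dim_sum(self):
        X = np.vstack([two_point_class(0.0, 1.0),
                       two_point_class(10.0, 1.0),
                       two_point_class(20.0, 1.0)])
        y = np.repeat([0, 1, 2], 2)
        res = g.gamma_metric(X, y)
        # pairs: (0,10): 4, (10,20): 4, (0,20): 9
        assert res.gamma == pytest.approx(17.0, abs=1e-9)
        assert res.gamma == pytest.approx(
            sum(s.distance for s in res.pairwise.values()), abs=1e-12)

    def test_identical_classes_negative(self, rng):
        pts = rng.normal(size=(30, 2))
        X = np.vstack([pts, pts])
        y = np.repeat([0, 1], 30)
        assert g.gamma_metric(X, y).gamma < 0

    def test_subset_selection_and_errors(self, rng):
        X, y = random_instance(rng, p=3)
        df = pd.DataFrame(X, columns=["a", "b", "c"])
        full = g.gamma_metric(df, y)
        sub = g.gamma_metric(df, y, subset=["a"])
        assert sub.ellipsoids[0].dim == 1
        assert full.gamma != sub.gamma
        with pytest.raises(g.ValidationError):
            g.gamma_metric(df, y, subset=["nope"])
        with pytest.raises(g.ValidationError):
            g.gamma_metric(df, y, subset=[])
        with pytest.raises(g.DegenerateClassError):
            g.gamma_metric(df, np.r_[0, np.ones(len(df) - 1)])

    @settings(max_examples=60, derandomize=True)
    @given(m1=st.floats(-50, 50), m2=st.floats(-50, 50),
           s1=st.floats(0.01, 10), s2=st.floats(0.01, 10))
    def test_one_dimensional_oracle(self, m1, m2, s1, s2):
        X = np.vstack([two_point_class(m1, s1), two_point_class(m2, s2)])
        y = np.repeat([0, 1], 2)
        got = g.gamma_metric(X, y).gamma
        expected = (abs(m2 - m1) - (s1 + s2)) / (s1 + s2)
        assert got == pytest.approx(expected, abs=1e-9)

    def test_rigid_motion_and_scale_invariance(self, rng):
        for _ in range(25):
            X, y = random_instance(rng, n_per_class=30)
            base = g.gamma_metric(X, y).gamma
            theta = rng.uniform(0, 2 * np.pi)
            R = np.array([[np.cos(theta), -np.sin(theta)],
                          [np.sin(theta), np.cos(theta)]])
            shifted = (X + rng.normal(size=2)) @ R.T
            assert abs(g.gamma_metric(shifted, y).gamma - base) < 1e-8
            c = rng.uniform(0.1, 100.0)
            assert abs(g.gamma_metric(c * X, y).gamma - base) < 1e-8

    def test_label_permutation_symmetry(self, rng):
        X, y = random_instance(rng, k=3)
        assert g.gamma_metric(X, y).gamma == pytest.approx(
            g.gamma_metric(X, 2 - y).gamma, abs=1e-12)

    def test_translation_monotonicity(self, rng):
        # moving one centre out along the mean-mean axis increases separation
        X, y = random_instance(rng)
        axis = X[y == 1].mean(axis=0) - X[y == 0].mean(axis=0)
        axis /= np.linalg.norm(axis)
        vals = []
        for shift in (0.0, 1.0, 2.0, 5.0):
            X2 = X.copy()
            X2[y == 1] += shift * axis
            vals.append(g.gamma_metric(X2, y).gamma)
        assert np.all(np.diff(vals) > 0)

    def test_matches_naive_transcription(self, rng):
        for _ in range(50):
            X, y = random_instance(rng)
            assert g.gamma_metric(X, y).gamma == pytest.approx(
                naive_gamma(X, y), abs=1e-10)
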