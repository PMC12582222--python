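"""Expansion-model geometry: scale factors, cloud scaling, closed forms."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hvctrack import expansion_model as em


class TestScaleFactor:
    @pytest.mark.parametrize(
        "p, expected",
        [
            (0.0, 1.0),
            (100.0, 2.0 ** (1.0 / 3.0)),
            (90.0, np.exp(np.log(1.9) / 3.0)),
        ],
    )
    def test_values(self, p, expected):
        assert em.scale_factor(p) == pytest.approx(expected, rel=1e-12)

    @given(st.floats(min_value=-99.0, max_value=500.0), st.floats(min_value=1e-6, max_value=10.0))
    def test_strictly_increasing(self, p, dp):
        assert em.scale_factor(p + dp) > em.scale_factor(p)

    def test_rejects_negative_volume(self):
        with pytest.raises(em.DomainError):
            em.scale_factor(-100.0)
        with pytest.raises(em.DomainError):
            em.scale_factor(-150.0)


def test_cube_volume_anchor():
    assert em.cube_volume_mm3(500.0) == 0.125


class TestExpandCloud:
    def test_identity_at_zero(self, uniform_cloud):
        spec = em.ExpansionSpec(p=0.0)
        out = em.expand_cloud(uniform_cloud, spec)
        np.testing.assert_array_equal(out.xyz, uniform_cloud.xyz)
        assert out.ids == uniform_cloud.ids

    def test_center_is_fixed_point(self):
        cloud = em.PointCloud(ids=("c",), xyz=np.zeros((1, 3)), side=500.0)
        out = em.expand_cloud(cloud, em.ExpansionSpec(p=75.0))
        np.testing.assert_allclose(out.xyz, 0.0)

    def test_radial_scaling(self):
        # a point 100 µm from the center moves to 100·2^(1/3) under p=100
        cloud = em.PointCloud(ids=("p",), xyz=np.array([[100.0, 0.0, 0.0]]), side=500.0)
        out = em.expand_cloud(cloud, em.ExpansionSpec(p=100.0))
        assert np.linalg.norm(out.xyz) == pytest.approx(100.0 * 2 ** (1 / 3), rel=1e-12)

    def test_unknown_center_mode_rejected(self):
        with pytest.raises(ValueError, match="center_mode"):
            em.ExpansionSpec(p=10.0, center_mode="barycenter")

    def test_shrink_needs_flag(self):
        with pytest.raises(em.DomainError):
            em.ExpansionSpec(p=-10.0)
        assert em.ExpansionSpec(p=-10.0, allow_shrink=True).scale < 1.0


class TestDisplacements:
    def test_identical_clouds_zero(self, uniform_cloud):
        disp = em.per_point_displacements(uniform_cloud, uniform_cloud)
        np.testing.assert_array_equal(disp, 0.0)

    def test_3_4_5_triangle(self):
        a = em.PointCloud(ids=("x",), xyz=np.zeros((1, 3)), side=10.0)
        b = em.PointCloud(ids=("x",), xyz=np.array([[3.0, 4.0, 0.0]]), side=10.0)
        assert em.per_point_displacements(a, b)[0] == pytest.approx(5.0)

    def test_mismatched_ids_listed(self, tiny_cloud):
        other = em.PointCloud(ids=("a", "b", "d"), xyz=tiny_cloud.xyz, side=10.0)
        with pytest.raises(em.PairingError, match="d"):
            em.per_point_displacements(tiny_cloud, other)

    def test_uniform_cloud_mean_matches_closed_form(self, uniform_cloud):
        spec = em.ExpansionSpec(p=50.0)
        disp = em.per_point_displacements(uniform_cloud, em.expand_cloud(uniform_cloud, spec))
        cf_mean, cf_sd = em.closed_form_displacement(50.0, 500.0)
        assert cf_mean == pytest.approx(34.75, abs=0.01)
        # single realisation of 100 points: within 3 SE of the analytic mean
        assert disp.mean() == pytest.approx(cf_mean, abs=3 * cf_sd / 10)

    def test_translation_equivariance(self, uniform_cloud):
        """Scaling about the (tracked) cube center commutes with translation."""
        spec = em.ExpansionSpec(p=30.0)
        disp0 = em.per_point_displacements(uniform_cloud, em.expand_cloud(uniform_cloud, spec))
        shifted = em.PointCloud(
            ids=uniform_cloud.ids, xyz=uniform_cloud.xyz + [10.0, -20.0, 5.0],
            side=500.0, center=(10.0, -20.0, 5.0),
        )
        disp1 = em.per_point_displacements(shifted, em.expand_cloud(shifted, spec))
        np.testing.assert_allclose(np.sort(disp0), np.sort(disp1), rtol=1e-9)


class TestPairwiseDelta:
    def test_zero_at_p0(self, uniform_cloud):
        dd = em.pairwise_delta(uniform_cloud, em.expand_cloud(uniform_cloud, em.ExpansionSpec(p=0.0)))
        np.testing.assert_array_equal(dd.deltas, 0.0)
        assert dd.n_pairs == 100 * 99 // 2

    def test_two_points(self):
        a = em.PointCloud(ids=("u", "v"), xyz=np.array([[0.0, 0, 0], [100.0, 0, 0]]), side=500.0)
        dd = em.pairwise_delta(a, em.expand_cloud(a, em.ExpansionSpec(p=100.0)))
        assert dd.deltas[0] == pytest.approx(100.0 * (2 ** (1 / 3) - 1), rel=1e-12)

    @pytest.mark.parametrize("mode", ["origin_corner", "centroid"])
    def test_center_mode_invariance(self, uniform_cloud, mode):
        """Pairwise deltas do not depend on where the scaling is anchored."""
        ref = em.pairwise_delta(
            uniform_cloud, em.expand_cloud(uniform_cloud, em.ExpansionSpec(p=37.0))
        )
        alt = em.pairwise_delta(
            uniform_cloud,
            em.expand_cloud(uniform_cloud, em.ExpansionSpec(p=37.0, center_mode=mode)),
        )
        np.testing.assert_allclose(np.sort(ref.deltas), np.sort(alt.deltas), rtol=1e-9)

    def test_all_positive_under_expansion(self, uniform_cloud):
        dd = em.pairwise_delta(uniform_cloud, em.expand_cloud(uniform_cloud, em.ExpansionSpec(p=5.0)))
        assert np.all(dd.deltas > 0)

    def test_insufficient_points(self):
        single = em.PointCloud(ids=("a",), xyz=np.zeros((1, 3)), side=10.0)
        with pytest.raises(em.PairingError):
            em.pairwise_delta(single, single)


class TestSimulateExpansion:
    def test_zero_expansion_exact(self):
        sim = em.simulate_expansion(0.0, n_points=10, n_reps=3, seed=0)
        assert sim["per_point_displacement"].mean == 0.0
        assert sim["per_point_displacement"].sd == 0.0

    def test_reproducible(self):
        a = em.simulate_expansion(5.0, n_points=20, n_reps=5, seed=42)
        b = em.simulate_expansion(5.0, n_points=20, n_reps=5, seed=42)
        assert a["pairwise_delta"].mean == b["pairwise_delta"].mean

    @pytest.mark.parametrize("p", [2.0, 10.0, 100.0])
    def test_converges_to_closed_forms(self, p):
        """Monte Carlo means agree with the analytic oracles (3 SE)."""
        reps = 200
        sim = em.simulate_expansion(p, n_points=50, side=500.0, n_reps=reps, seed=7)
        cf_mean, cf_sd = em.closed_form_displacement(p, 500.0)
        se = cf_sd / np.sqrt(sim["per_point_displacement"].n)
        assert abs(sim["per_point_displacement"].mean - cf_mean) < 3 * se
        # pairwise deltas within a replicate are correlated: use a
        # conservative per-replicate SE for the pooled pairwise mean
        cf_pair = em.closed_form_pairwise_delta(p, 500.0)
        se_pair = sim["pairwise_delta"].sd / np.sqrt(reps * 50)
        assert abs(sim["pairwise_delta"].mean - cf_pair) < 3 * se_pair

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            em.simulate_expansion(5.0, n_points=1)
        with pytest.raises(ValueError):
            em.simulate_expansion(5.0, n_reps=0)


class TestEstimateExpansion:
    def test_zero_deltas(self, uniform_cloud):
        dd = em.pairwise_delta(uniform_cloud, uniform_cloud)
        assert em.estimate_expansion(dd) == pytest.approx(0.0, abs=1e-12)

    def test_exact_inversion(self, uniform_cloud):
        for p in (7.0, 20.0, 33.1):
            dd = em.pairwise_delta(
                uniform_cloud, em.expand_cloud(uniform_cloud, em.ExpansionSpec(p=p))
            )
            assert em.estimate_expansion(dd) == pytest.approx(p, rel=1e-9)

    def test_linear_scale_1_1(self):
        # s = 1.1 corresponds to p = (1.1³ − 1)·100 = 33.1%
        xyz = np.array([[0.0, 0, 0], [10.0, 0, 0], [0, 20.0, 0]])
        a = em.PointCloud(ids=("a", "b", "c"), xyz=xyz, side=100.0)
        b = em.PointCloud(ids=("a", "b", "c"), xyz=xyz * 1.1, side=100.0)
        assert em.estimate_expansion(em.pairwise_delta(a, b)) == pytest.approx(33.1, rel=1e-9)

    def test_degenerate_geometry(self):
        with pytest.raises(em.DomainError):
            em.estimate_expansion(np.array([0.0, 0.0]), np.array([0.0, 0.0]))


def test_closed_form_values():
    mean, sd = em.closed_form_displacement(50.0, 500.0)
    assert (mean, sd) == (pytest.approx(34.75, abs=0.01), pytest.approx(10.06, abs=0.01))
    mean90, sd90 = em.closed_form_displacement(90.0, 500.0)
    assert (mean90, sd90) == (pytest.approx(57.3, abs=0.05), pytest.approx(16.6, abs=0.05))
    assert em.closed_form_displacement(0.0) == (0.0, 0.0)
    assert em.closed_form_pairwise_delta(5.0, 500.0) == pytest.approx(5.42, abs=0.01)
    assert em.closed_form_pairwise_delta(100.0, 500.0) == pytest.approx(86.0, abs=0.05)
    assert em.closed_form_pairwise_delta(0.0) == 0.0
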