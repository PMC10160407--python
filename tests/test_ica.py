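"""Whitening, angular metrics, gradients, and the search procedures."""

import numpy as np
import pytest
from sklearn.decomposition import FastICA

from hermica import distributions as dist
from hermica.contrasts import ContrastSpec
from hermica.ica import (
    PrecisionProfile,
    aggregate_profiles,
    angular_variance,
    axial_circular_variance,
    cross_contrast_select,
    deflation_search,
    error_angle,
    exhaustive_search_2d,
    j_gradient,
    order_study_search,
    precision_from_profile,
    project_and_score,
    whiten,
)

J15 = ContrastSpec("j_n", n=15)


class TestWhitening:
    def test_identity_covariance_and_round_trip(self, rng):
        x = rng.standard_normal((5_000, 4)) @ rng.standard_normal((4, 4))
        z, wh = whiten(x)
        cov = z.T @ z / z.shape[0]
        np.testing.assert_allclose(cov, np.eye(4), atol=1e-8)
        np.testing.assert_allclose(wh.inverse(z), x, atol=1e-10)

    def test_rank_deficiency_reduces_dimension(self, rng):
        x = rng.standard_normal((1_000, 2))
        x3 = np.column_stack([x, x[:, 0] + x[:, 1]])
        with pytest.warns(UserWarning, match="rank"):
            z, _ = whiten(x3)
        assert z.shape[1] == 2

    def test_mapped_direction_is_unit(self, rng):
        x = rng.standard_normal((2_000, 3)) * np.array([1.0, 3.0, 0.5])
        _, wh = whiten(x)
        v = wh.map_direction(np.array([1.0, 1.0, 1.0]))
        assert np.linalg.norm(v) == pytest.approx(1.0, abs=1e-12)


class TestAngularMetrics:
    def test_error_angle_basics(self):
        u = np.array([1.0, 0.0])
        assert error_angle(u, u) == pytest.approx(0.0)
        assert error_angle(u, -u) == pytest.approx(0.0)
        assert error_angle(u, np.array([0.0, 1.0])) == pytest.approx(90.0)

    def test_error_angle_dimension_mismatch(self):
        with pytest.raises(ValueError):
            error_angle(np.ones(2), np.ones(3))

    def test_angular_variance_identical_and_flipped(self):
        u = np.array([0.6, 0.8])
        assert angular_variance([u, u, u], u) == pytest.approx(0.0)
        assert angular_variance([u, -u], u) == pytest.approx(0.0)

    def test_angular_variance_orthogonal_pair(self):
        members = [np.array([1.0, 0.0]), np.array([0.0, 1.0])]
        assert angular_variance(members, np.array([1.0, 0.0])) == pytest.approx(
            1 - np.sqrt(2) / 2, abs=1e-12
        )

    def test_angular_variance_rejects_zero_member(self):
        with pytest.raises(ValueError):
            angular_variance([np.zeros(2)], np.array([1.0, 0.0]))

    def test_axial_circular_variance_limits(self):
        assert axial_circular_variance([12.0] * 10) == pytest.approx(0.0)
        # estimates scattered uniformly over the half circle
        assert axial_circular_variance(np.linspace(-90, 89, 180)) == pytest.approx(
            1.0, abs=0.02
        )


class TestProjectionScoring:
    def test_true_axis_scores_above_orthogonal(self):
        spec = dist.gaussian_mixture(0.5, -2, 1, 2, 1)
        wins = 0
        for s in range(20):
            ds = dist.make_product_dataset(spec, d=2, n=10_000, seed=s)
            s_true = project_and_score(ds.data, np.array([1.0, 0.0]), J15)
            s_orth = project_and_score(ds.data, np.array([0.0, 1.0]), J15)
            wins += s_true > s_orth
        assert wins >= 19

    def test_sign_flip_invariance(self, rng):
        x = rng.standard_normal((3_000, 2)) ** 3
        u = np.array([0.6, 0.8])
        assert project_and_score(x, u, J15) == pytest.approx(
            project_and_score(x, -u, J15), abs=1e-12
        )

    def test_isotropic_gaussian_is_flat(self, rng):
        x = rng.standard_normal((20_000, 2))
        angles = np.arange(0, 180, 5)
        scores = np.array(
            [
                project_and_score(
                    x, np.array([np.cos(np.radians(a)), np.sin(np.radians(a))]), J15
                )
                for a in angles
            ]
        )
        # no direction stands out from the rest
        for i in range(len(scores)):
            others = np.delete(scores, i)
            assert scores[i] <= others.mean() + 4 * others.std()

    def test_non_unit_direction_rejected(self, rng):
        with pytest.raises(ValueError):
            project_and_score(rng.standard_normal((100, 2)), np.array([1.0, 1.0]), J15)


class TestJGradient:
    def test_matches_central_differences(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal((400, 4))
        x[:, 0] = rng.laplace(size=400)
        for trial in range(5):
            u = rng.standard_normal(4)
            u /= np.linalg.norm(u)
            _, g = j_gradient(x, u, 15)
            eps = 1e-5
            num = np.empty(4)
            for i in range(4):
                up, um = u.copy(), u.copy()
                up[i] += eps
                um[i] -= eps
                num[i] = (j_gradient(x, up, 15)[0] - j_gradient(x, um, 15)[0]) / (
                    2 * eps
                )
            assert np.abs(g - num).max() / np.abs(num).max() < 1e-4


class TestExhaustiveSearch2D:
    def test_recovers_bimodal_axis(self):
        ds = dist.make_product_dataset(
            dist.gaussian_mixture(0.5, -2, 1, 2, 1), d=2, n=10_000, seed=4
        )
        est, angles, scores = exhaustive_search_2d(ds.data, J15)
        assert error_angle(est.direction, ds.true_direction) <= 1.0
        assert angles.size == 180

    def test_rotation_equivariance(self):
        ds = dist.make_product_dataset(
            dist.gaussian_mixture(0.5, -2, 1, 2, 1), d=2, n=10_000, seed=4
        )
        theta = np.radians(30.0)
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        est, _, _ = exhaustive_search_2d(ds.data, J15)
        est_rot, _, _ = exhaustive_search_2d(ds.data @ rot.T, J15)
        assert error_angle(est_rot.direction, rot @ est.direction) <= 0.2

    def test_fine_grid_resolution(self):
        ds = dist.make_product_dataset(
            dist.generalized_normal(1.0), d=2, n=5_000, seed=5
        )
        est, _, _ = exhaustive_search_2d(ds.data, J15)
        angle = np.degrees(np.arctan2(est.direction[1], est.direction[0])) % 180
        assert (angle * 10) == pytest.approx(round(angle * 10), abs=1e-6)

    def test_requires_two_columns(self, rng):
        with pytest.raises(ValueError):
            exhaustive_search_2d(rng.standard_normal((100, 3)), J15)


class TestOrderStudySearch:
    def test_odd_variant_blind_to_symmetric_family(self):
        ds = dist.make_product_dataset(
            dist.gaussian_mixture(0.5, -2, 1, 2, 1), d=2, n=5_000, seed=6
        )
        res = order_study_search(ds.data, 0.0, n_values=(5, 15), variants=("all", "odd"))
        best_all = res.query("variant == 'all' and n == 15")["error_deg"].iloc[0]
        assert best_all <= 2.0
        # odd orders carry no signal for a symmetric source: argmax is noise
        assert res.query("variant == 'odd'")["score"].max() < 0.05


class TestDeflation:
    @pytest.fixture(scope="class")
    def heavy_5d(self):
        ds = dist.make_product_dataset(
            dist.generalized_normal(1.0), d=5, n=8_000, rotate=True, seed=8
        )
        z, wh = whiten(ds.data)
        return ds, z, wh

    def test_components_mutually_orthogonal(self, heavy_5d):
        _, z, _ = heavy_5d
        ests = deflation_search(
            z, ContrastSpec("fastica_ii"), n_components=3, restarts=4, seed=0
        )
        dirs = np.array([e.direction for e in ests])
        np.testing.assert_allclose(dirs @ dirs.T, np.eye(3), atol=1e-8)

    @pytest.mark.parametrize("name", ["j_n", "fastica_i", "fastica_ii", "fastica_iii"])
    def test_recovers_heavy_tailed_direction(self, heavy_5d, name):
        ds, z, wh = heavy_5d
        u_true = wh.map_direction(ds.true_direction)
        est = deflation_search(
            z, ContrastSpec(name), n_components=1, restarts=6, seed=1, max_iter=200
        )[0]
        assert error_angle(est.direction, u_true) < 10.0

    def test_contrast_value_consistent_with_direction(self, heavy_5d):
        _, z, _ = heavy_5d
        est = deflation_search(z, J15, n_components=1, restarts=3, seed=2, max_iter=200)[0]
        assert est.contrast_value == pytest.approx(
            project_and_score(z, est.direction, J15), abs=1e-12
        )
        assert np.linalg.norm(est.direction) == pytest.approx(1.0, abs=1e-10)

    def test_gaussian_control_no_confident_component(self, rng):
        """With no non-Gaussian axis, restarts land on equivalent noise optima."""
        x = rng.standard_normal((20_000, 5))
        z, _ = whiten(x)
        values = []
        for r in range(6):
            est = deflation_search(
                z, J15, n_components=1, restarts=1, seed=100 + r, max_iter=150
            )[0]
            values.append(est.contrast_value)
        assert np.ptp(values) < 0.05

    def test_sklearn_fastica_agrees_on_recovery(self, heavy_5d):
        """Independent route: sklearn's deflation FastICA finds the same source."""
        ds, z, wh = heavy_5d
        u_true = wh.map_direction(ds.true_direction)
        ours = deflation_search(
            z, ContrastSpec("fastica_i"), n_components=1, restarts=6, seed=3
        )[0]
        ica = FastICA(
            n_components=5, algorithm="deflation", fun="cube", random_state=0,
            whiten="unit-variance",
        )
        sources = ica.fit_transform(ds.data)
        true_sig = ds.data @ ds.true_direction
        corrs = [abs(np.corrcoef(sources[:, k], true_sig)[0, 1]) for k in range(5)]
        assert max(corrs) > 0.95  # sklearn recovers the source
        assert error_angle(ours.direction, u_true) < 5.0  # and so do we


class TestCrossContrastSelect:
    def test_single_candidate_unchanged(self, rng):
        x = rng.standard_normal((2_000, 3))
        z, _ = whiten(x)
        u = np.zeros(3)
        u[0] = 1.0
        from hermica.ica import UnmixingEstimate

        cand = UnmixingEstimate(u, "J_15", 0.0)
        out = cross_contrast_select(z, [cand], J15)
        np.testing.assert_array_equal(out.direction, u)

    def test_selection_never_worse_than_own_best(self):
        ds = dist.make_product_dataset(
            dist.generalized_normal(1.0), d=5, n=5_000, rotate=True, seed=9
        )
        z, _ = whiten(ds.data)
        own = deflation_search(z, J15, n_components=1, restarts=2, seed=4, max_iter=150)[0]
        other = deflation_search(
            z, ContrastSpec("fastica_ii"), n_components=1, restarts=4, seed=5
        )[0]
        sel = cross_contrast_select(z, [own, other], J15)
        assert sel.contrast_value >= own.contrast_value - 1e-12

    def test_empty_candidates_rejected(self, rng):
        with pytest.raises(ValueError):
            cross_contrast_select(rng.standard_normal((50, 2)), [], J15)


class TestPrecisionProfiles:
    def _bump_profile(self, width, sd):
        angles = np.arange(0.0, 180.0, 1.0)
        delta = np.minimum(np.abs(angles - 90.0), 180 - np.abs(angles - 90.0))
        mean = np.exp(-0.5 * (delta / width) ** 2)
        return PrecisionProfile(angles, mean, np.full_like(mean, sd), n_replicates=10)

    def test_half_width_tracks_bump_scale(self):
        narrow = precision_from_profile(self._bump_profile(3.0, 0.05))
        wide = precision_from_profile(self._bump_profile(12.0, 0.05))
        assert narrow.separated and wide.separated
        assert narrow.half_width_deg < wide.half_width_deg
        assert narrow.half_width_deg <= 4.0

    def test_flat_profile_flagged(self):
        angles = np.arange(0.0, 180.0, 1.0)
        prof = PrecisionProfile(angles, np.ones_like(angles), np.ones_like(angles), 5)
        res = precision_from_profile(prof)
        assert not res.separated
        assert res.half_width_deg == pytest.approx(90.0)

    def test_shrinking_sd_never_widens(self):
        wide_sd = precision_from_profile(self._bump_profile(5.0, 0.05))
        tight_sd = precision_from_profile(self._bump_profile(5.0, 0.005))
        assert tight_sd.half_width_deg <= wide_sd.half_width_deg

    def test_requires_replicates(self):
        prof = PrecisionProfile(np.arange(5.0), np.ones(5), np.zeros(5), 1)
        with pytest.raises(ValueError):
            precision_from_profile(prof)

    def test_aggregate_profiles_statistics(self):
        angles = np.arange(3.0)
        curves = np.array([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
        prof = aggregate_profiles(angles, curves)
        np.testing.assert_allclose(prof.mean_curve, [2.0, 2.0, 2.0])
        assert prof.n_replicates == 2
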