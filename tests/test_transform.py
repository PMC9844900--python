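"""Latent transform: kNN coefficients, cone membership, config validation."""

import numpy as np
import pytest

from casimac import (
    LabeledDataset,
    TransformConfig,
    average_transforms,
    build_vertices,
    mean_knn_distance,
    transform_dataset,
)
from casimac.exceptions import (
    ConfigurationError,
    DegenerateDataError,
    InsufficientNeighborsError,
)
from casimac.simplex import segments_of
from casimac.transform import attraction, repulsion


class TestMeanKnnDistance:
    def test_hand_worked_line(self):
        # pool {1,2,4} around x=0: two nearest at 1 and 2 -> mean 1.5
        pool = [np.array([1.0]), np.array([2.0]), np.array([4.0])]
        assert mean_knn_distance(np.array([0.0]), pool, 2, "euclidean") == pytest.approx(1.5)

    def test_k_equals_pool_size_is_plain_mean(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=3)
        pool = list(rng.normal(size=(5, 3)))
        full = np.mean([np.linalg.norm(x - p) for p in pool])
        assert mean_knn_distance(x, pool, 5, "euclidean") == pytest.approx(full)

    def test_duplicate_at_distance_zero(self):
        x = np.array([1.0, 2.0])
        assert mean_knn_distance(x, [x.copy(), x + 1], 1, "euclidean") == 0.0

    def test_insufficient_pool(self):
        with pytest.raises(InsufficientNeighborsError):
            mean_knn_distance(np.zeros(1), [np.ones(1)], 2, "euclidean")


class TestCoefficients:
    def setup_method(self):
        # class 'a' at 0, 2, 4 on the line; class 'b' at 10, 13
        self.ds = LabeledDataset(points=[[0.0], [2.0], [4.0], [10.0], [13.0]],
                                 labels=["a", "a", "a", "b", "b"])

    def test_attraction_reciprocal_mean(self):
        cfg = TransformConfig(alpha=1.0, beta=0.0, k_alpha=2)
        # own-class neighbors of x=0 at distances 2 and 4 -> A = 1/3
        assert attraction(self.ds.points[0], self.ds, cfg, index=0) == pytest.approx(1 / 3)

    def test_attraction_scales_inversely_with_features(self):
        cfg = TransformConfig(alpha=1.0, beta=0.0, k_alpha=2)
        doubled = LabeledDataset(points=2 * self.ds.points, labels=self.ds.labels)
        a1 = attraction(self.ds.points[0], self.ds, cfg, index=0)
        a2 = attraction(doubled.points[0], doubled, cfg, index=0)
        assert a2 == pytest.approx(a1 / 2)

    def test_repulsion_nearest_foreign(self):
        cfg = TransformConfig(k_beta=1)
        # nearest class-b point to x=13... for x=0: at distance 10
        assert repulsion(self.ds.points[0], 2, self.ds, cfg, index=0) == pytest.approx(10.0)

    def test_repulsion_equidistant_pool(self):
        ds = LabeledDataset(points=[[0.0, 0.0], [1.0, 0.0], [-1.0, 0.0], [0.0, 1.0]],
                            labels=["a", "b", "b", "b"])
        for kb in (1, 2, 3):
            cfg = TransformConfig(k_beta=kb)
            assert repulsion(ds.points[0], 2, ds, cfg, index=0) == pytest.approx(1.0)


class TestTransformDataset:
    def test_line_fixture_signed_distances(self, line_fixture):
        ds, cfg, expected = line_fixture
        lat = transform_dataset(ds, cfg)
        np.testing.assert_allclose(lat.targets.ravel(), expected)

    def test_targets_inside_own_cone(self, ternary_toy):
        for cfg in (TransformConfig(alpha=0, beta=1),
                    TransformConfig(alpha=1, beta=0, k_alpha=2),
                    TransformConfig.from_gamma(0.5, k_alpha=2, k_beta=3)):
            lat = transform_dataset(ternary_toy, cfg)
            assert np.array_equal(segments_of(lat.targets, lat.basis), ternary_toy.y)
            # strict interior: the own vertex is the unique nearest one
            dots = lat.targets @ lat.basis.vertices.T
            top2 = np.sort(dots, axis=1)[:, -2:]
            assert np.all(top2[:, 1] > top2[:, 0])

    def test_rewritten_form_agrees(self, ternary_toy):
        """f(x) = alpha*A*p_y + sum beta*R*(-p_l) equals the all-mirrored-vertex
        form sum_{l != y} (alpha*A + beta*R_l)*(-p_l) (uses sum p_i = 0)."""
        cfg = TransformConfig.from_gamma(0.25, k_alpha=1, k_beta=2)
        lat = transform_dataset(ternary_toy, cfg)
        V = lat.basis.vertices
        alt = np.zeros_like(lat.targets)
        for i in range(len(ternary_toy)):
            yi = ternary_toy.y[i]
            A = attraction(ternary_toy.points[i], ternary_toy, cfg, index=i)
            for l in range(1, ternary_toy.n_classes + 1):
                if l == yi:
                    continue
                R = repulsion(ternary_toy.points[i], l, ternary_toy, cfg, index=i)
                alt[i] += (cfg.alpha * A + cfg.beta * R) * (-V[l - 1])
        np.testing.assert_allclose(alt, lat.targets, atol=1e-10)

    def test_random_fuzzing_cone_membership(self):
        rng = np.random.default_rng(42)
        for trial in range(5):
            n = rng.integers(2, 6)
            X = rng.normal(size=(6 * n, 3))
            y = np.repeat(np.arange(1, n + 1), 6).tolist()
            ds = LabeledDataset(points=X, labels=y)
            cfg = TransformConfig.from_gamma(
                float(rng.choice([0.25, 0.5, 0.75, 1.0])),
                k_alpha=int(rng.integers(1, 5)), k_beta=int(rng.integers(1, 6)))
            lat = transform_dataset(ds, cfg)
            assert np.array_equal(segments_of(lat.targets, lat.basis), ds.y)

    def test_taxicab_semimetric(self, line_fixture):
        ds, _, expected = line_fixture
        cfg = TransformConfig(alpha=0, beta=1, semimetric="taxicab")
        np.testing.assert_allclose(transform_dataset(ds, cfg).targets.ravel(), expected)

    def test_intra_class_duplicates_error_when_attracting(self):
        ds = LabeledDataset(points=[[0.0], [0.0], [5.0], [6.0]],
                            labels=["a", "a", "b", "b"])
        with pytest.raises(DegenerateDataError):
            transform_dataset(ds, TransformConfig(alpha=1, beta=0))
        # harmless when alpha = 0
        transform_dataset(ds, TransformConfig(alpha=0, beta=1))

    def test_inter_class_duplicates_warn(self):
        ds = LabeledDataset(points=[[0.0], [1.0], [0.0], [5.0]],
                            labels=["a", "a", "b", "b"])
        with pytest.warns(UserWarning, match="coincides"):
            transform_dataset(ds, TransformConfig(alpha=0, beta=1))


class TestConfigValidation:
    def test_bounds(self, ternary_toy):
        # c = 3: k_alpha <= 2 when alpha > 0, k_beta <= 3 when beta > 0
        TransformConfig(alpha=1, beta=1, k_alpha=2, k_beta=3).validate(ternary_toy)
        with pytest.raises(ConfigurationError):
            TransformConfig(alpha=1, beta=1, k_alpha=3).validate(ternary_toy)
        with pytest.raises(ConfigurationError):
            TransformConfig(alpha=0, beta=1, k_beta=4).validate(ternary_toy)
        with pytest.raises(ConfigurationError):
            TransformConfig(alpha=0, beta=0).validate(ternary_toy)

    def test_gamma_constructor(self):
        cfg = TransformConfig.from_gamma(0.25)
        assert cfg.alpha == pytest.approx(0.75) and cfg.beta == pytest.approx(0.25)
        with pytest.raises(ConfigurationError):
            TransformConfig.from_gamma(1.5)


class TestAverageTransforms:
    def test_identity_and_arithmetic(self, line_fixture):
        ds, cfg, expected = line_fixture
        lat = transform_dataset(ds, cfg)
        np.testing.assert_array_equal(average_transforms([lat]).targets, lat.targets)
        np.testing.assert_array_equal(average_transforms([lat, lat]).targets, lat.targets)
        other = transform_dataset(ds, TransformConfig(alpha=0, beta=1, semimetric="taxicab"))
        avg = average_transforms([lat, other])
        np.testing.assert_allclose(avg.targets, (lat.targets + other.targets) / 2)

    def test_average_preserves_cone_membership(self, ternary_toy):
        lats = [transform_dataset(ternary_toy, TransformConfig.from_gamma(g, 1, 2))
                for g in (0.5, 0.75, 1.0)]
        avg = average_transforms(lats)
        assert np.array_equal(segments_of(avg.targets, avg.basis), ternary_toy.y)

    def test_mismatched_lengths_rejected(self, line_fixture, ternary_toy):
        ds, cfg, _ = line_fixture
        a = transform_dataset(ds, cfg)
        b = transform_dataset(ternary_toy, TransformConfig(alpha=0, beta=1))
        with pytest.raises(ValueError):
            average_transforms([a, b])
        with pytest.raises(ValueError):
            average_transforms([])
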