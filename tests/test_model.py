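"""End-to-end classifier: label rule, calibrated probabilities, persistence."""

import numpy as np
import pytest
from scipy.stats import norm

from casimac import (
    BackendSpec,
    CasimacModel,
    CasimacResults,
    TransformConfig,
    closed_form_binary,
)
from casimac.exceptions import CapabilityError


def noise_free_backend(seed=0):
    return BackendSpec(noise_level=1e-10, noise_level_bounds=None, seed=seed)


@pytest.fixture(scope="module")
def binary_line_results():
    """1-D binary problem separable at x ~ 2."""
    rng = np.random.default_rng(11)
    x = np.concatenate([rng.uniform(0, 1.8, 13), rng.uniform(2.2, 4, 12)])
    labels = ["neg"] * 13 + ["pos"] * 12
    return CasimacModel(x[:, None], labels,
                        transform=TransformConfig(alpha=0, beta=1),
                        backend=BackendSpec(seed=0), mc_seed=3).fit()


class TestClosedFormBinary:
    def test_symmetry_and_limits(self):
        assert closed_form_binary(0.0, 1.0) == pytest.approx(0.5)
        assert closed_form_binary(50.0, 1.0) == pytest.approx(1.0)
        assert closed_form_binary(-50.0, 1.0) == pytest.approx(0.0)
        assert closed_form_binary(1.0, 1.0) == pytest.approx(norm.cdf(1.0))

    def test_quadrature_oracle(self):
        # independent oracle: numerically integrate the normal density on [0, inf)
        from scipy.integrate import quad

        for mu, sd in [(0.3, 0.7), (-1.2, 2.0), (2.5, 0.4)]:
            oracle, _ = quad(lambda z: norm.pdf(z, loc=mu, scale=sd), 0, np.inf)
            assert closed_form_binary(mu, sd) == pytest.approx(oracle, abs=1e-9)

    def test_monte_carlo_agreement(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            mu, sd = rng.normal(), rng.uniform(0.3, 2.0)
            draws = rng.normal(mu, sd, size=100_000)
            mc = np.mean(draws >= 0)
            se = np.sqrt(mc * (1 - mc) / 100_000) + 1e-12
            assert abs(closed_form_binary(mu, sd) - mc) < 3 * se

    def test_invalid_std(self):
        with pytest.raises(ValueError):
            closed_form_binary(0.0, 0.0)


class TestPredict:
    def test_binary_labels_and_sign_rule(self, binary_line_results):
        res = binary_line_results
        assert res.predict([[0.5], [3.5]]) == ["neg", "pos"]
        lat = res.predict_latent([[0.5], [3.5]]).ravel()
        assert lat[0] < 0 < lat[1]

    def test_perfect_reconstruction_on_training_data(self, ternary_toy):
        res = CasimacModel.from_dataset(
            ternary_toy, transform=TransformConfig(alpha=0, beta=1),
            backend=noise_free_backend()).fit()
        assert res.predict(ternary_toy.points) == ternary_toy.labels
        assert res.training_accuracy_ == 1.0

    def test_refit_is_deterministic(self, ternary_toy):
        kw = dict(transform=TransformConfig.from_gamma(0.5, 1, 2),
                  backend=BackendSpec(seed=9), mc_seed=4)
        X = np.random.default_rng(2).uniform(0, 1, (20, 2))
        a = CasimacModel.from_dataset(ternary_toy, **kw).fit()
        b = CasimacModel.from_dataset(ternary_toy, **kw).fit()
        np.testing.assert_array_equal(a.predict_latent(X), b.predict_latent(X))
        np.testing.assert_array_equal(a.predict_proba(X), b.predict_proba(X))


class TestPredictProba:
    def test_rows_sum_to_one_exactly(self, binary_line_results, ternary_toy):
        X = np.random.default_rng(5).uniform(0, 4, (30, 1))
        P = binary_line_results.predict_proba(X)
        np.testing.assert_array_equal(P.sum(axis=1), np.ones(30))
        res3 = CasimacModel.from_dataset(ternary_toy).fit()
        P3 = res3.predict_proba(np.random.default_rng(6).uniform(0, 1, (30, 2)))
        np.testing.assert_array_equal(P3.sum(axis=1), np.ones(30))
        assert np.all(P3 >= 0)

    def test_binary_monotone_in_latent_mean(self, binary_line_results):
        x = np.linspace(0, 4, 40)[:, None]
        order = np.argsort(binary_line_results.predict_latent(x).ravel())
        p_pos = binary_line_results.predict_proba(x)[:, 1]
        assert np.all(np.diff(p_pos[order]) >= -1e-12)

    def test_multiclass_symmetric_density_is_uniform(self, ternary_toy):
        """A predictive mean at the origin assigns ~1/n to each class."""
        res = CasimacModel.from_dataset(ternary_toy, mc_seed=8).fit()

        class Iso:
            def __init__(self, inner):
                self.inner = inner

            def predict_mean(self, X):
                return np.zeros((len(X), 2))

            def predict_gaussian(self, X):
                from casimac.backend import PredictiveGaussian
                return [PredictiveGaussian(np.zeros(2), 1.0) for _ in range(len(X))]

        res.backend = Iso(res.backend)
        P = res.predict_proba(np.zeros((1, 2)))[0]
        assert np.allclose(P, 1 / 3, atol=0.02)  # Monte-Carlo error at 1e4 draws

    def test_argmax_matches_predict_far_from_boundaries(self, binary_line_results):
        res = binary_line_results
        X = np.array([[0.3], [3.8]])
        P = res.predict_proba(X)
        labels = [res.classes_[j] for j in np.argmax(P, axis=1)]
        assert labels == res.predict(X)

    def test_backend_without_density_raises(self, ternary_toy):
        class PointOnly:
            def fit(self, X, t):
                self.t = t
                return self

            def predict_mean(self, X):
                return np.zeros((len(X), 2))

        res = CasimacModel.from_dataset(ternary_toy, backend=PointOnly(),
                                        standardize=False).fit()
        with pytest.raises(CapabilityError):
            res.predict_proba(np.zeros((1, 2)))


class TestStandardizer:
    def test_zero_variance_feature_warns_and_survives(self):
        X = np.column_stack([np.linspace(0, 1, 10), np.full(10, 7.0)])
        labels = ["a"] * 5 + ["b"] * 5
        with pytest.warns(UserWarning, match="zero-variance"):
            res = CasimacModel(X, labels).fit()
        assert len(res.predict(X)) == 10


def test_save_load_roundtrip(tmp_path, ternary_toy):
    res = CasimacModel.from_dataset(ternary_toy, mc_seed=1).fit()
    path = tmp_path / "model.joblib"
    res.save(path)
    loaded = CasimacResults.load(path)
    X = np.random.default_rng(3).uniform(0, 1, (10, 2))
    assert loaded.predict(X) == res.predict(X)
    np.testing.assert_array_equal(loaded.predict_proba(X), res.predict_proba(X))


def test_summary_mentions_key_facts(ternary_toy):
    s = CasimacModel.from_dataset(ternary_toy).fit().summary()
    assert "classes (n):            3" in s
    assert "training accuracy" in s
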