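"""Latent-space regression backends.

The classifier needs a regressor ``fhat: X -> Z`` fitted to the transformed
training data, ideally with a predictive a-posteriori density ``qhat(.|x)``
over latent points.  Any object exposing ``fit(X, targets)``,
``predict_mean(X)`` and ``predict_gaussian(X)`` with these semantics is
accepted (duck-typed), so e.g. a neural-network density regressor can be
plugged in.  The default backend is a Gaussian-process regressor with a
Matern + white-noise kernel whose predictive distribution is modeled as an
isotropic normal ``N(mean, std^2 I)`` over ``R^(n-1)`` — a single regressor
with a shared kernel across output dimensions, since the method nowhere
introduces inter-dimension covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import warnings

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel

from .exceptions import CasimacError
from .transform import LatentDataset

__all__ = ["PredictiveGaussian", "BackendSpec", "GaussianProcessBackend", "fit_backend"]

# Lower floor on the predictive standard deviation, so qhat is a proper density
# even for a perfectly interpolating (noise-free) backend.
_STD_FLOOR = 1e-12


@dataclass(frozen=True)
class PredictiveGaussian:
    """Isotropic normal predictive distribution over the latent space."""

    mean: np.ndarray
    std: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean", np.atleast_1d(np.asarray(self.mean, float)))
        if not self.std > 0:
            raise ValueError(f"std must be positive, got {self.std}")


@dataclass(frozen=True)
class BackendSpec:
    """Configuration of the default Gaussian-process backend.

    ``amplitude`` is the signal variance multiplying the Matern term,
    ``length_scale`` / ``nu`` parameterize the Matern kernel, ``noise_level``
    the additive white-noise term; marginal-likelihood optimization may move
    both within their bounds.  ``kind="custom"`` marks a user-provided
    backend object used as-is.
    """

    kind: str = "gaussian_process"
    amplitude: float = 1.0
    amplitude_bounds: tuple = (1e-3, 1e3)
    length_scale: float = 1.0
    length_scale_bounds: tuple = (1e-2, 1e2)
    nu: float = 2.5
    noise_level: float = 1e-3
    noise_level_bounds: tuple = (1e-6, 1e1)
    n_restarts: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_restarts < 0:
            raise ValueError("n_restarts must be >= 0")

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "amplitude": self.amplitude,
            "amplitude_bounds": (None if self.amplitude_bounds is None
                                 else list(self.amplitude_bounds)),
            "length_scale": self.length_scale,
            "length_scale_bounds": list(self.length_scale_bounds),
            "nu": self.nu,
            "noise_level": self.noise_level,
            "noise_level_bounds": (None if self.noise_level_bounds is None
                                   else list(self.noise_level_bounds)),
            "n_restarts": self.n_restarts,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BackendSpec":
        d = dict(d)
        for key in ("amplitude_bounds", "length_scale_bounds", "noise_level_bounds"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)


class GaussianProcessBackend:
    """Matern + white-noise Gaussian-process regressor on the latent targets."""

    def __init__(self, spec: BackendSpec | None = None):
        self.spec = spec or BackendSpec()
        self._gpr: GaussianProcessRegressor | None = None

    def fit(self, X: np.ndarray, targets: np.ndarray) -> "GaussianProcessBackend":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise CasimacError(
                "the Gaussian-process backend requires numeric feature vectors; "
                "use a custom backend for non-numeric features"
            )
        s = self.spec
        noise_bounds = ("fixed" if s.noise_level_bounds is None else s.noise_level_bounds)
        amp_bounds = ("fixed" if s.amplitude_bounds is None else s.amplitude_bounds)
        kernel = ConstantKernel(constant_value=s.amplitude,
                                constant_value_bounds=amp_bounds) \
            * Matern(length_scale=s.length_scale,
                     length_scale_bounds=s.length_scale_bounds, nu=s.nu) \
            + WhiteKernel(noise_level=s.noise_level,
                          noise_level_bounds=noise_bounds)
        self._gpr = GaussianProcessRegressor(
            kernel=kernel,
            n_restarts_optimizer=s.n_restarts,
            random_state=s.seed,
            normalize_y=False,
        )
        with warnings.catch_warnings():
            # hyperparameters pinned at a kernel bound are acceptable here
            warnings.simplefilter("ignore", ConvergenceWarning)
            self._gpr.fit(X, np.asarray(targets, dtype=float))
        self._n_features = X.shape[1]
        return self

    def _check(self, X: np.ndarray) -> np.ndarray:
        if self._gpr is None:
            raise CasimacError("backend is not fitted")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self._n_features:
            raise ValueError(
                f"expected {self._n_features} features, got {X.shape[1]}"
            )
        return X

    def predict_mean(self, X: np.ndarray) -> np.ndarray:
        """Point predictions ``fhat(x)``, shape (m, n-1)."""
        X = self._check(X)
        mean = self._gpr.predict(X)
        return np.atleast_2d(mean.T).T if mean.ndim == 1 else mean

    def predict_gaussian(self, X: np.ndarray) -> list[PredictiveGaussian]:
        """Predictive isotropic normals for every row of ``X``."""
        X = self._check(X)
        mean, std = self._gpr.predict(X, return_std=True)
        if mean.ndim == 1:
            mean = mean[:, np.newaxis]
        # shared kernel across outputs -> identical per-dimension stds
        std = np.atleast_2d(std.T).T[:, 0]
        std = np.maximum(std, _STD_FLOOR)
        return [PredictiveGaussian(mean=m, std=float(s)) for m, s in zip(mean, std)]

    @property
    def kernel_(self):
        """Optimized kernel of the underlying regressor."""
        return None if self._gpr is None else self._gpr.kernel_


def fit_backend(latent: LatentDataset, spec: BackendSpec | object | None = None):
    """Fit a regression backend on a latent dataset and return its handle.

    ``spec`` may be a :class:`BackendSpec` (default Gaussian process) or any
    duck-typed backend object exposing ``fit`` / ``predict_mean`` /
    ``predict_gaussian``; the object is fitted in place and returned.
    """
    if len(latent.points) < 2:
        raise CasimacError("need at least 2 training points to fit a backend")
    if spec is None or isinstance(spec, BackendSpec):
        backend = GaussianProcessBackend(spec)
    elif hasattr(spec, "fit") and hasattr(spec, "predict_mean"):
        backend = spec
    else:
        raise CasimacError(
            "spec must be a BackendSpec or an object with fit/predict_mean"
        )
    backend.fit(np.asarray(latent.points, dtype=float), latent.targets)
    return backend
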