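"""Calibrated simplex-mapping classifier (CASIMAC).

The estimator follows the model/results idiom: :class:`CasimacModel` holds
the data and configuration, ``fit()`` performs the two training steps —
(1) map each training point into its class's cone segment of the latent
space ``Z = R^(n-1)`` via the kNN attraction/repulsion transform, and
(2) fit a probabilistic regressor to the transformed data — and returns a
:class:`CasimacResults` carrying predictions, class probabilities,
diagnostics and persistence.

Class labels are decided by the nearest-central-vector rule applied to the
regressor's latent mean.  Class probabilities are the mass the predictive
density ``qhat(.|x)`` assigns to each cone segment: a closed form for two
classes, Monte-Carlo integration for more.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import norm

from .backend import BackendSpec, PredictiveGaussian, fit_backend
from .data import LabeledDataset
from .exceptions import CapabilityError
from .simplex import build_vertices, compress, segments_of
from .transform import TransformConfig, transform_dataset

__all__ = ["CasimacModel", "CasimacResults", "closed_form_binary"]


def closed_form_binary(mean: float, std: float) -> float:
    """Probability of the positive-half-line class for a binary problem.

    With two classes the segments are the half-lines around 0 and ``qhat``
    is ``N(mean, std^2)``, so the mass on ``[0, inf)`` — the second (sorted)
    class — is ``Phi(mean / std)``; the first class gets the complement.
    """
    if not std > 0:
        raise ValueError(f"std must be positive, got {std}")
    return float(norm.cdf(float(mean) / float(std)))


class _Standardizer:
    """Per-feature training mean/std scaler; zero-variance features are
    centered only (divisor 1)."""

    def fit(self, X: np.ndarray) -> "_Standardizer":
        self.mean_ = X.mean(axis=0)
        std = X.std(axis=0, ddof=0)
        if np.any(std == 0):
            warnings.warn("zero-variance feature(s) centered but not scaled",
                          stacklevel=2)
        self.scale_ = np.where(std == 0, 1.0, std)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean_) / self.scale_


class CasimacModel:
    """Calibrated simplex-mapping classifier specification.

    Parameters
    ----------
    X : array-like of shape (D, m)
        Training feature vectors (or an opaque sequence usable by a custom
        semimetric together with a custom backend).
    y : sequence of length D
        Class labels; mapped to indices 1..n by sorted order.
    transform : TransformConfig, optional
        Attraction/repulsion weights, neighbor counts and semimetric.
    backend : BackendSpec or duck-typed backend object, optional
        Latent-space regressor; defaults to a Matern + white-noise Gaussian
        process.
    mc_samples : int
        Monte-Carlo draws per query point for class probabilities with
        three or more classes.
    mc_seed : int
        Seed of the Monte-Carlo integration stream.
    standardize : bool
        Standardize features on training statistics before the transform
        and the regression (numeric features only).
    """

    def __init__(self, X, y, *, transform: TransformConfig | None = None,
                 backend=None, mc_samples: int = 10_000, mc_seed: int = 0,
                 standardize: bool = True):
        if mc_samples < 1:
            raise ValueError("mc_samples must be >= 1")
        self.dataset = X if isinstance(X, LabeledDataset) and y is None else \
            LabeledDataset(points=X, labels=list(y))
        self.transform_config = transform or TransformConfig()
        self.backend_spec = backend if backend is not None else BackendSpec()
        self.mc_samples = int(mc_samples)
        self.mc_seed = int(mc_seed)
        self.standardize = bool(standardize)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_column: str, **kwargs) -> "CasimacModel":
        """Build from a DataFrame with numeric features and a label column."""
        ds = LabeledDataset.from_dataframe(df, label_column)
        return cls(ds, None, **kwargs)

    @classmethod
    def from_dataset(cls, dataset: LabeledDataset, **kwargs) -> "CasimacModel":
        return cls(dataset, None, **kwargs)

    def fit(self) -> "CasimacResults":
        """Run both training steps and return the fitted results."""
        ds = self.dataset
        basis = build_vertices(ds.n_classes)
        self.transform_config.validate(ds)

        numeric = isinstance(ds.points, np.ndarray)
        scaler = None
        points = ds.points
        if self.standardize and numeric:
            scaler = _Standardizer().fit(ds.points)
            points = scaler.transform(ds.points)
            work = LabeledDataset(points=points, labels=ds.labels)
        else:
            work = ds

        latent = transform_dataset(work, self.transform_config, basis)
        handle = fit_backend(latent, self.backend_spec)
        return CasimacResults(model=self, basis=basis, scaler=scaler,
                              latent=latent, backend=handle)


class CasimacResults:
    """Fitted calibrated simplex-mapping classifier."""

    def __init__(self, model: CasimacModel, basis, scaler, latent, backend):
        self.model = model
        self.basis = basis
        self.scaler = scaler
        self.latent = latent
        self.backend = backend
        self.classes_ = list(model.dataset.classes)

    # -- internals ---------------------------------------------------------
    def _prepare(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.scaler is not None:
            X = self.scaler.transform(X)
        return X

    def _gaussians(self, X) -> list[PredictiveGaussian]:
        if not hasattr(self.backend, "predict_gaussian"):
            raise CapabilityError(
                "backend provides no predictive distribution; "
                "class probabilities are unavailable"
            )
        return self.backend.predict_gaussian(self._prepare(X))

    # -- predictions -------------------------------------------------------
    def predict_latent(self, X) -> np.ndarray:
        """Latent point predictions ``fhat(x)``, shape (m, n-1)."""
        return self.backend.predict_mean(self._prepare(X))

    def predict(self, X) -> list:
        """Class labels via the nearest-central-vector rule on ``fhat(x)``."""
        seg = segments_of(self.predict_latent(X), self.basis)
        return self.model.dataset.decode(seg)

    def predict_proba(self, X) -> np.ndarray:
        """Class probabilities, one row per query, columns in sorted-label order.

        Two classes use the closed normal form; three or more classes use
        Monte-Carlo integration of ``qhat`` over the cone segments with
        ``mc_samples`` draws, deterministic in ``mc_seed``.  Rows sum to one
        by construction.
        """
        gaussians = self._gaussians(X)
        n = self.basis.n_classes
        if n == 2:
            p2 = np.array([closed_form_binary(g.mean[0], g.std) for g in gaussians])
            return np.column_stack([1.0 - p2, p2])
        return self._mc_proba(gaussians)

    def _mc_proba(self, gaussians: list[PredictiveGaussian]) -> np.ndarray:
        S = self.model.mc_samples
        n = self.basis.n_classes
        V = self.basis.vertices  # (n, n-1)
        rng = np.random.default_rng(self.model.mc_seed)
        # One shared standard-normal block: z_i = mean_i + std_i * E, so the
        # per-class score of draw s is mean_i.p_k + std_i * (E.p_k).
        E = rng.standard_normal((S, self.basis.dim))
        U = E @ V.T                                  # (S, n)
        means = np.array([g.mean for g in gaussians])
        stds = np.array([g.std for g in gaussians])
        M = means @ V.T                              # (m, n)
        out = np.empty((len(gaussians), n))
        batch = max(1, int(2e6 // max(S, 1)))
        for start in range(0, len(gaussians), batch):
            stop = min(start + batch, len(gaussians))
            scores = M[start:stop, None, :] + stds[start:stop, None, None] * U[None, :, :]
            winners = np.argmax(scores, axis=2)      # min-index tie-break
            for i, w in enumerate(winners):
                out[start + i] = np.bincount(w, minlength=n)
        return out / S

    def compress_latent(self, X) -> np.ndarray:
        """Compressed latent predictions ``C(fhat(x))`` in the open simplex."""
        return compress(self.predict_latent(X), self.basis)

    def compress_training(self) -> np.ndarray:
        """Compressed latent targets ``C(f(x_i))`` of the training points."""
        return compress(self.latent.targets, self.basis)

    # -- diagnostics ---------------------------------------------------------
    @property
    def training_accuracy_(self) -> float:
        pred = self.predict(self.model.dataset.points)
        return float(np.mean([p == t for p, t in
                              zip(pred, self.model.dataset.labels)]))

    def summary(self) -> str:
        """Plain-text summary of the fitted classifier."""
        ds = self.model.dataset
        cfg = self.model.transform_config
        lines = [
            "Calibrated simplex-mapping classifier",
            "=" * 44,
            f"classes (n):            {ds.n_classes}  {ds.classes}",
            f"training points (D):    {len(ds)}",
            f"class counts:           {ds.class_counts.tolist()}",
            f"latent dimension:       {self.basis.dim}",
            f"alpha / beta:           {cfg.alpha:g} / {cfg.beta:g}",
            f"k_alpha / k_beta:       {cfg.k_alpha} / {cfg.k_beta}",
            f"semimetric:             {cfg.semimetric}",
            f"mc_samples / mc_seed:   {self.model.mc_samples} / {self.model.mc_seed}",
        ]
        kernel = getattr(self.backend, "kernel_", None)
        if kernel is not None:
            lines.append(f"backend kernel:         {kernel}")
        lines.append(f"training accuracy:      {self.training_accuracy_:.3f}")
        return "\n".join(lines)

    # -- persistence ---------------------------------------------------------
    def save(self, path) -> None:
        """Persist the fitted classifier as a single joblib bundle."""
        import joblib

        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "CasimacResults":
        import joblib

        obj = joblib.load(path)
        if not isinstance(obj, CasimacResults):
            raise TypeError(f"{path} does not contain a CasimacResults bundle")
        return obj
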