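"""Semimetric registry for the latent-space transform.

A semimetric is a symmetric nonnegative distance with ``d(x, x') = 0`` iff
``x = x'``; the triangle inequality is *not* required.  Built-ins cover the
common vector cases; arbitrary user callables are accepted and spot-checked
for symmetry and nonnegativity (identity of indiscernibles remains the
caller's contract).
"""

from __future__ import annotations

from typing import Callable

import numpy as np
from scipy.spatial.distance import cdist

__all__ = ["get_semimetric", "register_semimetric", "pairwise_distances", "validate_semimetric"]

Semimetric = Callable[[np.ndarray, np.ndarray], float]

# name -> (callable, cdist metric name or None)
_REGISTRY: dict[str, tuple[Semimetric, str | None]] = {}


def register_semimetric(name: str, func: Semimetric, *, cdist_metric: str | None = None) -> None:
    """Register a named semimetric; ``cdist_metric`` enables fast batch paths."""
    _REGISTRY[name] = (func, cdist_metric)


def get_semimetric(spec: str | Semimetric) -> tuple[Semimetric, str | None]:
    """Resolve a semimetric by registry name or accept a callable as-is."""
    if callable(spec):
        return spec, None
    try:
        return _REGISTRY[spec]
    except KeyError:
        raise KeyError(
            f"unknown semimetric {spec!r}; registered: {sorted(_REGISTRY)}"
        ) from None


register_semimetric(
    "euclidean",
    lambda a, b: float(np.linalg.norm(np.asarray(a, float) - np.asarray(b, float))),
    cdist_metric="euclidean",
)
register_semimetric(
    "taxicab",
    lambda a, b: float(np.abs(np.asarray(a, float) - np.asarray(b, float)).sum()),
    cdist_metric="cityblock",
)


def pairwise_distances(points, semimetric: str | Semimetric) -> np.ndarray:
    """Full symmetric distance matrix between the given points.

    Named semimetrics with a vectorised backend go through ``cdist``; user
    callables are evaluated pairwise (the small-sample regime this method
    targets makes the quadratic loop acceptable).
    """
    func, metric = get_semimetric(semimetric)
    if metric is not None:
        X = np.asarray(points, dtype=float)
        return cdist(X, X, metric=metric)
    D = len(points)
    out = np.zeros((D, D))
    for i in range(D):
        for j in range(i + 1, D):
            out[i, j] = out[j, i] = func(points[i], points[j])
    return out


def distances_to(points_a, points_b, semimetric: str | Semimetric) -> np.ndarray:
    """Rectangular distance matrix ``(len(a), len(b))``."""
    func, metric = get_semimetric(semimetric)
    if metric is not None:
        A = np.asarray(points_a, dtype=float)
        B = np.asarray(points_b, dtype=float)
        return cdist(A, B, metric=metric)
    out = np.zeros((len(points_a), len(points_b)))
    for i, a in enumerate(points_a):
        for j, b in enumerate(points_b):
            out[i, j] = func(a, b)
    return out


def validate_semimetric(func: Semimetric, sample, *, atol: float = 1e-9) -> None:
    """Spot-check symmetry and nonnegativity of a user semimetric on a sample.

    Raises ``ValueError`` on the first violation found.  Full identity of
    indiscernibles cannot be verified on a finite sample and is not checked.
    """
    for i, a in enumerate(sample):
        for b in sample[i + 1:]:
            dab, dba = func(a, b), func(b, a)
            if dab < -atol or dba < -atol:
                raise ValueError("semimetric returned a negative distance")
            if abs(dab - dba) > atol:
                raise ValueError(f"semimetric is not symmetric: d(a,b)={dab}, d(b,a)={dba}")
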