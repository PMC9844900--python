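"""Regular-simplex geometry of the latent space.

For an ``n``-class problem the latent space is ``Z = R^(n-1)``, partitioned
into ``n`` cone segments by the vertices ``p_1 .. p_n`` of a regular
``(n-1)``-simplex with barycenter 0 and unit circumradius.  Segment ``C_k``
is the cone spanned by the mirrored vertices ``{-p_i : i != k}``; it is the
decision region of class ``k`` and contains the "central vector" ``p_k`` on
its central ray.  Membership can be decided purely from distances: ``z`` lies
in ``C_k`` iff ``p_k`` is a nearest central vector of ``z``, equivalently iff
``z . p_k`` is maximal over all vertices (the squared distance is
``|z|^2 - 2 z.p_k + 1``).

A cone-invariant bijective compression map onto the open simplex interior is
provided for visualisation of unbounded latent points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SimplexBasis",
    "build_vertices",
    "segment_of",
    "cone_contains",
    "compress",
    "decompress",
]


@dataclass(frozen=True)
class SimplexBasis:
    """Vertices of the regular (n-1)-simplex that segments the latent space.

    Attributes
    ----------
    n_classes : int
        Number of classes ``n >= 2``.
    vertices : ndarray of shape (n, n-1)
        Row ``k`` holds the central vector ``p_{k+1}`` (unit norm, zero sum,
        pairwise dot product ``-1/(n-1)``).
    """

    n_classes: int
    vertices: np.ndarray = field(repr=False)

    @property
    def dim(self) -> int:
        """Latent-space dimension ``n - 1``."""
        return self.n_classes - 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "vertices", np.asarray(self.vertices, dtype=float))
        if self.vertices.shape != (self.n_classes, self.n_classes - 1):
            raise ValueError(
                f"vertices must have shape {(self.n_classes, self.n_classes - 1)}, "
                f"got {self.vertices.shape}"
            )


def _helmert_rows(n: int) -> np.ndarray:
    """Orthonormal basis (rows) of the sum-zero hyperplane of R^n."""
    H = np.zeros((n - 1, n))
    for j in range(1, n):
        norm = np.sqrt(j * (j + 1))
        H[j - 1, :j] = 1.0 / norm
        H[j - 1, j] = -j / norm
    return H


def build_vertices(n_classes: int) -> SimplexBasis:
    """Construct the regular simplex basis for ``n_classes`` classes.

    The vertices are the columns of the centered identity ``e_i - 1/n``,
    expressed in the Helmert orthonormal basis of their span and rescaled to
    unit norm.  The construction is deterministic and, for ``n = 2``, pinned
    to ``p_1 = (-1)``, ``p_2 = (+1)`` so that the first (sorted) class owns
    the negative half-line.

    Parameters
    ----------
    n_classes : int
        Number of classes, at least 2.

    Returns
    -------
    SimplexBasis
    """
    if not isinstance(n_classes, (int, np.integer)) or n_classes < 2:
        raise ValueError(f"n_classes must be an integer >= 2, got {n_classes!r}")
    n = int(n_classes)
    # Columns of the Helmert rows are the centered identity columns expressed
    # in the orthonormal basis; their norm is sqrt((n-1)/n).  The global sign
    # flip pins p_1 = -1 for n = 2 and is immaterial otherwise (all decisions
    # depend only on distances).
    V = -np.sqrt(n / (n - 1.0)) * _helmert_rows(n).T
    return SimplexBasis(n_classes=n, vertices=V)


def _check_point(z: np.ndarray, basis: SimplexBasis) -> np.ndarray:
    z = np.asarray(z, dtype=float)
    if z.ndim == 0:
        z = z.reshape(1)
    if z.shape[-1] != basis.dim:
        raise ValueError(
            f"latent point has dimension {z.shape[-1]}, expected {basis.dim}"
        )
    return z


def segment_of(z: np.ndarray, basis: SimplexBasis) -> int:
    """Class index (1-based) of the first cone segment containing ``z``.

    Implements the nearest-central-vector rule: the owner of ``z`` is the
    smallest index ``y`` with ``|z - p_y| = min_l |z - p_l|``.  Since all
    vertices are unit vectors the rule reduces to the first index maximising
    ``z . p_y``, which is exact at ties (e.g. the origin maps to class 1).
    """
    z = _check_point(z, basis)
    if z.ndim != 1:
        raise ValueError("segment_of expects a single latent point")
    return int(np.argmax(basis.vertices @ z)) + 1


def segments_of(Z: np.ndarray, basis: SimplexBasis) -> np.ndarray:
    """Vectorised :func:`segment_of` for an ``(m, n-1)`` array of points."""
    Z = np.atleast_2d(_check_point(Z, basis))
    return np.argmax(Z @ basis.vertices.T, axis=1) + 1


def cone_contains(z: np.ndarray, k: int, basis: SimplexBasis) -> bool:
    """Whether ``z`` belongs to cone segment ``C_k`` (boundary inclusive).

    True iff ``|z - p_k| <= |z - p_l|`` for every ``l``; points on segment
    boundaries belong to several cones.
    """
    if not 1 <= k <= basis.n_classes:
        raise ValueError(f"class index must be in 1..{basis.n_classes}, got {k}")
    z = _check_point(z, basis)
    dots = basis.vertices @ z
    return bool(dots[k - 1] >= np.max(dots))


def _facet_margin(Z: np.ndarray, basis: SimplexBasis) -> np.ndarray:
    """``m(z) = (n-1) * max_k(-z . p_k)``; nonnegative, zero only at 0.

    ``m(w) < 1`` is exactly the facet description of the open simplex
    interior, and ``m`` is positively homogeneous of degree one.
    """
    return (basis.n_classes - 1) * np.max(-(Z @ basis.vertices.T), axis=-1)


def compress(z: np.ndarray, basis: SimplexBasis) -> np.ndarray:
    """Compress latent points into the open simplex interior.

    ``C(z) = z / (1 + m(z))`` is a radial (positive-scalar) rescaling, hence
    cone-invariant: ``segment_of(C(z)) = segment_of(z)``.  It is a bijection
    of ``Z`` onto the open simplex ``S`` with inverse :func:`decompress`.
    Accepts a single point or an ``(m, n-1)`` array.
    """
    z = _check_point(z, basis)
    m = _facet_margin(z, basis)
    return z / (1.0 + m)[..., np.newaxis] if z.ndim > 1 else z / (1.0 + m)


def decompress(w: np.ndarray, basis: SimplexBasis) -> np.ndarray:
    """Inverse of :func:`compress`: ``w -> w / (1 - m(w))`` for ``m(w) < 1``."""
    w = _check_point(w, basis)
    m = _facet_margin(w, basis)
    if np.any(m >= 1.0):
        raise ValueError("point lies outside the open simplex interior")
    return w / (1.0 - m)[..., np.newaxis] if w.ndim > 1 else w / (1.0 - m)
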