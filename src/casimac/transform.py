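"""Training-data transformation into the simplex-segmented latent space.

Each training point ``x`` with class ``y(x)`` is mapped to

    f(x) = alpha * A(x) * p_{y(x)}  +  sum_{y != y(x)} beta * R(x, y) * (-p_y)

where the attraction coefficient ``A(x)`` is the reciprocal mean distance of
``x`` to its ``k_alpha`` nearest own-class neighbors and the repulsion
coefficient ``R(x, y)`` is the mean distance of ``x`` to its ``k_beta``
nearest neighbors of foreign class ``y``.  Provided ``alpha + beta > 0``,
``k_alpha <= c - 1`` and ``k_beta <= c`` (``c`` the smallest class size),
every target lands strictly inside its own class's cone segment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data import LabeledDataset
from .exceptions import ConfigurationError, DegenerateDataError, InsufficientNeighborsError
from .semimetrics import distances_to, get_semimetric, pairwise_distances
from .simplex import SimplexBasis, build_vertices, segments_of

__all__ = [
    "TransformConfig",
    "LatentDataset",
    "mean_knn_distance",
    "attraction",
    "repulsion",
    "transform_dataset",
    "average_transforms",
]

# Above this many points the full distance matrix is not materialized.
_DENSE_LIMIT = 4000


@dataclass(frozen=True)
class TransformConfig:
    """Hyperparameters of the latent-space transform.

    ``alpha`` weights attraction toward the own-class vertex, ``beta``
    weights repulsion away from foreign segments; ``k_alpha`` / ``k_beta``
    are the neighbor counts of the respective mean-distance coefficients and
    ``semimetric`` is a registry name or a user callable.
    """

    alpha: float = 0.0
    beta: float = 1.0
    k_alpha: int = 1
    k_beta: int = 1
    semimetric: object = "euclidean"

    @classmethod
    def from_gamma(cls, gamma: float, k_alpha: int = 1, k_beta: int = 1,
                   semimetric: object = "euclidean") -> "TransformConfig":
        """Single-parameter weighting ``gamma = beta = 1 - alpha`` in [0, 1]."""
        if not 0.0 <= gamma <= 1.0:
            raise ConfigurationError(f"gamma must lie in [0, 1], got {gamma}")
        return cls(alpha=1.0 - gamma, beta=gamma, k_alpha=k_alpha,
                   k_beta=k_beta, semimetric=semimetric)

    def validate(self, dataset: LabeledDataset) -> None:
        """Check basic positivity and the neighbor-count bounds for ``dataset``."""
        if self.alpha < 0 or self.beta < 0:
            raise ConfigurationError("alpha and beta must be nonnegative")
        if self.alpha + self.beta <= 0:
            raise ConfigurationError("alpha + beta must be positive")
        if self.k_alpha < 1 or self.k_beta < 1:
            raise ConfigurationError("k_alpha and k_beta must be >= 1")
        c = dataset.min_class_size
        if self.alpha > 0 and self.k_alpha > c - 1:
            raise ConfigurationError(
                f"k_alpha={self.k_alpha} exceeds c-1={c - 1} (smallest class size {c})"
            )
        if self.beta > 0 and self.k_beta > c:
            raise ConfigurationError(f"k_beta={self.k_beta} exceeds c={c}")

    def is_valid_for(self, dataset: LabeledDataset) -> bool:
        try:
            self.validate(dataset)
        except ConfigurationError:
            return False
        return True


@dataclass
class LatentDataset:
    """Training points paired with their latent-space targets in R^(n-1)."""

    points: object
    targets: np.ndarray
    basis: SimplexBasis
    y: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.targets = np.asarray(self.targets, dtype=float)
        if self.targets.shape != (len(self.points), self.basis.dim):
            raise ValueError(
                f"targets must have shape {(len(self.points), self.basis.dim)}, "
                f"got {self.targets.shape}"
            )


def mean_knn_distance(x, pool, k: int, semimetric) -> float:
    """Mean distance of ``x`` from its ``k`` nearest neighbors in ``pool``.

    ``pool`` must exclude ``x`` itself (by index, not by value); equal to the
    minimum over all size-``k`` subsets of the average distance.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if len(pool) < k:
        raise InsufficientNeighborsError(
            f"pool of size {len(pool)} cannot supply k={k} neighbors"
        )
    d = distances_to([x], list(pool), semimetric)[0]
    return float(np.sort(d)[:k].mean())


def attraction(x, dataset: LabeledDataset, cfg: TransformConfig, *, index: int | None = None) -> float:
    """Attraction coefficient: reciprocal mean own-class kNN distance."""
    if index is None:
        index = _find_index(x, dataset)
    own = [dataset.points[j] for j in dataset.members_of(dataset.y[index]) if j != index]
    mean_d = mean_knn_distance(x, own, cfg.k_alpha, cfg.semimetric)
    if mean_d == 0.0:
        raise DegenerateDataError(
            f"point {index} duplicates {cfg.k_alpha} own-class point(s); "
            "attraction would be infinite"
        )
    return 1.0 / mean_d


def repulsion(x, foreign_class: int, dataset: LabeledDataset, cfg: TransformConfig,
              *, index: int | None = None) -> float:
    """Repulsion coefficient: mean kNN distance to the foreign class."""
    if index is None:
        index = _find_index(x, dataset)
    if foreign_class == dataset.y[index]:
        raise ValueError("repulsion is defined against foreign classes only")
    pool = [dataset.points[j] for j in dataset.members_of(foreign_class)]
    return mean_knn_distance(x, pool, cfg.k_beta, cfg.semimetric)


def _find_index(x, dataset: LabeledDataset) -> int:
    pts = dataset.points
    if isinstance(pts, np.ndarray):
        hits = np.flatnonzero(np.all(pts == np.asarray(x, float), axis=1))
        if hits.size:
            return int(hits[0])
    else:
        for i, p in enumerate(pts):
            if p is x:
                return i
    raise ValueError("x is not a training point of the dataset")


def _knn_means(sorted_block: np.ndarray, k: int) -> np.ndarray:
    """Row-wise mean of the k smallest entries of an already-sorted block."""
    return sorted_block[:, :k].mean(axis=1)


def transform_dataset(dataset: LabeledDataset, cfg: TransformConfig,
                      basis: SimplexBasis | None = None) -> LatentDataset:
    """Map every training point into its class's open cone segment.

    Computes all pairwise distances once (dense for up to 4000 points,
    row-wise beyond), derives the attraction / repulsion coefficients, and
    assembles the latent targets.  Neighbor ties are broken by original index
    order, which leaves the mean unchanged.
    """
    cfg.validate(dataset)
    n = dataset.n_classes
    if basis is None:
        basis = build_vertices(n)
    elif basis.n_classes != n:
        raise ConfigurationError(
            f"basis has {basis.n_classes} classes but dataset has {n}"
        )
    D = len(dataset)
    V = basis.vertices  # (n, n-1)
    targets = np.zeros((D, basis.dim))

    row_iter = _distance_rows(dataset, cfg)
    class_members = {k: dataset.members_of(k) for k in range(1, n + 1)}

    inter_dup_warned = False
    for i, row in enumerate(row_iter):
        yi = int(dataset.y[i])
        coef = np.zeros(n)  # per-class pull along -p_k; own class handled via alpha
        for k in range(1, n + 1):
            members = class_members[k]
            if k == yi:
                if cfg.alpha == 0.0:
                    continue
                own = row[members[members != i]]
                mean_d = np.sort(own)[: cfg.k_alpha].mean()
                if mean_d == 0.0:
                    dup = members[members != i][np.argsort(own)[: cfg.k_alpha]]
                    raise DegenerateDataError(
                        f"training point {i} duplicates own-class point(s) "
                        f"{dup.tolist()} at distance 0; attraction is infinite "
                        "(set alpha=0 or deduplicate)"
                    )
                targets[i] += cfg.alpha / mean_d * V[k - 1]
            else:
                if cfg.beta == 0.0:
                    continue
                foreign = row[members]
                mean_d = np.sort(foreign)[: cfg.k_beta].mean()
                if mean_d == 0.0 and not inter_dup_warned:
                    warnings.warn(
                        f"training point {i} coincides with a point of class "
                        f"{dataset.classes[k - 1]!r}; its latent target may sit on "
                        "a cone boundary",
                        stacklevel=2,
                    )
                    inter_dup_warned = True
                coef[k - 1] = cfg.beta * mean_d
        targets[i] -= coef @ V

    return LatentDataset(points=dataset.points, targets=targets, basis=basis,
                         y=dataset.y.copy())


def _distance_rows(dataset: LabeledDataset, cfg: TransformConfig):
    """Yield rows of the pairwise distance matrix, dense when small."""
    D = len(dataset)
    pts = dataset.points
    if D <= _DENSE_LIMIT:
        M = pairwise_distances(pts, cfg.semimetric)
        yield from M
    else:
        pts_list = pts if isinstance(pts, list) else list(pts)
        for i in range(D):
            yield distances_to([pts_list[i]], pts_list, cfg.semimetric)[0]


def average_transforms(transforms: list[LatentDataset]) -> LatentDataset:
    """Element-wise mean of several transforms of the same dataset.

    Cones are convex, so averaging targets that share class membership keeps
    every point inside its own segment; used for mixture transforms combining
    several semimetrics.
    """
    if not transforms:
        raise ValueError("need at least one transform to average")
    first = transforms[0]
    for t in transforms[1:]:
        if t.targets.shape != first.targets.shape:
            raise ValueError("transforms have mismatched target shapes")
        if t.y is not None and first.y is not None and not np.array_equal(t.y, first.y):
            raise ValueError("transforms come from differently-labeled datasets")
    mean_targets = np.mean([t.targets for t in transforms], axis=0)
    return LatentDataset(points=first.points, targets=mean_targets,
                         basis=first.basis, y=None if first.y is None else first.y.copy())


def check_cone_membership(latent: LatentDataset) -> np.ndarray:
    """Segment index of every latent target (diagnostic helper)."""
    return segments_of(latent.targets, latent.basis)
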