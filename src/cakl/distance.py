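"""Weighted algebraic genetic distances between sequence representations.

For one feature type, the distance between two sequences is a weighted
Euclidean metric over the curve coordinates,

    d(S1, S2) = sqrt( sum_k sum_i a_{k,i} ||v1_{i,k} - v2_{i,k}||^2 ),

where the inner norm runs over the (kmer x radius) block of algebraic
dimension i and a_{k,i} >= 0 weights dimension i at word length k.  The
composite distance sums the per-feature-type metrics (f-curves, h-curves,
facet curves); a sum of metrics is again a metric.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, TransformerMixin

from .featurize import FeatureConfig, SequenceRepresentation, feature_index

WEIGHT_SCHEMES = ("uniform", "per_k", "per_k_and_dim")


@dataclass(frozen=True)
class WeightScheme:
    """Dimension/scale weights a_{k,i}.

    uniform: a = 1; per_k: a = 1/2^(k-1) (the default; with a single k this
    is a harmless global rescaling); per_k_and_dim: a = 1/2^(i*K + k - 1)
    with K the maximum word length considered.
    """

    name: str = "per_k"
    K: int | None = None

    def __post_init__(self) -> None:
        if self.name not in WEIGHT_SCHEMES:
            raise ValueError(f"unknown weight scheme {self.name!r}; choose from {WEIGHT_SCHEMES}")

    def weight(self, k: int, i: int) -> float:
        if self.name == "uniform":
            return 1.0
        if self.name == "per_k":
            return 1.0 / 2 ** (k - 1)
        K = self.K if self.K is not None else k
        return 1.0 / 2 ** (i * K + k - 1)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric nonnegative pairwise distances with a zero diagonal."""

    ids: tuple[str, ...]
    D: np.ndarray

    def __post_init__(self) -> None:
        D = np.asarray(self.D)
        if D.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if np.isnan(D).any() or (D < 0).any():
            raise ValueError("distance matrix must be nonnegative and NaN-free")

    def submatrix(self, keep: Sequence[str]) -> "DistanceMatrix":
        idx = [self.ids.index(s) for s in keep]
        return DistanceMatrix(ids=tuple(keep), D=self.D[np.ix_(idx, idx)])


def _check_same_layout(c1: FeatureConfig, c2: FeatureConfig) -> None:
    if c1 != c2:
        diffs = [
            f
            for f in ("k", "alphabet", "r_min", "r_max", "r_step", "dmax", "feature_types", "normalize")
            if getattr(c1, f) != getattr(c2, f)
        ]
        raise ValueError(f"representation layouts differ in: {', '.join(diffs)}")


def _column_arrays(config: FeatureConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-column feature type and algebraic dimension, in vector order."""
    idx = feature_index(config)
    types = np.array([ft for _, ft, _, _ in idx])
    dims = np.array([dim for _, _, dim, _ in idx])
    return types, dims


def _column_weights(config: FeatureConfig, w: WeightScheme) -> np.ndarray:
    _, dims = _column_arrays(config)
    return np.array([w.weight(config.k, int(i)) for i in dims])


def weighted_distance(
    v1: SequenceRepresentation, v2: SequenceRepresentation, w: WeightScheme = WeightScheme()
) -> float:
    """Dimension- and scale-weighted Euclidean distance over all coordinates.

    Applied to a single-feature-type representation this is the per-type
    metric; :func:`composite_distance` sums it over feature types.
    """
    _check_same_layout(v1.config, v2.config)
    a = _column_weights(v1.config, w)
    diff = v1.vector - v2.vector
    return float(np.sqrt(np.sum(a * diff * diff)))


def composite_distance(
    v1: SequenceRepresentation, v2: SequenceRepresentation, w: WeightScheme = WeightScheme()
) -> float:
    """Sum of per-feature-type weighted metrics (d_f + d_h + d_F as enabled)."""
    _check_same_layout(v1.config, v2.config)
    types, dims = _column_arrays(v1.config)
    a = _column_weights(v1.config, w)
    diff = v1.vector - v2.vector
    total = 0.0
    for ft in v1.config.feature_types:
        mask = types == ft
        total += float(np.sqrt(np.sum(a[mask] * diff[mask] ** 2)))
    return total


def pairwise_distances_from_array(
    X: np.ndarray, config: FeatureConfig, w: WeightScheme = WeightScheme()
) -> np.ndarray:
    """Composite distances between rows of a feature matrix (vectorized)."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != config.n_features:
        raise ValueError(
            f"feature matrix has {X.shape[1]} columns, layout expects {config.n_features}"
        )
    types, _ = _column_arrays(config)
    sqrt_a = np.sqrt(_column_weights(config, w))
    D = np.zeros((X.shape[0], X.shape[0]))
    for ft in config.feature_types:
        mask = types == ft
        D += squareform(pdist(X[:, mask] * sqrt_a[mask], metric="euclidean"))
    return D


def distance_matrix(
    reps: Sequence[SequenceRepresentation], w: WeightScheme = WeightScheme()
) -> DistanceMatrix:
    """All pairwise composite distances between representations."""
    if len(reps) < 2:
        raise ValueError("need at least 2 representations for a distance matrix")
    config = reps[0].config
    for rep in reps[1:]:
        _check_same_layout(config, rep.config)
    X = np.vstack([rep.vector for rep in reps])
    D = pairwise_distances_from_array(X, config, w)
    return DistanceMatrix(ids=tuple(r.seq_id for r in reps), D=D)


class AlgebraicDistance(TransformerMixin, BaseEstimator):
    """Pairwise-distance transformer over k-mer algebraic feature matrices.

    ``transform(X)`` maps an ``(n, n_features)`` feature array (the output of
    :class:`~cakl.featurize.KmerAlgebraicFeaturizer` under ``config``) to the
    ``(n, n)`` composite distance matrix, suitable for downstream estimators
    with ``metric="precomputed"``.
    """

    def __init__(self, config: FeatureConfig = FeatureConfig(), weights: str = "per_k", K: int | None = None):
        self.config = config
        self.weights = weights
        self.K = K

    def fit(self, X=None, y=None) -> "AlgebraicDistance":
        self.scheme_ = WeightScheme(name=self.weights, K=self.K)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if not hasattr(self, "scheme_"):
            self.fit()
        return pairwise_distances_from_array(X, self.config, self.scheme_)


def write_distance_tsv(dm: DistanceMatrix, path: str | Path) -> None:
    """Square TSV with a header row/column of sequence ids."""
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(dm.ids) + "\n")
        for sid, row in zip(dm.ids, dm.D):
            fh.write(sid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_distance_tsv(path: str | Path) -> DistanceMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
        rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    ids = tuple(header)
    D = np.array([[float(v) for v in r[1:]] for r in rows])
    if tuple(r[0] for r in rows) != ids:
        raise ValueError(f"row/column id mismatch in {path}")
    return DistanceMatrix(ids=ids, D=D)


def write_phylip(dm: DistanceMatrix, path: str | Path) -> None:
    """PHYLIP square distance matrix (relaxed names, tab-separated)."""
    with open(path, "w") as fh:
        fh.write(f"{len(dm.ids)}\n")
        for sid, row in zip(dm.ids, dm.D):
            fh.write(sid + "\t" + "\t".join(f"{float(v):.10f}" for v in row) + "\n")
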