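"""Friedman-Rafsky / Henze-Penrose separability from a Euclidean MST.

Given pooled samples X (m points) and Y (n points), build the minimum
spanning tree of the complete Euclidean graph and count the edges C that
join points from different samples.  The divergence estimate is

    D = max(0, 1 - C * (m + n) / (2 * m * n))

and the separability score S = (1 + D) / 2 lies in [0.5, 1]: 0.5 for
indistinguishable samples, 1 for completely separable samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

from cortsep.corrfeat import FeatureMatrix
from cortsep.io_atlas import CASE, CONTROL


def euclidean_mst(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Minimum spanning tree of the complete Euclidean graph.

    Kruskal's algorithm on the condensed distance list, with edges sorted
    by (weight, i, j): tied distances are broken lexicographically by
    point-index pair, so the tree is deterministic.

    Returns ``(edges, weights)`` where ``edges`` is an (N-1, 2) int array
    with each row (i, j), i < j.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    n = pts.shape[0]
    if n < 2:
        raise ValueError("need at least 2 points")
    if not np.all(np.isfinite(pts)):
        raise ValueError("non-finite coordinates")
    w = pdist(pts)
    ii, jj = np.triu_indices(n, 1)
    order = np.lexsort((jj, ii, w))

    parent = np.arange(n)

    def find(a: int) -> int:
        root = a
        while parent[root] != root:
            root = parent[root]
        while parent[a] != root:  # path compression
            parent[a], a = root, parent[a]
        return root

    edges = np.empty((n - 1, 2), dtype=int)
    weights = np.empty(n - 1)
    k = 0
    for o in order:
        a, b = find(int(ii[o])), find(int(jj[o]))
        if a != b:
            parent[a] = b
            edges[k] = ii[o], jj[o]
            weights[k] = w[o]
            k += 1
            if k == n - 1:
                break
    return edges, weights


def cross_edge_count(edges: np.ndarray, labels: np.ndarray) -> int:
    """Number of MST edges whose endpoints carry different sample labels."""
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("labels must cover both samples")
    edges = np.asarray(edges, dtype=int)
    return int(np.sum(labels[edges[:, 0]] != labels[edges[:, 1]]))


@dataclass(frozen=True)
class HPDResult:
    """MST cross-edge count with divergence and separability scores."""

    m: int
    n: int
    cross_edges: int
    divergence: float
    separability: float

    def __post_init__(self) -> None:
        if not 1 <= self.cross_edges <= self.m + self.n - 1:
            raise ValueError("cross-edge count outside [1, m + n - 1]")
        if not 0.5 - 1e-12 <= self.separability <= 1 + 1e-12:
            raise ValueError("separability outside [0.5, 1]")


def hp_divergence(case_points: np.ndarray, control_points: np.ndarray) -> HPDResult:
    """Henze-Penrose divergence and separability of two point samples."""
    X = np.atleast_2d(np.asarray(case_points, dtype=float))
    Y = np.atleast_2d(np.asarray(control_points, dtype=float))
    if X.shape[1] != Y.shape[1]:
        raise ValueError(f"dimension mismatch: {X.shape[1]} vs {Y.shape[1]}")
    m, n = X.shape[0], Y.shape[0]
    if m < 2 or n < 2:
        raise ValueError("each sample needs at least 2 points")
    pooled = np.vstack([X, Y])
    labels = np.r_[np.zeros(m, dtype=int), np.ones(n, dtype=int)]
    edges, _ = euclidean_mst(pooled)
    c = cross_edge_count(edges, labels)
    divergence = max(0.0, 1.0 - c * (m + n) / (2.0 * m * n))
    separability = (1.0 + divergence) / 2.0
    return HPDResult(m, n, c, divergence, separability)


@dataclass
class SeparabilityCurve:
    """Separability as a function of the number of leading features used."""

    feature_counts: np.ndarray
    separability_values: np.ndarray

    def __post_init__(self) -> None:
        self.feature_counts = np.asarray(self.feature_counts, dtype=int)
        self.separability_values = np.asarray(self.separability_values, dtype=float)
        if self.feature_counts.shape != self.separability_values.shape:
            raise ValueError("curve arrays length mismatch")
        if np.any((self.separability_values < 0.5 - 1e-12) | (self.separability_values > 1 + 1e-12)):
            raise ValueError("separability values outside [0.5, 1]")

    @property
    def final_value(self) -> float:
        return float(self.separability_values[-1])


def hpd_feature_curve(feature_matrix: FeatureMatrix) -> SeparabilityCurve:
    """Cumulative separability over the ranked features.

    For j = 1..k, computes the Henze-Penrose separability between the case
    and control rows restricted to the first j (highest-ranked) feature
    columns.
    """
    labels = feature_matrix.label_array()
    case_rows = feature_matrix.values[labels == CASE]
    control_rows = feature_matrix.values[labels == CONTROL]
    k = feature_matrix.features.k
    values = np.empty(k)
    for j in range(1, k + 1):
        values[j - 1] = hp_divergence(case_rows[:, :j], control_rows[:, :j]).separability
    return SeparabilityCurve(np.arange(1, k + 1), values)
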