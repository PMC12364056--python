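"""Brute-force reference implementations for validating the closed forms.

Everything here enumerates subsets or builds boundary matrices explicitly and
is guarded to small vertex counts; it exists so the production fast paths
(closed-form facet barcodes, gap-pair graded Betti numbers, the persistent
h-vector shortcut) can be checked against independent combinatorics in tests.
Homology is computed over GF(2), which suffices for the rank and vanishing
statements asserted about 1-D Rips complexes.
"""

from __future__ import annotations

from itertools import combinations
from typing import Hashable, Iterable, Sequence

import numpy as np

MAX_VERTICES = 14


class SmallComplex:
    """An abstract simplicial complex given by its faces (downward closed)."""

    def __init__(self, vertices: Iterable[Hashable], simplices: Iterable[Iterable[Hashable]]):
        self.vertices = tuple(vertices)
        if len(self.vertices) > MAX_VERTICES:
            raise ValueError(f"oracle guard: > {MAX_VERTICES} vertices")
        faces: set[frozenset] = {frozenset()}
        for s in simplices:
            s = frozenset(s)
            for r in range(len(s) + 1):
                faces.update(frozenset(c) for c in combinations(s, r))
        self.faces = faces

    @classmethod
    def from_facets(cls, facets: Iterable[Iterable[Hashable]]) -> "SmallComplex":
        facets = [frozenset(f) for f in facets]
        verts = sorted(set().union(*facets)) if facets else []
        return cls(verts, facets)

    def induced(self, W: Iterable[Hashable]) -> "SmallComplex":
        W = frozenset(W)
        return SmallComplex(sorted(W), [f for f in self.faces if f <= W])

    def faces_of_dim(self, q: int) -> list[frozenset]:
        return sorted((f for f in self.faces if len(f) == q + 1), key=sorted)


def brute_facets(points: Sequence[float], t: float) -> list[frozenset]:
    """Maximal subsets of diameter <= t, by exhaustive subset enumeration."""
    pts = list(points)
    if len(pts) > MAX_VERTICES:
        raise ValueError("oracle guard exceeded")
    admissible = [
        frozenset(c)
        for r in range(1, len(pts) + 1)
        for c in combinations(pts, r)
        if max(c) - min(c) <= t
    ]
    return [s for s in admissible if not any(s < other for other in admissible)]


def vr_complex(points: Sequence[float], t: float) -> SmallComplex:
    """The full Rips complex at scale t, built from brute-force facets."""
    return SmallComplex(sorted(points), brute_facets(points, t))


def _gf2_rank(M: np.ndarray) -> int:
    M = M.copy() % 2
    rank = 0
    rows, cols = M.shape
    for c in range(cols):
        pivot = next((r for r in range(rank, rows) if M[r, c]), None)
        if pivot is None:
            continue
        M[[rank, pivot]] = M[[pivot, rank]]
        for r in range(rows):
            if r != rank and M[r, c]:
                M[r] ^= M[rank]
        rank += 1
        if rank == rows:
            break
    return rank


def _boundary_matrix(cx: SmallComplex, q: int) -> np.ndarray:
    """GF(2) boundary from q-faces to (q-1)-faces of the augmented chain complex."""
    rows = cx.faces_of_dim(q - 1)  # q = 0 -> single empty face (augmentation)
    cols = cx.faces_of_dim(q)
    M = np.zeros((len(rows), len(cols)), dtype=np.uint8)
    idx = {f: i for i, f in enumerate(rows)}
    for j, f in enumerate(cols):
        for v in f:
            M[idx[f - {v}], j] = 1
    return M


def reduced_betti(cx: SmallComplex, q: int) -> int:
    """dim of reduced simplicial homology in degree q over GF(2)."""
    if q < 0:
        return 0
    n_q = len(cx.faces_of_dim(q))
    rank_dq = _gf2_rank(_boundary_matrix(cx, q))
    rank_dq1 = _gf2_rank(_boundary_matrix(cx, q + 1))
    return n_q - rank_dq - rank_dq1


def betti(cx: SmallComplex, q: int) -> int:
    """Non-reduced Betti number; in degree 0 this is the component count."""
    return reduced_betti(cx, q) + (1 if q == 0 else 0)


def hochster_betti(cx: SmallComplex, i: int, j: int) -> int:
    """Graded Betti number β_{i,i+j} by direct Hochster subset-sums.

    For j = 1 this is Σ_{|W|=i+1} (β_0(Δ_W) - 1); for j >= 2 it is
    Σ_{|W|=i+j} β_{j-1}(Δ_W).
    """
    if i < 1 or j < 1:
        raise ValueError("hochster_betti expects i >= 1, j >= 1")
    total = 0
    for W in combinations(cx.vertices, i + j):
        sub = cx.induced(W)
        total += betti(sub, 0) - 1 if j == 1 else betti(sub, j - 1)
    return total


def persistent_component_rank(
    points: Sequence[float], W: Iterable[float], t: float, t2: float
) -> int:
    """Rank of H~_0(Δ_W^t) -> H~_0(Δ_W^{t2}) via union-find merge tracking."""
    if t > t2:
        raise ValueError(f"need t <= t2, got t={t}, t2={t2}")
    W = sorted(W)
    if not set(W) <= set(points):
        raise ValueError("W must be a subset of the point cloud")
    if not W:
        return 0

    def component_reps(scale: float) -> list[int]:
        parent = list(range(len(W)))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for a in range(len(W)):
            for b in range(a + 1, len(W)):
                if abs(W[b] - W[a]) <= scale:
                    parent[find(a)] = find(b)
        return [find(x) for x in range(len(W))]

    reps_t, reps_t2 = component_reps(t), component_reps(t2)
    # image of each t-component inside the t2-partition; the map on reduced H0
    # has rank (#distinct images) - 1
    images = {reps_t2[rep] for rep in set(reps_t)}
    return len(images) - 1


def persistent_graded_betti_bruteforce(
    points: Sequence[float], t: float, t2: float, i: int
) -> int:
    """β_{i,i+1}(t,t2) as the direct subset-sum of persistent component ranks."""
    pts = sorted(points)
    if len(pts) > MAX_VERTICES:
        raise ValueError("oracle guard exceeded")
    return sum(
        persistent_component_rank(pts, W, t, t2) for W in combinations(pts, i + 1)
    )
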