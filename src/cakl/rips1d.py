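"""Exact Vietoris-Rips machinery for 1-D point clouds.

For a finite set ``X = {x_1 < ... < x_n} ⊂ ℝ`` the Rips complex at scale ``t``
(closed edge rule ``|x - y| <= t``) has a very rigid structure: every facet is
a maximal run of consecutive sorted points of diameter <= t, and is uniquely
determined by its minimal element.  This makes facet enumeration, facet
barcodes and face counting available in closed form — no boundary matrices.

Facet life intervals are half-open ``[birth, death)``: a facet is alive at its
birth scale and gone at its death scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb, inf
from typing import Sequence


def _check_points(points: Sequence[float]) -> list[float]:
    pts = list(points)
    if any(b <= a for a, b in zip(pts, pts[1:])):
        raise ValueError("points must be sorted strictly increasing (ties not allowed)")
    return pts


@dataclass(frozen=True)
class Facet:
    """A maximal simplex: a contiguous index run [a, b] into the sorted points."""

    a: int
    b: int
    birth: float
    death: float  # math.inf for the facet on the full point set

    @property
    def dim(self) -> int:
        return self.b - self.a

    def alive_at(self, t: float) -> bool:
        return self.birth <= t < self.death


@dataclass(frozen=True)
class FacetBarcode:
    """All facet life intervals of the filtration on one point cloud."""

    points: tuple[float, ...]
    facets: tuple[Facet, ...]

    def alive(self, t: float) -> list[Facet]:
        return [f for f in self.facets if f.alive_at(t)]


def facets_at_scale(points: Sequence[float], t: float) -> list[tuple[int, int]]:
    """Index intervals [a, b] of the facets of VR_t, ordered by minimal vertex.

    The run from ``a`` extends to the largest ``j`` with ``x_j - x_a <= t``; it
    is maximal (a facet) iff it is not contained in the run from ``a - 1``.
    """
    if t < 0:
        raise ValueError("scale t must be >= 0")
    pts = _check_points(points)
    n = len(pts)
    out: list[tuple[int, int]] = []
    j = 0
    for a in range(n):
        if j < a:
            j = a
        while j + 1 < n and pts[j + 1] - pts[a] <= t:
            j += 1
        if a == 0 or pts[j] - pts[a - 1] > t:
            out.append((a, j))
    return out


def facet_barcode(points: Sequence[float]) -> FacetBarcode:
    """Birth/death of every facet over the whole filtration.

    The run sigma = {x_a, ..., x_b} is a facet exactly for scales in
    [x_b - x_a, min(x_{b+1} - x_a, x_b - x_{a-1})); runs with an empty
    interval are never facets.
    """
    pts = _check_points(points)
    n = len(pts)
    facets: list[Facet] = []
    for a in range(n):
        for b in range(a, n):
            birth = pts[b] - pts[a]
            death = inf
            if b + 1 < n:
                death = pts[b + 1] - pts[a]
            if a > 0:
                death = min(death, pts[b] - pts[a - 1])
            if birth < death:
                facets.append(Facet(a=a, b=b, birth=birth, death=death))
    facets.sort(key=lambda f: (f.a, f.b))
    return FacetBarcode(points=tuple(pts), facets=tuple(facets))


def run_lengths_at_scale(points: Sequence[float], t: float) -> list[int]:
    """For each index a, the length of the maximal run starting at a within diameter t."""
    pts = _check_points(points)
    n = len(pts)
    lengths = []
    j = 0
    for a in range(n):
        if j < a:
            j = a
        while j + 1 < n and pts[j + 1] - pts[a] <= t:
            j += 1
        lengths.append(j - a + 1)
    return lengths


def complex_dimension(points: Sequence[float], t: float) -> int:
    """dim VR_t = (largest run length) - 1; -1 for the empty point set."""
    if len(points) == 0:
        return -1
    return max(run_lengths_at_scale(points, t)) - 1


def f_vector_at_scale(points: Sequence[float], t: float, dmax: int | None = None) -> list[int]:
    """Face counts (f_{-1}, f_0, ..., f_{d-1}) of VR_t, optionally capped at dmax.

    Every (i+1)-subset of diameter <= t is counted once at its minimal
    element: a run of length L starting at a contributes C(L-1, i) subsets of
    dimension i with minimum x_a.
    """
    if t < 0:
        raise ValueError("scale t must be >= 0")
    if len(points) == 0:
        return [1]
    lengths = run_lengths_at_scale(points, t)
    d = max(lengths)  # top face has d vertices, dimension d-1
    top = d if dmax is None else min(d, dmax)
    fv = [1] + [0] * top
    for L in lengths:
        for i in range(min(L - 1, top - 1) + 1):
            fv[i + 1] += comb(L - 1, i)
    return fv


def component_count(points: Sequence[float], t: float) -> int:
    """Number of connected components of VR_t: 1 + number of gaps > t."""
    if t < 0:
        raise ValueError("scale t must be >= 0")
    pts = _check_points(points)
    if not pts:
        return 0
    return 1 + sum(1 for a, b in zip(pts, pts[1:]) if b - a > t)


def write_barcode_tsv(barcode: FacetBarcode, path) -> None:
    """Export bars as TSV: facet-min, facet-max, dim, birth, death."""
    with open(path, "w") as fh:
        fh.write("facet_min\tfacet_max\tdim\tbirth\tdeath\n")
        for f in barcode.facets:
            death = "inf" if f.death == inf else repr(f.death)
            fh.write(
                f"{barcode.points[f.a]!r}\t{barcode.points[f.b]!r}\t{f.dim}\t{f.birth!r}\t{death}\n"
            )
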