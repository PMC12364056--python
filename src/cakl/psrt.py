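"""Persistent Stanley-Reisner invariants of 1-D Rips filtrations.

The Stanley-Reisner ideal of the Rips complex at scale ``t`` decomposes into
prime components, one per facet; tracking the components shared by two scales
``t <= t'`` gives the facet persistent numbers.  The graded Betti numbers of
the quotient ring are, by Hochster's formula, sums of reduced homology ranks
of induced subcomplexes; in the 1-D setting only the degree-shift-one entries
β_{i,i+1} survive and they admit a polynomial-time gap-pair evaluation (no
free resolutions are ever built).  Classical and persistent f-/h-vectors are
recovered from these via exact integer binomial transforms.

Conventions: ``C(a, 0) = 1`` for every integer ``a`` (including negative, so
that the leading coefficient α_m^m is 1 and h_0 ≡ 1 holds on the full
simplex); ``C(a, b) = 0`` for ``b < 0`` or ``b > max(a, 0)``.  All arithmetic
is exact integer arithmetic.
"""

from __future__ import annotations

from math import comb
from typing import Sequence

import numpy as np

from .rips1d import (
    FacetBarcode,
    _check_points,
    complex_dimension,
    f_vector_at_scale,
)

__all__ = [
    "binom",
    "facet_persistent_number",
    "facet_count_curve",
    "graded_betti_j1",
    "persistent_graded_betti",
    "h_from_f",
    "f_from_h",
    "h_vector_at_scale",
    "persistent_h_vector",
    "persistent_f_vector",
]


def binom(a: int, b: int) -> int:
    """Binomial coefficient with C(a, 0) = 1 for all a, zero outside 0 <= b <= a."""
    if b == 0:
        return 1
    if b < 0 or a < b:
        return 0
    return comb(a, b)


def facet_persistent_number(barcode: FacetBarcode, i: int, t: float, t2: float) -> int:
    """Number of dimension-``i`` facet primes alive at both scales ``t <= t2``.

    A facet prime persists from t to t2 iff its half-open life interval
    contains both, i.e. birth <= t and death > t2.
    """
    if t > t2:
        raise ValueError(f"need t <= t2, got t={t}, t2={t2}")
    return sum(1 for f in barcode.facets if f.dim == i and f.birth <= t and f.death > t2)


def facet_count_curve(
    barcode: FacetBarcode, grid: Sequence[float], dmax: int
) -> np.ndarray:
    """Alive-facet counts per dimension over a scale grid.

    Returns an integer matrix of shape (dmax, len(grid)); row ``i < dmax - 1``
    counts alive facets of dimension exactly ``i`` and the last row is an
    overflow bucket accumulating all facets of dimension >= dmax - 1.
    """
    if dmax < 1:
        raise ValueError("dmax must be >= 1")
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or len(grid) == 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be nonempty and sorted strictly increasing")
    F = np.zeros((dmax, len(grid)), dtype=np.int64)
    for f in barcode.facets:
        # alive on [birth, death): grid indices with birth <= r < death
        lo = int(np.searchsorted(grid, f.birth, side="left"))
        hi = int(np.searchsorted(grid, f.death, side="left"))
        if lo < hi:
            F[min(f.dim, dmax - 1), lo:hi] += 1
    return F


def graded_betti_j1(points: Sequence[float], t: float, i: int) -> int:
    """β_{i,i+1} of the Stanley-Reisner ring of VR_t, for i >= 1.

    Hochster's formula reduces this to Σ_W (components(Δ_W^t) - 1) over all
    (i+1)-subsets W.  Each "break" in W is a consecutive-in-W pair (a, b)
    with x_b - x_a > t; summing over subsets instead sums over index pairs:
    a pair a < b with x_b - x_a > t is a break of C(n - (b - a + 1), i - 1)
    subsets (the other i - 1 members avoid the open interval).
    """
    if i < 1:
        raise ValueError("graded_betti_j1 is defined for i >= 1")
    if t < 0:
        raise ValueError("scale t must be >= 0")
    pts = _check_points(points)
    n = len(pts)
    total = 0
    for a in range(n):
        for b in range(a + 1, n):
            if pts[b] - pts[a] > t:
                total += binom(n - (b - a + 1), i - 1)
    return total


def persistent_graded_betti(
    points: Sequence[float], t: float, t2: float, i: int, j: int
) -> int:
    """Persistent graded Betti number β_{i,i+j}(t, t2) of a 1-D Rips filtration.

    Structural facts used: β_{0,0} = 1; β_{i,i} = 0 for i >= 1; β_{0,j} = 0
    for j >= 1; and in ambient dimension one every induced subcomplex has
    vanishing homology above degree zero, so β_{i,i+j} = 0 for all j >= 2.
    For j = 1 the inclusion Δ_W^t ⊆ Δ_W^{t2} on a fixed vertex set induces a
    surjection on reduced degree-0 homology, hence the persistent value
    equals the static value at t2 (validated against the union-find oracle
    in the test suite).
    """
    if t > t2:
        raise ValueError(f"need t <= t2, got t={t}, t2={t2}")
    if i < 0 or j < 0:
        raise ValueError("indices i, j must be >= 0")
    if j == 0:
        return 1 if i == 0 else 0
    if i == 0 or j >= 2:
        return 0
    return graded_betti_j1(points, t2, i)


def _check_f(f: Sequence[int]) -> list[int]:
    f = list(f)
    if not f or f[0] != 1:
        raise ValueError("f-vector must start with f_{-1} = 1")
    return f


def h_from_f(f: Sequence[int], d: int) -> list[int]:
    """h-vector (h_0..h_d) from the f-vector (f_{-1}..f_{d-1}).

    h_m = Σ_{j=0}^m (-1)^{m-j} C(d-j, m-j) f_{j-1}.
    """
    f = _check_f(f)
    fget = lambda j: f[j] if j < len(f) else 0
    return [
        sum((-1) ** (m - j) * binom(d - j, m - j) * fget(j) for j in range(m + 1))
        for m in range(d + 1)
    ]


def f_from_h(h: Sequence[int], d: int) -> list[int]:
    """Inverse transform: f_{m-1} = Σ_{i=0}^m C(d-i, m-i) h_i for m = 0..d."""
    h = list(h)
    hget = lambda i: h[i] if i < len(h) else 0
    return [
        sum(binom(d - i, m - i) * hget(i) for i in range(m + 1)) for m in range(d + 1)
    ]


def h_vector_at_scale(points: Sequence[float], t: float) -> list[int]:
    """Classical h-vector of VR_t via the f->h transform."""
    if len(points) == 0:
        return [1]
    d = complex_dimension(points, t) + 1
    return h_from_f(f_vector_at_scale(points, t), d)


def persistent_h_vector(points: Sequence[float], t: float, t2: float) -> list[int]:
    """Persistent h-vector (h_0(t,t2), ..., h_d(t,t2)), d = dim(VR_{t2}) + 1.

    h_m(t,t2) = α_0^m + Σ_{j=1}^m α_j^m (-1)^{j-1} β_{j-1,j}(t,t2) with
    α_j^m = C(n - d + m - j - 1, m - j).  β_{0,1} = 0, so the j = 1 term
    always vanishes; h_0 = α_0^0 = 1.
    """
    if t > t2:
        raise ValueError(f"need t <= t2, got t={t}, t2={t2}")
    pts = _check_points(points)
    n = len(pts)
    if n == 0:
        return [1]
    d = complex_dimension(pts, t2) + 1
    betti = {j: persistent_graded_betti(pts, t, t2, j - 1, 1) for j in range(2, d + 1)}
    out = []
    for m in range(d + 1):
        alpha = lambda j: binom(n - d + m - j - 1, m - j)
        h_m = alpha(0)
        for j in range(2, m + 1):
            h_m += alpha(j) * (-1) ** (j - 1) * betti[j]
        out.append(h_m)
    return out


def persistent_f_vector(h: Sequence[int], d: int) -> list[int]:
    """Persistent f-vector from a persistent h-vector: the same inverse transform."""
    return f_from_h(h, d)
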