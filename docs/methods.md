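# Methods

## Model

A sequence is reduced, per k-mer, to the set of occurrence positions
S_x ⊆ {1, …, N−k+1} (1-based, overlapping occurrences all counted, forward
strand only). Each S_x is a finite subset of ℝ and is filtered by the
Vietoris–Rips complex with the *closed* edge rule: two positions are adjacent
at scale t iff |i − j| ≤ t. The closed rule is what makes the worked primer
statements literal: the isolated cytosine's edge is alive *at* radius 5 and 6
and gone at 7, because facet life intervals are half-open [birth, death).

In ambient dimension one the Rips complex is rigid: every facet is a maximal
run of consecutive sorted points of diameter ≤ t and is uniquely determined
by its minimal element. This gives closed forms used throughout:

- the run σ = {x_a, …, x_b} is a facet exactly on the scale interval
  [x_b − x_a, min(x_{b+1} − x_a, x_b − x_{a−1})) (+∞ when no neighbor
  exists); enumerating all O(n²) contiguous runs with nonempty intervals
  yields the complete facet barcode;
- f_i(t) = Σ_a C(L_a − 1, i), where L_a is the run length starting at index
  a, because every (i+1)-subset of diameter ≤ t is counted once at its
  minimal element;
- every 1-D Rips complex has vanishing reduced homology in all degrees ≥ 1
  (Mayer–Vietoris induction over facets ordered by their minima), so the
  graded Betti numbers of the Stanley–Reisner ring vanish for all degree
  shifts j ≥ 2 and β_{i,i+1} is determined by the 1-skeleton alone;
- β_{i,i+1}(t) = Σ_{a<b, x_b − x_a > t} C(n − (b − a + 1), i − 1): a gap
  pair (a, b) is a "break" of exactly that many (i+1)-subsets. This replaces
  the exponential Hochster subset-sum Σ_W (components(Δ_W) − 1);
- for the persistent value β_{i,i+1}(t, t′): the inclusion Δ_W^t ⊆ Δ_W^{t′}
  on a fixed vertex set induces a surjection on reduced degree-0 homology,
  so the persistent rank sum equals the static value at t′. This shortcut is
  not proved in closed form here; it is gated by tests that compare it with
  an independent union-find rank computation on random instances.

Persistent h-vectors follow the alternating-sum identity
h_m(t,t′) = α_0^m + Σ_{j≥2} α_j^m (−1)^{j−1} β_{j−1,j}(t,t′) with
α_j^m = C(n − d + m − j − 1, m − j) and d = dim(Δ^{t′}) + 1, and persistent
f-vectors are the inverse binomial transform of h. On the diagonal t = t′
these reduce exactly to the classical f/h-vectors (asserted in tests over
random instances, in integer arithmetic).

Numerical conventions worth stating:

- **Binomials.** C(a, 0) = 1 for *every* integer a, including negative;
  C(a, b) = 0 for b < 0 or b > a. The negative-argument case occurs only as
  α_m^m = C(−1, 0) when the complex is a full simplex (n = d), where the
  identities h_0 ≡ 1 and α_m^m = 1 force the value 1. All Betti/f/h
  computations are exact integers; no floats.
- **d index.** The persistent transforms use d = dim(Δ^{t′}) + 1, i.e. the
  *later* scale; this is the reading under which the diagonal case reduces to
  the classical vectors, which the tests verify.
- **Ties.** Distinct occurrence positions are guaranteed by construction;
  the filtration modules reject tied points rather than deduplicate.
- **Off-diagonal vectors** may be non-integer-monotone or negative; they are
  emitted as computed, never clamped. Production featurization uses the
  diagonal r = r′ only.

## Featurization

Per k-mer and feature type, a (dmax × |grid|) curve matrix is sampled:
facet counts per dimension (default), classical f-vector entries f_0..f_{dmax−1},
or h-vector entries h_0..h_{dmax−1}. Defaults: k = 4 (the word length that
performs best for the classification protocol), radius grid 0..50 in unit
steps, dmax = 5. Because positions are integers, all birth/death scales are
integers and the unit grid is lossless up to radius 50; the grid bound and
dmax are configuration, echoed into output metadata. Facets of dimension
≥ dmax − 1 accumulate in the last row (overflow bucket) so the layout stays
fixed — dense k-mer clusters otherwise create unboundedly high-dimensional
facets. An empty position set maps to an all-zero block; a singleton
contributes a constant row of ones in dimension 0. Curves are raw counts;
division by sequence length is available behind a flag (off by default).
All invariants depend only on pairwise position gaps, so representations are
translation-invariant — verified by property test.

## Distances

For one feature type, d(S₁,S₂) = √(Σ_k Σ_i a_{k,i} ‖Δv_{i,k}‖²) — a weighted
Euclidean metric (the square root is applied to the total; without it the
form is not a metric). The composite distance sums the per-type metrics and
is therefore itself a metric. Weight schemes: uniform; a_{k,i} = 1/2^{k−1}
(default — with a single k it is a global rescale and cannot change neighbor
ranks, also property-tested); a_{k,i} = 1/2^{i·K + k − 1}. Accumulation is
plain double precision; curve entries are small integers, so cancellation is
negligible against the 1e-9 relative tolerance used in equality tests.

## Trees and purity

UPGMA with average linkage; merge height = distance/2; among tied minimal
pairs the pair whose smallest member id (then partner id) sorts first is
merged, and children are ordered by smallest leaf id — full determinism
across platforms. Heights are cross-checked against SciPy average linkage on
tie-free instances. Purity is evaluated on the rooted UPGMA tree as produced
(no rerooting): maximal subtrees whose leaves all carry label ℓ define the
block partition; singleton blocks are legitimate. purity ∈ (0, 1], equal to
1 iff the label is monophyletic; the average over labels is unweighted.

## Classification protocols

1-NN is realized as leave-one-out over the full distance matrix (each sample
annotated by its nearest other sample; distance ties go to the smallest id).
5-NN uses stratified 5-fold cross-validation repeated over the canonical
seed list 0..29; vote ties are broken by the smaller summed neighbor
distance, then the lexicographically smaller class name. Accuracy is plain
(micro); balanced accuracy, F1, recall, precision are macro-averaged so small
families weigh equally — balanced accuracy equals macro-recall by definition,
asserted on every report. Classes below 15 members are dropped before
evaluation (configurable).

## Synthetic data generator

Each family descends from an independent uniform-random ancestor; members
apply i.i.d. per-site substitutions, uniform over the three alternative bases
(a Jukes–Cantor-like neutral model), and optionally indel events (length
uniform in [1, max]; off by default). Defaults — 4 families × 10 members,
length 3000, substitution rate 0.01 — give families whose within-family
distances are well below between-family distances, so ground truth for tree
purity and neighbor recovery is unambiguous. The generator is seeded per
family, making ancestors a function of (seed, family index, length) alone.

What the generator does *not* emulate: rate heterogeneity across sites,
coalescent within-family structure, recombination, base-composition bias,
sequencing error, and real viral genome organization. Passing the recovery
tests therefore shows the pipeline separates independently drifted families
at 1% divergence — it does not certify performance on real taxonomies, whose
label structure is far less separable.

## Problem sizes

Unit and property tests run on point clouds of n ≤ 10 (where brute-force
subset enumeration and GF(2) boundary-matrix homology serve as oracles) and
on the 40-sequence synthetic benchmark above; the brute-force oracle module
refuses inputs beyond 14 vertices by design. These sizes were chosen so the
oracle comparisons are exhaustive rather than sampled.

## Known limitations

- The closed-form machinery is inherently 1-D; the facet/minimum bijection
  fails already for planar point sets, so no higher-dimensional ambient
  support is provided or planned.
- Ambiguity codes are preserved in sequences but any window containing one
  matches no k-mer; heavily masked genomes therefore lose windows.
- Only the forward strand is scanned; no reverse-complement collapsing.
- Multi-k aggregation is implemented in the distance layer but the tooling
  runs one k at a time; ensembles are left to the caller.
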