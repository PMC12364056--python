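"""UPGMA tree inference, Newick export, and monophyly purity scoring.

Purity measures how concentrated a label's leaves are inside single-label
subtrees of a rooted tree.  For label ℓ with n_ℓ leaves, the maximal subtrees
whose leaves all carry ℓ partition those leaves into blocks S_1..S_k and

    purity(ℓ) = sum_i (|S_i| / n_ℓ)^2 ,

which is 1 exactly when ℓ is monophyletic and 1/n_ℓ when every leaf is
isolated.  The average over labels summarizes taxonomic coherence of the tree
without needing a reference topology.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .distance import DistanceMatrix


@dataclass
class TreeNode:
    """Node of a rooted (binary, under UPGMA) tree with ultrametric heights."""

    name: str | None = None  # leaf id; None for internal nodes
    height: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [l.name for l in self.leaves()]

    def postorder(self):
        for c in self.children:
            yield from c.postorder()
        yield self


def upgma(dm: DistanceMatrix) -> TreeNode:
    """Average-linkage agglomeration into a rooted ultrametric tree.

    At each step the pair of clusters at minimal average distance is merged at
    height d/2.  Ties are broken deterministically by merging the pair whose
    (lexicographically smallest member id, then partner id) sorts first.
    """
    n = len(dm.ids)
    if n < 2:
        raise ValueError("UPGMA needs at least 2 leaves")
    D = np.asarray(dm.D, dtype=float)
    if np.isnan(D).any() or (D < 0).any():
        raise ValueError("distance matrix must be nonnegative and NaN-free")

    clusters: dict[int, TreeNode] = {
        i: TreeNode(name=sid) for i, sid in enumerate(dm.ids)
    }
    sizes = {i: 1 for i in range(n)}
    keys = {i: dm.ids[i] for i in range(n)}  # smallest leaf id in the cluster
    dist = {(min(i, j), max(i, j)): D[i, j] for i in range(n) for j in range(i + 1, n)}
    next_id = n

    while len(clusters) > 1:
        live = sorted(clusters)
        best = min(
            ((i, j) for a, i in enumerate(live) for j in live[a + 1 :]),
            key=lambda p: (dist[p], tuple(sorted((keys[p[0]], keys[p[1]])))),
        )
        i, j = best
        d = dist[(i, j)]
        first, second = (i, j) if keys[i] <= keys[j] else (j, i)
        node = TreeNode(height=d / 2.0, children=[clusters[first], clusters[second]])
        for other in clusters:
            if other in (i, j):
                continue
            di = dist[(min(i, other), max(i, other))]
            dj = dist[(min(j, other), max(j, other))]
            merged = (sizes[i] * di + sizes[j] * dj) / (sizes[i] + sizes[j])
            dist[(min(other, next_id), max(other, next_id))] = merged
        sizes[next_id] = sizes[i] + sizes[j]
        keys[next_id] = min(keys[i], keys[j])
        clusters[next_id] = node
        for x in (i, j):
            del clusters[x], sizes[x], keys[x]
        next_id += 1
    return clusters.popitem()[1]


def _newick_label(name: str) -> str:
    if any(c in name for c in " \t(),:;'[]"):
        return "'" + name.replace("'", "''") + "'"
    return name


def write_newick(tree: TreeNode, path: str | Path | None = None) -> str:
    """Serialize with branch lengths (parent height - child height)."""

    def render(node: TreeNode, parent_height: float | None) -> str:
        if node.is_leaf:
            body = _newick_label(node.name)
        else:
            body = "(" + ",".join(render(c, node.height) for c in node.children) + ")"
        if parent_height is None:
            return body
        return f"{body}:{float(parent_height - node.height)!r}"

    s = render(tree, None) + ";"
    if path is not None:
        Path(path).write_text(s + "\n")
    return s


@dataclass(frozen=True)
class LabeledPartition:
    """Blocks of one label's leaves induced by its maximal pure subtrees."""

    label: str
    blocks: tuple[tuple[str, ...], ...]

    @property
    def n(self) -> int:
        return sum(len(b) for b in self.blocks)

    @property
    def block_sizes(self) -> list[int]:
        return [len(b) for b in self.blocks]


@dataclass(frozen=True)
class PurityResult:
    per_label: dict[str, float]
    partitions: dict[str, LabeledPartition]

    @property
    def average(self) -> float:
        return float(np.mean(list(self.per_label.values())))


def partition_purity(block_sizes: Sequence[int], n: int) -> float:
    """sum over blocks of (size/n)^2 for a partition of an n-element set."""
    if any(s <= 0 for s in block_sizes):
        raise ValueError("block sizes must be positive")
    if sum(block_sizes) != n:
        raise ValueError(f"block sizes sum to {sum(block_sizes)}, expected n={n}")
    return float(sum((s / n) ** 2 for s in block_sizes))


def _pure_blocks(tree: TreeNode, labels: Mapping[str, str], label: str) -> list[list[str]]:
    """Leaf sets of the maximal subtrees labeled exclusively ``label``."""
    pure: dict[int, bool] = {}
    for node in tree.postorder():
        if node.is_leaf:
            if node.name not in labels:
                raise ValueError(f"leaf {node.name!r} has no label")
            pure[id(node)] = labels[node.name] == label
        else:
            pure[id(node)] = all(pure[id(c)] for c in node.children)

    blocks: list[list[str]] = []

    def collect(node: TreeNode) -> None:
        if pure[id(node)]:
            blocks.append(node.leaf_names())
        else:
            for c in node.children:
                collect(c)

    collect(tree)
    return blocks


def label_purity(
    tree: TreeNode, labels: Mapping[str, str], label: str
) -> tuple[float, LabeledPartition]:
    """Purity of one label and the underlying block partition."""
    blocks = _pure_blocks(tree, labels, label)
    if not blocks:
        raise ValueError(f"label {label!r} not present among the leaves")
    part = LabeledPartition(label=label, blocks=tuple(tuple(b) for b in blocks))
    return partition_purity(part.block_sizes, part.n), part


def avg_purity(tree: TreeNode, labels: Mapping[str, str]) -> PurityResult:
    """Unweighted mean of per-label purities over all distinct labels."""
    leaf_names = tree.leaf_names()
    missing = [l for l in leaf_names if l not in labels]
    if missing:
        raise ValueError(f"unlabeled leaves: {missing[:5]}")
    distinct = sorted({labels[l] for l in leaf_names})
    per_label: dict[str, float] = {}
    partitions: dict[str, LabeledPartition] = {}
    for lab in distinct:
        per_label[lab], partitions[lab] = label_purity(tree, labels, lab)
    return PurityResult(per_label=per_label, partitions=partitions)


def write_purity_report(result: PurityResult, path: str | Path) -> None:
    """TSV: (label, n, num_blocks, purity) per label plus an average line."""
    with open(path, "w") as fh:
        fh.write("label\tn\tnum_blocks\tpurity\n")
        for lab in sorted(result.per_label):
            part = result.partitions[lab]
            fh.write(f"{lab}\t{part.n}\t{len(part.blocks)}\t{result.per_label[lab]:.6f}\n")
        fh.write(f"# avg_purity\t{result.average:.6f}\n")
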