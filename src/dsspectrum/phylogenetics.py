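"""Average-distance (UPGMA) tree on percent-identity distances.

The spectrum-of-activity report places the trigger species and each
non-target among their relatives with an ultrametric tree built from
d(i, j) = 100 - percent_identity(i, j), in percentage points, with the
unrounded identity. UPGMA (size-weighted average linkage) is used: the
closest pair of clusters is merged, the new node sits at height d/2, and
distances to the merged cluster are the size-weighted means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import AlignedPair, percent_identity
from .errors import ValidationError


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric identity-based distances in percentage points."""

    labels: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self):
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValidationError("duplicate taxon labels")
        if self.d.shape != (n, n):
            raise ValidationError("distance matrix shape mismatch")
        if not np.allclose(self.d, self.d.T, atol=1e-9):
            raise ValidationError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-9):
            raise ValidationError("distance matrix diagonal not zero")
        if (self.d < -1e-9).any():
            raise ValidationError("negative distances")

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.d[i, j])


@dataclass
class Node:
    """A rooted tree node; height is the distance from the node to its leaves."""

    label: str | None
    children: list["Node"] = field(default_factory=list)
    height: float = 0.0
    branch_length: float = 0.0
    parent_known: bool = False

    def leaves(self) -> list["Node"]:
        if not self.children:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class Tree:
    root: Node

    def leaf_labels(self) -> list[str]:
        return [leaf.label for leaf in self.root.leaves()]

    def leaf_depths(self) -> dict[str, float]:
        """Root-to-leaf path lengths (equal for an ultrametric tree)."""
        depths: dict[str, float] = {}

        def walk(node: Node, acc: float):
            acc += node.branch_length if node.parent_known else 0.0
            if not node.children:
                depths[node.label] = acc
            for c in node.children:
                walk(c, acc)

        walk(self.root, 0.0)
        return depths


def identity_distance_matrix(
    labels: list[str] | tuple[str, ...],
    pairs: dict[tuple[str, str], AlignedPair],
) -> DistanceMatrix:
    """Build d(i,j) = 100 - PID(i,j) from all pairwise alignments.

    ``pairs`` must contain every unordered label pair (either key order);
    the unrounded percent identity is used.
    """
    labels = tuple(labels)
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            key = (labels[i], labels[j])
            pair = pairs.get(key) or pairs.get((key[1], key[0]))
            if pair is None:
                raise ValidationError(f"missing alignment for pair {key}")
            d[i, j] = d[j, i] = 100.0 - percent_identity(pair, rounded=False)
    return DistanceMatrix(labels=labels, d=d)


def upgma(matrix: DistanceMatrix) -> Tree:
    """Size-weighted average-linkage agglomeration (classical UPGMA).

    Repeatedly merges the closest pair of clusters; the new cluster's
    distance to every other is the member-count-weighted mean, and the new
    node's height is half the merge distance. Ties are broken toward the
    lowest label-index pair for determinism.
    """
    n = len(matrix.labels)
    if n < 2:
        raise ValidationError("UPGMA requires at least 2 taxa")
    d = matrix.d.astype(float).copy()
    nodes: dict[int, Node] = {
        i: Node(label=lab) for i, lab in enumerate(matrix.labels)
    }
    sizes = {i: 1 for i in range(n)}
    min_leaf = {i: i for i in range(n)}  # for stable child ordering
    active = list(range(n))
    dist = {
        (i, j): float(d[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    next_id = n
    while len(active) > 1:
        # lowest-index pair among minima
        best = min(
            ((dist[(i, j)], i, j) for idx, i in enumerate(active) for j in active[idx + 1 :]),
            key=lambda t: (t[0], t[1], t[2]),
        )
        dmin, i, j = best
        height = dmin / 2.0
        for child_id in (i, j):
            child = nodes[child_id]
            child.branch_length = height - child.height
            child.parent_known = True
        first, second = (i, j) if min_leaf[i] <= min_leaf[j] else (j, i)
        new = Node(label=None, children=[nodes[first], nodes[second]], height=height)
        nodes[next_id] = new
        sizes[next_id] = sizes[i] + sizes[j]
        min_leaf[next_id] = min(min_leaf[i], min_leaf[j])
        active = [a for a in active if a not in (i, j)]
        for a in active:
            dij = lambda x, y: dist[(min(x, y), max(x, y))]
            dist[(min(a, next_id), max(a, next_id))] = (
                sizes[i] * dij(a, i) + sizes[j] * dij(a, j)
            ) / (sizes[i] + sizes[j])
        active.append(next_id)
        next_id += 1
    return Tree(root=nodes[active[0]])
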