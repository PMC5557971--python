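"""Neighbor-joining tree construction from a symmetric distance matrix.

Classical Saitou-Nei agglomeration: at each step the pair (i, j)
minimizing Q(i,j) = (n-2) d(i,j) - sum_k d(i,k) - sum_k d(j,k) is joined;
pendant lengths come from the standard two-point formulas and the new
node's distances from d(u,k) = (d(i,k) + d(j,k) - d(i,j)) / 2.  The
result is an unrooted tree emitted with one trifurcating internal node at
the final join.

Determinism: when several pairs share the minimal Q the lexicographically
smallest pair of subtree labels (each subtree is labelled by its smallest
leaf) is joined, so the output does not depend on input row order.
Negative estimated branch lengths are clamped to zero with the deficit
transferred to the sister branch, preserving the pair's summed length.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import InputError, ValidationError


@dataclass
class Node:
    name: str = ""
    length: float | None = None  # branch length to the parent
    children: list["Node"] = field(default_factory=list)

    def leaves(self) -> list["Node"]:
        if not self.children:
            return [self]
        return [leaf for c in self.children for leaf in c.leaves()]


@dataclass
class PhyloTree:
    """Unrooted tree (root is a display-only trifurcation)."""

    root: Node

    @property
    def leaf_names(self) -> list[str]:
        return sorted(leaf.name for leaf in self.root.leaves())

    def path_length_matrix(self) -> tuple[list[str], np.ndarray]:
        """Leaf-to-leaf path lengths (sorted label order)."""
        labels = self.leaf_names
        index = {name: i for i, name in enumerate(labels)}
        n = len(labels)
        d = np.zeros((n, n))

        def walk(node: Node) -> dict[int, float]:
            # distances from every leaf under `node` up to `node`
            if not node.children:
                return {index[node.name]: 0.0}
            below: dict[int, float] = {}
            child_maps = []
            for child in node.children:
                cmap = {k: v + (child.length or 0.0)
                        for k, v in walk(child).items()}
                child_maps.append(cmap)
            for a, b in itertools.combinations(child_maps, 2):
                for i, di in a.items():
                    for j, dj in b.items():
                        d[i, j] = d[j, i] = di + dj
            for cmap in child_maps:
                below.update(cmap)
            return below

        walk(self.root)
        return labels, d


def _validate(labels: Sequence[str], d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    n = len(labels)
    if d.shape != (n, n):
        raise InputError(f"matrix shape {d.shape} does not match {n} labels")
    if len(set(labels)) != n:
        raise InputError("duplicate taxon labels")
    if not np.all(np.isfinite(d)):
        raise ValidationError("distance matrix has non-finite entries")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValidationError("distance matrix is not symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-12):
        raise ValidationError("distance matrix diagonal is not zero")
    return d


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    # clamp-and-transfer: keep li + lj, forbid negative lengths
    if li < 0.0:
        lj += li
        li = 0.0
    if lj < 0.0:
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


def neighbor_joining(labels: Sequence[str], d: np.ndarray) -> PhyloTree:
    """Build the NJ tree for ``labels`` from symmetric distances ``d``.

    Requires a symmetric, zero-diagonal, finite matrix.  Two taxa yield the
    single connecting edge (split at the display root); three or more taxa
    yield the classical unrooted NJ tree with a trifurcating root.
    """
    d = _validate(labels, d)
    n = len(labels)
    if n < 2:
        raise InputError("neighbor joining needs at least 2 taxa")

    nodes: dict[str, Node] = {lab: Node(name=lab) for lab in labels}
    # each active cluster is keyed by its smallest leaf label
    active: list[str] = sorted(labels)
    dist: dict[tuple[str, str], float] = {}
    order = {lab: i for i, lab in enumerate(labels)}
    for a, b in itertools.combinations(labels, 2):
        key = (a, b) if a < b else (b, a)
        dist[key] = float(d[order[a], order[b]])

    def get(a: str, b: str) -> float:
        return dist[(a, b) if a < b else (b, a)]

    if n == 2:
        a, b = active
        half = get(a, b) / 2.0
        nodes[a].length = nodes[b].length = half
        return PhyloTree(root=Node(children=[nodes[a], nodes[b]]))

    while len(active) > 3:
        m = len(active)
        r = {a: sum(get(a, b) for b in active if b != a) for a in active}
        best_pair: tuple[str, str] | None = None
        best_q = np.inf
        for a, b in itertools.combinations(active, 2):  # lexicographic order
            q = (m - 2) * get(a, b) - r[a] - r[b]
            if q < best_q - 1e-15:
                best_q, best_pair = q, (a, b)
        assert best_pair is not None
        i, j = best_pair
        dij = get(i, j)
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = _clamp_pair(li, lj)
        nodes[i].length, nodes[j].length = li, lj
        parent_key = min(i, j)
        parent = Node(children=[nodes[i], nodes[j]])
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (get(i, k) + get(j, k) - dij)
            dist[(parent_key, k) if parent_key < k else (k, parent_key)] = duk
        active = sorted(set(active) - {i, j} | {parent_key})
        nodes[parent_key] = parent

    a, b, c = active
    la = 0.5 * (get(a, b) + get(a, c) - get(b, c))
    lb = 0.5 * (get(a, b) + get(b, c) - get(a, c))
    lc = 0.5 * (get(a, c) + get(b, c) - get(a, b))
    nodes[a].length = max(la, 0.0)
    nodes[b].length = max(lb, 0.0)
    nodes[c].length = max(lc, 0.0)
    return PhyloTree(root=Node(children=[nodes[a], nodes[b], nodes[c]]))
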