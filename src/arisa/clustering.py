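"""Dice similarity, UPGMA dendrograms and bootstrap supports.

Banding patterns are compared as presence/absence sets with the Dice
coefficient ``Dc = 2j / (a + b)`` (j bands shared, a and b per-sample band
counts), ignoring intensities.  Samples are clustered by UPGMA on the
distance ``1 - Dc``; node heights are half the merge distance so the tree is
ultrametric.  Branch support is estimated by resampling bin columns with
replacement and counting how often each clade recurs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import AbstractSet, Sequence

import numpy as np

from .peaks import BinTable

__all__ = [
    "SimilarityMatrix",
    "TreeNode",
    "dice_coefficient",
    "similarity_matrix",
    "upgma",
    "bootstrap_supports",
    "cophenetic_distances",
]


def dice_coefficient(bands_a: AbstractSet, bands_b: AbstractSet) -> float:
    """Presence/absence Dice similarity 2j/(a+b); undefined for two empty sets."""
    a, b = len(bands_a), len(bands_b)
    if a + b == 0:
        raise ValueError("Dice coefficient undefined for two empty band sets")
    j = len(set(bands_a) & set(bands_b))
    return 2.0 * j / (a + b)


@dataclass(frozen=True)
class SimilarityMatrix:
    samples: tuple[str, ...]
    values: np.ndarray
    metric: str = "dice"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.samples)
        if v.shape != (n, n):
            raise ValueError("similarity matrix must be square over the samples")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("similarity matrix must be symmetric")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("similarity values must lie in [0, 1]")
        object.__setattr__(self, "values", v)

    def distances(self) -> np.ndarray:
        return 1.0 - self.values


def similarity_matrix(bin_table: BinTable) -> SimilarityMatrix:
    """All pairwise Dice similarities between the samples of a BinTable."""
    if len(bin_table.samples) < 2:
        raise ValueError("need at least 2 samples")
    presence = bin_table.presence
    for s, row in zip(bin_table.samples, presence):
        if not row.any():
            raise ValueError(f"sample {s!r} has zero bands; Dice is undefined")
    sets = [frozenset(np.flatnonzero(row).tolist()) for row in presence]
    n = len(sets)
    values = np.eye(n)
    for i in range(n):
        for k in range(i + 1, n):
            values[i, k] = values[k, i] = dice_coefficient(sets[i], sets[k])
    return SimilarityMatrix(samples=tuple(bin_table.samples), values=values)


@dataclass(frozen=True)
class TreeNode:
    """Node of a rooted ultrametric dendrogram.

    ``height`` is the node's distance from the leaf level (half the merge
    distance for internal UPGMA nodes, 0 for leaves); ``support`` is a
    bootstrap clade frequency in [0, 1] when estimated.
    """

    height: float = 0.0
    label: str | None = None
    children: tuple["TreeNode", ...] = ()
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> frozenset[str]:
        if self.is_leaf:
            return frozenset([self.label] if self.label else [])
        out: frozenset[str] = frozenset()
        for c in self.children:
            out |= c.leaves()
        return out

    def clades(self) -> set[frozenset[str]]:
        """Leaf sets of all internal nodes (including the root)."""
        out: set[frozenset[str]] = set()
        if not self.is_leaf:
            out.add(self.leaves())
            for c in self.children:
                out |= c.clades()
        return out

    def with_supports(self, supports: dict[frozenset[str], float]) -> "TreeNode":
        if self.is_leaf:
            return self
        children = tuple(c.with_supports(supports) for c in self.children)
        return TreeNode(
            height=self.height,
            children=children,
            support=supports.get(self.leaves(), self.support),
        )

    def newick(self, parent_height: float | None = None) -> str:
        """Newick string; branch lengths are height differences, supports label internal nodes."""
        if self.is_leaf:
            body = self.label or ""
        else:
            inner = ",".join(c.newick(self.height) for c in self.children)
            sup = "" if self.support is None else f"{self.support:g}"
            body = f"({inner}){sup}"
        if parent_height is None:
            return body + ";"
        return f"{body}:{parent_height - self.height:.10g}"


def upgma(similarity: SimilarityMatrix) -> TreeNode:
    """UPGMA dendrogram on the distance 1 - Dc.

    Repeatedly merges the closest pair of clusters; the merged cluster's
    distance to every other cluster is the size-weighted arithmetic mean of
    its members' distances.  Node height is half the merge distance.  When
    several pairs tie at the minimal distance, the pair whose (smallest leaf
    label, smallest leaf label) pair sorts lexicographically first is merged,
    which makes the output deterministic.
    """
    n = len(similarity.samples)
    if n < 2:
        raise ValueError("need at least 2 samples")
    dist = {
        (i, k): float(1.0 - similarity.values[i, k])
        for i in range(n)
        for k in range(i + 1, n)
    }
    nodes: dict[int, TreeNode] = {
        i: TreeNode(height=0.0, label=s) for i, s in enumerate(similarity.samples)
    }
    sizes = {i: 1 for i in range(n)}
    keys = {i: similarity.samples[i] for i in range(n)}  # smallest leaf label per cluster
    next_id = n

    def pair_key(i: int, k: int) -> tuple[str, str]:
        return tuple(sorted((keys[i], keys[k])))  # type: ignore[return-value]

    while len(nodes) > 1:
        best = min(dist.items(), key=lambda item: (item[1], pair_key(*item[0])))
        (i, k), d = best
        new = TreeNode(
            height=d / 2.0,
            children=tuple(sorted((nodes[i], nodes[k]), key=lambda nd: min(nd.leaves()))),
        )
        others = [c for c in nodes if c not in (i, k)]
        for c in others:
            dic = dist[tuple(sorted((i, c)))]
            dkc = dist[tuple(sorted((k, c)))]
            merged = (sizes[i] * dic + sizes[k] * dkc) / (sizes[i] + sizes[k])
            dist[tuple(sorted((next_id, c)))] = merged
        for key in [p for p in dist if i in p or k in p]:
            del dist[key]
        nodes[next_id] = new
        sizes[next_id] = sizes[i] + sizes[k]
        keys[next_id] = min(keys[i], keys[k])
        for c in (i, k):
            del nodes[c], sizes[c], keys[c]
        next_id += 1
    return next(iter(nodes.values()))


def cophenetic_distances(tree: TreeNode) -> tuple[tuple[str, ...], np.ndarray]:
    """Pairwise cophenetic distances (twice the height of the lowest common ancestor)."""
    leaves = tuple(sorted(tree.leaves()))
    index = {s: i for i, s in enumerate(leaves)}
    d = np.zeros((len(leaves), len(leaves)))

    def visit(node: TreeNode) -> None:
        if node.is_leaf:
            return
        for c in node.children:
            visit(c)
        for a_idx in range(len(node.children)):
            for b_idx in range(a_idx + 1, len(node.children)):
                for la in node.children[a_idx].leaves():
                    for lb in node.children[b_idx].leaves():
                        i, k = index[la], index[lb]
                        d[i, k] = d[k, i] = 2.0 * node.height

    visit(tree)
    return leaves, d


def _dice_from_presence(presence: np.ndarray) -> np.ndarray:
    """Dice similarity over (possibly resampled, duplicated) presence columns."""
    counts = presence.sum(axis=1).astype(float)
    joint = (presence[:, None, :] & presence[None, :, :]).sum(axis=2).astype(float)
    denom = counts[:, None] + counts[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(denom > 0, 2.0 * joint / np.where(denom > 0, denom, 1.0), 1.0)
    np.fill_diagonal(sim, 1.0)
    return sim


def bootstrap_supports(
    bin_table: BinTable,
    n_reps: int = 1000,
    seed: int = 0,
) -> TreeNode:
    """UPGMA tree with clade supports from a bin-column bootstrap.

    Bin columns are resampled with replacement ``n_reps`` times; the support
    of an internal node is the fraction of replicate trees containing the
    same leaf clade.  A replicate sample that loses all its bands is treated
    as maximally distant from non-empty samples and identical to other empty
    ones.  Deterministic for a fixed seed.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if len(bin_table.samples) < 3:
        raise ValueError("bootstrap needs >= 3 samples")
    n_bins = len(bin_table.bin_centers)
    if n_bins < 2:
        raise ValueError("bootstrap needs >= 2 bins")

    base_tree = upgma(similarity_matrix(bin_table))
    clade_counts: dict[frozenset[str], int] = {c: 0 for c in base_tree.clades()}

    presence = bin_table.presence
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        cols = rng.integers(0, n_bins, size=n_bins)
        sim = _dice_from_presence(presence[:, cols])
        rep_tree = upgma(SimilarityMatrix(samples=tuple(bin_table.samples), values=sim))
        for clade in rep_tree.clades():
            if clade in clade_counts:
                clade_counts[clade] += 1

    supports = {c: cnt / n_reps for c, cnt in clade_counts.items()}
    all_leaves = base_tree.leaves()
    supports[all_leaves] = 1.0  # the root clade is trivially present
    return base_tree.with_supports(supports)
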