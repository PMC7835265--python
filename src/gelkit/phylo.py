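"""Binary-fingerprint similarity coefficients and UPGMA phylogeny.

Fourteen named similarity coefficients over the contingency quadruple
(a, b, c, d) of two samples' band profiles — a: bands shared, b: first
sample only, c: second sample only, d: absent from both — and classical
size-weighted UPGMA clustering of the derived distances (d = 1 - s) into an
ultrametric tree, exportable as Newick.

Several of the fourteen published formulas are algebraically identical
(Czekanowski = Dice = Sorensen = Nei & Li, Anderberg = Sokal & Sneath 1,
simple matching = Sokal & Michener); all fourteen names remain selectable
because the field's literature cites them separately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


@dataclass
class SimilarityCounts:
    a: int  # present in both
    b: int  # first only
    c: int  # second only
    d: int  # absent in both

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def count_abcd(x, y) -> SimilarityCounts:
    """Contingency counts between two equal-length binary band profiles."""
    x = np.asarray(x, dtype=int)
    y = np.asarray(y, dtype=int)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 1:
        raise ValueError("profiles must be equal-length 1-D with length >= 1")
    return SimilarityCounts(
        a=int(np.sum((x == 1) & (y == 1))),
        b=int(np.sum((x == 1) & (y == 0))),
        c=int(np.sum((x == 0) & (y == 1))),
        d=int(np.sum((x == 0) & (y == 0))),
    )


def _ratio(num: float, den: float, method: str) -> float:
    if den == 0:
        warnings.warn(
            f"{method}: zero denominator (no informative classes); returning 0",
            UserWarning, stacklevel=3)
        return 0.0
    return num / den


# the 14 selectable coefficients, keyed by their conventional names
METHODS = {
    "anderberg": lambda a, b, c, d: _ratio(a, a + 2 * (b + c), "anderberg"),
    "czekanowski": lambda a, b, c, d: _ratio(2 * a, 2 * a + b + c, "czekanowski"),
    "dice": lambda a, b, c, d: _ratio(2 * a, 2 * a + b + c, "dice"),
    "faith": lambda a, b, c, d: _ratio(a + 0.5 * d, a + b + c + d, "faith"),
    "gower_legendre": lambda a, b, c, d: _ratio(a + d, a + 0.5 * (b + c) + d,
                                                "gower_legendre"),
    "jaccard": lambda a, b, c, d: _ratio(a, a + b + c, "jaccard"),
    "nei_li": lambda a, b, c, d: _ratio(2 * a, (a + b) + (a + c), "nei_li"),
    "rogers_tanimoto": lambda a, b, c, d: _ratio(a + d, a + 2 * (b + c) + d,
                                                 "rogers_tanimoto"),
    "russel_rao": lambda a, b, c, d: _ratio(a, a + b + c + d, "russel_rao"),
    "simple_matching": lambda a, b, c, d: _ratio(a + d, a + b + c + d,
                                                 "simple_matching"),
    "sokal_michener": lambda a, b, c, d: _ratio(a + d, a + b + c + d,
                                                "sokal_michener"),
    "sokal_sneath_1": lambda a, b, c, d: _ratio(a, a + 2 * (b + c),
                                                "sokal_sneath_1"),
    "sokal_sneath_2": lambda a, b, c, d: _ratio(2 * (a + d), 2 * (a + d) + b + c,
                                                "sokal_sneath_2"),
    "sorensen": lambda a, b, c, d: _ratio(2 * a, 2 * a + b + c, "sorensen"),
}


def similarity(counts: SimilarityCounts, method: str) -> float:
    """Evaluate one named similarity coefficient on a count quadruple."""
    if method not in METHODS:
        raise ValueError(
            f"unknown method {method!r}; valid methods: {', '.join(sorted(METHODS))}")
    return METHODS[method](counts.a, counts.b, counts.c, counts.d)


@dataclass
class SimilarityMatrix:
    """Pairwise similarities between samples, in [0, 1]."""

    samples: list
    values: np.ndarray
    method: str

    def to_percent_dataframe(self, decimals: int = 2):
        import pandas as pd
        return pd.DataFrame(np.round(self.values * 100.0, decimals),
                            index=self.samples, columns=self.samples)


def similarity_matrix(m, method: str) -> SimilarityMatrix:
    """Pairwise similarity over a presence/absence matrix's sample columns."""
    samples = list(m.samples)
    if len(samples) < 2:
        raise ValueError("similarity matrix needs at least 2 samples")
    n = len(samples)
    vals = np.zeros((n, n))
    cols = np.asarray(m.entries)
    for i in range(n):
        for j in range(i, n):
            s = similarity(count_abcd(cols[:, i], cols[:, j]), method)
            vals[i, j] = vals[j, i] = s
    return SimilarityMatrix(samples=samples, values=vals, method=method)


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    height: float
    children: list = field(default_factory=list)  # 0 or 2
    label: str | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self):
        if self.is_leaf:
            return [self.label]
        return [l for ch in self.children for l in ch.leaves()]


@dataclass
class PhyloTree:
    root: TreeNode
    leaf_order: list

    def cophenetic(self) -> np.ndarray:
        """Leaf x leaf matrix of cophenetic distances (2 x LCA height).

        Rows/columns follow the order of `leaf_order` sorted alphabetically
        for a canonical, implementation-independent layout.
        """
        names = sorted(self.leaf_order)
        index = {n: i for i, n in enumerate(names)}
        n = len(names)
        out = np.zeros((n, n))

        def walk(node):
            if node.is_leaf:
                return [node.label]
            sides = [walk(ch) for ch in node.children]
            for ai, la in enumerate(sides):
                for lb in sides[ai + 1:]:
                    for x in la:
                        for y in lb:
                            out[index[x], index[y]] = out[index[y], index[x]] = \
                                2.0 * node.height
            return [l for s in sides for l in s]

        walk(self.root)
        return out


def upgma(sim: SimilarityMatrix) -> PhyloTree:
    """Classical size-weighted UPGMA on distances ``1 - similarity``.

    At each step the pair of clusters with the smallest mean pairwise
    distance (over original leaf pairs) is joined at height d/2.  Ties are
    broken by the lexicographically smallest pair of sorted leaf-name sets,
    so the result is fully deterministic.
    """
    D = 1.0 - np.asarray(sim.values, dtype=float)
    if not np.allclose(D, D.T, atol=1e-9):
        raise ValueError("similarity matrix must be symmetric")
    names = list(sim.samples)
    n = len(names)
    if n == 1:
        return PhyloTree(root=TreeNode(height=0.0, label=names[0]),
                         leaf_order=names)
    index = {name: i for i, name in enumerate(names)}
    # cluster = (sorted tuple of leaf names, node)
    clusters = [((name,), TreeNode(height=0.0, label=name)) for name in names]

    def cluster_dist(A, B):
        total = 0.0
        for x in A:
            for y in B:
                total += D[index[x], index[y]]
        return total / (len(A) * len(B))

    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                A, B = clusters[i][0], clusters[j][0]
                d = cluster_dist(A, B)
                key = (d,) + tuple(sorted((A, B)))
                if best is None or key < best[0]:
                    best = (key, i, j, d)
        _, i, j, d = best
        (A, na), (B, nb) = clusters[i], clusters[j]
        first, second = sorted(((A, na), (B, nb)), key=lambda t: t[0])
        node = TreeNode(height=d / 2.0, children=[first[1], second[1]])
        merged = (tuple(sorted(A + B)), node)
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
        clusters.sort(key=lambda c: c[0])
    root = clusters[0][1]
    return PhyloTree(root=root, leaf_order=root.leaves())


def _fmt(x: float) -> str:
    return format(x, ".10g")


def to_newick(tree: PhyloTree) -> str:
    """Serialize with branch lengths = parent height - child height."""

    def walk(node, parent_height):
        length = parent_height - node.height
        if node.is_leaf:
            return f"{node.label}:{_fmt(length)}"
        inner = ",".join(walk(ch, node.height) for ch in node.children)
        return f"({inner}):{_fmt(length)}"

    root = tree.root
    if root.is_leaf:
        return f"{root.label};"
    inner = ",".join(walk(ch, root.height) for ch in root.children)
    return f"({inner});"
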