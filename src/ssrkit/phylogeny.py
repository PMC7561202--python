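"""Rogers' genetic distance, neighbor-joining trees, locus bootstrap, Newick.

The NJ implementation is deterministic: Q-criterion ties are broken by the
lexicographically smallest pair of cluster labels (the smallest leaf label
in each cluster), and negative estimated branch lengths are clamped to zero
with the deficit transferred to the sibling edge.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .genotypes import MISSING, GenotypeError, GenotypeMatrix


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("distance matrix diagonal is not zero")
        if (self.d < 0).any():
            raise ValueError("negative distances")


def _locus_indicator(gm: GenotypeMatrix, j: int) -> tuple[np.ndarray, np.ndarray]:
    """Allele-frequency vectors (0, 0.5, 1 entries) for one locus.

    Returns (X, typed): X is n x A with rows summing to 1 for typed calls
    and all-zero for missing ones.
    """
    typed = gm.a1[:, j] != MISSING
    alleles = np.unique(
        np.concatenate([gm.a1[typed, j], gm.a2[typed, j]])
    ) if typed.any() else np.array([], dtype=int)
    idx = {int(a): k for k, a in enumerate(alleles)}
    X = np.zeros((gm.n_accessions, len(alleles)))
    for i in np.nonzero(typed)[0]:
        X[i, idx[int(gm.a1[i, j])]] += 0.5
        X[i, idx[int(gm.a2[i, j])]] += 0.5
    return X, typed


def per_locus_rogers(gm: GenotypeMatrix) -> np.ndarray:
    """Stack of single-locus Rogers distances, shape (L, n, n).

    d_l(x, y) = sqrt(0.5 * sum_a (x_a - y_a)^2); NaN where either
    individual is untyped at the locus.
    """
    n, L = gm.n_accessions, gm.n_loci
    out = np.full((L, n, n), np.nan)
    for j in range(L):
        X, typed = _locus_indicator(gm, j)
        if not typed.any():
            continue
        sq = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
        d = np.sqrt(np.maximum(0.5 * sq, 0.0))
        mask = typed[:, None] & typed[None, :]
        out[j][mask] = d[mask]
    return out


def rogers_distance(gm: GenotypeMatrix) -> DistanceMatrix:
    """Pairwise Rogers' distance: mean of single-locus distances over the
    loci typed in both individuals (pairwise deletion), bounded in [0, 1].

    Raises if some pair shares no typed locus.
    """
    stack = per_locus_rogers(gm)
    with np.errstate(invalid="ignore"):
        shared = (~np.isnan(stack)).sum(axis=0)
        if (shared == 0).any():
            i, j = np.argwhere(shared == 0)[0]
            raise GenotypeError(
                f"accessions {gm.accession_ids[i]!r} and "
                f"{gm.accession_ids[j]!r} share no typed locus"
            )
        d = np.nanmean(stack, axis=0)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix(list(gm.accession_ids), d)


# -- trees -----------------------------------------------------------------


@dataclass
class TreeNode:
    label: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class Tree:
    """Unrooted tree stored with an arbitrary trifurcating root."""

    root: TreeNode

    def leaf_names(self) -> list[str]:
        return [l.label for l in self.root.leaves()]

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial bipartitions, each canonicalized as the side not
        containing the lexicographically smallest leaf."""
        all_leaves = frozenset(self.leaf_names())
        anchor = min(all_leaves)
        out: set[frozenset] = set()

        def walk(node: TreeNode, under_root: bool) -> frozenset:
            if node.is_leaf:
                return frozenset([node.label])
            below = frozenset().union(*(walk(c, False) for c in node.children))
            if not under_root and 2 <= len(below) <= len(all_leaves) - 2:
                side = below if anchor not in below else all_leaves - below
                out.add(side)
            return below

        walk(self.root, True)
        return out

    def _edge_map(self) -> dict[frozenset, TreeNode]:
        all_leaves = frozenset(self.leaf_names())
        anchor = min(all_leaves)
        edges: dict[frozenset, TreeNode] = {}

        def walk(node: TreeNode, under_root: bool) -> frozenset:
            if node.is_leaf:
                return frozenset([node.label])
            below = frozenset().union(*(walk(c, False) for c in node.children))
            if not under_root and 2 <= len(below) <= len(all_leaves) - 2:
                side = below if anchor not in below else all_leaves - below
                edges[side] = node
            return below

        walk(self.root, True)
        return edges

    def leaf_distance_matrix(self) -> DistanceMatrix:
        """Path-length distances between all leaf pairs (additivity oracle)."""
        names = sorted(self.leaf_names())
        pos = {n: k for k, n in enumerate(names)}
        n = len(names)
        d = np.zeros((n, n))

        def walk(node: TreeNode) -> dict[str, float]:
            if node.is_leaf:
                return {node.label: 0.0}
            sub = [
                {k: v + c.length for k, v in walk(c).items()}
                for c in node.children
            ]
            for a in range(len(sub)):
                for b in range(a + 1, len(sub)):
                    for la, da in sub[a].items():
                        for lb, db in sub[b].items():
                            d[pos[la], pos[lb]] = d[pos[lb], pos[la]] = da + db
            merged: dict[str, float] = {}
            for s in sub:
                merged.update(s)
            return merged

        walk(self.root)
        return DistanceMatrix(names, d)


def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking."""
    n = len(dm.labels)
    if n < 3:
        raise GenotypeError("neighbor joining requires >= 3 labels")
    nodes = [TreeNode(label=l) for l in dm.labels]
    canon = list(dm.labels)  # smallest leaf label per active cluster
    D = dm.d.astype(float).copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cands = np.argwhere(np.isclose(Q, qmin, rtol=0, atol=1e-12))
        best = min(
            (tuple(sorted((canon[active[a]], canon[active[b]]))), a, b)
            for a, b in cands
            if a < b
        )
        _, ai, bi = best
        i, j = active[ai], active[bi]
        dij = sub[ai, bi]
        li = 0.5 * dij + (r[ai] - r[bi]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:  # clamp, deficit to sibling
            li, lj = 0.0, dij
        if lj < 0:
            li, lj = dij, 0.0
        parent = TreeNode()
        nodes[i].length, nodes[j].length = li, lj
        parent.children = [nodes[i], nodes[j]]
        # distances to the new node
        newd = 0.5 * (D[i, active] + D[j, active] - dij)
        D[i, active] = newd
        D[active, i] = newd
        D[i, i] = 0.0
        nodes[i] = parent
        canon[i] = min(canon[i], canon[j])
        active.remove(j)

    i, j, k = active
    a = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    b = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    c = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    nodes[i].length = max(a, 0.0)
    nodes[j].length = max(b, 0.0)
    nodes[k].length = max(c, 0.0)
    order = sorted([i, j, k], key=lambda x: canon[x])
    return Tree(TreeNode(children=[nodes[x] for x in order]))


def bootstrap_supports(
    gm: GenotypeMatrix,
    replicates: int = 1000,
    seed: int | None = None,
) -> Tree:
    """NJ tree with per-edge bootstrap supports (% of replicates).

    Loci are resampled with replacement (the resampling unit for unlinked
    markers); each replicate recomputes the distance matrix and tree.  With
    ``replicates=0`` the plain tree is returned without supports.
    Reproducible given *seed*.
    """
    if gm.n_loci < 2:
        raise GenotypeError("bootstrap requires >= 2 loci")
    stack = per_locus_rogers(gm)
    with np.errstate(invalid="ignore"):
        full_d = np.nanmean(stack, axis=0)
    np.fill_diagonal(full_d, 0.0)
    dm = DistanceMatrix(list(gm.accession_ids), (full_d + full_d.T) / 2)
    tree = neighbor_joining(dm)
    if replicates == 0:
        return tree
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {bp: 0 for bp in tree.bipartitions()}
    L = gm.n_loci
    for _ in range(replicates):
        pick = rng.integers(0, L, size=L)
        with np.errstate(invalid="ignore"):
            d = np.nanmean(stack[pick], axis=0)
        # pairs untyped at every resampled locus fall back to the full-data
        # distance (documented policy; cannot occur on complete data)
        nanpairs = np.isnan(d)
        d[nanpairs] = full_d[nanpairs]
        np.fill_diagonal(d, 0.0)
        rep = neighbor_joining(DistanceMatrix(list(gm.accession_ids), (d + d.T) / 2))
        for bp in rep.bipartitions():
            if bp in counts:
                counts[bp] += 1
    edges = tree._edge_map()
    for bp, node in edges.items():
        node.support = 100.0 * counts.get(bp, 0) / replicates
    return tree


# -- Newick ----------------------------------------------------------------

_NEEDS_QUOTE = re.compile(r"[\s()\[\]:;,'\"]")


def _quote_label(label: str) -> str:
    if _NEEDS_QUOTE.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: Tree) -> str:
    """Standard Newick with branch lengths; supports as internal labels."""

    def fmt(node: TreeNode, top: bool) -> str:
        if node.is_leaf:
            s = _quote_label(node.label or "")
        else:
            s = "(" + ",".join(fmt(c, False) for c in node.children) + ")"
            if node.support is not None:
                s += format(node.support, "g")
        if not top:
            s += f":{node.length:g}"
        return s

    return fmt(tree.root, True) + ";"


def read_newick(text: str) -> Tree:
    """Parse Newick into a :class:`Tree` (dendropy-backed)."""
    import dendropy

    dt = dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)

    def convert(nd) -> TreeNode:
        node = TreeNode(
            label=nd.taxon.label if nd.taxon is not None else None,
            length=nd.edge.length if nd.edge.length is not None else 0.0,
        )
        if nd.label is not None and not nd.is_leaf():
            try:
                node.support = float(nd.label)
            except ValueError:
                pass
        node.children = [convert(c) for c in nd.child_nodes()]
        return node

    return Tree(convert(dt.seed_node))


def topology_equal(t1: Tree, t2: Tree) -> bool:
    """Same leaf set and same set of non-trivial bipartitions."""
    return (
        sorted(t1.leaf_names()) == sorted(t2.leaf_names())
        and t1.bipartitions() == t2.bipartitions()
    )
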