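"""UPGMA clustering, cophenetic matrices and Mantel matrix comparison.

The two marker classes yield parallel distance matrices over the same
samples; their agreement is quantified with a Mantel permutation test,
both on the raw distances and on the cophenetic distances implied by the
UPGMA dendrograms (topology-level agreement).  The graphical tanglegram is
replaced by a textual side-by-side leaf ordering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from hexassr.bruvo import DistanceMatrix

__all__ = [
    "TreeNode",
    "Dendrogram",
    "MantelResult",
    "TreeComparison",
    "upgma",
    "cophenetic_matrix",
    "mantel",
    "compare_trees",
]


@dataclass(frozen=True)
class TreeNode:
    height: float
    label: str | None = None
    children: tuple["TreeNode", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]  # type: ignore[list-item]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class Dendrogram:
    """Rooted ultrametric tree; node heights are half the merge distances."""

    root: TreeNode

    def leaf_order(self) -> list[str]:
        return self.root.leaves()

    @property
    def height(self) -> float:
        return self.root.height

    def to_newick(self) -> str:
        def render(node: TreeNode, parent_height: float) -> str:
            length = parent_height - node.height
            if node.is_leaf:
                return f"{node.label}:{length:.10g}"
            inner = ",".join(render(c, node.height) for c in node.children)
            return f"({inner}):{length:.10g}"

        if self.root.is_leaf:
            return f"{self.root.label};"
        inner = ",".join(render(c, self.root.height) for c in self.root.children)
        return f"({inner});"

    def write_newick(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")


@dataclass
class MantelResult:
    r: float
    p: float
    n_permutations: int
    alternative: str = "greater"


@dataclass
class TreeComparison:
    """Mantel test on cophenetic matrices plus aligned leaf orderings."""

    mantel: MantelResult
    leaf_order_1: list[str]
    leaf_order_2: list[str]


def upgma(dm: DistanceMatrix) -> Dendrogram:
    """Average-linkage (UPGMA) agglomerative clustering.

    Cluster-size-weighted average update; merge height is half the merge
    distance so leaves sit at height 0 and the tree is ultrametric.  Ties
    are broken deterministically toward the pair containing the
    lexicographically smallest member label.
    """
    if dm.n < 2:
        raise ValueError("need at least 2 labels")
    if np.isnan(dm.values).any():
        raise ValueError("distance matrix contains NaN")
    # active clusters: id -> (node, size, smallest member label)
    nodes: dict[int, TreeNode] = {
        i: TreeNode(height=0.0, label=lab) for i, lab in enumerate(dm.labels)
    }
    sizes = {i: 1 for i in nodes}
    minlab = {i: lab for i, lab in enumerate(dm.labels)}
    dist: dict[tuple[int, int], float] = {}
    for i in range(dm.n):
        for j in range(i + 1, dm.n):
            dist[(i, j)] = float(dm.values[i, j])
    next_id = dm.n
    while len(nodes) > 1:
        best_key = min(
            dist,
            key=lambda ij: (
                dist[ij],
                min(minlab[ij[0]], minlab[ij[1]]),
                max(minlab[ij[0]], minlab[ij[1]]),
            ),
        )
        i, j = best_key
        d = dist[best_key]
        # deterministic child order: smaller min-label first
        first, second = (i, j) if minlab[i] <= minlab[j] else (j, i)
        merged = TreeNode(height=d / 2.0, children=(nodes[first], nodes[second]))
        for k in list(nodes):
            if k in (i, j):
                continue
            dik = dist[(min(i, k), max(i, k))]
            djk = dist[(min(j, k), max(j, k))]
            dnew = (sizes[i] * dik + sizes[j] * djk) / (sizes[i] + sizes[j])
            dist[(min(k, next_id), max(k, next_id))] = dnew
        for key in [k for k in dist if i in k or j in k]:
            del dist[key]
        nodes[next_id] = merged
        sizes[next_id] = sizes[i] + sizes[j]
        minlab[next_id] = min(minlab[i], minlab[j])
        for c in (i, j):
            del nodes[c], sizes[c], minlab[c]
        next_id += 1
    return Dendrogram(root=next(iter(nodes.values())))


def cophenetic_matrix(tree: Dendrogram) -> DistanceMatrix:
    """Pairwise leaf distances implied by the dendrogram.

    The cophenetic distance of two leaves is twice the height of their
    lowest common ancestor (the distance at which their clusters merged).
    """
    labels = tree.leaf_order()
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    values = np.zeros((n, n))

    def walk(node: TreeNode) -> list[str]:
        if node.is_leaf:
            return [node.label]  # type: ignore[list-item]
        groups = [walk(c) for c in node.children]
        d = 2.0 * node.height
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                for a in groups[gi]:
                    for b in groups[gj]:
                        ia, ib = index[a], index[b]
                        values[ia, ib] = values[ib, ia] = d
        out: list[str] = []
        for g in groups:
            out.extend(g)
        return out

    walk(tree.root)
    return DistanceMatrix(labels=labels, values=values)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
    if denom == 0:
        raise ValueError("zero variance in distance vector")
    return float(xc @ yc) / denom


def mantel(
    dm1: DistanceMatrix,
    dm2: DistanceMatrix,
    n_permutations: int = 9999,
    seed: int | None = None,
    alternative: str = "greater",
) -> MantelResult:
    """Mantel permutation test of correlation between two distance matrices.

    ``r`` is the Pearson correlation of the off-diagonal upper triangles
    after aligning ``dm2`` to ``dm1``'s label order.  The null distribution
    is built by jointly permuting rows and columns of the second matrix;
    ``p = (#{r* at least as extreme} + 1) / (n_permutations + 1)``.
    ``alternative``: "greater" (default), "less" or "two-sided".
    """
    if alternative not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    if sorted(dm1.labels) != sorted(dm2.labels):
        raise ValueError("label sets differ between matrices")
    dm2 = dm2.reorder(dm1.labels)
    n = dm1.n
    iu0, iu1 = np.triu_indices(n, k=1)
    x = dm1.values[iu0, iu1]
    y_mat = dm2.values
    r_obs = _pearson(x, y_mat[iu0, iu1])
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_permutations)])
    y_perm = y_mat[perms[:, iu0], perms[:, iu1]]  # (P, n_pairs)
    xc = x - x.mean()
    yc = y_perm - y_perm.mean(axis=1, keepdims=True)
    num = yc @ xc
    denom = np.sqrt(float(xc @ xc) * np.einsum("ij,ij->i", yc, yc))
    r_perm = num / denom
    eps = 1e-12
    if alternative == "greater":
        extreme = int(np.sum(r_perm >= r_obs - eps))
    elif alternative == "less":
        extreme = int(np.sum(r_perm <= r_obs + eps))
    else:
        extreme = int(np.sum(np.abs(r_perm) >= abs(r_obs) - eps))
    p = (extreme + 1) / (n_permutations + 1)
    return MantelResult(r=r_obs, p=p, n_permutations=n_permutations, alternative=alternative)


def compare_trees(
    t1: Dendrogram,
    t2: Dendrogram,
    n_permutations: int = 9999,
    seed: int | None = None,
    alternative: str = "greater",
) -> TreeComparison:
    """Topology-level agreement: Mantel test on the cophenetic matrices.

    Also returns the two leaf orderings side by side, the textual stand-in
    for a tanglegram.
    """
    c1 = cophenetic_matrix(t1)
    c2 = cophenetic_matrix(t2)
    result = mantel(c1, c2, n_permutations=n_permutations, seed=seed, alternative=alternative)
    return TreeComparison(
        mantel=result,
        leaf_order_1=t1.leaf_order(),
        leaf_order_2=t2.leaf_order(),
    )
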