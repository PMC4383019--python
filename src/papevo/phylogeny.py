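"""Region phylogenies from binary mutation presence/absence matrices.

Pairwise distance between tumour regions is the number of mutations with
discordant presence (unevaluable cells skipped pairwise — the
number-of-differences distance).  Trees are built with UPGMA (agglomerative
average linkage, producing ultrametric trees), ties in merge order broken by
lexicographic region label so results are deterministic.  Branch lengths are
in mutation-count units; node support comes from a column bootstrap
(resampling mutations with replacement); the trunk is the set of mutations
present in every region and its size is reported as the trunk length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TreeNode",
    "RegionTree",
    "build_presence_matrix",
    "distance_matrix",
    "upgma_tree",
    "upgma_from_distance",
    "bootstrap_support",
    "annotate_trunk_branch",
]


@dataclass
class TreeNode:
    """Node of a rooted ultrametric region tree.

    height is in mutation-count distance units (leaf height 0); support is a
    bootstrap percentage for internal nodes (None until computed).
    """

    name: str | None = None
    children: list = field(default_factory=list)
    height: float = 0.0
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list:
        if self.is_leaf:
            return [self.name]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return sorted(out)

    def newick(self, parent_height: float | None = None) -> str:
        length = "" if parent_height is None else f":{parent_height - self.height:g}"
        if self.is_leaf:
            return f"{self.name}{length}"
        inner = ",".join(
            sorted(c.newick(self.height) for c in self.children)
        )
        label = "" if self.support is None else f"{self.support:g}"
        return f"({inner}){label}{length}"


@dataclass
class RegionTree:
    root: TreeNode
    trunk_length: int
    tumour: str = ""

    def internal_nodes(self) -> list:
        out = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            if not node.is_leaf:
                out.append(node)
                stack.extend(node.children)
        return out

    def clades(self) -> dict:
        """frozenset of leaf names -> node, for every node in the tree."""
        out = {}
        stack = [self.root]
        while stack:
            node = stack.pop()
            out[frozenset(node.leaves())] = node
            stack.extend(node.children)
        return out

    def newick(self) -> str:
        return self.root.newick() + ";"

    def check_ultrametric(self, atol: float = 1e-9) -> bool:
        def depth_ok(node, acc):
            if node.is_leaf:
                return {acc}
            depths = set()
            for c in node.children:
                depths |= depth_ok(c, acc + node.height - c.height)
            return depths
        depths = depth_ok(self.root, 0.0)
        return max(depths) - min(depths) <= atol


def build_presence_matrix(
    presence: pd.DataFrame,
    variants=None,
    nonsynonymous_only: bool = False,
    tumour: str = "",
) -> tuple:
    """Orient a validated presence matrix and compute the heterogeneity
    fraction.

    ``presence`` is mutation x region with values 1/0/NaN (from
    ``validate_presence``).  With ``nonsynonymous_only`` and a ``variants``
    list carrying effect annotations, synonymous SNVs are dropped first.
    Mutations present in no evaluable region are dropped (they are validation
    failures, not tumour mutations).  Returns (regions x mutations matrix,
    heterogeneity percentage): the percentage of mutations absent from at
    least one evaluable region.
    """
    mat = presence.copy()
    if nonsynonymous_only:
        if variants is None:
            raise ValueError("variants with effect annotations required")
        keep = []
        effects = {
            (getattr(v, "mutation_id", None) or f"{v.chrom}:{v.pos}"):
                (v.effect or "").lower()
            for v in variants
        }
        for mut in mat.index:
            eff = effects.get(mut, "")
            if not eff.startswith("synonymous"):
                keep.append(mut)
        mat = mat.loc[keep]
    # drop mutations never present
    present_any = (mat == 1).any(axis=1)
    mat = mat.loc[present_any]
    total = len(mat)
    if total == 0:
        return mat.T, 0.0
    heterogeneous = int(((mat == 0).any(axis=1)).sum())
    out = mat.T
    out.attrs["tumour"] = tumour
    return out, 100.0 * heterogeneous / total


def distance_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Number-of-differences distance between regions (rows); unevaluable
    cells are excluded pairwise."""
    regions = list(matrix.index)
    vals = matrix.to_numpy(dtype=float)
    n = len(regions)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ~np.isnan(vals[i]) & ~np.isnan(vals[j])
            d[i, j] = d[j, i] = float(np.sum(vals[i, both] != vals[j, both]))
    return pd.DataFrame(d, index=regions, columns=regions)


def upgma_tree(matrix: pd.DataFrame, tumour: str = "") -> RegionTree:
    """UPGMA agglomeration of the region distance matrix.

    At each step the pair at minimal distance is merged at height d/2; among
    tied pairs the one whose (sorted) label pair is lexicographically smallest
    is chosen, so the tree is deterministic.  The trunk length is the number
    of mutations present in every region (evaluable or not elsewhere).
    """
    if matrix.shape[0] < 2:
        raise ValueError("need >= 2 regions for a tree")
    dist = distance_matrix(matrix)
    vals = matrix.to_numpy(dtype=float)
    trunk = int(np.sum(np.all(vals == 1, axis=0)))
    return upgma_from_distance(dist, trunk_length=trunk, tumour=tumour)


def upgma_from_distance(
    dist: pd.DataFrame, trunk_length: int = 0, tumour: str = ""
) -> RegionTree:
    """UPGMA over an explicit symmetric distance matrix (see upgma_tree)."""
    nodes = {r: TreeNode(name=r) for r in dist.index}
    sizes = {r: 1 for r in dist.index}
    # track SUMS of leaf-pair distances (exact under addition); the average
    # is formed only at comparison time, so equal averages compare equal and
    # the lexicographic tie-break is deterministic
    dsum = {frozenset((a, b)): float(dist.loc[a, b])
            for i, a in enumerate(dist.index) for b in dist.index[i + 1:]}
    labels = {r: (r,) for r in dist.index}  # sorted leaf tuple for tie-breaks

    while len(nodes) > 1:
        best = None
        for pair, total in dsum.items():
            a, b = sorted(pair, key=lambda x: labels[x])
            avg = total / (sizes[a] * sizes[b])
            key = (avg, labels[a], labels[b])
            if best is None or key < best[0]:
                best = (key, a, b)
        (avg, _, _), a, b = best
        new = TreeNode(children=[nodes[a], nodes[b]], height=avg / 2.0)
        new_name = f"({a}+{b})"
        na, nb = sizes[a], sizes[b]
        for other in list(nodes):
            if other in (a, b):
                continue
            dsum[frozenset((new_name, other))] = (
                dsum[frozenset((a, other))] + dsum[frozenset((b, other))]
            )
        for pair in [p for p in dsum if a in p or b in p]:
            del dsum[pair]
        del nodes[a], nodes[b], sizes[a], sizes[b]
        nodes[new_name] = new
        sizes[new_name] = na + nb
        labels[new_name] = tuple(sorted(labels[a] + labels[b]))

    root = next(iter(nodes.values()))
    return RegionTree(root=root, trunk_length=trunk_length, tumour=tumour)


def bootstrap_support(
    matrix: pd.DataFrame,
    replicates: int = 1000,
    seed: int = 0,
    tree: RegionTree | None = None,
) -> RegionTree:
    """Column bootstrap supports for the UPGMA tree of ``matrix``.

    Mutations (columns) are resampled with replacement ``replicates`` times;
    each internal node's support is the percentage of replicate trees that
    contain its region bipartition.  Supports are written onto the returned
    tree's internal nodes.  A matrix with no discordant columns yields a tree
    flagged uninformative (attribute ``uninformative`` on the result).
    """
    if matrix.shape[0] < 3:
        raise ValueError("bootstrap needs >= 3 regions")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    tree = tree or upgma_tree(matrix)
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    target_clades = {frozenset(n.leaves()) for n in tree.internal_nodes()}
    hits = {c: 0 for c in target_clades}
    n_cols = matrix.shape[1]
    for _ in range(replicates):
        cols = rng.integers(0, n_cols, size=n_cols)
        rep = matrix.iloc[:, cols]
        rep_tree = upgma_tree(rep)
        rep_clades = {frozenset(n.leaves()) for n in rep_tree.internal_nodes()}
        for c in target_clades & rep_clades:
            hits[c] += 1
    for node in tree.internal_nodes():
        node.support = 100.0 * hits[frozenset(node.leaves())] / replicates
    dist = distance_matrix(matrix)
    tree.uninformative = bool((dist.to_numpy() == 0).all())
    return tree


def annotate_trunk_branch(matrix: pd.DataFrame, tree: RegionTree) -> pd.DataFrame:
    """Map each mutation onto a tree edge.

    A mutation present in all regions is truncal; one present in exactly the
    leaf set of a clade maps to the edge above that clade (single-region
    presence -> the private leaf edge).  Presence sets matching no clade are
    flagged homoplasic — candidate parallel evolution, reversion or
    validation noise.  Returns a table with columns mutation_id, assignment
    (trunk | shared-branch | private | homoplasic) and edge (sorted region
    tuple).
    """
    all_regions = frozenset(matrix.index)
    if frozenset(tree.root.leaves()) != all_regions:
        raise ValueError("tree leaves do not match matrix regions")
    clades = set(tree.clades())
    rows = []
    for mut in matrix.columns:
        col = matrix[mut]
        present = frozenset(col[col == 1].index)
        if present == all_regions:
            assignment = "trunk"
        elif len(present) == 1:
            assignment = "private"
        elif present in clades:
            assignment = "shared-branch"
        else:
            assignment = "homoplasic"
        rows.append((mut, assignment, tuple(sorted(present))))
    return pd.DataFrame(rows, columns=["mutation_id", "assignment", "edge"])
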