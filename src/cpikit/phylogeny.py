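"""Distance-based phylogeny: corrected distances, neighbor-joining, bootstrap.

The tree search is plain neighbor-joining on p/Poisson/Kimura-corrected
pairwise distances with pairwise deletion of gapped columns, deterministic
tie-breaking (smallest index pair), and non-negative branch lengths. Bootstrap
supports are percentages of column-resampled replicates containing each
internal bipartition of the full-data tree.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from cpikit.conservation import Alignment, GAP

CORRECTIONS = ("p", "poisson", "kimura")

# largest p for which 1 - p - 0.2 p^2 > 0
_KIMURA_P_BOUND = (-1.0 + math.sqrt(1.8)) / 0.4


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric nonnegative distances (substitutions/site) over ordered ids."""

    ids: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match id count")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("non-finite distances")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("matrix not symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("nonzero diagonal")

    @property
    def n(self) -> int:
        return len(self.ids)


class Node:
    """Tree node; leaves carry a label, internal edges may carry a support."""

    __slots__ = ("label", "length", "support", "children")

    def __init__(self, label: str | None = None, length: float = 0.0,
                 support: int | None = None,
                 children: list["Node"] | None = None):
        self.label = label
        self.length = length
        self.support = support
        self.children = children if children is not None else []

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        if self.is_leaf:
            return [self]
        out: list[Node] = []
        for child in self.children:
            out.extend(child.leaves())
        return out


@dataclass
class PhyloTree:
    """Unrooted tree represented with a (usually trifurcating) root node."""

    root: Node
    diagnostics: dict = field(default_factory=dict)

    @property
    def leaf_labels(self) -> set[str]:
        return {leaf.label for leaf in self.root.leaves()}

    def bipartitions(self) -> dict[frozenset[str], Node]:
        """Non-trivial bipartitions, keyed by the canonical (smaller) side."""
        all_leaves = self.leaf_labels
        out: dict[frozenset[str], Node] = {}

        def visit(node: Node) -> set[str]:
            if node.is_leaf:
                return {node.label}
            below: set[str] = set()
            for child in node.children:
                below |= visit(child)
            if node is not self.root and 2 <= len(below) <= len(all_leaves) - 2:
                side = frozenset(below)
                other = frozenset(all_leaves - below)
                key = min(side, other, key=lambda s: tuple(sorted(s)))
                out[key] = node
            return below

        visit(self.root)
        return out


def pairwise_distances(aln: Alignment, correction: str = "kimura") -> DistanceMatrix:
    """Corrected pairwise distances with pairwise deletion of gapped columns.

    ``p`` is the raw mismatch fraction; ``poisson`` applies -ln(1-p);
    ``kimura`` applies -ln(1 - p - 0.2 p^2). A pair with no comparable
    columns, or with p outside the correction's domain, is an error.
    """
    if correction not in CORRECTIONS:
        raise ValueError(f"unknown correction {correction!r}")
    if aln.nrow < 2:
        raise ValueError("need at least 2 rows")
    rows = [row for _, row in aln.records]
    ids = tuple(aln.ids)
    n = len(rows)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comparable = 0
            mismatches = 0
            for a, b in zip(rows[i], rows[j]):
                if a == GAP or b == GAP:
                    continue
                comparable += 1
                if a != b:
                    mismatches += 1
            if comparable == 0:
                raise ValueError(f"no comparable columns for pair ({ids[i]}, {ids[j]})")
            p = mismatches / comparable
            if correction == "p":
                dist = p
            elif correction == "poisson":
                if p >= 1.0:
                    raise ValueError(f"p={p:.4f} out of Poisson domain for pair ({ids[i]}, {ids[j]})")
                dist = -math.log(1.0 - p)
            else:
                if p >= _KIMURA_P_BOUND:
                    raise ValueError(f"p={p:.4f} out of Kimura domain for pair ({ids[i]}, {ids[j]})")
                dist = -math.log(1.0 - p - 0.2 * p * p)
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(ids=ids, d=d)


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Neighbor-joining tree (unrooted, trifurcating root).

    Deterministic: ties in the Q criterion are broken by the smallest index
    pair. Negative intermediate branch lengths are clamped to 0.
    """
    n = dm.n
    if n < 3:
        raise ValueError("neighbor-joining needs at least 3 taxa")
    nodes: list[Node] = [Node(label=rid) for rid in dm.ids]
    d = dm.d.astype(float).copy()
    active = list(range(n))

    while len(active) > 3:
        r = len(active)
        sums = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1:]:
                q = (r - 2) * d[i, j] - sums[i] - sums[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (sums[i] - sums[j]) / (2.0 * (r - 2))
        lj = d[i, j] - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        nodes[i].length, nodes[j].length = li, lj
        parent = Node(children=[nodes[i], nodes[j]])
        # grow matrix with the new node's row
        d = np.pad(d, ((0, 1), (0, 1)))
        u = d.shape[0] - 1
        for k in active:
            if k in (i, j):
                continue
            d[u, k] = d[k, u] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [u]

    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    for k, lk in ((a, la), (b, lb), (c, lc)):
        nodes[k].length = max(lk, 0.0)
    return PhyloTree(root=Node(children=[nodes[a], nodes[b], nodes[c]]))


def bootstrap_supports(aln: Alignment, n_reps: int, seed: int,
                       correction: str = "kimura") -> PhyloTree:
    """Full-data NJ tree with bootstrap supports on internal edges.

    Columns are resampled with replacement per replicate; a replicate whose
    distance matrix is degenerate (no comparable columns / out-of-domain p)
    is skipped and counted in ``diagnostics['skipped_replicates']``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    tree = nj_tree(pairwise_distances(aln, correction))
    target = tree.bipartitions()
    counts = {key: 0 for key in target}

    rng = np.random.default_rng(seed)
    ncol = aln.ncol
    skipped = 0
    used = 0
    for _ in range(n_reps):
        cols = rng.integers(0, ncol, size=ncol)
        resampled = Alignment(tuple(
            (rid, "".join(row[c] for c in cols)) for rid, row in aln.records
        ))
        try:
            rep_tree = nj_tree(pairwise_distances(resampled, correction))
        except ValueError:
            skipped += 1
            continue
        used += 1
        rep_bips = rep_tree.bipartitions()
        for key in counts:
            if key in rep_bips:
                counts[key] += 1

    for key, node in target.items():
        node.support = round(100.0 * counts[key] / used) if used else 0
    tree.diagnostics = {
        "n_replicates": n_reps,
        "used_replicates": used,
        "skipped_replicates": skipped,
        "seed": seed,
        "correction": correction,
    }
    return tree


def _newick_label(text: str) -> str:
    if any(ch in text for ch in " (),:;'"):
        return "'" + text.replace("'", "''") + "'"
    return text


def write_newick(tree: PhyloTree) -> str:
    """Newick text with branch lengths and integer supports as internal labels."""

    def render(node: Node, is_root: bool) -> str:
        if node.is_leaf:
            return f"{_newick_label(node.label)}:{node.length:.6g}"
        inner = ",".join(render(child, False) for child in node.children)
        if is_root:
            return f"({inner})"
        label = "" if node.support is None else str(int(node.support))
        return f"({inner}){label}:{node.length:.6g}"

    return render(tree.root, True) + ";"


def read_newick(text: str) -> PhyloTree:
    """Parse Newick produced by :func:`write_newick` (supports as internal labels)."""
    dtree = dendropy.Tree.get(data=text, schema="newick",
                              suppress_internal_node_taxa=True)

    def convert(dnode) -> Node:
        length = dnode.edge.length if dnode.edge.length is not None else 0.0
        if dnode.is_leaf():
            return Node(label=dnode.taxon.label if dnode.taxon else dnode.label,
                        length=length)
        support = None
        if dnode.label is not None and dnode.label.strip().isdigit():
            support = int(dnode.label)
        return Node(length=length, support=support,
                    children=[convert(c) for c in dnode.child_nodes()])

    return PhyloTree(root=convert(dtree.seed_node))


def write_supports_tsv(tree: PhyloTree, path: str | Path) -> None:
    """Bipartition supports as TSV (sorted leaf-side, support percent)."""
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["bipartition", "support_pct"])
        for key, node in sorted(tree.bipartitions().items(),
                                key=lambda kv: tuple(sorted(kv[0]))):
            writer.writerow([",".join(sorted(key)),
                             "" if node.support is None else node.support])
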