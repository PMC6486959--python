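"""Rooted phylogenetic trees with branch lengths.

A deliberately small tree container: node identity is a unique string name,
internal nodes without a label in the source Newick get stable generated names
(``nd<preorder index>``) so that reconstruction output is addressable. Trees
are immutable in practice — operations that change topology return new trees.

Polytomies are allowed everywhere; zero-length branches are allowed (they are
produced when several accessions of one species hang off the same node).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

import dendropy
import numpy as np

__all__ = [
    "PhyloTree",
    "NewickError",
    "parse_newick",
    "write_newick",
    "prune_tips",
    "diploid_view",
]


class NewickError(ValueError):
    """Raised for malformed or invalid Newick input."""


@dataclass(frozen=True)
class PhyloTree:
    """Rooted tree: one root, every non-root node has one parent, lengths >= 0."""

    root: str
    parent: Mapping[str, str | None]
    children: Mapping[str, tuple[str, ...]]
    length: Mapping[str, float]  # length of the edge above each node; 0.0 at root

    def __post_init__(self) -> None:
        if self.parent[self.root] is not None:
            raise ValueError("root must have no parent")
        for node, par in self.parent.items():
            if node != self.root and par is None:
                raise ValueError(f"multiple roots: {node!r}")
            if self.length[node] < 0:
                raise ValueError(f"negative branch length at {node!r}")

    # -- basic queries ---------------------------------------------------
    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(self.preorder())

    @property
    def tips(self) -> tuple[str, ...]:
        return tuple(n for n in self.preorder() if not self.children[n])

    @property
    def internal_nodes(self) -> tuple[str, ...]:
        return tuple(n for n in self.preorder() if self.children[n])

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    def is_tip(self, node: str) -> bool:
        return not self.children[node]

    def preorder(self) -> Iterator[str]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(self.children[node]))

    def postorder(self) -> Iterator[str]:
        out: list[str] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(self.children[node])
        return iter(reversed(out))

    def edge_list(self) -> list[tuple[str, str, float]]:
        """All (parent, child, length) edges in deterministic preorder."""
        return [
            (self.parent[n], n, self.length[n])  # type: ignore[misc]
            for n in self.preorder()
            if n != self.root
        ]

    def depths(self) -> dict[str, float]:
        """Distance from the root to every node."""
        out = {self.root: 0.0}
        for node in self.preorder():
            if node != self.root:
                out[node] = out[self.parent[node]] + self.length[node]
        return out

    def ancestors(self, node: str) -> list[str]:
        """Path root-ward from ``node`` (exclusive) to the root (inclusive)."""
        out = []
        cur = self.parent[node]
        while cur is not None:
            out.append(cur)
            cur = self.parent[cur]
        return out

    def mrca(self, a: str, b: str) -> str:
        anc_a = set([a]) | set(self.ancestors(a))
        cur = b
        while cur not in anc_a:
            cur = self.parent[cur]  # type: ignore[assignment]
            if cur is None:  # pragma: no cover - root is a common ancestor
                raise ValueError("disconnected nodes")
        return cur

    def path_length(self, a: str, b: str) -> float:
        d = self.depths()
        return d[a] + d[b] - 2.0 * d[self.mrca(a, b)]

    def total_length(self) -> float:
        return float(sum(self.length[n] for n in self.parent if n != self.root))

    # -- phylogenetic covariance -----------------------------------------
    def vcv(self, taxa: Iterable[str] | None = None) -> tuple[np.ndarray, list[str]]:
        """Shared-path-length matrix C: C[i, j] = depth of MRCA(taxon_i, taxon_j).

        Under Brownian motion with rate sigma^2, tip covariance is sigma^2 * C.
        """
        taxa = list(taxa) if taxa is not None else list(self.tips)
        depths = self.depths()
        anc = {t: [t, *self.ancestors(t)] for t in taxa}
        anc_sets = {t: set(a) for t, a in anc.items()}
        n = len(taxa)
        C = np.empty((n, n))
        for i, a in enumerate(taxa):
            C[i, i] = depths[a]
            for j in range(i + 1, n):
                b = taxa[j]
                sa = anc_sets[b]
                m = next(x for x in anc[a] if x in sa)
                C[i, j] = C[j, i] = depths[m]
        return C, taxa

    # -- construction ----------------------------------------------------
    @staticmethod
    def from_edges(
        root: str,
        edges: Iterable[tuple[str, str, float]],
    ) -> "PhyloTree":
        parent: dict[str, str | None] = {root: None}
        children: dict[str, list[str]] = {root: []}
        length: dict[str, float] = {root: 0.0}
        for par, child, ln in edges:
            if child in parent:
                raise ValueError(f"node {child!r} has more than one parent")
            parent[child] = par
            length[child] = float(ln)
            children.setdefault(par, []).append(child)
            children.setdefault(child, [])
        missing = set(parent) - set(children)
        if missing:  # pragma: no cover - defensive
            raise ValueError(f"dangling nodes: {missing}")
        return PhyloTree(
            root=root,
            parent=parent,
            children={k: tuple(v) for k, v in children.items()},
            length=length,
        )


def parse_newick(text: str, default_length: float = 1.0) -> PhyloTree:
    """Parse a Newick string into a :class:`PhyloTree`.

    Branch lengths are optional (missing lengths become ``default_length``);
    polytomies are preserved. Unlabeled internal nodes are assigned generated
    names ``nd<i>`` by preorder index. Raises :class:`NewickError` on
    unbalanced input, duplicate tip labels, or negative lengths.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=False,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickError(f"malformed Newick: {exc}") from None

    names: dict[int, str] = {}
    seen: set[str] = set()
    for i, nd in enumerate(dtree.preorder_node_iter()):
        label = None
        if nd.taxon is not None and nd.taxon.label:
            label = str(nd.taxon.label)
        elif nd.label:
            label = str(nd.label)
        if label is None:
            label = f"nd{i}"
        if label in seen:
            raise NewickError(f"duplicate node label: {label!r}")
        seen.add(label)
        names[id(nd)] = label

    edges: list[tuple[str, str, float]] = []
    root_name = names[id(dtree.seed_node)]
    for nd in dtree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        ln = nd.edge.length
        if ln is None:
            ln = default_length
        if ln < 0:
            raise NewickError(
                f"negative branch length {ln} above node {names[id(nd)]!r}"
            )
        edges.append((names[id(nd.parent_node)], names[id(nd)], float(ln)))
    tree = PhyloTree.from_edges(root_name, edges)
    if tree.n_tips < 1:
        raise NewickError("tree has no tips")
    return tree


def _fmt_len(x: float) -> str:
    return format(x, ".17g")


def write_newick(tree: PhyloTree, include_internal_labels: bool = True) -> str:
    """Serialize a tree to Newick; round-trips topology and lengths."""

    def rec(node: str) -> str:
        kids = tree.children[node]
        label = node if (not kids or include_internal_labels) else ""
        body = f"({','.join(rec(k) for k in kids)})" if kids else ""
        if node == tree.root:
            return f"{body}{label}"
        return f"{body}{label}:{_fmt_len(tree.length[node])}"

    return rec(tree.root) + ";"


def prune_tips(
    tree: PhyloTree, drop: Iterable[str]
) -> tuple[PhyloTree, dict[str, tuple[str, float]]]:
    """Remove the named tips; suppress the degree-2 nodes this creates.

    Suppressing a node merges its two incident edges (lengths summed), so path
    lengths between all retained tips are conserved. Returns the pruned tree
    and a placement map for every suppressed node::

        suppressed_name -> (retained_descendant, distance_above_descendant)

    i.e. the suppressed node sits on the pruned tree's edge *above*
    ``retained_descendant``, at the given distance up from it. This is what
    lets ancestral states be evaluated at allopolyploid-origin anchor points
    after the polyploid tips themselves are removed.
    """
    drop = set(drop)
    missing = drop - set(tree.tips)
    if missing:
        raise ValueError(f"tips not in tree: {sorted(missing)}")
    if len(drop) >= tree.n_tips:
        raise ValueError("cannot prune all tips")

    placement: dict[str, tuple[str, float]] = {}

    def rec(node: str) -> tuple[str, float, list] | None:
        """Return (name, edge_length_above, child_entries) for the kept subtree."""
        kids = tree.children[node]
        if not kids:
            if node in drop:
                return None
            return (node, tree.length[node], [])
        kept = [r for r in (rec(k) for k in kids) if r is not None]
        if not kept:
            return None
        if len(kept) == 1:
            # suppress this node onto the surviving child's edge
            name, ln, sub = kept[0]
            placement[node] = (name, ln)
            return (name, ln + tree.length[node], sub)
        return (node, tree.length[node], kept)

    top = rec(tree.root)
    assert top is not None
    root_name, _, sub = top
    edges: list[tuple[str, str, float]] = []

    def collect(parent_name: str, entries: list) -> None:
        for name, ln, sub_entries in entries:
            edges.append((parent_name, name, ln))
            collect(name, sub_entries)

    collect(root_name, sub)
    pruned = PhyloTree.from_edges(root_name, edges)
    return pruned, placement


def diploid_view(tree: PhyloTree, registry) -> PhyloTree:
    """Tree with all allopolyploid homeolog-copy tips removed.

    ``registry`` is a :class:`floralevo.tables.PolyploidRegistry`. Both the
    maternal and the paternal copy tip of every accession are pruned and the
    resulting degree-2 nodes suppressed, leaving the diploid species tree the
    ancestral reconstructions run on.
    """
    copies = registry.copy_tips()
    missing = [c for c in copies if c not in set(tree.tips)]
    if missing:
        raise ValueError(f"registry copy tips missing from tree: {missing}")
    bad = [p for p in registry.progenitors() if p not in set(tree.tips)]
    if bad:
        raise ValueError(f"registry progenitors missing from tree: {bad}")
    pruned, _ = prune_tips(tree, copies)
    return pruned
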