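"""Phylogenetic trees: Newick round-tripping, rooting, and traversal.

Trees are held as :class:`dendropy.Tree` objects behind a thin wrapper that
adds the conventions the rest of the package relies on:

* every node carries a stable string id — leaves use their taxon label,
  unlabeled internal nodes are assigned ``N1``, ``N2``, ... in preorder
  (parse order);
* branch lengths are substitutions per site, ``>= 0``, with absent lengths
  read as 0;
* polytomies are permitted, but there is exactly one root.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import dendropy
import numpy as np

from .errors import (
    InvalidArgumentError,
    NewickParseError,
    NonMonophyleticOutgroupError,
)


def _format_length(x: float) -> str:
    return format(float(x), ".17g")


class PhylogeneticTree:
    """Rooted tree with branch lengths and stable node ids."""

    def __init__(self, dtree: dendropy.Tree):
        self._tree = dtree
        self._assign_ids()
        self._validate()

    # -- construction -------------------------------------------------------
    @classmethod
    def from_newick(cls, text: str) -> "PhylogeneticTree":
        """Parse a Newick string.

        Raises :class:`NewickParseError` on malformed input or duplicate
        leaf labels.
        """
        if not text or not text.strip():
            raise NewickParseError("empty Newick string")
        try:
            dtree = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several error types
            raise NewickParseError(f"malformed Newick: {exc}") from None
        return cls(dtree)

    def to_newick(self) -> str:
        """Serialize to Newick; inverse of :meth:`from_newick`."""

        def render(node: dendropy.Node) -> str:
            if node.is_leaf():
                label = node.taxon.label if node.taxon else (node.label or "")
            else:
                label = node.label or ""
            if node.is_leaf():
                body = label
            else:
                body = "(" + ",".join(render(c) for c in node.child_nodes()) + ")"
                body += label
            if node.parent_node is not None and node.edge.length is not None:
                body += ":" + _format_length(node.edge.length)
            return body

        return render(self._tree.seed_node) + ";"

    def copy(self) -> "PhylogeneticTree":
        return PhylogeneticTree.from_newick(self.to_newick())

    # -- internals -----------------------------------------------------------
    def _assign_ids(self) -> None:
        counter = 0
        seen: dict[str, int] = {}
        self._nodes: dict[str, dendropy.Node] = {}
        for node in self._tree.preorder_node_iter():
            if node.is_leaf():
                nid = node.taxon.label if node.taxon else node.label
                if not nid:
                    raise NewickParseError("leaf without a label")
            elif node.label:
                nid = node.label
            else:
                counter += 1
                nid = f"N{counter}"
                while nid in seen:
                    counter += 1
                    nid = f"N{counter}"
            seen[nid] = seen.get(nid, 0) + 1
            node.nid = nid
            self._nodes[nid] = node
        dup = sorted(k for k, v in seen.items() if v > 1)
        if dup:
            raise NewickParseError(f"duplicate node labels: {dup}")

    def _validate(self) -> None:
        for node in self._tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            length = node.edge.length
            if length is None:
                continue
            if not math.isfinite(length) or length < 0:
                raise InvalidArgumentError(
                    f"branch length of node {node.nid!r} is {length}; "
                    "must be finite and >= 0"
                )

    def _node(self, nid: str) -> dendropy.Node:
        try:
            return self._nodes[nid]
        except KeyError:
            raise InvalidArgumentError(f"unknown node id {nid!r}") from None

    # -- queries -------------------------------------------------------------
    @property
    def root_id(self) -> str:
        return self._tree.seed_node.nid

    @property
    def leaf_labels(self) -> list[str]:
        return [n.nid for n in self._tree.leaf_node_iter()]

    @property
    def node_ids(self) -> list[str]:
        return [n.nid for n in self._tree.preorder_node_iter()]

    @property
    def internal_ids(self) -> list[str]:
        return [
            n.nid for n in self._tree.preorder_node_iter() if not n.is_leaf()
        ]

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    def is_leaf(self, nid: str) -> bool:
        return self._node(nid).is_leaf()

    def branch_length(self, nid: str) -> float:
        """Length of the branch above ``nid`` (0 for the root)."""
        node = self._node(nid)
        if node.parent_node is None:
            return 0.0
        return float(node.edge.length or 0.0)

    def parent_id(self, nid: str) -> str | None:
        node = self._node(nid)
        return node.parent_node.nid if node.parent_node is not None else None

    def children_ids(self, nid: str) -> list[str]:
        return [c.nid for c in self._node(nid).child_nodes()]

    def total_branch_length(self) -> float:
        return sum(
            float(n.edge.length or 0.0)
            for n in self._tree.preorder_node_iter()
            if n.parent_node is not None
        )

    def leaves_below(self, nid: str) -> frozenset[str]:
        node = self._node(nid)
        return frozenset(leaf.nid for leaf in node.leaf_iter())

    def mrca(self, labels: Iterable[str]) -> str:
        """Id of the most recent common ancestor of the given leaves."""
        want = set(labels)
        missing = want - set(self.leaf_labels)
        if missing:
            raise InvalidArgumentError(f"unknown leaf labels: {sorted(missing)}")
        best = None
        for node in self._tree.postorder_node_iter():
            below = frozenset(leaf.nid for leaf in node.leaf_iter())
            if want <= below and (best is None or len(below) < len(best[1])):
                best = (node.nid, below)
        assert best is not None
        return best[0]

    def flatten(self) -> "FlatTree":
        """Array view of the tree in postorder, for numeric code."""
        order = list(self._tree.postorder_node_iter())
        index = {id(n): k for k, n in enumerate(order)}
        ids = [n.nid for n in order]
        parent = np.full(len(order), -1, dtype=np.int64)
        blen = np.zeros(len(order))
        is_leaf = np.zeros(len(order), dtype=bool)
        children: list[list[int]] = [[] for _ in order]
        for k, node in enumerate(order):
            is_leaf[k] = node.is_leaf()
            if node.parent_node is not None:
                parent[k] = index[id(node.parent_node)]
                blen[k] = float(node.edge.length or 0.0)
            children[k] = [index[id(c)] for c in node.child_nodes()]
        return FlatTree(
            ids=ids,
            parent=parent,
            branch_lengths=blen,
            is_leaf=is_leaf,
            children=children,
        )

    # -- rooting -------------------------------------------------------------
    def root_on_outgroup(self, outgroup_labels: Iterable[str]) -> "PhylogeneticTree":
        """Return a new tree rooted on the branch separating ``outgroup_labels``.

        The outgroup must form one side of a branch when the tree is viewed
        as unrooted; the new root splits that branch at its midpoint, so the
        total branch length is unchanged.
        """
        outgroup = frozenset(outgroup_labels)
        leaves = frozenset(self.leaf_labels)
        missing = outgroup - leaves
        if missing:
            raise InvalidArgumentError(
                f"outgroup labels not in tree: {sorted(missing)}"
            )
        if outgroup == leaves or not outgroup:
            raise InvalidArgumentError(
                "outgroup must be a proper non-empty subset of the leaves"
            )
        work = self.copy()
        dtree = work._tree
        target = None
        for node in dtree.postorder_node_iter():
            if node.parent_node is None:
                continue
            below = frozenset(leaf.nid for leaf in node.leaf_iter())
            if below == outgroup or below == leaves - outgroup:
                target = node
                break
        if target is None:
            raise NonMonophyleticOutgroupError(
                f"outgroup {sorted(outgroup)} does not form one side of any "
                f"branch (offending bipartition vs {sorted(leaves - outgroup)})"
            )
        length = float(target.edge.length or 0.0)
        dtree.reroot_at_edge(
            target.edge,
            length1=length / 2.0,
            length2=length / 2.0,
            update_bipartitions=False,
        )
        dtree.suppress_unifurcations()
        dtree.seed_node.edge.length = None
        return PhylogeneticTree(dtree)


@dataclass
class FlatTree:
    """Postorder array representation used by the likelihood machinery."""

    ids: list[str]
    parent: np.ndarray
    branch_lengths: np.ndarray
    is_leaf: np.ndarray
    children: list[list[int]] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return len(self.ids)

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    def index_of(self, nid: str) -> int:
        try:
            return self.ids.index(nid)
        except ValueError:
            raise InvalidArgumentError(f"unknown node id {nid!r}") from None


def parse_newick(text: str) -> PhylogeneticTree:
    """Module-level convenience alias for :meth:`PhylogeneticTree.from_newick`."""
    return PhylogeneticTree.from_newick(text)


def write_newick(tree: PhylogeneticTree) -> str:
    return tree.to_newick()


def root_on_outgroup(
    tree: PhylogeneticTree, outgroup_labels: Iterable[str]
) -> PhylogeneticTree:
    return tree.root_on_outgroup(outgroup_labels)
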