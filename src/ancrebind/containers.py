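"""Core containers: aligned amino-acid sequences and the rooted phylogeny
they evolve on."""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .model import AMINO_ACIDS, GAP_CODE, encode_residue

_VALID = set(AMINO_ACIDS) | {"-"}


@dataclass
class AminoAlignment:
    """Aligned protein sequences over the 20 standard residues plus '-'.

    Rows are equal-length strings; names are unique identifiers matching the
    tree's leaf labels.
    """

    names: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.rows):
            raise ValueError("names and rows must have equal length")
        if len(set(self.names)) != len(self.names):
            dupes = sorted({n for n in self.names if self.names.count(n) > 1})
            raise ValueError(f"duplicate sequence names: {dupes}")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"rows have unequal lengths: {sorted(lengths)}")
        self.rows = [r.upper() for r in self.rows]
        for name, row in zip(self.names, self.rows):
            bad = set(row) - _VALID
            if bad:
                raise ValueError(
                    f"sequence {name!r} contains invalid symbols {sorted(bad)}")

    @property
    def n_sites(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def n_sequences(self) -> int:
        return len(self.rows)

    def codes(self) -> np.ndarray:
        """Integer state matrix (n_sequences, n_sites); gaps are GAP_CODE."""
        out = np.full((self.n_sequences, self.n_sites), GAP_CODE, dtype=np.int8)
        for i, row in enumerate(self.rows):
            out[i] = [encode_residue(c) for c in row]
        return out

    def sequence(self, name: str) -> str:
        try:
            return self.rows[self.names.index(name)]
        except ValueError:
            raise KeyError(f"no sequence named {name!r}") from None


class PhyloTree:
    """Rooted tree with branch lengths and (optionally) labeled internal nodes.

    Thin wrapper over a dendropy tree that preserves internal-node labels and
    exposes the flattened arrays the pruning code works on.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._validate()

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        tree = dendropy.Tree.get(
            data=newick, schema="newick",
            suppress_internal_node_taxa=False, preserve_underscores=True)
        return cls(tree)

    def _validate(self) -> None:
        for edge in self._tree.preorder_edge_iter():
            if edge.length is not None and (
                    not np.isfinite(edge.length) or edge.length < 0):
                raise ValueError(f"invalid branch length {edge.length}")
        labels = [self.node_label(n) for n in self._tree.preorder_node_iter()
                  if not n.is_leaf() and self.node_label(n)]
        if len(labels) != len(set(labels)):
            raise ValueError("internal node labels are not unique")

    @staticmethod
    def node_label(node: dendropy.Node) -> str | None:
        if node.taxon is not None and node.taxon.label:
            return node.taxon.label
        return node.label or None

    @property
    def leaf_labels(self) -> list[str]:
        return [self.node_label(n) for n in self._tree.leaf_node_iter()]

    @property
    def internal_labels(self) -> list[str]:
        return [self.node_label(n) for n in self._tree.preorder_node_iter()
                if not n.is_leaf() and self.node_label(n)]

    def find_internal(self, label: str) -> dendropy.Node:
        for node in self._tree.preorder_node_iter():
            if not node.is_leaf() and self.node_label(node) == label:
                return node
        raise KeyError(
            f"no internal node labeled {label!r}; available: "
            f"{self.internal_labels}")

    def clade_leaves(self, label: str) -> list[str]:
        """Extant members of the clade rooted at `label` (a leaf label names
        a single-sequence clade)."""
        if label in self.leaf_labels:
            return [label]
        node = self.find_internal(label)
        return [self.node_label(n) for n in node.leaf_iter()]

    def to_newick(self) -> str:
        return self._tree.as_string(
            schema="newick", suppress_rooting=True,
            unquoted_underscores=True).strip()

    def clone(self) -> "PhyloTree":
        return PhyloTree(self._tree.clone(depth=1))

    # --- flattened view for likelihood code -------------------------------

    def flatten(self) -> "FlatTree":
        nodes = list(self._tree.postorder_node_iter())
        index = {id(n): i for i, n in enumerate(nodes)}
        parent = np.full(len(nodes), -1, dtype=int)
        lengths = np.zeros(len(nodes))
        children: list[list[int]] = [[] for _ in nodes]
        labels: list[str | None] = [None] * len(nodes)
        is_leaf = np.zeros(len(nodes), dtype=bool)
        for i, n in enumerate(nodes):
            labels[i] = self.node_label(n)
            is_leaf[i] = n.is_leaf()
            if n.parent_node is not None:
                p = index[id(n.parent_node)]
                parent[i] = p
                children[p].append(i)
                lengths[i] = n.edge.length if n.edge.length is not None else 0.0
        return FlatTree(parent=parent, children=children, lengths=lengths,
                        labels=labels, is_leaf=is_leaf, source=self)

    def set_lengths_from(self, flat: "FlatTree") -> None:
        nodes = list(self._tree.postorder_node_iter())
        for i, n in enumerate(nodes):
            if n.parent_node is not None:
                n.edge.length = float(flat.lengths[i])


@dataclass
class FlatTree:
    """Postorder array representation used by the pruning algorithm."""

    parent: np.ndarray
    children: list[list[int]]
    lengths: np.ndarray
    labels: list[str | None]
    is_leaf: np.ndarray
    source: PhyloTree = field(repr=False)

    @property
    def n_nodes(self) -> int:
        return len(self.lengths)

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    def leaf_index(self) -> dict[str, int]:
        return {self.labels[i]: i for i in range(self.n_nodes)
                if self.is_leaf[i]}

    def internal_index(self) -> dict[str, int]:
        return {self.labels[i]: i for i in range(self.n_nodes)
                if not self.is_leaf[i] and self.labels[i]}
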