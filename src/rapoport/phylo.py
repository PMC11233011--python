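"""Rooted phylogenies for comparative analyses.

Thin wrapper around :mod:`dendropy` providing the pieces the statistical
machinery needs: Newick IO, tip pruning, and the Brownian-motion covariance
matrix ``C`` whose entry ``C[i, j]`` is the shared path length from the root
to the most recent common ancestor of tips ``i`` and ``j``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np

from .errors import InvalidTreeError, NewickParseError

__all__ = ["Phylogeny"]


class Phylogeny:
    """A rooted tree with branch lengths and uniquely labelled tips.

    Polytomies are accepted on input and resolved into arbitrary
    zero-length bifurcations, so downstream algebra can assume a binary
    tree without changing the induced Brownian covariance.
    """

    def __init__(self, tree: dendropy.Tree):
        tree = tree.clone(depth=1)
        tree.resolve_polytomies()
        for edge in tree.preorder_edge_iter():
            if edge.length is None:
                edge.length = 0.0
            elif edge.length < 0:
                raise InvalidTreeError(f"negative branch length {edge.length}")
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if any(lbl is None or lbl == "" for lbl in labels):
            raise InvalidTreeError("every tip must carry a non-empty label")
        if len(set(labels)) != len(labels):
            raise InvalidTreeError("tip labels must be unique")
        self._tree = tree
        self._labels = labels

    # ------------------------------------------------------------------ IO
    @classmethod
    def from_newick(cls, source: str | Path) -> "Phylogeny":
        """Parse a Newick string or file path."""
        text = None
        if isinstance(source, Path) or (
            isinstance(source, str) and "(" not in source and Path(source).exists()
        ):
            text = Path(source).read_text()
        else:
            text = str(source)
        try:
            tree = dendropy.Tree.get(
                data=text, schema="newick", suppress_internal_node_taxa=True
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise NewickParseError(f"malformed Newick: {exc}") from exc
        return cls(tree)

    def to_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()

    def write_newick(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")

    # ------------------------------------------------------------ structure
    @property
    def tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def tip_labels(self) -> list[str]:
        return list(self._labels)

    @property
    def n_tips(self) -> int:
        return len(self._labels)

    @property
    def n_edges(self) -> int:
        root = self._tree.seed_node
        return sum(1 for nd in self._tree.preorder_node_iter() if nd is not root)

    def depth(self) -> float:
        """Maximum root-to-tip path length."""
        return max(self.root_distances().values())

    def root_distances(self) -> dict[str, float]:
        self._tree.calc_node_root_distances(
            return_leaf_distances_only=False
        )
        return {
            leaf.taxon.label: leaf.root_distance
            for leaf in self._tree.leaf_node_iter()
        }

    def prune_to(self, labels: Iterable[str]) -> "Phylogeny":
        """Return a copy retaining only the given tip labels."""
        keep = set(labels)
        missing = keep - set(self._labels)
        if missing:
            raise InvalidTreeError(f"labels absent from tree: {sorted(missing)}")
        tree = self._tree.clone(depth=1)
        tree.retain_taxa_with_labels(sorted(keep))
        return Phylogeny(tree)

    def rescale_depth(self, target: float = 1.0) -> "Phylogeny":
        """Return a copy with maximum root-to-tip depth rescaled to ``target``."""
        d = self.depth()
        if d <= 0:
            raise InvalidTreeError("tree has zero depth; cannot rescale")
        tree = self._tree.clone(depth=1)
        factor = target / d
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= factor
        return Phylogeny(tree)

    # ------------------------------------------------------------- algebra
    def brownian_covariance(
        self, order: Sequence[str] | None = None
    ) -> tuple[np.ndarray, list[str]]:
        """Brownian covariance matrix and the tip order it uses.

        ``C[i, j]`` is the root-to-MRCA path length of tips ``i`` and
        ``j``; the diagonal holds root-to-tip distances.  The matrix is
        symmetric positive semi-definite by construction.
        """
        labels = list(order) if order is not None else self.tip_labels
        index = {lbl: i for i, lbl in enumerate(labels)}
        if len(index) != len(labels):
            raise InvalidTreeError("requested tip order contains duplicates")
        missing = set(labels) - set(self._labels)
        if missing:
            raise InvalidTreeError(f"labels absent from tree: {sorted(missing)}")
        n = len(labels)
        C = np.zeros((n, n))
        self._tree.calc_node_root_distances(return_leaf_distances_only=False)
        # Post-order sweep: at each internal node, tips in different child
        # subtrees share exactly that node's depth.
        tipsets: dict[int, list[int]] = {}
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                lbl = node.taxon.label
                if lbl in index:
                    i = index[lbl]
                    C[i, i] = node.root_distance
                    tipsets[id(node)] = [i]
                else:
                    tipsets[id(node)] = []
                continue
            child_sets = [tipsets.pop(id(ch)) for ch in node.child_nodes()]
            depth = node.root_distance or 0.0
            for a in range(len(child_sets)):
                for b in range(a + 1, len(child_sets)):
                    for i in child_sets[a]:
                        for j in child_sets[b]:
                            C[i, j] = C[j, i] = depth
            merged: list[int] = []
            for s in child_sets:
                merged.extend(s)
            tipsets[id(node)] = merged
        return C, labels
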