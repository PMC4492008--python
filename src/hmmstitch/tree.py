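"""Unrooted leaf-labelled phylogenetic trees.

A thin wrapper over :mod:`dendropy` providing exactly what the method needs:
Newick I/O, leaf-label access, enumeration of edges as leaf-set splits
(bipartitions), and restriction to a label subset with suppression of the
resulting degree-2 nodes.  Trees are treated as unrooted throughout; the
bipartition set is invariant under re-rooting.
"""

from __future__ import annotations

from typing import Iterable

import dendropy

from .errors import TreeError

Split = tuple[frozenset, frozenset]


class PhyloTree:
    def __init__(self, dtree: dendropy.Tree):
        dtree.is_rooted = False
        if dtree.seed_node.num_child_nodes() == 2 and len(dtree.leaf_nodes()) > 2:
            dtree.deroot()
        self._tree = dtree
        labels = [lf.taxon.label for lf in dtree.leaf_node_iter()]
        if any(lb is None for lb in labels):
            raise TreeError("tree has unlabelled leaves")
        if len(set(labels)) != len(labels):
            dup = sorted({lb for lb in labels if labels.count(lb) > 1})
            raise TreeError(f"duplicate leaf labels: {dup}")
        self._labels = tuple(labels)

    # -- construction -------------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        try:
            dtree = dendropy.Tree.get(
                data=newick,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise TreeError(f"Newick parse error: {exc}") from exc
        return cls(dtree)

    @classmethod
    def read(cls, path) -> "PhyloTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    # -- output -------------------------------------------------------------
    def to_newick(self) -> str:
        return self._tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    # -- queries ------------------------------------------------------------
    @property
    def leaf_labels(self) -> tuple[str, ...]:
        return self._labels

    def __len__(self) -> int:
        return len(self._labels)

    def edge_splits(self) -> list[Split]:
        """One (side, other-side) leaf-set split per edge, pendant included.

        Deterministic order (tree traversal order); duplicate splits arising
        from the arbitrary internal rooting of the data structure are merged.
        """
        all_leaves = frozenset(self._labels)
        seen = set()
        splits: list[Split] = []
        for node in self._tree.preorder_node_iter():
            if node is self._tree.seed_node:
                continue
            side = frozenset(
                lf.taxon.label for lf in node.leaf_iter()
            )
            other = all_leaves - side
            if not side or not other:
                continue
            key = frozenset((side, other))
            if key in seen:
                continue
            seen.add(key)
            splits.append((side, other))
        return splits

    def bipartitions(self) -> set[frozenset]:
        """Internal-edge bipartitions as frozensets of the two leaf sides."""
        return {
            frozenset((a, b))
            for a, b in self.edge_splits()
            if len(a) >= 2 and len(b) >= 2
        }

    def restrict(self, labels: Iterable[str]) -> "PhyloTree":
        wanted = set(labels)
        missing = wanted - set(self._labels)
        if missing:
            raise TreeError(f"labels not in tree: {sorted(missing)}")
        sub = self._tree.extract_tree_with_taxa_labels(wanted)
        return PhyloTree(sub)

    def validate_leaf_set(self, ids: Iterable[str], context: str = "tree") -> None:
        have, want = set(self._labels), set(ids)
        if have != want:
            extra, missing = sorted(have - want), sorted(want - have)
            raise TreeError(
                f"{context}: leaf set mismatch (extra: {extra[:5]}, "
                f"missing: {missing[:5]})"
            )
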