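"""Ensemble of HMMs via recursive centroid-edge tree decomposition.

The backbone tree is decomposed by removing a *centroid edge* — an edge whose
removal splits the leaves into two sides as equal as possible — and recursing
on the induced subtrees until every subset holds at most ``subset_max``
sequences.  One HMM is trained on the backbone alignment restricted to each
subset's leaf set; the full backbone set itself is always the first member
(subsets produced this way are local regions of the tree but need not be
clades).  Two variant ensembles are supported: ``none`` keeps only the single
full-set HMM, and ``disjoint`` keeps only the leaf-level subsets, which
partition the backbone.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import RunConfig
from .errors import ConfigError, HmmstitchError
from .phmm import ProfileHMM, build_profile, residue_frequencies
from .seqio import Alignment
from .tree import PhyloTree, Split


@dataclass
class DecompositionNode:
    leaf_ids: frozenset
    children: tuple = ()  # empty or (DecompositionNode, DecompositionNode)

    def nodes(self):
        """All nodes, preorder (self first)."""
        yield self
        for child in self.children:
            yield from child.nodes()

    def leaves(self):
        """Leaf-level nodes only, preorder."""
        if not self.children:
            yield self
        else:
            for child in self.children:
                yield from child.leaves()


def find_centroid_edge(tree: PhyloTree) -> Split:
    """The edge minimising the larger side's leaf count, as a (smaller,
    larger) split.  Ties are broken by the lexicographically least leaf label
    on the smaller side, then by the full sorted smaller side, which makes
    the choice deterministic."""
    if len(tree) < 2:
        raise HmmstitchError("centroid edge requires a tree with >= 2 leaves")

    def key(split: Split):
        a, b = split
        smaller, larger = sorted((a, b), key=lambda s: (len(s), min(s)))
        return (len(larger), min(smaller), tuple(sorted(smaller)))

    best = min(tree.edge_splits(), key=key)
    a, b = best
    smaller, larger = sorted((a, b), key=lambda s: (len(s), min(s)))
    return smaller, larger


def decompose(tree: PhyloTree, cfg: RunConfig) -> DecompositionNode:
    """Recursive centroid-edge decomposition down to ``cfg.subset_max``.

    Each recursion splits the subtree induced on the current subset (degree-2
    nodes suppressed); children's leaf sets partition the parent's.
    """
    leaf_ids = frozenset(tree.leaf_labels)
    if len(leaf_ids) <= cfg.subset_max:
        return DecompositionNode(leaf_ids)
    smaller, larger = find_centroid_edge(tree)
    children = tuple(
        decompose(tree.restrict(side), cfg) for side in (smaller, larger)
    )
    return DecompositionNode(leaf_ids, children)


@dataclass
class EnsembleMember:
    subset_id: int
    leaf_ids: frozenset
    hmm: ProfileHMM


@dataclass
class HMMEnsemble:
    members: list[EnsembleMember]

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)


def build_ensemble(
    backbone_aln: Alignment, decomp: DecompositionNode, cfg: RunConfig
) -> HMMEnsemble:
    """Train the ensemble on row-restrictions of the backbone alignment.

    ``hierarchical`` keeps every decomposition node (full set first, preorder);
    ``none`` keeps only the full set; ``disjoint`` keeps only the leaf-level
    subsets.  Every member HMM shares the full backbone's null frequencies so
    bit scores are comparable, and its ``column_map`` indexes the shared
    backbone alignment (all-gap columns within a subset are dropped by the
    profile builder).
    """
    mode = cfg.decomposition_mode
    if mode == "hierarchical":
        nodes = list(decomp.nodes())
    elif mode == "none":
        nodes = [DecompositionNode(decomp.leaf_ids)]
    elif mode == "disjoint":
        nodes = list(decomp.leaves())
    else:  # pragma: no cover - RunConfig already validates
        raise ConfigError(f"unknown decomposition mode {mode!r}")

    missing = decomp.leaf_ids - set(backbone_aln.rows)
    if missing:
        raise HmmstitchError(
            f"decomposition references ids absent from the backbone: "
            f"{sorted(missing)[:5]}"
        )
    null = residue_frequencies(backbone_aln, cfg.pseudocount)
    members = []
    for sid, node in enumerate(nodes):
        subaln = backbone_aln.restrict(node.leaf_ids)
        hmm = build_profile(subaln, cfg.pseudocount, null_frequencies=null)
        members.append(EnsembleMember(sid, node.leaf_ids, hmm))
    return HMMEnsemble(members)
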