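"""Sequence evolution simulator and the fragmentation protocol.

The simulator evolves a root sequence down a tree with branch lengths in
expected substitutions per site: Jukes-Cantor substitutions for nucleotides
(uniform replacement for amino acids), and insertions/deletions occurring per
site at ``indel_rate`` x branch length with geometric lengths.  Every site
ever created carries a unique identity, so the *true alignment* of the leaves
— the complete record of which residues are homologous — falls out directly;
it is returned together with the leaf sequences and the (input) tree.

``fragment`` implements the fragmentary-sequence protocol: a stated fraction
of sequences is replaced by contiguous substrings whose target lengths are
drawn from a normal distribution (the benchmark convention is mean 500, sd
60); selection of sequences and of substring positions is uniform and seeded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabet import GAP, Alphabet, get_alphabet
from .errors import HmmstitchError
from .seqio import Alignment, SequenceRecord, SequenceSet
from .tree import PhyloTree


@dataclass
class SimulationSpec:
    tree: PhyloTree
    root_length: int = 500
    substitution_rate: float = 1.0  # per site per unit branch length
    indel_rate: float = 0.02  # insertion and deletion rate, per site
    indel_p: float = 0.5  # geometric length parameter (mean 1/p)
    alphabet: str = "dna"
    seed: int = 0

    def __post_init__(self):
        if self.root_length < 1:
            raise HmmstitchError("root_length must be positive")
        if self.substitution_rate < 0 or self.indel_rate < 0:
            raise HmmstitchError("rates must be non-negative")
        if not 0.0 < self.indel_p <= 1.0:
            raise HmmstitchError("indel_p must lie in (0, 1]")


@dataclass
class FragmentSpec:
    fraction: float
    mean: float = 500.0
    sd: float = 60.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.fraction <= 1.0:
            raise HmmstitchError("fraction must lie in [0, 1]")
        if self.mean <= 0 or self.sd < 0:
            raise HmmstitchError("mean must be > 0 and sd >= 0")


def _sub_probability(rate_times_t: float, a_size: int) -> float:
    """Probability a site shows a different symbol after branch length t,
    under the Jukes-Cantor style uniform-replacement model."""
    frac = (a_size - 1) / a_size
    return frac * (1.0 - np.exp(-rate_times_t / frac))


def simulate(spec: SimulationSpec) -> tuple[SequenceSet, Alignment, PhyloTree]:
    """Evolve sequences down ``spec.tree``; returns (leaf sequences, true
    alignment, tree).  Ungapping any true-alignment row reproduces the
    corresponding leaf sequence exactly."""
    ab = get_alphabet(spec.alphabet)
    rng = np.random.default_rng(spec.seed)
    symbols = spec_symbols = list(ab.canonical)
    A = len(symbols)

    next_site = [0]

    def new_sites(n: int) -> list[int]:
        ids = list(range(next_site[0], next_site[0] + n))
        next_site[0] += n
        return ids

    # master column order over every site ever created
    root_sites = new_sites(spec.root_length)
    master: list[int] = list(root_sites)
    root_chars = {
        s: symbols[i] for s, i in zip(root_sites, rng.integers(0, A, len(root_sites)))
    }

    def evolve(sites: list[int], chars: dict[int, str], t: float):
        child_sites = list(sites)
        child_chars = dict(chars)
        if t > 0 and spec.substitution_rate > 0 and child_sites:
            p_sub = _sub_probability(spec.substitution_rate * t, A)
            hits = np.flatnonzero(rng.random(len(child_sites)) < p_sub)
            for h in hits:
                s = child_sites[h]
                cur = child_chars[s]
                alt = [c for c in spec_symbols if c != cur]
                child_chars[s] = alt[rng.integers(0, A - 1)]
        if t > 0 and spec.indel_rate > 0:
            p_indel = min(spec.indel_rate * t, 0.5)
            # deletions: each site may start a geometric-length deletion
            if child_sites:
                starts = np.flatnonzero(rng.random(len(child_sites)) < p_indel)
                doomed = set()
                for h in starts:
                    if h in doomed:
                        continue
                    length = int(rng.geometric(spec.indel_p))
                    for j in range(h, min(h + length, len(child_sites))):
                        doomed.add(j)
                if doomed:
                    for j in doomed:
                        del child_chars[child_sites[j]]
                    child_sites = [
                        s for j, s in enumerate(child_sites) if j not in doomed
                    ]
            # insertions: each inter-site position (ends included) may gain
            # a geometric-length run of fresh sites
            positions = np.flatnonzero(
                rng.random(len(child_sites) + 1) < p_indel
            )
            for p in reversed(positions.tolist()):
                length = int(rng.geometric(spec.indel_p))
                ids = new_sites(length)
                for s, i in zip(ids, rng.integers(0, A, length)):
                    child_chars[s] = symbols[i]
                # splice into the master order after the left neighbour
                if p == 0:
                    if child_sites:
                        mpos = master.index(child_sites[0])
                    else:
                        mpos = 0
                else:
                    mpos = master.index(child_sites[p - 1]) + 1
                master[mpos:mpos] = ids
                child_sites[p:p] = ids
        return child_sites, child_chars

    # rooted traversal of the (unrooted) tree from its internal seed node
    dtree = spec.tree._tree
    leaves: dict[str, tuple[list[int], dict[int, str]]] = {}

    def walk(node, sites, chars):
        for child in node.child_nodes():
            t = child.edge.length if child.edge.length is not None else 0.0
            cs, cc = evolve(sites, chars, float(t))
            if child.is_leaf():
                leaves[child.taxon.label] = (cs, cc)
            else:
                walk(child, cs, cc)

    walk(dtree.seed_node, root_sites, root_chars)

    used = set()
    for sites, _ in leaves.values():
        used.update(sites)
    columns = [s for s in master if s in used]
    col_of = {s: j for j, s in enumerate(columns)}

    rows = {}
    order = list(spec.tree.leaf_labels)
    for label in order:
        sites, chars = leaves[label]
        row = [GAP] * len(columns)
        for s in sites:
            row[col_of[s]] = chars[s]
        rows[label] = "".join(row)
    true_aln = Alignment(rows, ab)
    seqs = SequenceSet(
        SequenceRecord(label, true_aln.ungapped(label), ab) for label in order
    )
    return seqs, true_aln, spec.tree


def fragment(seqs: SequenceSet, spec: FragmentSpec) -> SequenceSet:
    """Replace round(fraction x n) sequences by contiguous substrings.

    Target lengths are normal(mean, sd) draws: non-positive draws are redrawn,
    draws longer than the source are clamped to the full length.  Selection of
    sequences and substring start positions is uniform.  Returns a new set in
    the original order; untouched sequences are identical objects.
    """
    rng = np.random.default_rng(spec.seed)
    ids = list(seqs.ids)
    n_frag = int(np.floor(spec.fraction * len(ids) + 0.5))  # round half up
    chosen = set(
        rng.choice(np.array(ids, dtype=object), n_frag, replace=False).tolist()
    )
    out = []
    for rec in seqs:
        if rec.id not in chosen:
            out.append(rec)
            continue
        L = len(rec.residues)
        target = 0
        while target < 1:
            target = int(round(rng.normal(spec.mean, spec.sd)))
        target = min(target, L)
        start = int(rng.integers(0, L - target + 1))
        out.append(
            SequenceRecord(rec.id, rec.residues[start : start + target], rec.alphabet)
        )
    return SequenceSet(out)


def random_tree(
    n_leaves: int,
    seed: int = 0,
    mean_branch_length: float = 0.05,
    prefix: str = "S",
) -> PhyloTree:
    """A random binary topology with exponential branch lengths, built by
    repeatedly joining two uniformly chosen clusters (label order S1..Sn)."""
    if n_leaves < 2:
        raise HmmstitchError("need at least 2 leaves")
    rng = np.random.default_rng(seed)
    clusters = [f"{prefix}{i + 1}" for i in range(n_leaves)]

    def bl() -> float:
        return float(rng.exponential(mean_branch_length))

    clusters = [f"{c}:{bl():.6f}" for c in clusters]
    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), 2, replace=False).tolist())
        b = clusters.pop(j)
        a = clusters.pop(i)
        merged = f"({a},{b})"
        if len(clusters) > 0:
            merged = f"{merged}:{bl():.6f}"
        clusters.append(merged)
    return PhyloTree.from_newick(clusters[0] + ";")
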