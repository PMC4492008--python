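"""Alignment and tree evaluation metrics.

Every MATCH column of an alignment is read as a statement of positional
homology among the residues it contains; INSERTION columns assert nothing and
are excluded.  With R and E the homology-pair sets of a reference and an
estimated alignment:

    SPFN = 100 * |R \\ E| / |R|      (reference pairs missed)
    SPFP = 100 * |E \\ R| / |E|      (estimated pairs that are wrong)
    SP-error = (SPFN + SPFP) / 2
    TC   = 100 * fraction of reference columns holding >= 2 residues whose
           exact residue set is reproduced as a column of the estimate

Pairs are keyed by (sequence id, ungapped residue index), so the scores are
insensitive to column order and to how insertion blocks are packed.  An empty
pair set contributes a rate of 0 by convention, and TC of an alignment with
no >= 2-residue reference columns is 100, so degenerate inputs never crash.

Tree error is the FN (missing branch) rate: the percentage of internal-edge
bipartitions of the reference tree absent from the estimated tree.  dFN
subtracts the FN rate of the tree built on the true alignment, and may be
negative.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from itertools import combinations

from .alphabet import GAP
from .errors import AlignmentError, TreeError
from .seqio import MATCH, Alignment
from .tree import PhyloTree


def homology_pairs(aln: Alignment) -> set:
    """All unordered residue pairs asserted by the alignment's MATCH columns.

    Each pair is a frozenset of two (id, ungapped-index) tuples.  Quadratic in
    rows per column; intended for small alignments and oracle checks —
    :func:`sp_scores` counts pairs without materialising them.
    """
    pairs = set()
    pos = {sid: -1 for sid in aln.rows}
    for j in range(aln.width):
        members = []
        for sid, row in aln.rows.items():
            if row[j] != GAP:
                pos[sid] += 1
                if aln.column_flags[j] == MATCH:
                    members.append((sid, pos[sid]))
        for a, b in combinations(members, 2):
            pairs.add(frozenset((a, b)))
    return pairs


@dataclass
class ScoreReport:
    spfn: float
    spfp: float
    sp_error: float
    tc: float


def _column_keys(aln: Alignment) -> dict[str, list[int]]:
    """Per sequence, the MATCH-column index of each ungapped residue
    (-1 when the residue sits in an INSERTION column)."""
    out = {}
    for sid, row in aln.rows.items():
        cols = []
        for j, ch in enumerate(row):
            if ch != GAP:
                cols.append(j if aln.column_flags[j] == MATCH else -1)
        out[sid] = cols
    return out


def _n_choose_2(n: int) -> int:
    return n * (n - 1) // 2


def sp_scores(estimated: Alignment, reference: Alignment) -> ScoreReport:
    """SPFN / SPFP / SP-error / TC of ``estimated`` against ``reference``.

    Both alignments must contain the same sequences with identical ungapped
    residues.  Runs in time linear in the number of residues.
    """
    if set(estimated.rows) != set(reference.rows):
        bad = sorted(set(estimated.rows) ^ set(reference.rows))[0]
        raise AlignmentError(f"sequence sets differ; first offender: {bad!r}")
    for sid in reference.rows:
        if estimated.ungapped(sid) != reference.ungapped(sid):
            raise AlignmentError(
                f"ungapped residues differ for sequence {sid!r}"
            )

    ref_cols = _column_keys(reference)
    est_cols = _column_keys(estimated)

    ref_count = Counter()
    est_count = Counter()
    both_count = Counter()
    ref_members = defaultdict(list)  # ref column -> [(sid, est col)]
    for sid in reference.rows:
        for idx, (rc, ec) in enumerate(zip(ref_cols[sid], est_cols[sid])):
            if rc >= 0:
                ref_count[rc] += 1
                ref_members[rc].append(ec)
            if ec >= 0:
                est_count[ec] += 1
            if rc >= 0 and ec >= 0:
                both_count[(rc, ec)] += 1

    n_ref = sum(_n_choose_2(m) for m in ref_count.values())
    n_est = sum(_n_choose_2(m) for m in est_count.values())
    n_shared = sum(_n_choose_2(m) for m in both_count.values())

    spfn = 100.0 * (n_ref - n_shared) / n_ref if n_ref else 0.0
    spfp = 100.0 * (n_est - n_shared) / n_est if n_est else 0.0

    tc_denom = tc_hit = 0
    for rc, members in ref_members.items():
        if len(members) < 2:
            continue
        tc_denom += 1
        first = members[0]
        if first >= 0 and all(ec == first for ec in members):
            if est_count[first] == len(members):
                tc_hit += 1
    tc = 100.0 * tc_hit / tc_denom if tc_denom else 100.0
    return ScoreReport(
        spfn=spfn, spfp=spfp, sp_error=(spfn + spfp) / 2.0, tc=tc
    )


def tree_fn(estimated: PhyloTree, reference: PhyloTree) -> float:
    """Missing-branch (FN) rate: percent of reference internal-edge
    bipartitions absent from the estimated tree."""
    if set(estimated.leaf_labels) != set(reference.leaf_labels):
        raise TreeError("trees have different leaf sets")
    ref_bip = reference.bipartitions()
    if not ref_bip:
        return 0.0
    est_bip = estimated.bipartitions()
    return 100.0 * len(ref_bip - est_bip) / len(ref_bip)


def delta_fn(
    estimated: PhyloTree, reference: PhyloTree, true_alignment_tree: PhyloTree
) -> float:
    """FN rate of the estimated tree minus that of the tree computed on the
    true alignment; negative when the estimate beats the true-alignment tree."""
    return tree_fn(estimated, reference) - tree_fn(true_alignment_tree, reference)
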