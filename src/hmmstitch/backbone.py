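"""Backbone selection and backbone alignment/tree estimation.

Phase 1 splits the input into backbone and query sequences.  Only sequences
within ``length_tolerance`` (default 25 %) of the typical length — the median
input length unless the user declares a locus length — are eligible for the
backbone; if more than ``backbone_size`` sequences are eligible, a seeded
uniform random sample is drawn.  Disabling the restriction makes every
sequence eligible (the "random backbone" variant, useful only for study).

Phase 2 produces a multiple sequence alignment and unrooted tree on the
backbone.  A user-supplied alignment + tree pass through unchanged after
validation; this is the intended path whenever a stronger external aligner
is available, since backbone quality drives final quality.  The built-in
stand-in estimator is a classic progressive aligner: k-mer distance matrix,
neighbor-joining guide tree, and profile-profile Needleman-Wunsch with affine
gaps (+1 match / -1 mismatch, gap open 3, extend 1 — arbitrary but fixed).
The returned tree is neighbor joining on normalized Hamming distances of the
final alignment.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

from .alphabet import GAP
from .config import RunConfig
from .errors import HmmstitchError, TreeError
from .seqio import Alignment, SequenceSet
from .tree import PhyloTree


@dataclass
class BackboneSplit:
    backbone: SequenceSet
    queries: SequenceSet
    median_length: float
    eligible_ids: frozenset


def select_backbone(seqs: SequenceSet, cfg: RunConfig) -> BackboneSplit:
    """Partition input sequences into backbone and queries (Phase 1)."""
    if len(seqs) < 2:
        raise HmmstitchError("need at least 2 input sequences")
    lengths = {rec.id: len(rec) for rec in seqs}
    median = (
        float(cfg.typical_length)
        if cfg.typical_length is not None
        else float(statistics.median(lengths.values()))
    )
    if cfg.restrict_backbone_full_length:
        eligible = [
            i for i, L in lengths.items()
            if abs(L - median) <= cfg.length_tolerance * median
        ]
        if not eligible:
            raise HmmstitchError(
                "no sequence is within the full-length window "
                f"[{(1 - cfg.length_tolerance) * median:.0f}, "
                f"{(1 + cfg.length_tolerance) * median:.0f}]; relax "
                "length_tolerance or disable the full-length restriction"
            )
    else:
        eligible = list(lengths)
    if len(eligible) > cfg.backbone_size:
        rng = np.random.default_rng(cfg.seed)
        chosen = set(
            rng.choice(np.array(eligible, dtype=object), cfg.backbone_size, replace=False)
        )
        backbone_ids = [i for i in lengths if i in chosen]  # keep input order
    else:
        backbone_ids = eligible
    backbone = seqs.subset(backbone_ids)
    queries = SequenceSet(r for r in seqs if r.id not in set(backbone_ids))
    return BackboneSplit(
        backbone=backbone,
        queries=queries,
        median_length=median,
        eligible_ids=frozenset(eligible),
    )


# ---------------------------------------------------------------------------
# built-in stand-in aligner

#: fixed stand-in scoring scheme
MATCH_SCORE, MISMATCH_SCORE, GAP_OPEN, GAP_EXTEND = 1.0, -1.0, 3.0, 1.0

_NEG = -1e30  # acts as -inf but stays finite under arithmetic


def _profile(rows: list[str], alphabet) -> np.ndarray:
    """Column residue-frequency profile (W, A); gaps and ambiguity codes
    carry no mass, frequencies are normalised by the number of rows."""
    A = alphabet.size
    W = len(rows[0])
    prof = np.zeros((W, A))
    for r in rows:
        for j, ch in enumerate(r):
            if ch == GAP:
                continue
            idx = alphabet.index(ch)
            if idx is not None:
                prof[j, idx] += 1
    return prof / len(rows)


def _align_profiles(rows1: list[str], rows2: list[str], alphabet):
    """Affine-gap (Gotoh) global alignment of two column profiles.

    Returns the merged gapped rows (rows1 first).  The horizontal gap state
    is evaluated with a running-maximum trick, exact because re-opening a gap
    is never cheaper than extending one under gap_open >= gap_extend.
    """
    A = alphabet.size
    f1, f2 = _profile(rows1, alphabet), _profile(rows2, alphabet)
    smat = np.full((A, A), MISMATCH_SCORE) + np.eye(A) * (MATCH_SCORE - MISMATCH_SCORE)
    sc = f1 @ smat @ f2.T  # (n1, n2)
    n1, n2 = sc.shape
    go, ge = GAP_OPEN, GAP_EXTEND

    S = np.full((n1 + 1, n2 + 1), _NEG)
    V = np.full((n1 + 1, n2 + 1), _NEG)  # gap in profile2 (vertical)
    H = np.full((n1 + 1, n2 + 1), _NEG)  # gap in profile1 (horizontal)
    S[0, 0] = 0.0
    j = np.arange(1, n2 + 1)
    S[0, 1:] = H[0, 1:] = -(go + (j - 1) * ge)
    i_idx = np.arange(1, n1 + 1)
    S[1:, 0] = V[1:, 0] = -(go + (i_idx - 1) * ge)
    jj = np.arange(n2 + 1)
    for i in range(1, n1 + 1):
        V[i, 1:] = np.maximum(S[i - 1, 1:] - go, V[i - 1, 1:] - ge)
        diag = S[i - 1, :-1] + sc[i - 1, :]
        T = np.empty(n2 + 1)
        T[0] = S[i, 0]
        T[1:] = np.maximum(diag, V[i, 1:])
        run = np.maximum.accumulate(T + jj * ge)
        H[i, 1:] = run[:-1] - go - (jj[1:] - 1) * ge
        S[i, 1:] = np.maximum(T[1:], H[i, 1:])
        S[i, 0] = T[0]

    # traceback: prefer substitution, then vertical, then horizontal
    ops = []  # 'B' both, '1' column from profile1 only, '2' from profile2 only
    i, jcur = n1, n2
    tol = 1e-6
    while i > 0 or jcur > 0:
        if i == 0:
            ops.extend("2" * jcur)
            break
        if jcur == 0:
            ops.extend("1" * i)
            break
        s = S[i, jcur]
        if abs(s - (S[i - 1, jcur - 1] + sc[i - 1, jcur - 1])) <= tol:
            ops.append("B")
            i, jcur = i - 1, jcur - 1
        elif abs(s - V[i, jcur]) <= tol:
            # walk the vertical gap run
            while True:
                ops.append("1")
                opened = abs(V[i, jcur] - (S[i - 1, jcur] - go)) <= tol
                i -= 1
                if opened or i == 0:
                    break
        else:
            while True:
                ops.append("2")
                opened = abs(H[i, jcur] - (S[i, jcur - 1] - go)) <= tol
                jcur -= 1
                if opened or jcur == 0:
                    break
    ops.reverse()

    out1 = ["".join(r[j] if op != "2" else GAP
                    for op, j in _emit(ops, "2")) for r in rows1]
    out2 = ["".join(r[j] if op != "1" else GAP
                    for op, j in _emit(ops, "1")) for r in rows2]
    return out1 + out2


def _emit(ops, gap_op):
    """Yield (op, source-column) pairs walking ops; gap_op columns emit a
    placeholder index (unused)."""
    j = 0
    for op in ops:
        if op == gap_op:
            yield op, 0
        else:
            yield op, j
            j += 1


def _kmer_distance_matrix(seqs: SequenceSet, k: int) -> np.ndarray:
    """1 - fraction of shared k-mers (multiset intersection over the smaller
    k-mer count); crude but adequate for a guide tree."""
    from collections import Counter

    counters = []
    for rec in seqs:
        s = rec.residues
        counters.append(Counter(s[i : i + k] for i in range(max(len(s) - k + 1, 0))))
    n = len(counters)
    dist = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            ca, cb = counters[a], counters[b]
            inter = sum((ca & cb).values())
            denom = max(min(sum(ca.values()), sum(cb.values())), 1)
            dist[a, b] = dist[b, a] = 1.0 - inter / denom
    return dist


def _nj_tree_newick(dist: np.ndarray, labels: list[str]) -> str:
    dm = DistanceMatrix(dist, labels)
    return str(_skbio_nj(dm))


def _merge_order(dist: np.ndarray, labels: list[str]):
    """Postorder merge plan from a neighbor-joining guide tree.

    Returns a nested tuple structure of labels; trifurcations are folded
    left-to-right.
    """
    dm = DistanceMatrix(dist, labels)
    guide = _skbio_nj(dm)

    def fold(node):
        if node.is_tip():
            return node.name
        parts = [fold(ch) for ch in node.children]
        plan = parts[0]
        for p in parts[1:]:
            plan = (plan, p)
        return plan

    return fold(guide)


def _hamming_distance_matrix(aln: Alignment) -> tuple[np.ndarray, list[str]]:
    ids = list(aln.rows)
    mat = np.frombuffer(
        "".join(aln.rows[i] for i in ids).encode(), dtype="S1"
    ).reshape(len(ids), aln.width)
    gap = GAP.encode()
    n = len(ids)
    dist = np.zeros((n, n))
    for a in range(n):
        both = (mat[a] != gap) & (mat != gap)
        diff = (mat[a] != mat) & both
        ov = both.sum(axis=1)
        with np.errstate(invalid="ignore"):
            d = np.where(ov > 0, diff.sum(axis=1) / np.maximum(ov, 1), 1.0)
        dist[a] = d
    np.fill_diagonal(dist, 0.0)
    return (dist + dist.T) / 2.0, ids


def estimate_backbone(
    backbone: SequenceSet,
    cfg: RunConfig,
    alignment: Alignment | None = None,
    tree: PhyloTree | None = None,
) -> tuple[Alignment, PhyloTree]:
    """Backbone alignment + unrooted tree (Phase 2).

    With ``alignment``/``tree`` supplied, both are validated against the
    backbone ids and returned unchanged.  Otherwise the built-in progressive
    stand-in estimator runs.
    """
    ids = list(backbone.ids)
    if len(ids) < 2:
        raise HmmstitchError("backbone must contain at least 2 sequences")
    if (alignment is None) != (tree is None):
        raise HmmstitchError("supply both backbone alignment and tree, or neither")
    if alignment is not None:
        if set(alignment.rows) != set(ids):
            extra = sorted(set(alignment.rows) - set(ids))
            missing = sorted(set(ids) - set(alignment.rows))
            raise HmmstitchError(
                f"backbone alignment rows != backbone ids "
                f"(extra: {extra[:5]}, missing: {missing[:5]})"
            )
        tree.validate_leaf_set(ids, "backbone tree")
        return alignment, tree

    ab = backbone.alphabet
    if len(ids) == 2:
        rows = _align_profiles(
            [backbone[ids[0]].residues], [backbone[ids[1]].residues], ab
        )
        aln = Alignment(dict(zip(ids, rows)), ab)
        ptree = PhyloTree.from_newick(f"({ids[0]}:0.1,{ids[1]}:0.1);")
        return aln, ptree

    k = 5 if ab.name == "dna" else 3
    dist = _kmer_distance_matrix(backbone, k)
    plan = _merge_order(dist, ids)

    def build(node) -> dict[str, str]:
        if isinstance(node, str):
            return {node: backbone[node].residues}
        left, right = (build(n) for n in node)
        merged = _align_profiles(
            list(left.values()), list(right.values()), ab
        )
        out = {}
        for sid, row in zip(list(left) + list(right), merged):
            out[sid] = row
        return out

    rows = build(plan)
    aln = Alignment({i: rows[i] for i in ids}, ab)

    hdist, hids = _hamming_distance_matrix(aln)
    if len(hids) == 2:
        newick = f"({hids[0]}:{hdist[0,1]/2},{hids[1]}:{hdist[0,1]/2});"
    else:
        newick = _nj_tree_newick(hdist, hids)
    try:
        ptree = PhyloTree.from_newick(newick)
    except TreeError as exc:  # pragma: no cover - defensive
        raise HmmstitchError(f"backbone tree construction failed: {exc}") from exc
    ptree.validate_leaf_set(ids, "estimated backbone tree")
    return aln, ptree
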