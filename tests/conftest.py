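"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the library's dynamic-programming and counting
code paths: HMM scores are obtained by explicitly enumerating every legal
state path, and alignment scores by materialising every homology pair.  They
are exponential/quadratic and only usable on tiny inputs, which is the point.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
import pytest

from hmmstitch import DNA, Alignment, SequenceRecord


# ---------------------------------------------------------------------------
# brute-force path-enumeration oracle for the profile HMM


def enumerate_paths(hmm, query):
    """All legal uni-hit local paths: returns (forward_bits, viterbi_bits).

    A path picks a first matched residue, an entry match state, then walks
    the core {M,I,D} grammar; it may exit after any match state, leaving the
    remaining residues as free flanks.  Weights are accumulated in log2.
    """
    K, L = hmm.K, len(query.residues)
    ab, null = hmm.alphabet, hmm.null_frequencies
    t = hmm.transitions

    def em(table, row, i):
        a = ab.index(query.residues[i])
        if a is None:
            return 0.0
        return math.log2(table[row][a]) - math.log2(null[a])

    weights = []

    def walk(i, k, state, logw):
        if state == "M":
            weights.append(logw)  # exit here, rest is right flank
        if k < K - 1:
            src = {"M": 0, "I": 1, "D": 2}[state]
            if i < L:
                walk(i + 1, k + 1, "M",
                     logw + math.log2(t[k][src][0]) + em(hmm.match_emissions, k + 1, i))
                walk(i + 1, k, "I",
                     logw + math.log2(t[k][src][1]) + em(hmm.insert_emissions, k + 1, i))
            walk(i, k + 1, "D", logw + math.log2(t[k][src][2]))

    for s in range(L):  # left flank length s
        for b in range(K):
            walk(s + 1, b, "M", -math.log2(K) + em(hmm.match_emissions, b, s))

    mx = max(weights)
    forward = mx + math.log2(sum(2.0 ** (w - mx) for w in weights))
    return forward, mx


def random_small_profile(rng, alphabet=DNA, max_states=5):
    """A profile HMM trained on a random tiny alignment (K <= max_states)."""
    from hmmstitch import build_profile

    while True:
        n_rows = int(rng.integers(1, 4))
        width = int(rng.integers(1, max_states + 3))
        rows = {
            f"r{i}": "".join(rng.choice(list("ACGT-"), width).tolist())
            for i in range(n_rows)
        }
        if all(set(col) == {"-"} for col in zip(*rows.values())):
            continue
        hmm = build_profile(Alignment(rows, alphabet), 1.0)
        if hmm.K <= max_states:
            return hmm


def random_query(rng, max_len=6, alphabet=DNA):
    L = int(rng.integers(1, max_len + 1))
    return SequenceRecord("q", "".join(rng.choice(list("ACGT"), L).tolist()), alphabet)


# ---------------------------------------------------------------------------
# brute-force alignment-metric oracle


def brute_force_pairs(aln: Alignment) -> set:
    """Homology pairs by direct column scan (all columns, all row pairs)."""
    pairs = set()
    upos = {sid: -1 for sid in aln.rows}
    for j in range(aln.width):
        col = []
        for sid in aln.rows:
            ch = aln.rows[sid][j]
            if ch != "-":
                upos[sid] += 1
                if aln.column_flags[j] == "M":
                    col.append((sid, upos[sid]))
        pairs.update(frozenset(p) for p in combinations(col, 2))
    return pairs


def brute_force_sp(est: Alignment, ref: Alignment):
    """(spfn, spfp, sp_error, tc) from explicit pair sets and column sets."""
    R, E = brute_force_pairs(ref), brute_force_pairs(est)
    spfn = 100.0 * len(R - E) / len(R) if R else 0.0
    spfp = 100.0 * len(E - R) / len(E) if E else 0.0

    def column_sets(aln):
        out = []
        upos = {sid: -1 for sid in aln.rows}
        for j in range(aln.width):
            col = set()
            for sid in aln.rows:
                if aln.rows[sid][j] != "-":
                    upos[sid] += 1
                    if aln.column_flags[j] == "M":
                        col.add((sid, upos[sid]))
            out.append(col)
        return out

    ref_cols = [c for c in column_sets(ref) if len(c) >= 2]
    est_cols = set(map(frozenset, column_sets(est)))
    tc_hits = sum(1 for c in ref_cols if frozenset(c) in est_cols)
    tc = 100.0 * tc_hits / len(ref_cols) if ref_cols else 100.0
    return spfn, spfp, (spfn + spfp) / 2.0, tc


def random_alignment(rng, alphabet=DNA, max_rows=6, max_cols=20) -> Alignment:
    n = int(rng.integers(2, max_rows + 1))
    w = int(rng.integers(1, max_cols + 1))
    while True:
        rows = {
            f"s{i}": "".join(rng.choice(list("ACGT-"), w).tolist()) for i in range(n)
        }
        if all(any(ch != "-" for ch in r) for r in rows.values()):
            return Alignment(rows, alphabet)


def realign_randomly(rng, aln: Alignment) -> Alignment:
    """A different alignment of the same sequences (for SP comparisons):
    each row's residues are re-gapped at random into a fresh width."""
    seqs = {sid: aln.ungapped(sid) for sid in aln.rows}
    w = max(len(s) for s in seqs.values()) + int(rng.integers(0, 6))
    rows = {}
    for sid, s in seqs.items():
        pos = sorted(rng.choice(w, size=len(s), replace=False).tolist())
        row = ["-"] * w
        for p, ch in zip(pos, s):
            row[p] = ch
        rows[sid] = "".join(row)
    return Alignment(rows, aln.alphabet)


def match_only_pairs(aln: Alignment) -> set:
    """Homology pairs keyed by each residue's index among its row's
    MATCH-column residues — the numbering the masked alignment sees, since
    masking removes insertion-column residues.  Lets the masked and unmasked
    outputs be compared pair-for-pair."""
    pairs = set()
    pos = {sid: -1 for sid in aln.rows}
    for j in range(aln.width):
        if aln.column_flags[j] != "M":
            continue
        col = []
        for sid in aln.rows:
            if aln.rows[sid][j] != "-":
                pos[sid] += 1
                col.append((sid, pos[sid]))
        pairs.update(frozenset(p) for p in combinations(col, 2))
    return pairs


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def balanced_newick(n: int, prefix: str = "t") -> str:
    """A balanced binary tree on n leaves (recursive halving), unit branch
    lengths."""

    def build(lo, hi):
        if hi - lo == 1:
            return f"{prefix}{lo}:1"
        mid = (lo + hi) // 2
        return f"({build(lo, mid)},{build(mid, hi)}):1"

    return build(0, n)[: -2] + ";"
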