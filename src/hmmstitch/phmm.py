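"""Native profile hidden Markov model mathematics.

A profile HMM is built from a (sub)alignment under the modified match-state
rule: *every* column containing at least one non-gap residue becomes a match
state (the ``--symfrac 0.0`` convention), so match states map one-to-one onto
occupied alignment columns and ``column_map`` records that mapping.  Columns
that are all-gap within the given subalignment are dropped.

Architecture: a simplified Plan7 in uni-hit local mode.  A state path is

    [flank]* -> entry -> M_b -> (M|I|D)* -> M_e -> exit -> [flank]*

Entry is uniform over the K match states (probability 1/K) and exit from any
match state has unit weight; unmatched flanking residues are emitted at null
frequency, so their net log-odds contribution is zero.  The core has full
{M,I,D} -> {M,I,D} transition bundles between adjacent positions (insert
states sit between match positions and may self-loop).  Delete states are
never terminal: a legal path enters and leaves the core at match states.

All parameters are estimated with add-``alpha`` (Laplace) pseudocounts.
Under the all-columns match rule the training rows traverse only match and
delete states, so insert emissions and insert-involving transitions receive
pure pseudocount mass.  Ambiguity codes emit at null frequency (log-odds 0).

Scoring is carried out in log2 space (bit scores):

    score(q) = log2( sum over legal paths P(path, q) / P_null(q) )

with logsumexp-style accumulation, safe for queries up to 10^4 residues.
``viterbi_align`` returns the single best path under the same grammar, with
ties broken deterministically preferring M over D over I.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .alphabet import GAP, Alphabet, get_alphabet
from .errors import AlignmentError, HmmstitchError, SequenceFormatError
from .seqio import Alignment, SequenceRecord

# transition source/target order inside each bundle
_M, _I, _D = 0, 1, 2

_NEG_INF = -np.inf
# absolute/relative slack when re-deriving argmax decisions in traceback
_TIE_TOL = 1e-9


@dataclass
class ProfileHMM:
    """Parameters of one profile HMM over ``alphabet``.

    ``transitions`` has shape (K-1, 3, 3): ``transitions[k, s, t]`` is the
    probability of moving from source state ``s`` in {M_k+1, I_k+1, D_k+1}
    (1-based position k+1) to target ``t`` in {M_k+2, I_k+1, D_k+2}; target
    index 1 is the insert state *between* positions k+1 and k+2.
    ``column_map[k]`` is the 0-based source-alignment column of match state
    k+1 (strictly increasing).
    """

    alphabet: Alphabet
    match_emissions: np.ndarray  # (K, A)
    insert_emissions: np.ndarray  # (K+1, A)
    transitions: np.ndarray  # (K-1, 3, 3)
    null_frequencies: np.ndarray  # (A,)
    column_map: np.ndarray  # (K,), int

    @property
    def K(self) -> int:
        return self.match_emissions.shape[0]

    def validate(self, tol: float = 1e-9) -> None:
        A = self.alphabet.size
        if self.match_emissions.shape != (self.K, A):
            raise HmmstitchError("match_emissions shape mismatch")
        if self.insert_emissions.shape != (self.K + 1, A):
            raise HmmstitchError("insert_emissions shape mismatch")
        if self.transitions.shape != (max(self.K - 1, 0), 3, 3):
            raise HmmstitchError("transitions shape mismatch")
        for name, table in (
            ("match_emissions", self.match_emissions),
            ("insert_emissions", self.insert_emissions),
        ):
            if np.any(np.abs(table.sum(axis=1) - 1.0) > tol):
                raise HmmstitchError(f"{name} rows do not sum to 1")
        if self.K > 1 and np.any(np.abs(self.transitions.sum(axis=2) - 1.0) > tol):
            raise HmmstitchError("transition bundles do not sum to 1")
        if abs(self.null_frequencies.sum() - 1.0) > tol:
            raise HmmstitchError("null_frequencies do not sum to 1")
        if len(self.column_map) != self.K or np.any(np.diff(self.column_map) <= 0):
            raise HmmstitchError("column_map must be strictly increasing, length K")

    # -- plain-text serialization ------------------------------------------
    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("HMMSTITCH-HMM 1\n")
            fh.write(f"alphabet {self.alphabet.name}\n")
            fh.write(f"K {self.K}\n")
            fh.write("columns " + " ".join(map(str, self.column_map)) + "\n")
            fh.write("null " + " ".join(f"{x:.17g}" for x in self.null_frequencies) + "\n")
            for k in range(self.K):
                fh.write(
                    f"match {k} " + " ".join(f"{x:.17g}" for x in self.match_emissions[k]) + "\n"
                )
            for k in range(self.K + 1):
                fh.write(
                    f"insert {k} " + " ".join(f"{x:.17g}" for x in self.insert_emissions[k]) + "\n"
                )
            for k in range(self.K - 1):
                fh.write(
                    f"trans {k} " + " ".join(f"{x:.17g}" for x in self.transitions[k].ravel()) + "\n"
                )

    @classmethod
    def load(cls, path) -> "ProfileHMM":
        with open(path) as fh:
            lines = [ln.rstrip("\n") for ln in fh]
        if not lines or not lines[0].startswith("HMMSTITCH-HMM"):
            raise HmmstitchError(f"not an hmmstitch model file: {path}")
        fields = {}
        match_rows, insert_rows, trans_rows = {}, {}, {}
        for ln in lines[1:]:
            if not ln.strip():
                continue
            tok = ln.split()
            if tok[0] == "match":
                match_rows[int(tok[1])] = [float(x) for x in tok[2:]]
            elif tok[0] == "insert":
                insert_rows[int(tok[1])] = [float(x) for x in tok[2:]]
            elif tok[0] == "trans":
                trans_rows[int(tok[1])] = [float(x) for x in tok[2:]]
            else:
                fields[tok[0]] = tok[1:]
        ab = get_alphabet(fields["alphabet"][0])
        K = int(fields["K"][0])
        hmm = cls(
            alphabet=ab,
            match_emissions=np.array([match_rows[k] for k in range(K)]),
            insert_emissions=np.array([insert_rows[k] for k in range(K + 1)]),
            transitions=(
                np.array([trans_rows[k] for k in range(K - 1)]).reshape(K - 1, 3, 3)
                if K > 1
                else np.zeros((0, 3, 3))
            ),
            null_frequencies=np.array([float(x) for x in fields["null"]]),
            column_map=np.array([int(x) for x in fields["columns"]], dtype=int),
        )
        hmm.validate(tol=1e-6)
        return hmm


@dataclass
class StatePath:
    """A state path through a profile HMM, covering the query left to right.

    ``steps`` is a list of (kind, position) with kind in {'M','I','D','flank'};
    positions are 1-based match-state numbers (for 'I', the insert slot after
    that match position; 0 for 'flank').  Emitting steps (M, I, flank) consume
    exactly one query residue; D consumes none.
    """

    steps: list[tuple[str, int]]
    score: float = field(default=float("nan"))

    def emitted_count(self) -> int:
        return sum(1 for kind, _ in self.steps if kind in ("M", "I", "flank"))


# ---------------------------------------------------------------------------
# model construction


def residue_frequencies(aln: Alignment, pseudocount: float = 1.0) -> np.ndarray:
    """Background frequencies of an alignment's canonical residues (+alpha)."""
    A = aln.alphabet.size
    counts = np.zeros(A)
    for row in aln.rows.values():
        for ch in row:
            if ch == GAP:
                continue
            idx = aln.alphabet.index(ch)
            if idx is not None:
                counts[idx] += 1
    counts += pseudocount
    return counts / counts.sum()


def build_profile(
    subaln: Alignment,
    pseudocount: float = 1.0,
    null_frequencies: np.ndarray | None = None,
) -> ProfileHMM:
    """Build a profile HMM from an alignment.

    One match state per column with at least one non-gap residue; all-gap
    columns are dropped and absent from ``column_map``.  Emissions and
    transitions are count estimates with add-``pseudocount`` smoothing and
    uniform sequence weights.  ``null_frequencies`` defaults to the overall
    residue frequencies of ``subaln`` itself; an ensemble builder passes the
    full backbone's frequencies instead so bit scores are comparable across
    subset models.
    """
    if "I" in subaln.column_flags:
        raise AlignmentError("profile training alignment must be all-MATCH columns")
    ab = subaln.alphabet
    A = ab.size
    rows = list(subaln.rows.values())
    occupied = [
        j for j in range(subaln.width) if any(r[j] != GAP for r in rows)
    ]
    if not occupied:
        raise AlignmentError("alignment has no occupied columns")
    K = len(occupied)

    match_counts = np.zeros((K, A))
    for k, j in enumerate(occupied):
        for r in rows:
            ch = r[j]
            if ch == GAP:
                continue
            idx = ab.index(ch)
            if idx is not None:  # ambiguity codes carry no emission counts
                match_counts[k, idx] += 1
    match_em = match_counts + pseudocount
    match_em /= match_em.sum(axis=1, keepdims=True)

    # training rows traverse only M/D states under the all-columns rule, so
    # insert emissions are pure pseudocount (uniform over the alphabet)
    insert_em = np.full((K + 1, A), 1.0 / A)

    trans_counts = np.zeros((max(K - 1, 0), 3, 3))
    for r in rows:
        states = [(_M if r[j] != GAP else _D) for j in occupied]
        for k in range(K - 1):
            src = states[k]
            dst = states[k + 1]
            trans_counts[k, src, _M if dst == _M else _D] += 1
    trans = trans_counts + pseudocount
    if K > 1:
        trans /= trans.sum(axis=2, keepdims=True)

    null = (
        np.asarray(null_frequencies, dtype=float)
        if null_frequencies is not None
        else residue_frequencies(subaln, pseudocount)
    )
    hmm = ProfileHMM(
        alphabet=ab,
        match_emissions=match_em,
        insert_emissions=insert_em,
        transitions=trans,
        null_frequencies=null,
        column_map=np.asarray(occupied, dtype=int),
    )
    hmm.validate()
    return hmm


# ---------------------------------------------------------------------------
# dynamic programming


def _emission_logodds(hmm: ProfileHMM, query: SequenceRecord):
    """Per-residue log2 odds tables (L, K) for match and (L, K-1) for insert.

    Ambiguity codes score zero everywhere (null-frequency emission).
    """
    if query.alphabet.name != hmm.alphabet.name:
        raise SequenceFormatError(
            f"alphabet mismatch: query {query.alphabet.name!r} vs "
            f"model {hmm.alphabet.name!r}"
        )
    L, K = len(query.residues), hmm.K
    lm = np.zeros((L, K))
    li = np.zeros((L, max(K - 1, 0)))
    log_match = np.log2(hmm.match_emissions)  # (K, A)
    log_ins = np.log2(hmm.insert_emissions[1:K]) if K > 1 else None  # (K-1, A)
    log_null = np.log2(hmm.null_frequencies)
    for i, ch in enumerate(query.residues):
        a = hmm.alphabet.index(ch)
        if a is None:
            continue
        lm[i] = log_match[:, a] - log_null[a]
        if K > 1:
            li[i] = log_ins[:, a] - log_null[a]
    return lm, li


def _log_transitions(hmm: ProfileHMM):
    t = np.log2(hmm.transitions) if hmm.K > 1 else np.zeros((0, 3, 3))
    return {
        "MM": t[:, _M, _M], "MI": t[:, _M, _I], "MD": t[:, _M, _D],
        "IM": t[:, _I, _M], "II": t[:, _I, _I], "ID": t[:, _I, _D],
        "DM": t[:, _D, _M], "DI": t[:, _D, _I], "DD": t[:, _D, _D],
    }


def _dp_matrices(hmm: ProfileHMM, query: SequenceRecord, viterbi: bool):
    """Shared Forward/Viterbi recursion.

    Returns (M, I, D) score matrices of shape (L+1, K) / (L+1, K-1) /
    (L+1, K), in bits, where row i holds scores after consuming i residues.
    Entry into any match state costs log2(1/K); flanking residues are free.
    The delete-chain recursion within a row is evaluated with a prefix
    accumulate (logaddexp2 or maximum), exact up to float re-association.
    """
    lm, li = _emission_logodds(hmm, query)
    t = _log_transitions(hmm)
    L, K = len(query.residues), hmm.K
    entry = -np.log2(K)
    combine = np.maximum if viterbi else np.logaddexp2
    acc = np.maximum.accumulate if viterbi else np.logaddexp2.accumulate

    M = np.full((L + 1, K), _NEG_INF)
    I = np.full((L + 1, max(K - 1, 0)), _NEG_INF)
    D = np.full((L + 1, K), _NEG_INF)
    # cumulative delete-extension cost: C[d] = sum of DD steps up to index d
    if K > 1:
        cum_dd = np.concatenate(([0.0], np.cumsum(t["DD"][1:])))  # length K-1
    for i in range(1, L + 1):
        pm, pi, pd = M[i - 1], I[i - 1], D[i - 1]
        # match row
        M[i, 0] = lm[i - 1, 0] + entry
        if K > 1:
            core = combine(
                combine(pm[:-1] + t["MM"], pi + t["IM"]), pd[:-1] + t["DM"]
            )
            M[i, 1:] = lm[i - 1, 1:] + combine(core, entry)
            # insert row (slot k sits after match state k)
            I[i] = li[i - 1] + combine(
                combine(pm[:-1] + t["MI"], pi + t["II"]), pd[:-1] + t["DI"]
            )
            # delete row: D_{j+2} opened from M/I at slot j+1, extended by DD
            base = combine(M[i, :-1] + t["MD"], I[i] + t["ID"])  # (K-1,)
            g = acc(base - cum_dd)
            D[i, 1:] = g + cum_dd
    return M, I, D


def _odds_tables(hmm: ProfileHMM):
    """Emission odds (emission / null) indexed by canonical symbol, with an
    extra all-ones row for ambiguity codes."""
    A = hmm.alphabet.size
    om = np.ones((A + 1, hmm.K))
    om[:A] = (hmm.match_emissions / hmm.null_frequencies[None, :]).T
    oi = np.ones((A + 1, max(hmm.K - 1, 0)))
    if hmm.K > 1:
        oi[:A] = (hmm.insert_emissions[1 : hmm.K] / hmm.null_frequencies[None, :]).T
    return om, oi


def _encode(alphabet: Alphabet, residues: str) -> np.ndarray:
    """Residues as canonical indices; ambiguity codes map to index A."""
    A = alphabet.size
    return np.array(
        [a if (a := alphabet.index(ch)) is not None else A for ch in residues],
        dtype=np.intp,
    )


@njit(cache=False)
def _forward_kernel(enc, om, oi, trans):  # pragma: no cover - exercised via wrapper
    """Per-row exit masses (bits) of the uni-hit local Forward recursion.

    Probability-space dynamic programming with lazy rescaling: all state
    masses are kept within float range by dividing every lattice row by its
    maximum whenever it leaves [1e-100, 1e100], accumulating the log of the
    applied factor.  Exact up to float rounding.
    """
    K = om.shape[1]
    L = enc.size
    entry = 1.0 / K
    cum_log = 0.0
    exits = np.empty(L)
    M = np.zeros(K)
    I = np.zeros(K - 1)
    D = np.zeros(K)
    newM = np.zeros(K)
    newI = np.zeros(K - 1)
    newD = np.zeros(K)
    for i in range(L):
        a = enc[i]
        se = entry * 2.0 ** (-cum_log) if cum_log < 1060.0 else 0.0
        newM[0] = om[a, 0] * se
        for k in range(1, K):
            core = (
                M[k - 1] * trans[k - 1, 0, 0]
                + I[k - 1] * trans[k - 1, 1, 0]
                + D[k - 1] * trans[k - 1, 2, 0]
            )
            newM[k] = om[a, k] * (core + se)
        for k in range(K - 1):
            newI[k] = oi[a, k] * (
                M[k] * trans[k, 0, 1]
                + I[k] * trans[k, 1, 1]
                + D[k] * trans[k, 2, 1]
            )
        newD[0] = 0.0
        prev = 0.0
        for k in range(1, K):
            prev = (
                newM[k - 1] * trans[k - 1, 0, 2]
                + newI[k - 1] * trans[k - 1, 1, 2]
                + trans[k - 1, 2, 2] * prev
            )
            newD[k] = prev
        s = 0.0
        mx = 0.0
        for k in range(K):
            s += newM[k]
            if newM[k] > mx:
                mx = newM[k]
            if newD[k] > mx:
                mx = newD[k]
        for k in range(K - 1):
            if newI[k] > mx:
                mx = newI[k]
        exits[i] = np.log2(s) + cum_log if s > 0.0 else -np.inf
        if mx > 0.0 and (mx > 1e100 or mx < 1e-100):
            inv = 1.0 / mx
            for k in range(K):
                newM[k] *= inv
                newD[k] *= inv
            for k in range(K - 1):
                newI[k] *= inv
            cum_log += np.log2(mx)
        M, newM = newM, M
        I, newI = newI, I
        D, newD = newD, D
    return exits


def forward_bitscore(hmm: ProfileHMM, query: SequenceRecord) -> float:
    """Total log2-odds (bit) score of ``query`` against ``hmm``.

    Sum over every legal uni-hit local state path of the path probability,
    divided by the null-model probability of the query.  Flanking residues
    emitted at null frequency contribute odds 1 and cancel exactly.
    """
    if not query.residues:
        raise SequenceFormatError("query must be non-empty")
    if query.alphabet.name != hmm.alphabet.name:
        raise SequenceFormatError(
            f"alphabet mismatch: query {query.alphabet.name!r} vs "
            f"model {hmm.alphabet.name!r}"
        )
    om, oi = _odds_tables(hmm)
    enc = _encode(hmm.alphabet, query.residues)
    if hmm.K == 1:
        # single match state: exactly one residue is matched, the rest flank
        return float(np.log2(om[enc, 0].sum()) - np.log2(hmm.K))
    exits = _forward_kernel(enc, om, oi, hmm.transitions)
    return float(np.logaddexp2.reduce(exits))


def _pick(cands: list[tuple[str, float]]) -> str:
    """First candidate (priority order) whose value ties the maximum."""
    best = max(v for _, v in cands)
    tol = _TIE_TOL + 1e-12 * abs(best)
    for name, v in cands:
        if v >= best - tol:
            return name
    raise HmmstitchError("traceback failed to locate predecessor")  # pragma: no cover


def viterbi_align(hmm: ProfileHMM, query: SequenceRecord) -> StatePath:
    """Maximum-probability state path of ``query`` through ``hmm``.

    Ties are broken preferring M over D over I (and any core predecessor over
    a fresh local entry), which maximises residues assigned to match columns.
    """
    if not query.residues:
        raise SequenceFormatError("query must be non-empty")
    M, I, D = _dp_matrices(hmm, query, viterbi=True)
    lm, li = _emission_logodds(hmm, query)
    t = _log_transitions(hmm)
    L, K = len(query.residues), hmm.K
    entry = -np.log2(K)

    flat = int(np.argmax(M[1:].ravel()))
    i, k = divmod(flat, K)
    i += 1
    score = float(M[i, k])
    steps: list[tuple[str, int]] = [("flank", 0)] * (L - i)  # right flank
    state = "M"
    while True:
        if state == "M":
            steps.append(("M", k + 1))
            cands = [("entry", entry)]
            if k > 0:
                cands = [
                    ("M", M[i - 1, k - 1] + t["MM"][k - 1]),
                    ("D", D[i - 1, k - 1] + t["DM"][k - 1]),
                    ("I", I[i - 1, k - 1] + t["IM"][k - 1]),
                    ("entry", entry),
                ]
            choice = _pick(cands)
            i -= 1
            if choice == "entry":
                steps.extend([("flank", 0)] * i)
                break
            k -= 1
            state = choice
        elif state == "D":
            steps.append(("D", k + 1))
            cands = [
                ("M", M[i, k - 1] + t["MD"][k - 1]),
                ("D", D[i, k - 1] + t["DD"][k - 1]),
                ("I", I[i, k - 1] + t["ID"][k - 1]),
            ]
            state = _pick(cands)
            k -= 1
        else:  # insert slot k+1 (I array index k)
            steps.append(("I", k + 1))
            cands = [
                ("M", M[i - 1, k] + t["MI"][k]),
                ("D", D[i - 1, k] + t["DI"][k]),
                ("I", I[i - 1, k] + t["II"][k]),
            ]
            choice = _pick(cands)
            i -= 1
            state = choice
    steps.reverse()
    path = StatePath(steps=steps, score=score)
    if path.emitted_count() != L:  # pragma: no cover - internal invariant
        raise HmmstitchError("viterbi path does not cover the query")
    return path
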