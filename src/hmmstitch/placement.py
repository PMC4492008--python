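"""Query scoring, HMM selection, and transitive extension of the backbone.

Each query is scored (Forward bit score) against every HMM in the ensemble
with no score or E-value threshold — every query is always placed.  The best
scoring HMM (ties to the lowest subset id, i.e. the full-set model first) is
chosen and the query is aligned to it by Viterbi.  Because match states map
one-to-one onto backbone columns, homology is transitive: a query residue
aligned to a subset-model match state is thereby aligned to the corresponding
full-backbone column and to every residue in it.  Residues emitted by insert
or flank states are not homologous to any backbone column; they are collected
in insertion blocks between backbone columns (adjacent insertion sites are
combined into a minimal block, residues left-justified, queries in input
order), flagged INSERTION, and masked before any phylogenetic use.
"""

from __future__ import annotations

from dataclasses import dataclass

from .alphabet import GAP
from .ensemble import HMMEnsemble
from .errors import HmmstitchError
from .phmm import StatePath, forward_bitscore, viterbi_align
from .seqio import INSERTION, MATCH, Alignment, SequenceRecord


@dataclass
class PlacementResult:
    """Where one query goes.

    ``residue_map`` holds one entry per query residue, in order: ``('M', c)``
    assigns the residue to backbone column ``c`` (0-based), ``('I', s)`` puts
    it in the insertion slot *before* backbone column ``s`` (``s`` ranges 0..W,
    W meaning after the last column).  Match columns are strictly increasing
    along the query.
    """

    query_id: str
    subset_id: int
    bit_score: float
    path: StatePath
    residue_map: list[tuple[str, int]]
    residues: str


def _residue_map(path: StatePath, column_map) -> list[tuple[str, int]]:
    """Translate a Viterbi path into backbone-column assignments."""
    out: list[tuple[str, int]] = []
    pending_left = 0  # flank residues seen before the first match state
    last_col = None
    for kind, pos in path.steps:
        if kind == "M":
            col = int(column_map[pos - 1])
            if pending_left:
                out.extend([("I", col)] * pending_left)  # slot before first column
                pending_left = 0
            out.append(("M", col))
            last_col = col
        elif kind == "I":
            col = int(column_map[pos - 1])
            out.append(("I", col + 1))  # slot after the insert's match position
        elif kind == "flank":
            if last_col is None:
                pending_left += 1
            else:
                out.append(("I", last_col + 1))
        # 'D' consumes no residue
    if pending_left:  # pragma: no cover - grammar guarantees >=1 match state
        raise HmmstitchError("state path contains no match state")
    cols = [c for kind, c in out if kind == "M"]
    if any(b <= a for a, b in zip(cols, cols[1:])):  # pragma: no cover
        raise HmmstitchError("non-monotone residue map (internal error)")
    return out


def score_and_select(ensemble: HMMEnsemble, query: SequenceRecord) -> PlacementResult:
    """Score ``query`` against every ensemble member and place it with the
    best one (Phase 4).  Placement is total: no threshold is applied."""
    if not len(ensemble):
        raise HmmstitchError("empty ensemble")
    best = None
    best_score = None
    for member in ensemble:
        s = forward_bitscore(member.hmm, query)
        if best_score is None or s > best_score:
            best, best_score = member, s
    path = viterbi_align(best.hmm, query)
    return PlacementResult(
        query_id=query.id,
        subset_id=best.subset_id,
        bit_score=best_score,
        path=path,
        residue_map=_residue_map(path, best.hmm.column_map),
        residues=query.residues,
    )


@dataclass
class ExtendedAlignment:
    """Backbone plus placed queries, with INSERTION blocks interleaved."""

    alignment: Alignment
    backbone_ids: tuple
    query_ids: tuple

    @property
    def masked_width(self) -> int:
        return self.alignment.column_flags.count(MATCH)


def extend_alignment(
    backbone: Alignment, placements: list[PlacementResult]
) -> ExtendedAlignment:
    """Merge all query placements into the backbone by transitivity.

    For each between-column slot, the insertion block width is the maximum
    number of residues any single query assigns there (zero blocks are
    omitted); backbone rows carry gaps across insertion blocks, and the
    restriction of the result to backbone rows and MATCH columns reproduces
    the backbone alignment exactly.
    """
    W = backbone.width
    slot_width = [0] * (W + 1)
    per_query: list[tuple[str, dict[int, str], dict[int, list[str]]]] = []
    for pl in placements:
        seq_cols: dict[int, str] = {}
        ins: dict[int, list[str]] = {}
        residues = None  # filled from the map order
        idx = 0
        for kind, c in pl.residue_map:
            if kind == "M":
                if not 0 <= c < W:
                    raise HmmstitchError(
                        f"placement of {pl.query_id!r} references column {c} "
                        f"outside backbone width {W}"
                    )
                seq_cols[c] = idx
            else:
                ins.setdefault(c, []).append(idx)
            idx += 1
        per_query.append((pl.query_id, seq_cols, ins))
        for s, items in ins.items():
            slot_width[s] = max(slot_width[s], len(items))

    flags_parts = []
    col_layout = []  # ('ins', slot, offset) or ('match', col)
    for c in range(W + 1):
        for off in range(slot_width[c]):
            col_layout.append(("ins", c, off))
            flags_parts.append(INSERTION)
        if c < W:
            col_layout.append(("match", c, 0))
            flags_parts.append(MATCH)
    flags = "".join(flags_parts)

    rows: dict[str, str] = {}
    for sid in backbone.rows:
        src = backbone.rows[sid]
        rows[sid] = "".join(
            src[c] if kind == "match" else GAP for kind, c, _ in col_layout
        )
    residues_by_query = {pl.query_id: pl.residues for pl in placements}
    for qid, seq_cols, ins in per_query:
        qres = residues_by_query[qid]
        chars = []
        for kind, c, off in col_layout:
            if kind == "match":
                i = seq_cols.get(c)
                chars.append(qres[i] if i is not None else GAP)
            else:
                items = ins.get(c, [])
                chars.append(qres[items[off]] if off < len(items) else GAP)
        rows[qid] = "".join(chars)

    aln = Alignment(rows, backbone.alphabet, flags)
    return ExtendedAlignment(
        alignment=aln,
        backbone_ids=tuple(backbone.rows),
        query_ids=tuple(p.query_id for p in placements),
    )


def place_queries(ensemble: HMMEnsemble, queries) -> list[PlacementResult]:
    """Score-and-place every query, in input order."""
    return [score_and_select(ensemble, rec) for rec in queries]


def mask(ext: ExtendedAlignment) -> Alignment:
    """Drop all INSERTION columns; the result has the backbone's width."""
    return ext.alignment.drop_insertion_columns()
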