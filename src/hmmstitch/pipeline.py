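"""End-to-end orchestration of the four alignment phases.

1. split input into backbone and query sequences (full-length rule);
2. align the backbone and obtain its unrooted tree (built-in stand-in
   estimator, or user-supplied alignment + tree);
3. decompose the backbone tree by centroid edges and train the HMM ensemble;
4. score every query against every HMM, align each to its best model, and
   merge everything into the backbone by transitivity.

When every input sequence lands in the backbone (all full length and no more
sequences than the backbone size) the output is simply the backbone
estimator's alignment — there is no query phase.  Runs are deterministic
under a fixed seed, and every input sequence appears exactly once in the
output: a dropped sequence is a hard failure, never a warning.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field

from . import __version__
from .backbone import BackboneSplit, estimate_backbone, select_backbone
from .config import RunConfig
from .ensemble import build_ensemble, decompose, DecompositionNode
from .errors import HmmstitchError
from .placement import (
    ExtendedAlignment,
    extend_alignment,
    mask,
    place_queries,
)
from .seqio import Alignment, SequenceSet
from .tree import PhyloTree


@dataclass
class RunManifest:
    config: dict
    version: str
    n_input: int
    n_backbone: int
    n_queries: int
    n_hmms: int
    median_length: float
    stage_seconds: dict = field(default_factory=dict)
    placements: list = field(default_factory=list)  # (query id, subset id, bit score)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


@dataclass
class AlignResult:
    extended: ExtendedAlignment
    masked: Alignment
    manifest: RunManifest
    split: BackboneSplit
    backbone_alignment: Alignment
    backbone_tree: PhyloTree | None


def run_align(
    seqs: SequenceSet,
    cfg: RunConfig,
    backbone_alignment: Alignment | None = None,
    backbone_tree: PhyloTree | None = None,
) -> AlignResult:
    """Run phases 1-4 on ``seqs``.

    With ``backbone_alignment``/``backbone_tree`` supplied, the backbone set
    is exactly the rows of the supplied alignment (which must be a subset of
    the input ids) and phase 2 is a validated pass-through.
    """
    if len(seqs) < 2:
        raise HmmstitchError("need at least 2 input sequences")
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    if backbone_alignment is not None:
        bb_ids = list(backbone_alignment.rows)
        unknown = set(bb_ids) - set(seqs.ids)
        if unknown:
            raise HmmstitchError(
                f"backbone alignment rows absent from input: {sorted(unknown)[:5]}"
            )
        for sid in bb_ids:
            if backbone_alignment.ungapped(sid) != seqs[sid].residues:
                raise HmmstitchError(
                    f"backbone alignment row {sid!r} does not match the input residues"
                )
        split = BackboneSplit(
            backbone=seqs.subset(bb_ids),
            queries=SequenceSet(r for r in seqs if r.id not in set(bb_ids)),
            median_length=float("nan"),
            eligible_ids=frozenset(bb_ids),
        )
    else:
        split = select_backbone(seqs, cfg)
    timings["select_backbone"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    bb_aln, bb_tree = estimate_backbone(
        split.backbone, cfg, alignment=backbone_alignment, tree=backbone_tree
    )
    timings["estimate_backbone"] = time.perf_counter() - t0

    if len(split.queries) == 0:
        extended = ExtendedAlignment(
            alignment=bb_aln, backbone_ids=tuple(bb_aln.rows), query_ids=()
        )
        masked_aln = mask(extended)
        manifest = RunManifest(
            config=asdict(cfg),
            version=__version__,
            n_input=len(seqs),
            n_backbone=len(split.backbone),
            n_queries=0,
            n_hmms=0,
            median_length=split.median_length,
            stage_seconds=timings,
        )
        return AlignResult(extended, masked_aln, manifest, split, bb_aln, bb_tree)

    t0 = time.perf_counter()
    decomp = decompose(bb_tree, cfg)
    ensemble = build_ensemble(bb_aln, decomp, cfg)
    timings["build_ensemble"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    placements = place_queries(ensemble, split.queries)
    timings["score_and_place"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    extended = extend_alignment(bb_aln, placements)
    masked_aln = mask(extended)
    timings["extend_and_mask"] = time.perf_counter() - t0

    if set(extended.alignment.rows) != set(seqs.ids):
        raise HmmstitchError(
            "output row set differs from input sequence set (internal error)"
        )

    manifest = RunManifest(
        config=asdict(cfg),
        version=__version__,
        n_input=len(seqs),
        n_backbone=len(split.backbone),
        n_queries=len(split.queries),
        n_hmms=len(ensemble),
        median_length=split.median_length,
        stage_seconds=timings,
        placements=[
            (p.query_id, p.subset_id, p.bit_score) for p in placements
        ],
    )
    return AlignResult(extended, masked_aln, manifest, split, bb_aln, bb_tree)
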