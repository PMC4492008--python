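"""Query scoring/selection and the transitive extension of the backbone."""

import numpy as np
import pytest

from hmmstitch import (
    DNA,
    Alignment,
    PhyloTree,
    RunConfig,
    SequenceRecord,
    build_ensemble,
    decompose,
    extend_alignment,
    homology_pairs,
    mask,
    place_queries,
    score_and_select,
)
from hmmstitch.ensemble import EnsembleMember, HMMEnsemble
from hmmstitch.phmm import build_profile
from hmmstitch.placement import PlacementResult
from hmmstitch.phmm import StatePath


def single_member_ensemble(aln, subset_id=0):
    hmm = build_profile(aln)
    return HMMEnsemble([EnsembleMember(subset_id, frozenset(aln.rows), hmm)])


class TestScoreAndSelect:
    def test_single_hmm_always_chosen(self):
        ens = single_member_ensemble(Alignment({"a": "ACGT", "b": "ACGT"}, DNA))
        pl = score_and_select(ens, SequenceRecord("q", "TTTT", DNA))
        assert pl.subset_id == 0  # no threshold: even a poor match is placed

    def test_training_match_beats_shuffled_model(self):
        target = Alignment({"a": "ACGTA", "b": "ACGTA"}, DNA)
        shuffled = Alignment({"c": "TAGCA", "d": "TAGCA"}, DNA)
        ens = HMMEnsemble(
            [
                EnsembleMember(0, frozenset(target.rows), build_profile(target)),
                EnsembleMember(1, frozenset(shuffled.rows), build_profile(shuffled)),
            ]
        )
        pl = score_and_select(ens, SequenceRecord("q", "ACGTA", DNA))
        assert pl.subset_id == 0
        ens_rev = HMMEnsemble(
            [
                EnsembleMember(0, frozenset(shuffled.rows), build_profile(shuffled)),
                EnsembleMember(1, frozenset(target.rows), build_profile(target)),
            ]
        )
        assert score_and_select(ens_rev, SequenceRecord("q", "ACGTA", DNA)).subset_id == 1

    def test_identical_hmms_tie_to_lowest_subset_id(self):
        aln = Alignment({"a": "ACGT", "b": "ACGT"}, DNA)
        ens = HMMEnsemble(
            [
                EnsembleMember(0, frozenset(aln.rows), build_profile(aln)),
                EnsembleMember(1, frozenset(aln.rows), build_profile(aln)),
            ]
        )
        assert score_and_select(ens, SequenceRecord("q", "ACGT", DNA)).subset_id == 0

    def test_residue_map_strictly_increasing_match_columns(self):
        ens = single_member_ensemble(Alignment({"a": "ACGTACGT", "b": "ACGTACGT"}, DNA))
        pl = score_and_select(ens, SequenceRecord("q", "ACGTAACGT", DNA))
        cols = [c for kind, c in pl.residue_map if kind == "M"]
        assert cols == sorted(set(cols))
        assert len(pl.residue_map) == 9  # every residue mapped exactly once


def make_placement(qid, residues, residue_map, subset_id=0):
    return PlacementResult(
        query_id=qid,
        subset_id=subset_id,
        bit_score=0.0,
        path=StatePath(steps=[]),
        residue_map=residue_map,
        residues=residues,
    )


class TestExtendAlignment:
    def backbone(self):
        return Alignment({"b1": "ACG", "b2": "A-G"}, DNA)

    def test_zero_placements_identity(self):
        ext = extend_alignment(self.backbone(), [])
        assert ext.alignment.rows == self.backbone().rows
        assert ext.alignment.column_flags == "MMM"

    def test_gapless_query_no_insertions(self):
        pl = make_placement("q", "TTT", [("M", 0), ("M", 1), ("M", 2)])
        ext = extend_alignment(self.backbone(), [pl])
        assert ext.alignment.width == 3
        assert ext.alignment.rows["q"] == "TTT"
        assert ext.alignment.column_flags == "MMM"

    def test_insertion_block_width_is_max_over_queries(self):
        # two queries insert 1 and 2 residues between columns 2 and 3
        p1 = make_placement("q1", "AGT", [("M", 0), ("I", 2), ("M", 2)])
        p2 = make_placement("q2", "AGGT", [("M", 0), ("I", 2), ("I", 2), ("M", 2)])
        ext = extend_alignment(self.backbone(), [p1, p2])
        assert ext.alignment.width == 5
        assert ext.alignment.column_flags == "MMIIM"
        assert ext.alignment.rows["q1"] == "A-G-T"  # left-justified in block
        assert ext.alignment.rows["q2"] == "A-GGT"
        assert ext.alignment.rows["b1"] == "AC--G"

    def test_left_flank_goes_before_first_column(self):
        pl = make_placement("q", "TTA", [("I", 0), ("I", 0), ("M", 0)])
        ext = extend_alignment(self.backbone(), [pl])
        assert ext.alignment.column_flags == "IIMMM"
        assert ext.alignment.rows["q"] == "TTA--"
        assert ext.alignment.rows["b1"] == "--ACG"

    def test_backbone_rows_preserved_on_match_columns(self):
        p1 = make_placement("q1", "AGT", [("M", 0), ("I", 2), ("M", 2)])
        ext = extend_alignment(self.backbone(), [p1])
        masked = mask(ext)
        for sid, row in self.backbone().rows.items():
            assert masked.rows[sid] == row

    def test_mask_restores_backbone_width(self):
        p2 = make_placement("q2", "AGGT", [("M", 0), ("I", 2), ("I", 2), ("M", 2)])
        ext = extend_alignment(self.backbone(), [p2])
        assert mask(ext).width == 3

    def test_masked_and_unmasked_same_homology_pairs(self):
        # masking drops insertion residues, so pairs are compared with
        # residues keyed by their index among match-column residues
        from conftest import match_only_pairs

        p1 = make_placement("q1", "AGT", [("M", 0), ("I", 2), ("M", 2)])
        p2 = make_placement("q2", "AGGT", [("M", 0), ("I", 2), ("I", 2), ("M", 2)])
        ext = extend_alignment(self.backbone(), [p1, p2])
        assert match_only_pairs(ext.alignment) == homology_pairs(mask(ext))

    def test_ungapping_reproduces_each_query(self):
        p2 = make_placement("q2", "AGGT", [("M", 0), ("I", 2), ("I", 2), ("M", 2)])
        ext = extend_alignment(self.backbone(), [p2])
        assert ext.alignment.ungapped("q2") == "AGGT"


class TestEndToEndPlacement:
    def test_every_query_placed_and_recoverable(self):
        rng = np.random.default_rng(10)
        base = "".join(rng.choice(list("ACGT"), 60).tolist())
        rows = {f"b{i}": base for i in range(8)}
        backbone = Alignment(rows, DNA)
        tree = PhyloTree.from_newick("(" + ",".join(rows) + ");")
        cfg = RunConfig(backbone_size=100, subset_max=4)
        ens = build_ensemble(backbone, decompose(tree, cfg), cfg)
        queries = [
            SequenceRecord("full", base, DNA),
            SequenceRecord("frag", base[20:45], DNA),
            SequenceRecord("ins", base[:30] + "TTTT" + base[30:], DNA),
            SequenceRecord("junk", "".join(rng.choice(list("ACGT"), 40).tolist()), DNA),
        ]
        placements = place_queries(ens, queries)
        ext = extend_alignment(backbone, placements)
        assert set(ext.alignment.rows) == set(rows) | {q.id for q in queries}
        for q in queries:
            assert ext.alignment.ungapped(q.id) == q.residues
        # a perfect full-length copy aligns gaplessly onto the backbone
        assert mask(ext).rows["full"] == base
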