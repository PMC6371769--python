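"""Conflict detection, scaffold splitting, PCF chaining and sequences."""

from __future__ import annotations

import pytest

from refchrom import pcf_builder as pb
from refchrom.evidence import JunctionCoverage, ReliableAdjacency
from refchrom.io_formats import SequenceRecord, reverse_complement
from refchrom.sf_builder import SynFragment


def _sf(sf_id, scaffold, s_start, s_end, ref_chrom, r_start, r_end,
        orient="+", og=None):
    og = og or {}
    return SynFragment(sf_id, scaffold, s_start, s_end, ref_chrom,
                       r_start, r_end, orient,
                       og.get("chrom"), og.get("start"), og.get("end"),
                       og.get("strand"))


def _cov(pct, spanning=None):
    return JunctionCoverage("s", 0, 1000,
                            spanning if spanning is not None else pct, pct)


class TestDetectConflicts:
    """The 2x2 decision table: reference discordance x outgroup support."""

    def _scaffold_pair(self, ref_colinear, outgroup_colinear, outgroup_known=True):
        og1 = og2 = None
        if outgroup_known:
            if outgroup_colinear:
                og1 = {"chrom": "outX", "start": 0, "end": 200_000, "strand": "+"}
                og2 = {"chrom": "outX", "start": 200_000, "end": 400_000,
                       "strand": "+"}
            else:
                og1 = {"chrom": "outX", "start": 0, "end": 200_000, "strand": "+"}
                og2 = {"chrom": "outY", "start": 0, "end": 200_000, "strand": "+"}
        if ref_colinear:
            r2 = ("chr1", 200_000, 400_000)
        else:
            r2 = ("chr2", 0, 200_000)
        return [
            _sf("s1a", "s1", 0, 200_000, "chr1", 0, 200_000, og=og1),
            _sf("s1b", "s1", 200_000, 400_000, *r2, og=og2),
        ]

    def test_colinear_on_reference_is_not_a_candidate(self):
        assert pb.detect_conflicts(self._scaffold_pair(True, False)) == []

    def test_discordant_everywhere_is_a_candidate(self):
        cands = pb.detect_conflicts(self._scaffold_pair(False, False))
        assert [c.junction_id for c in cands] == ["s1a|s1b"]

    def test_outgroup_support_rescues_lineage_rearrangement(self):
        assert pb.detect_conflicts(self._scaffold_pair(False, True)) == []

    def test_unknown_outgroup_cannot_rescue(self):
        cands = pb.detect_conflicts(
            self._scaffold_pair(False, False, outgroup_known=False))
        assert len(cands) == 1


class TestSplitScaffolds:
    CAND = pb.SplitCandidate("a|b", "s1", "a", "b", 200_000, 200_000)

    @pytest.mark.parametrize("pct,threshold,expect_split", [
        (60.0, 51.16, False),
        (4.0, 5.0, True),
        (51.16, 51.16, False),   # split only strictly below the threshold
    ])
    def test_coverage_threshold(self, pct, threshold, expect_split):
        dec = pb.split_scaffolds([self.CAND], {"a|b": _cov(pct)}, threshold)
        assert dec[0].split is expect_split

    def test_reliable_junction_never_split(self):
        rel = ReliableAdjacency("a", "tail", "b", "head", (), "verified_junction")
        dec = pb.split_scaffolds([self.CAND], {"a|b": _cov(0.0)}, 99.0, [rel])
        assert dec[0].split is False and dec[0].is_reliable


class TestBuildPcfs:
    def test_two_scaffolds_consecutive_on_reference_join(self):
        sfs = [_sf("s1a", "s1", 0, 200_000, "chr1", 0, 200_000),
               _sf("s2a", "s2", 0, 200_000, "chr1", 201_000, 401_000)]
        pcfs = pb.build_pcfs(sfs)
        assert len(pcfs) == 1
        assert pcfs[0].sf_ids == ["s1a", "s2a"]
        assert pcfs[0].junctions[0].source == "reference_order"

    def test_reference_gap_beyond_tolerance_does_not_join(self):
        sfs = [_sf("s1a", "s1", 0, 200_000, "chr1", 0, 200_000),
               _sf("s2a", "s2", 0, 200_000, "chr1", 301_000, 501_000)]
        assert len(pb.build_pcfs(sfs)) == 2

    def test_intact_scaffold_junction_bridges_reference_fission(self):
        """A target chromosome split in the reference is reassembled through
        the intact intra-scaffold junction."""
        og = [{"chrom": "outX", "start": 0, "end": 200_000, "strand": "+"},
              {"chrom": "outX", "start": 200_000, "end": 400_000, "strand": "+"}]
        sfs = [_sf("s1a", "s1", 0, 200_000, "ref1", 800_000, 1_000_000, og=og[0]),
               _sf("s1b", "s1", 200_000, 400_000, "ref2", 0, 200_000, og=og[1])]
        assert pb.detect_conflicts(sfs) == []  # outgroup supports the target
        pcfs = pb.build_pcfs(sfs, intact_junctions=[("s1a", "s1b")])
        assert len(pcfs) == 1
        assert pcfs[0].sf_ids == ["s1a", "s1b"]
        assert pcfs[0].junctions[0].source == "intra_scaffold"

    def test_reliable_adjacency_joins_and_scores_one(self):
        sfs = [_sf("s1a", "s1", 0, 200_000, "chr1", 0, 200_000),
               _sf("s2a", "s2", 0, 200_000, "chr2", 0, 200_000)]
        rel = [ReliableAdjacency("s1a", "tail", "s2a", "head", ("g",),
                                 "gene_span")]
        pcfs = pb.build_pcfs(sfs, reliable=rel)
        assert len(pcfs) == 1
        assert pcfs[0].junctions[0].source == "reliable"
        assert pcfs[0].junctions[0].score == 1.0

    def test_reliable_contradicting_intact_junction_raises(self):
        sfs = [_sf("s1a", "s1", 0, 200_000, "chr1", 0, 200_000),
               _sf("s1b", "s1", 200_000, 400_000, "chr1", 200_000, 400_000),
               _sf("s2a", "s2", 0, 200_000, "chr2", 0, 200_000)]
        rel = [ReliableAdjacency("s1a", "tail", "s2a", "head", (), "gene_span")]
        with pytest.raises(ValueError, match="reliable adjacency contradicts"):
            pb.build_pcfs(sfs, intact_junctions=[("s1a", "s1b")], reliable=rel)

    def test_single_sf_pcf_flagged_low_confidence(self):
        pcfs = pb.build_pcfs([_sf("s1a", "s1", 0, 200_000, "chr1", 0, 200_000)])
        assert pcfs[0].low_confidence

    def test_idempotent_rebuild(self, identity_run):
        sfs = identity_run.sfs
        intact = pb.intact_intra_junctions(sfs)
        a = pb.build_pcfs(sfs, intact, identity_run.reliable_gene)
        b = pb.build_pcfs(sfs, intact, identity_run.reliable_gene)
        assert [(p.pcf_id, p.sf_ids, [o for _, o in p.members]) for p in a] == \
            [(p.pcf_id, p.sf_ids, [o for _, o in p.members]) for p in b]


class TestScoreAdjacency:
    def _adj(self, source, support, cov):
        return pb.Adjacency(("a", "R"), ("b", "L"), source, support, cov)

    def test_reliable_scores_one(self):
        assert pb.score_adjacency(self._adj("reliable", 0.0, None)) == 1.0

    def test_full_support_full_coverage(self):
        adj = self._adj("intra_scaffold", 1.0, _cov(100.0))
        assert pb.score_adjacency(adj) == 1.0

    def test_full_support_zero_coverage(self):
        adj = self._adj("intra_scaffold", 1.0, _cov(0.0))
        assert pb.score_adjacency(adj) == 0.5

    def test_monotone_in_both_arguments(self):
        lo = pb.score_adjacency(self._adj("reference_order", 0.2, _cov(30.0)))
        hi_support = pb.score_adjacency(self._adj("reference_order", 0.7, _cov(30.0)))
        hi_cov = pb.score_adjacency(self._adj("reference_order", 0.2, _cov(80.0)))
        assert hi_support > lo and hi_cov > lo


class TestAssemblyToFasta:
    SCAFFOLDS = [SequenceRecord("s1", "ACGTACGTAA")]

    def _pcf(self, members):
        return pb.PCF("PCF_1", members, [], gap_length=4)

    def test_plus_sf_is_subsequence_identity(self):
        sf = _sf("s1a", "s1", 2, 8, "chr1", 0, 6)
        recs = pb.assembly_to_fasta([self._pcf([(sf, "+")])], self.SCAFFOLDS, 4)
        assert recs[0].sequence == "GTACGT"

    def test_minus_sf_is_reverse_complement(self):
        sf = _sf("s1a", "s1", 2, 8, "chr1", 0, 6)
        recs = pb.assembly_to_fasta([self._pcf([(sf, "-")])], self.SCAFFOLDS, 4)
        assert recs[0].sequence == reverse_complement("GTACGT")

    def test_gap_arithmetic(self):
        a = _sf("s1a", "s1", 0, 4, "chr1", 0, 4)
        b = _sf("s1b", "s1", 6, 10, "chr1", 6, 10)
        recs = pb.assembly_to_fasta([self._pcf([(a, "+"), (b, "+")])],
                                    self.SCAFFOLDS, 4)
        assert len(recs[0].sequence) == 4 + 4 + 4
        assert recs[0].sequence[4:8] == "NNNN"

    def test_missing_scaffold_errors(self):
        sf = _sf("xa", "missing", 0, 4, "chr1", 0, 4)
        with pytest.raises(KeyError, match="missing"):
            pb.assembly_to_fasta([self._pcf([(sf, "+")])], self.SCAFFOLDS, 4)


def test_base_conservation_scaffolds_to_pcfs(chimera_run):
    """The multiset of SF bases in PCFs equals the input SF bases."""
    in_bases = sorted((sf.sf_id, sf.length) for sf in chimera_run.sfs)
    out_bases = sorted((sf.sf_id, sf.length)
                       for p in chimera_run.pcfs_run2 for sf, _ in p.members)
    assert in_bases == out_bases


def test_pcf_round_trip(tmp_path, chimera_run):
    p = tmp_path / "pcfs.tsv"
    pb.write_pcfs(chimera_run.pcfs_run2, p)
    back = pb.read_pcfs(p, chimera_run.sfs)
    assert [(q.pcf_id, q.sf_ids, [o for _, o in q.members]) for q in back] == \
        [(q.pcf_id, q.sf_ids, [o for _, o in q.members])
         for q in chimera_run.pcfs_run2]
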