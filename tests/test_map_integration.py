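"""Homology-map checks, PCF breaking, marker placement and assignment."""

from __future__ import annotations

import pytest

from refchrom import map_integration as mi
from refchrom.io_formats import ChromMapRow, MarkerAlnRow, MarkerMapRow
from refchrom.pcf_builder import PCF, Adjacency
from refchrom.sf_builder import SynFragment

MB = 1_000_000


def _sf(sf_id, scaffold, s_start, s_end, og_chrom):
    return SynFragment(sf_id, scaffold, s_start, s_end, "ref1",
                       s_start, s_end, "+", og_chrom, 0, s_end - s_start, "+")


def _pcf(pcf_id, spans, scores=None, gap=100):
    """spans: list of (length, outgroup_chrom); junction scores optional."""
    members = []
    pos = 0
    for i, (length, og) in enumerate(spans):
        members.append((_sf(f"{pcf_id}sf{i}", f"sc{pcf_id}{i}", pos,
                            pos + length, og), "+"))
        pos += length
    junctions = [Adjacency((m[0].sf_id, "R"), (members[i + 1][0].sf_id, "L"),
                           "reference_order", 1.0, None,
                           scores[i] if scores else 0.5)
                 for i, m in enumerate(members[:-1])]
    return PCF(pcf_id, members, junctions, gap_length=gap)


CHROM_MAP = [ChromMapRow("chrA", "outX", 1), ChromMapRow("chrB", "outY", 1)]


class TestCheckAgainstMap:
    def test_single_mapped_outgroup_chromosome_agrees(self):
        chk = mi.check_against_map([_pcf("p1", [(4 * MB, "outX")])], CHROM_MAP)
        assert chk[0].agrees and chk[0].candidate_chromosomes == ["chrA"]

    def test_small_discordant_run_is_exempt(self):
        pcf = _pcf("p1", [(4 * MB, "outX"), (2 * MB, "outY")])
        chk = mi.check_against_map([pcf], CHROM_MAP)
        assert chk[0].agrees
        assert any(r.outgroup_chrom == "outY" for r in chk[0].exempt_runs)

    def test_two_large_runs_on_differently_mapped_outgroups_disagree(self):
        pcf = _pcf("p1", [(4 * MB, "outX"), (4 * MB, "outY")])
        chk = mi.check_against_map([pcf], CHROM_MAP)
        assert not chk[0].agrees
        assert len(chk[0].disagreement_intervals) == 1


class TestBreakPcf:
    def test_splits_at_minimal_score(self):
        pcf = _pcf("p1", [(MB, "outX")] * 4, scores=[0.9, 0.2, 0.8])
        offs = pcf.sf_offsets()
        a, b = mi.break_pcf(pcf, (0, pcf.length, pcf.length))
        assert a.sf_ids == ["p1sf0", "p1sf1"]
        assert b.sf_ids == ["p1sf2", "p1sf3"]
        assert (a.pcf_id, b.pcf_id) == ("p1a", "p1b")

    def test_single_sf_pcf_is_unsplittable(self):
        pcf = _pcf("p1", [(MB, "outX")])
        with pytest.raises(mi.UnsplittableError):
            mi.break_pcf(pcf, (0, MB, MB // 2))

    def test_score_tie_broken_toward_switch_point(self):
        pcf = _pcf("p1", [(MB, "outX")] * 4, scores=[0.2, 0.9, 0.2])
        # switch point near the end: the later 0.2 junction wins
        a, b = mi.break_pcf(pcf, (0, pcf.length, pcf.length))
        assert len(a.members) == 3 and len(b.members) == 1

    def test_children_partition_parent(self):
        pcf = _pcf("p1", [(MB, "outX")] * 5, scores=[0.5, 0.1, 0.5, 0.5])
        a, b = mi.break_pcf(pcf, (0, pcf.length, 0))
        assert a.sf_ids + b.sf_ids == pcf.sf_ids


MARKER_MAP = [MarkerMapRow("m1", "chrA", 1), MarkerMapRow("m2", "chrA", 2),
              MarkerMapRow("m3", "chrA", 3), MarkerMapRow("m4", "chrB", 1)]


class TestPlaceMarkers:
    def _pcf_and_aln(self, frac):
        pcf = _pcf("p1", [(MB, "outX")])
        aln = MarkerAlnRow("m1", pcf.members[0][0].scaffold_id, 1000, 4000,
                           frac, 1.0)
        return pcf, aln

    def test_span_above_cutoff_retained(self):
        pcf, aln = self._pcf_and_aln(0.85)
        hits = mi.place_markers([pcf], MARKER_MAP, [aln])
        assert len(hits) == 1 and hits[0].pcf_id == "p1"

    def test_span_exactly_at_cutoff_discarded(self):
        pcf, aln = self._pcf_and_aln(0.80)
        assert mi.place_markers([pcf], MARKER_MAP, [aln]) == []

    def test_equal_hits_tie_break_is_deterministic(self):
        p1, p2 = _pcf("p1", [(MB, "outX")]), _pcf("p2", [(MB, "outX")])
        alns = [MarkerAlnRow("m1", p.members[0][0].scaffold_id, 0, 3000,
                             0.9, 1.0) for p in (p2, p1)]
        hits = mi.place_markers([p1, p2], MARKER_MAP, alns)
        assert hits[0].pcf_id == "p1"  # lexicographically smallest pcf id


class TestAssignChromosomes:
    def _hits(self, pcf_id, specs):
        return [mi.MarkerHit(m, c, o, pcf_id, pos, 0.9)
                for m, c, o, pos in specs]

    def test_one_marker_assigns_unoriented(self):
        pcf = _pcf("p1", [(MB, "outX")])
        res = mi.assign_chromosomes(
            [pcf], self._hits("p1", [("m1", "chrA", 1, 100)]), CHROM_MAP)
        placed = res.assembly.chromosomes["chrA"]
        assert len(placed) == 1
        assert placed[0].orientation == "?" and not placed[0].ordered

    @pytest.mark.parametrize("positions,expected", [
        ((1 * MB, 2 * MB), "+"),
        ((2 * MB, 1 * MB), "-"),
    ])
    def test_two_markers_orient_by_monotonicity(self, positions, expected):
        pcf = _pcf("p1", [(3 * MB, "outX")])
        hits = self._hits("p1", [("m2", "chrA", 2, positions[0]),
                                 ("m3", "chrA", 3, positions[1])])
        res = mi.assign_chromosomes([pcf], hits, CHROM_MAP)
        assert res.assembly.chromosomes["chrA"][0].orientation == expected

    def test_non_monotone_markers_route_to_break(self):
        pcf = _pcf("p1", [(3 * MB, "outX")])
        hits = self._hits("p1", [("m1", "chrA", 1, 1 * MB),
                                 ("m2", "chrA", 2, 3 * MB),
                                 ("m3", "chrA", 3, 2 * MB)])
        res = mi.assign_chromosomes([pcf], hits, CHROM_MAP)
        assert len(res.disagreeing) == 1
        assert res.disagreeing[0][2] == "marker order not monotone"

    def test_markers_from_two_chromosomes_conflict(self):
        pcf = _pcf("p1", [(3 * MB, "outX")])
        hits = self._hits("p1", [("m1", "chrA", 1, MB), ("m4", "chrB", 1, 2 * MB)])
        res = mi.assign_chromosomes([pcf], hits, CHROM_MAP)
        assert res.disagreeing[0][2] == "markers on two chromosomes"

    def test_markerless_pcf_assigned_by_unambiguous_homology(self):
        pcf = _pcf("p1", [(4 * MB, "outY")])
        res = mi.assign_chromosomes([pcf], [], CHROM_MAP)
        assert [p.pcf.pcf_id for p in res.assembly.chromosomes["chrB"]] == ["p1"]
        assert res.assembly.chromosomes["chrB"][0].evidence == "chrom_map"

    def test_markerless_ambiguous_pcf_stays_unplaced(self):
        cmap = CHROM_MAP + [ChromMapRow("chrB", "outX", 2)]
        pcf = _pcf("p1", [(4 * MB, "outX")])  # outX maps to chrA and chrB
        res = mi.assign_chromosomes([pcf], [], cmap)
        assert [p.pcf_id for p in res.assembly.unplaced] == ["p1"]

    def test_permutation_invariant(self):
        pcfs = [_pcf("p1", [(3 * MB, "outX")]), _pcf("p2", [(2 * MB, "outX")]),
                _pcf("p3", [(4 * MB, "outY")])]
        hits = (self._hits("p1", [("m1", "chrA", 1, MB)])
                + self._hits("p2", [("m2", "chrA", 2, MB)]))
        a = mi.assign_chromosomes(pcfs, hits, CHROM_MAP)
        b = mi.assign_chromosomes(list(reversed(pcfs)), hits, CHROM_MAP)
        key = lambda r: {c: [p.pcf.pcf_id for p in v]
                         for c, v in r.assembly.chromosomes.items()}
        assert key(a) == key(b)


class TestSummarizeDistribution:
    def _assembly(self, counts_per_chrom):
        chroms = {}
        order = []
        for i, n in enumerate(counts_per_chrom):
            name = f"c{i}"
            order.append(name)
            chroms[name] = [mi.PlacedPcf(_pcf(f"p{i}_{j}", [(MB, "outX")]),
                                         "+", True, "markers")
                            for j in range(n)]
        return mi.ChromAssembly(chroms, [], order)

    def test_all_single_pcf(self):
        summary = mi.summarize_distribution(self._assembly([1, 1, 1]))
        assert summary["percent"]["1"] == 100.0

    def test_printed_distribution_percentages(self):
        counts = [1] * 12 + [2] * 13 + [3] * 4 + [4] * 5 + [0] * 2
        summary = mi.summarize_distribution(self._assembly(counts))
        assert summary["counts"] == {"1": 12, "2": 13, "3": 4, ">3": 5,
                                     "unknown": 2}
        assert summary["percent"] == {"1": 33.3, "2": 36.1, "3": 11.1,
                                      ">3": 13.9, "unknown": 5.6}
        assert summary["percent_at_most_3"] == 80.6


def test_breaking_conserves_sf_content(chimera_run):
    """Every SF present before map integration is present after, exactly
    once, across placed and unplaced PCFs."""
    before = sorted(sf.sf_id for p in chimera_run.pcfs_run2 for sf, _ in p.members)
    after = sorted(
        sf.sf_id
        for placed in chimera_run.assembly.chromosomes.values()
        for p in placed for sf, _ in p.pcf.members
    ) + sorted(sf.sf_id for p in chimera_run.assembly.unplaced
               for sf, _ in p.members)
    assert sorted(after) == before
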