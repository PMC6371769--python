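"""Physical-map verification and chromosome placement of PCFs.

Two maps are integrated: a chromosome-to-outgroup homology map (FISH-style;
pairings of whole homology segments, blind to segments below its ~3 Mb
resolution) and an ordered gene-marker map per chromosome.  PCFs that
disagree with the homology map above map resolution are broken at the
junction with the lowest adjacency score inside the disagreement region;
marker hits (CDS alignments spanning more than 80% of the CDS) assign PCFs
to chromosomes, and two or more markers in consistent map order also place
and orient them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .io_formats import (
    ChromMapRow,
    MarkerAlnRow,
    MarkerMapRow,
    SequenceRecord,
    write_agp,
)
from .pcf_builder import PCF, assembly_to_fasta

logger = logging.getLogger(__name__)

DEFAULT_MAP_RESOLUTION = 3_000_000
DEFAULT_MARKER_SPAN_MIN = 0.8


# ---------------------------------------------------------------------------
# homology-map verification


@dataclass(frozen=True)
class HomologyRun:
    """A maximal run of consecutive SFs sharing one outgroup chromosome."""

    outgroup_chrom: Optional[str]
    start: int   # PCF coords
    end: int
    first_sf_index: int
    last_sf_index: int

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class MapCheck:
    pcf_id: str
    agrees: bool
    candidate_chromosomes: list[str]
    exempt_runs: list[HomologyRun]          # below map resolution
    disagreement_intervals: list[tuple[int, int, int]]  # (start, end, switch)


def _homology_runs(pcf: PCF) -> list[HomologyRun]:
    runs: list[HomologyRun] = []
    offs = pcf.sf_offsets()
    for i, (sf, _) in enumerate(pcf.members):
        og = sf.outgroup_chrom
        if runs and runs[-1].outgroup_chrom == og:
            prev = runs[-1]
            runs[-1] = HomologyRun(og, prev.start, offs[i] + sf.length,
                                   prev.first_sf_index, i)
        else:
            runs.append(HomologyRun(og, offs[i], offs[i] + sf.length, i, i))
    return runs


def check_against_map(
    pcfs: list[PCF],
    chrom_map: list[ChromMapRow],
    resolution: int = DEFAULT_MAP_RESOLUTION,
) -> list[MapCheck]:
    """Verify each PCF against the chromosome-outgroup homology map.

    A PCF disagrees iff no single target chromosome accounts for all its
    homology runs of at least ``resolution`` bp; shorter discordant runs
    are exempt ("below map resolution") and flagged.  For a disagreeing
    PCF the reported intervals cover the runs not explained by the best
    candidate chromosome, with the homology switch point at each interval's
    map-ward edge.
    """
    chroms_by_og: dict[str, set[str]] = {}
    for row in chrom_map:
        chroms_by_og.setdefault(row.outgroup_chrom, set()).add(row.chromosome_id)

    out: list[MapCheck] = []
    for pcf in pcfs:
        runs = _homology_runs(pcf)
        big = [r for r in runs if r.span >= resolution and r.outgroup_chrom]
        exempt = [r for r in runs if r.span < resolution]
        if not big:
            out.append(MapCheck(pcf.pcf_id, True, [], exempt, []))
            continue
        candidates: Optional[set[str]] = None
        for r in big:
            mapped = chroms_by_og.get(r.outgroup_chrom, set())
            candidates = mapped if candidates is None else candidates & mapped
        if candidates:
            out.append(MapCheck(pcf.pcf_id, True, sorted(candidates), exempt, []))
            continue
        # choose the chromosome explaining the most homology bp
        scores: dict[str, int] = {}
        for r in big:
            for c in chroms_by_og.get(r.outgroup_chrom, set()):
                scores[c] = scores.get(c, 0) + r.span
        best = max(sorted(scores), key=lambda c: scores[c]) if scores else None
        intervals = []
        for r in big:
            if best is not None and best in chroms_by_og.get(r.outgroup_chrom, set()):
                continue
            # switch point: the edge of the run facing the explained part
            switch = r.start if r.start > 0 else r.end
            intervals.append((r.start, r.end, switch))
        out.append(MapCheck(pcf.pcf_id, False,
                            [best] if best is not None else [], exempt, intervals))
    return out


class UnsplittableError(ValueError):
    """A disagreement interval contains no junction to break at."""


def break_pcf(pcf: PCF, interval: tuple[int, int, int]) -> tuple[PCF, PCF]:
    """Split a PCF at the lowest-scoring junction inside the interval.

    ``interval`` is (start, end, switch_point) in PCF coordinates.  Ties on
    the score are broken toward the junction nearest the homology switch
    point.  Children inherit the parent's id with letter suffixes.
    """
    start, end, switch = interval
    offs = pcf.sf_offsets()
    junction_pos = [offs[i] + pcf.members[i][0].length
                    for i in range(len(pcf.members) - 1)]
    in_interval = [i for i, p in enumerate(junction_pos) if start <= p <= end]
    if not in_interval:
        raise UnsplittableError(
            f"{pcf.pcf_id}: no junction inside disagreement interval "
            f"[{start}, {end})")
    best = min(in_interval,
               key=lambda i: (pcf.junctions[i].score,
                              abs(junction_pos[i] - switch), i))
    left = PCF(f"{pcf.pcf_id}a", pcf.members[: best + 1],
               pcf.junctions[:best], gap_length=pcf.gap_length,
               low_confidence=best == 0)
    right = PCF(f"{pcf.pcf_id}b", pcf.members[best + 1:],
                pcf.junctions[best + 1:], gap_length=pcf.gap_length,
                low_confidence=best + 2 == len(pcf.members))
    return left, right


# ---------------------------------------------------------------------------
# marker placement


@dataclass(frozen=True)
class MarkerHit:
    marker_id: str
    chromosome_id: str
    map_order: int
    pcf_id: str
    pcf_position: int
    cds_span_fraction: float


def place_markers(
    pcfs: list[PCF],
    marker_map: list[MarkerMapRow],
    marker_alns: list[MarkerAlnRow],
    span_min: float = DEFAULT_MARKER_SPAN_MIN,
) -> list[MarkerHit]:
    """Lift marker alignments onto PCF coordinates and keep reliable hits.

    Alignments spanning ``span_min`` of the CDS or less are discarded
    (strictly more than 80 % is required by default); each marker keeps a
    single best hit (highest span fraction, then identity, then pcf id —
    the deterministic tie-break is logged).
    """
    map_by_id = {m.marker_id: m for m in marker_map}
    # index SFs by scaffold for the lift
    lift: dict[str, list[tuple]] = {}
    for pcf in pcfs:
        offs = pcf.sf_offsets()
        for (sf, orient), off in zip(pcf.members, offs):
            lift.setdefault(sf.scaffold_id, []).append((sf, orient, off, pcf.pcf_id))

    best: dict[str, tuple] = {}
    for aln in marker_alns:
        if aln.span_fraction <= span_min:
            continue
        if aln.marker_id not in map_by_id:
            continue
        mid_pos = (aln.start + aln.end) // 2
        for sf, orient, off, pcf_id in lift.get(aln.scaffold_id, ()):
            if not sf.scaffold_start <= mid_pos < sf.scaffold_end:
                continue
            if orient == "+":
                pos = off + (mid_pos - sf.scaffold_start)
            else:
                pos = off + (sf.scaffold_end - mid_pos)
            key = (aln.span_fraction, aln.identity)
            cur = best.get(aln.marker_id)
            better = (
                cur is None
                or key > cur[0]
                or (key == cur[0] and pcf_id < cur[1])
            )
            if better:
                if cur is not None and key == cur[0]:
                    logger.info("marker %s: equal hits, tie-break to %s",
                                aln.marker_id, pcf_id)
                best[aln.marker_id] = (key, pcf_id, pos, aln.span_fraction)
            break
    hits = []
    for marker_id in sorted(best):
        _, pcf_id, pos, frac = best[marker_id]
        m = map_by_id[marker_id]
        hits.append(MarkerHit(marker_id, m.chromosome_id, m.map_order,
                              pcf_id, pos, frac))
    return hits


# ---------------------------------------------------------------------------
# chromosome assignment


@dataclass
class PlacedPcf:
    pcf: PCF
    orientation: str        # +, -, or ?
    ordered: bool
    evidence: str           # markers | chrom_map
    marker_hits: list[MarkerHit] = field(default_factory=list)


@dataclass
class ChromAssembly:
    """Chromosome -> ordered, oriented PCFs with placement provenance."""

    chromosomes: dict[str, list[PlacedPcf]]
    unplaced: list[PCF]
    chromosome_order: list[str]

    def to_agp(self, gap_length: int = 100) -> str:
        objects = []
        for chrom in self.chromosome_order:
            placed = self.chromosomes.get(chrom, [])
            if placed:
                objects.append((chrom, [(p.pcf.pcf_id, p.pcf.length, p.orientation)
                                        for p in placed]))
        for pcf in self.unplaced:
            objects.append((f"unplaced_{pcf.pcf_id}",
                            [(pcf.pcf_id, pcf.length, "?")]))
        return write_agp(objects, gap_length)

    def to_fasta(self, scaffolds: list[SequenceRecord],
                 gap_length: int = 100) -> list[SequenceRecord]:
        from .io_formats import reverse_complement

        all_pcfs = [p.pcf for chrom in self.chromosome_order
                    for p in self.chromosomes.get(chrom, [])] + self.unplaced
        pcf_seqs = {r.id: r.sequence
                    for r in assembly_to_fasta(all_pcfs, scaffolds, gap_length)}
        out = []
        for chrom in self.chromosome_order:
            placed = self.chromosomes.get(chrom, [])
            if not placed:
                continue
            parts = []
            for p in placed:
                seq = pcf_seqs[p.pcf.pcf_id]
                if p.orientation == "-":
                    seq = reverse_complement(seq)
                parts.append(seq)
            out.append(SequenceRecord(chrom, ("N" * gap_length).join(parts)))
        for pcf in self.unplaced:
            out.append(SequenceRecord(f"unplaced_{pcf.pcf_id}",
                                      pcf_seqs[pcf.pcf_id]))
        return out


@dataclass
class AssignmentResult:
    assembly: ChromAssembly
    disagreeing: list[tuple[PCF, tuple[int, int, int], str]]  # pcf, interval, reason


def _monotone_orientation(hits: list[MarkerHit]) -> Optional[str]:
    """'+' / '-' if pcf positions are strictly monotone in map order,
    else None (markers disagree with the map)."""
    ordered = sorted(hits, key=lambda h: h.map_order)
    pos = [h.pcf_position for h in ordered]
    if all(a < b for a, b in zip(pos, pos[1:])):
        return "+"
    if all(a > b for a, b in zip(pos, pos[1:])):
        return "-"
    return None


def _marker_disagreement_interval(hits: list[MarkerHit]) -> tuple[int, int, int]:
    """Smallest PCF interval bracketing an order violation between markers
    adjacent in map order."""
    ordered = sorted(hits, key=lambda h: h.map_order)
    pos = [h.pcf_position for h in ordered]
    sign = 1 if pos[-1] >= pos[0] else -1
    for a, b in zip(pos, pos[1:]):
        if (b - a) * sign < 0:
            lo, hi = min(a, b), max(a, b)
            return (lo, hi, (lo + hi) // 2)
    lo, hi = min(pos), max(pos)
    return (lo, hi, (lo + hi) // 2)


def assign_chromosomes(
    pcfs: list[PCF],
    hits: list[MarkerHit],
    chrom_map: list[ChromMapRow],
    map_resolution: int = DEFAULT_MAP_RESOLUTION,
) -> AssignmentResult:
    """Assign, order and orient PCFs into chromosomes.

    One marker assigns a PCF to its chromosome (unordered, orientation
    ``?``); two or more markers in strictly monotone map order place and
    orient it.  Markers from two chromosomes, or non-monotone marker order,
    route the PCF to breaking.  Marker-less PCFs fall back to the homology
    map when it maps their outgroup content to exactly one chromosome;
    otherwise they stay unplaced.  The result is independent of the input
    order of ``pcfs``.
    """
    hits_by_pcf: dict[str, list[MarkerHit]] = {}
    for h in hits:
        hits_by_pcf.setdefault(h.pcf_id, []).append(h)
    chroms_by_og: dict[str, set[str]] = {}
    for row in chrom_map:
        chroms_by_og.setdefault(row.outgroup_chrom, set()).add(row.chromosome_id)

    chrom_order = []
    for row in chrom_map:
        if row.chromosome_id not in chrom_order:
            chrom_order.append(row.chromosome_id)
    for h in hits:
        if h.chromosome_id not in chrom_order:
            chrom_order.append(h.chromosome_id)

    placed: dict[str, list[PlacedPcf]] = {c: [] for c in chrom_order}
    unplaced: list[PCF] = []
    disagreeing: list[tuple[PCF, tuple[int, int, int], str]] = []

    for pcf in sorted(pcfs, key=lambda p: p.pcf_id):
        phits = hits_by_pcf.get(pcf.pcf_id, [])
        chroms = sorted({h.chromosome_id for h in phits})
        if len(chroms) > 1:
            interval = (0, pcf.length, pcf.length // 2)
            disagreeing.append((pcf, interval, "markers on two chromosomes"))
            continue
        if len(phits) >= 2:
            orient = _monotone_orientation(phits)
            if orient is None:
                disagreeing.append((pcf, _marker_disagreement_interval(phits),
                                    "marker order not monotone"))
                continue
            placed[chroms[0]].append(PlacedPcf(pcf, orient, True, "markers", phits))
        elif len(phits) == 1:
            placed[chroms[0]].append(PlacedPcf(pcf, "?", False, "markers", phits))
        else:
            runs = [r for r in _homology_runs(pcf)
                    if r.outgroup_chrom and r.span >= map_resolution]
            cands: Optional[set[str]] = None
            for r in runs:
                mapped = chroms_by_og.get(r.outgroup_chrom, set())
                cands = mapped if cands is None else cands & mapped
            if cands and len(cands) == 1:
                chrom = next(iter(cands))
                if chrom not in placed:
                    placed[chrom] = []
                    chrom_order.append(chrom)
                placed[chrom].append(PlacedPcf(pcf, "?", False, "chrom_map", []))
            else:
                unplaced.append(pcf)

    # order within each chromosome: ordered PCFs by map order of their
    # markers, then unorderable ones appended in descending length
    for chrom in chrom_order:
        ordered = [p for p in placed[chrom] if p.ordered]
        rest = [p for p in placed[chrom] if not p.ordered]
        ordered.sort(key=lambda p: min(h.map_order for h in p.marker_hits))
        rest.sort(key=lambda p: (-p.pcf.length, p.pcf.pcf_id))
        placed[chrom] = ordered + rest

    unplaced.sort(key=lambda p: (-p.length, p.pcf_id))
    assembly = ChromAssembly(placed, unplaced, chrom_order)
    return AssignmentResult(assembly, disagreeing)


def summarize_distribution(
    assembly: ChromAssembly, total_chromosomes: Optional[int] = None
) -> dict:
    """Per-chromosome PCF counts binned as 1 / 2 / 3 / >3 / unknown, with
    percentages of the chromosome total (1 decimal, half-up rounding)."""
    from decimal import Decimal, ROUND_HALF_UP

    counts = {c: len(assembly.chromosomes.get(c, []))
              for c in assembly.chromosome_order}
    bins = {"1": 0, "2": 0, "3": 0, ">3": 0, "unknown": 0}
    for c, n in counts.items():
        if n == 0:
            bins["unknown"] += 1
        elif n <= 3:
            bins[str(n)] += 1
        else:
            bins[">3"] += 1
    total = total_chromosomes or len(counts)

    def pct(n):
        if total == 0:
            return 0.0
        return float(Decimal(100.0 * n / total).quantize(
            Decimal("0.1"), rounding=ROUND_HALF_UP))

    return {
        "counts": bins,
        "percent": {k: pct(v) for k, v in bins.items()},
        "total_chromosomes": total,
        "percent_at_most_3": pct(bins["1"] + bins["2"] + bins["3"]),
    }
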