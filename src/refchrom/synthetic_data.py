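"""Fully known ground-truth instances for the scaffolding pipeline.

The generator emulates the study design end to end: a multi-chromosome
target genome; a reference genome related to it by sampled inversions,
translocations, fissions and fusions (and an outgroup related to the
reference by an independent sample); fragmentation of the target into
scaffolds with a controlled fraction of injected chimeras; read pairs drawn
from the *true* genome and re-expressed in scaffold coordinates, so true
chimeric joins receive no spanning pairs by construction; and the two map
types (ordered gene-marker map per chromosome, chromosome-to-outgroup
homology map truncated at map resolution).

Every output is deterministic given the :class:`SimConfig` seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    BlockRow,
    ChromMapRow,
    GeneMapRow,
    MarkerAlnRow,
    MarkerMapRow,
    SequenceRecord,
    TruthPart,
    reverse_complement,
    write_blocks,
    write_chrom_map,
    write_fasta,
    write_gene_map,
    write_marker_alns,
    write_marker_map,
    write_pairs,
    write_truth,
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated instance.

    Defaults mirror the desk-scale conditions used throughout the test
    suite: five 2 Mb chromosomes fragmented into 40 scaffolds, insert sizes
    uniform in [250, 750] bp (typical short-insert mate bounds), 20-fold
    physical coverage, and a 3 Mb map resolution (the scale below which a
    FISH-style map cannot see a homology segment).
    """

    n_chromosomes: int = 5
    chrom_length: int = 2_000_000
    n_scaffolds: int = 40
    chimera_rate: float = 0.1
    n_rearrangements: int = 4
    insert_min: int = 250
    insert_max: int = 750
    pair_coverage: float = 20.0
    n_genes: int = 200
    n_markers_per_chrom: int = 4
    map_resolution: int = 3_000_000
    seed: int = 0
    # structural knobs (fixed conventions of this generator)
    min_segment_length: int = 200_000
    inter_scaffold_gap: int = 1_000
    scaffold_flip_prob: float = 0.5
    min_event_size: int = 150_000
    marker_cds_length: int = 3_000

    def validate(self) -> None:
        if not 0.0 <= self.chimera_rate <= 1.0:
            raise ValueError("chimera_rate must be in [0, 1]")
        if self.insert_min >= self.insert_max:
            raise ValueError("insert_min must be < insert_max")
        for name in ("n_chromosomes", "chrom_length", "n_scaffolds"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("n_rearrangements", "n_genes", "n_markers_per_chrom"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_scaffolds < self.n_chromosomes:
            raise ValueError("need at least one scaffold per chromosome")


# ---------------------------------------------------------------------------
# segment algebra for rearranged genomes


@dataclass(frozen=True)
class _Seg:
    """A source-genome interval carried by a derived chromosome."""

    src: str
    start: int
    end: int
    strand: str

    def __len__(self) -> int:
        return self.end - self.start


def _seg_len(segs: Sequence[_Seg]) -> int:
    return sum(len(s) for s in segs)


def _cut(segs: list[_Seg], offset: int) -> tuple[list[_Seg], list[_Seg]]:
    """Split a derived chromosome (list of segments) at a derived offset."""
    left: list[_Seg] = []
    pos = 0
    for i, s in enumerate(segs):
        if pos + len(s) <= offset:
            left.append(s)
            pos += len(s)
            continue
        k = offset - pos  # cut k bases into segment s
        if k == 0:
            return left, segs[i:]
        if s.strand == "+":
            a = _Seg(s.src, s.start, s.start + k, "+")
            b = _Seg(s.src, s.start + k, s.end, "+")
        else:
            a = _Seg(s.src, s.end - k, s.end, "-")
            b = _Seg(s.src, s.start, s.end - k, "-")
        return left + [a], [b] + segs[i + 1:]
    return left, []


def _invert(segs: list[_Seg]) -> list[_Seg]:
    return [_Seg(s.src, s.start, s.end, "-" if s.strand == "+" else "+")
            for s in reversed(segs)]


def _merge_colinear(segs: list[_Seg]) -> list[_Seg]:
    out: list[_Seg] = []
    for s in segs:
        if out:
            p = out[-1]
            if p.src == s.src and p.strand == s.strand:
                if s.strand == "+" and p.end == s.start:
                    out[-1] = _Seg(p.src, p.start, s.end, "+")
                    continue
                if s.strand == "-" and p.start == s.end:
                    out[-1] = _Seg(p.src, s.start, p.end, "-")
                    continue
        out.append(s)
    return out


def _apply_rearrangements(
    chroms: list[list[_Seg]],
    n_events: int,
    rng: np.random.Generator,
    min_event: int,
) -> tuple[list[list[_Seg]], list[tuple]]:
    """Sample and apply inversions/translocations/fissions/fusions.

    Infeasible draws (event longer than the chromosome allows) are resampled
    and logged in the event list as skipped attempts are not recorded.
    """
    chroms = [list(c) for c in chroms]
    events: list[tuple] = []
    kinds = ["inversion", "translocation", "fission", "fusion"]
    attempts = 0
    while len(events) < n_events and attempts < 50 * (n_events + 1):
        attempts += 1
        kind = kinds[rng.integers(0, len(kinds))]
        if kind == "inversion":
            ci = int(rng.integers(0, len(chroms)))
            L = _seg_len(chroms[ci])
            if L < 3 * min_event:
                continue
            a = int(rng.integers(min_event, L - 2 * min_event + 1))
            b = int(rng.integers(a + min_event, L - min_event + 1))
            head, rest = _cut(chroms[ci], a)
            mid, tail = _cut(rest, b - a)
            chroms[ci] = _merge_colinear(head + _invert(mid) + tail)
            events.append(("inversion", ci, a, b))
        elif kind == "translocation":
            if len(chroms) < 2:
                continue
            ci, cj = rng.choice(len(chroms), size=2, replace=False)
            Li, Lj = _seg_len(chroms[ci]), _seg_len(chroms[cj])
            if Li < 2 * min_event or Lj < 2 * min_event:
                continue
            a = int(rng.integers(min_event, Li - min_event + 1))
            b = int(rng.integers(min_event, Lj - min_event + 1))
            hi, ti = _cut(chroms[ci], a)
            hj, tj = _cut(chroms[cj], b)
            chroms[ci] = _merge_colinear(hi + tj)
            chroms[cj] = _merge_colinear(hj + ti)
            events.append(("translocation", int(ci), int(cj), a, b))
        elif kind == "fission":
            ci = int(rng.integers(0, len(chroms)))
            L = _seg_len(chroms[ci])
            if L < 2 * min_event:
                continue
            a = int(rng.integers(min_event, L - min_event + 1))
            head, tail = _cut(chroms[ci], a)
            chroms[ci] = head
            chroms.append(tail)
            events.append(("fission", ci, a))
        else:  # fusion
            if len(chroms) < 2:
                continue
            ci, cj = sorted(rng.choice(len(chroms), size=2, replace=False))
            merged = _merge_colinear(chroms[int(ci)] + chroms[int(cj)])
            chroms[int(ci)] = merged
            del chroms[int(cj)]
            events.append(("fusion", int(ci), int(cj)))
    return chroms, events


def _segments_to_records_and_blocks(
    chroms: list[list[_Seg]],
    src_seqs: dict[str, str],
    name_prefix: str,
) -> tuple[list[SequenceRecord], list[BlockRow]]:
    records: list[SequenceRecord] = []
    blocks: list[BlockRow] = []
    for i, segs in enumerate(chroms):
        name = f"{name_prefix}{i + 1}"
        parts = []
        off = 0
        for s in segs:
            sub = src_seqs[s.src][s.start:s.end]
            if s.strand == "-":
                sub = reverse_complement(sub)
            parts.append(sub)
            blocks.append(BlockRow(s.src, s.start, s.end, name, off,
                                   off + len(s), s.strand, 1.0))
            off += len(s)
        records.append(SequenceRecord(name, "".join(parts)))
    return records, blocks


# ---------------------------------------------------------------------------
# operations


def simulate_true_target(config: SimConfig) -> list[SequenceRecord]:
    """Draw the true target karyotype: i.i.d. uniform ACGT chromosomes."""
    config.validate()
    ss = np.random.SeedSequence([config.seed, 0])
    rng = np.random.default_rng(ss)
    records = []
    for i in range(config.n_chromosomes):
        idx = rng.integers(0, 4, size=config.chrom_length)
        seq = _BASES[idx].tobytes().decode("ascii")
        records.append(SequenceRecord(f"chr{i + 1}", seq))
    return records


@dataclass
class RefDerivation:
    reference: list[SequenceRecord]
    target_ref_blocks: list[BlockRow]
    outgroup: list[SequenceRecord]
    ref_outgroup_blocks: list[BlockRow]
    ref_events: list[tuple]
    outgroup_events: list[tuple]


def derive_reference(
    genome: list[SequenceRecord],
    n_rearrangements: int,
    seed: int,
    min_event_size: int = 150_000,
) -> RefDerivation:
    """Derive reference and outgroup genomes by sampled rearrangements.

    The reference differs from the target by exactly the sampled events; the
    outgroup is derived from the reference by an independent sample of the
    same size.  The returned block tables are the true homology segments
    (target vs reference, and reference vs outgroup).
    """
    if not genome:
        raise ValueError("genome must be nonempty")
    rng_ref = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    rng_out = np.random.default_rng(np.random.SeedSequence([seed, 2]))

    identity = [[_Seg(r.id, 0, len(r), "+")] for r in genome]
    ref_chroms, ref_events = _apply_rearrangements(
        identity, n_rearrangements, rng_ref, min_event_size)
    tgt_seqs = {r.id: r.sequence for r in genome}
    reference, tgt_ref_blocks = _segments_to_records_and_blocks(
        ref_chroms, tgt_seqs, "ref")

    identity_ref = [[_Seg(r.id, 0, len(r), "+")] for r in reference]
    out_chroms, out_events = _apply_rearrangements(
        identity_ref, n_rearrangements, rng_out, min_event_size)
    ref_seqs = {r.id: r.sequence for r in reference}
    outgroup, ref_out_blocks = _segments_to_records_and_blocks(
        out_chroms, ref_seqs, "out")

    return RefDerivation(reference, tgt_ref_blocks, outgroup, ref_out_blocks,
                         ref_events, out_events)


def fragment_scaffolds(
    genome: list[SequenceRecord],
    n_scaffolds: int,
    chimera_rate: float,
    seed: int,
    *,
    min_segment_length: int = 200_000,
    inter_scaffold_gap: int = 1_000,
    scaffold_flip_prob: float = 0.5,
) -> tuple[list[SequenceRecord], list[TruthPart]]:
    """Fragment the true genome into scaffolds, injecting chimeras.

    Scaffolds partition the genome minus fixed ``inter_scaffold_gap`` bases
    omitted between consecutive segments.  A fraction ``chimera_rate`` of
    scaffolds concatenates two segments from non-adjacent loci (different
    chromosomes, or >= 1 Mb apart), recorded in the truth table.  Each
    scaffold part is independently reverse-complemented with probability
    ``scaffold_flip_prob``, emulating arbitrary scaffold orientation.
    """
    if n_scaffolds < len(genome):
        raise ValueError("need at least one scaffold per chromosome")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    n_chim = int(round(chimera_rate * n_scaffolds))
    n_segments = n_scaffolds + n_chim

    # allocate segment counts per chromosome, proportional to length
    lens = np.array([len(r) for r in genome], dtype=float)
    raw = lens / lens.sum() * n_segments
    counts = np.maximum(1, np.floor(raw).astype(int))
    while counts.sum() < n_segments:
        counts[int(np.argmax(raw - counts))] += 1
    while counts.sum() > n_segments:
        i = int(np.argmax(counts - raw))
        if counts[i] > 1:
            counts[i] -= 1
        else:
            break

    def capacity(L: int) -> int:
        return (L + inter_scaffold_gap) // (min_segment_length + inter_scaffold_gap)

    caps = np.array([capacity(len(r)) for r in genome])
    # repair infeasible allocations deterministically
    for i in range(len(genome)):
        while counts[i] > caps[i]:
            j = int(np.argmax(caps - counts))
            if caps[j] - counts[j] <= 0:
                raise ValueError("too many scaffolds for genome size")
            counts[i] -= 1
            counts[j] += 1

    segments: list[tuple[str, int, int]] = []
    for rec, k in zip(genome, counts):
        L = len(rec)
        slack = L - k * min_segment_length - (k - 1) * inter_scaffold_gap
        cuts = np.sort(rng.integers(0, slack + 1, size=k - 1)) if k > 1 else np.array([], dtype=int)
        extras = np.diff(np.concatenate([[0], cuts, [slack]]))
        pos = 0
        for e in extras:
            seg_len = min_segment_length + int(e)
            segments.append((rec.id, pos, pos + seg_len))
            pos += seg_len + inter_scaffold_gap

    # pair up segments for chimeric scaffolds
    chrom_index = {r.id: i for i, r in enumerate(genome)}

    def non_adjacent(a, b) -> bool:
        if a[0] != b[0]:
            return True
        gap = max(a[1], b[1]) - min(a[2], b[2])
        return gap >= 1_000_000

    order = list(rng.permutation(len(segments)))
    used: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for i in order:
        if len(pairs) >= n_chim:
            break
        if i in used:
            continue
        for j in order:
            if j == i or j in used:
                continue
            if non_adjacent(segments[i], segments[j]):
                pairs.append((i, j))
                used.update((i, j))
                break

    scaffold_parts: list[list[tuple[str, int, int]]] = []
    for i, j in pairs:
        scaffold_parts.append([segments[i], segments[j]])
    for i in range(len(segments)):
        if i not in used:
            scaffold_parts.append([segments[i]])

    perm = rng.permutation(len(scaffold_parts))
    seqs = {r.id: r.sequence for r in genome}
    scaffolds: list[SequenceRecord] = []
    truth: list[TruthPart] = []
    for rank, pi in enumerate(perm):
        parts = scaffold_parts[int(pi)]
        sid = f"scaf{rank + 1:04d}"
        chunks = []
        for k, (chrom, s, e) in enumerate(parts):
            orient = "-" if rng.random() < scaffold_flip_prob else "+"
            sub = seqs[chrom][s:e]
            if orient == "-":
                sub = reverse_complement(sub)
            chunks.append(sub)
            truth.append(TruthPart(sid, k, chrom, s, e, orient,
                                   is_chimera=len(parts) > 1))
        scaffolds.append(SequenceRecord(sid, "".join(chunks)))
    return scaffolds, truth


def scaffold_blocks(
    truth: list[TruthPart], target_ref_blocks: list[BlockRow]
) -> list[BlockRow]:
    """Re-express genome-level target-vs-reference blocks in scaffold coords.

    Each scaffold part's provenance interval is intersected with the
    genome-level blocks and the overlap composed through the part's
    orientation, yielding the scaffold-vs-reference block table the SF
    builder consumes.
    """
    by_scaffold: dict[str, list[TruthPart]] = {}
    for t in truth:
        by_scaffold.setdefault(t.scaffold_id, []).append(t)
    by_chrom: dict[str, list[BlockRow]] = {}
    for b in target_ref_blocks:
        by_chrom.setdefault(b.query_id, []).append(b)

    out: list[BlockRow] = []
    for sid, parts in by_scaffold.items():
        parts = sorted(parts, key=lambda t: t.part_index)
        off = 0
        for part in parts:
            ps, pe = part.true_start, part.true_end
            for blk in by_chrom.get(part.true_chrom, ()):
                a = max(ps, blk.query_start)
                b = min(pe, blk.query_end)
                if b <= a:
                    continue
                if part.orientation == "+":
                    ss, se = off + (a - ps), off + (b - ps)
                else:
                    ss, se = off + (pe - b), off + (pe - a)
                if blk.strand == "+":
                    rs = blk.subject_start + (a - blk.query_start)
                    re_ = blk.subject_start + (b - blk.query_start)
                else:
                    rs = blk.subject_end - (b - blk.query_start)
                    re_ = blk.subject_end - (a - blk.query_start)
                strand = "+" if part.orientation == blk.strand else "-"
                out.append(BlockRow(sid, ss, se, blk.subject_id, rs, re_,
                                    strand, blk.identity))
            off += pe - ps
    out.sort(key=lambda b: (b.query_id, b.query_start))
    return out


def simulate_read_pairs(
    genome: list[SequenceRecord],
    truth: list[TruthPart],
    config: SimConfig,
) -> pd.DataFrame:
    """Simulate read pairs from the true genome, mapped to scaffold coords.

    Inserts are uniform in ``[insert_min, insert_max]``; a pair is retained
    iff its whole insert lies within a single scaffold part's provenance
    interval (a mapper would not place both mates properly otherwise), so
    chimeric joins receive zero spanning pairs by construction.
    """
    if config.pair_coverage <= 0:
        return pd.DataFrame(
            columns=["pair_id", "scaffold_id", "left_start", "right_end", "proper"]
        ).astype({"left_start": int, "right_end": int, "proper": bool})
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
    mean_insert = (config.insert_min + config.insert_max) / 2.0

    parts_by_chrom: dict[str, list[TruthPart]] = {}
    offsets: dict[tuple[str, int], int] = {}
    for sid in {t.scaffold_id for t in truth}:
        ps = sorted((t for t in truth if t.scaffold_id == sid),
                    key=lambda t: t.part_index)
        off = 0
        for t in ps:
            offsets[(sid, t.part_index)] = off
            off += t.true_end - t.true_start
    for t in truth:
        parts_by_chrom.setdefault(t.true_chrom, []).append(t)

    frames = []
    counter = 0
    for rec in genome:
        L = len(rec)
        n = int(round(config.pair_coverage * L / mean_insert))
        if n == 0:
            continue
        inserts = rng.integers(config.insert_min, config.insert_max + 1, size=n)
        lefts = (rng.random(n) * (L - inserts)).astype(np.int64)
        rights = lefts + inserts

        parts = sorted(parts_by_chrom.get(rec.id, ()), key=lambda t: t.true_start)
        if not parts:
            continue
        starts = np.array([p.true_start for p in parts])
        ends = np.array([p.true_end for p in parts])
        idx = np.searchsorted(starts, lefts, side="right") - 1
        ok = (idx >= 0)
        idx_c = np.clip(idx, 0, len(parts) - 1)
        ok &= (lefts >= starts[idx_c]) & (rights <= ends[idx_c])
        if not ok.any():
            continue
        idx_v = idx_c[ok]
        l_v, r_v = lefts[ok], rights[ok]
        s_left = np.empty(len(idx_v), dtype=np.int64)
        s_right = np.empty(len(idx_v), dtype=np.int64)
        sids = np.empty(len(idx_v), dtype=object)
        for k, part in enumerate(parts):
            m = idx_v == k
            if not m.any():
                continue
            off = offsets[(part.scaffold_id, part.part_index)]
            if part.orientation == "+":
                s_left[m] = off + (l_v[m] - part.true_start)
                s_right[m] = off + (r_v[m] - part.true_start)
            else:
                s_left[m] = off + (part.true_end - r_v[m])
                s_right[m] = off + (part.true_end - l_v[m])
            sids[m] = part.scaffold_id
        frames.append(pd.DataFrame({
            "pair_id": [f"p{counter + i:08d}" for i in range(len(idx_v))],
            "scaffold_id": sids,
            "left_start": s_left,
            "right_end": s_right,
            "proper": True,
        }))
        counter += len(idx_v)
    if not frames:
        return pd.DataFrame(
            columns=["pair_id", "scaffold_id", "left_start", "right_end", "proper"]
        ).astype({"left_start": int, "right_end": int, "proper": bool})
    return pd.concat(frames, ignore_index=True)


def expected_physical_coverage(config: SimConfig) -> float:
    """Closed-form expected spanning-pair count at an interior position."""
    return config.pair_coverage


def emit_gene_map(
    genome: list[SequenceRecord],
    truth: list[TruthPart],
    n_genes: int,
    seed: int,
    gene_min: int = 2_000,
    gene_max: int = 30_000,
) -> list[GeneMapRow]:
    """Place genes on the true genome and map them to scaffold intervals.

    A gene straddling an inter-scaffold boundary maps to two scaffolds and
    becomes raw material for a gene-based reliable adjacency downstream.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 5]))
    lens = np.array([len(r) for r in genome], dtype=float)
    probs = lens / lens.sum()
    rows: list[GeneMapRow] = []
    offsets: dict[tuple[str, int], int] = {}
    for sid in {t.scaffold_id for t in truth}:
        ps = sorted((t for t in truth if t.scaffold_id == sid),
                    key=lambda t: t.part_index)
        off = 0
        for t in ps:
            offsets[(sid, t.part_index)] = off
            off += t.true_end - t.true_start
    for g in range(n_genes):
        ci = int(rng.choice(len(genome), p=probs))
        glen = int(rng.integers(gene_min, gene_max + 1))
        L = len(genome[ci])
        gs = int(rng.integers(0, max(1, L - glen)))
        ge = gs + glen
        gid = f"gene{g + 1:05d}"
        for t in truth:
            if t.true_chrom != genome[ci].id:
                continue
            a, b = max(gs, t.true_start), min(ge, t.true_end)
            if b <= a:
                continue
            off = offsets[(t.scaffold_id, t.part_index)]
            if t.orientation == "+":
                s, e = off + (a - t.true_start), off + (b - t.true_start)
            else:
                s, e = off + (t.true_end - b), off + (t.true_end - a)
            rows.append(GeneMapRow(gid, t.scaffold_id, s, e))
    return rows


def emit_maps(
    genome: list[SequenceRecord],
    truth: list[TruthPart],
    target_ref_blocks: list[BlockRow],
    ref_outgroup_blocks: list[BlockRow],
    config: SimConfig,
) -> tuple[list[MarkerMapRow], list[MarkerAlnRow], list[ChromMapRow]]:
    """Emit the ordered marker map and the chromosome-outgroup homology map.

    Markers are gene CDSs placed at known, strictly increasing positions per
    chromosome; their alignments to scaffolds carry the CDS span fraction.
    The homology map lists (chromosome, outgroup chromosome) pairings of
    homology segments, omitting segments shorter than ``map_resolution``
    (segments below map resolution are invisible to the map, as with FISH).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 6]))
    cds = config.marker_cds_length
    marker_map: list[MarkerMapRow] = []
    marker_alns: list[MarkerAlnRow] = []
    offsets: dict[tuple[str, int], int] = {}
    for sid in {t.scaffold_id for t in truth}:
        ps = sorted((t for t in truth if t.scaffold_id == sid),
                    key=lambda t: t.part_index)
        off = 0
        for t in ps:
            offsets[(sid, t.part_index)] = off
            off += t.true_end - t.true_start
    for rec in genome:
        k = config.n_markers_per_chrom
        if k == 0:
            continue
        L = len(rec)
        positions = np.sort(rng.choice(
            np.arange(cds, max(cds + k, L - cds), dtype=np.int64),
            size=k, replace=False))
        for i, p in enumerate(positions):
            mid = f"mk_{rec.id}_{i + 1}"
            marker_map.append(MarkerMapRow(mid, rec.id, i + 1))
            gs, ge = int(p), int(p) + cds
            for t in truth:
                if t.true_chrom != rec.id:
                    continue
                a, b = max(gs, t.true_start), min(ge, t.true_end)
                if b <= a:
                    continue
                off = offsets[(t.scaffold_id, t.part_index)]
                if t.orientation == "+":
                    s, e = off + (a - t.true_start), off + (b - t.true_start)
                else:
                    s, e = off + (t.true_end - b), off + (t.true_end - a)
                marker_alns.append(MarkerAlnRow(mid, t.scaffold_id, s, e,
                                                (b - a) / cds, 1.0))

    chrom_map = _compose_chrom_map(target_ref_blocks, ref_outgroup_blocks,
                                   config.map_resolution)
    return marker_map, marker_alns, chrom_map


def _compose_chrom_map(
    target_ref_blocks: list[BlockRow],
    ref_outgroup_blocks: list[BlockRow],
    map_resolution: int,
) -> list[ChromMapRow]:
    out_by_ref: dict[str, list[BlockRow]] = {}
    for b in ref_outgroup_blocks:
        out_by_ref.setdefault(b.query_id, []).append(b)
    # target intervals annotated with outgroup chromosome
    spans: list[tuple[str, int, int, str]] = []
    for tb in target_ref_blocks:
        for ob in out_by_ref.get(tb.subject_id, ()):
            a = max(tb.subject_start, ob.query_start)
            b = min(tb.subject_end, ob.query_end)
            if b <= a:
                continue
            if tb.strand == "+":
                ts = tb.query_start + (a - tb.subject_start)
                te = tb.query_start + (b - tb.subject_start)
            else:
                ts = tb.query_end - (b - tb.subject_start)
                te = tb.query_end - (a - tb.subject_start)
            spans.append((tb.query_id, ts, te, ob.subject_id))
    spans.sort()
    rows: list[ChromMapRow] = []
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for chrom, ts, te, og in spans:
        by_chrom.setdefault(chrom, []).append((ts, te, og))
    for chrom in sorted(by_chrom):
        runs: list[list] = []
        for ts, te, og in by_chrom[chrom]:
            if runs and runs[-1][2] == og:
                runs[-1][1] = max(runs[-1][1], te)
            else:
                runs.append([ts, te, og])
        seen: set[str] = set()
        idx = 0
        for ts, te, og in runs:
            if te - ts < map_resolution or og in seen:
                continue
            idx += 1
            rows.append(ChromMapRow(chrom, og, idx))
            seen.add(og)
    return rows


# ---------------------------------------------------------------------------
# bundle


@dataclass
class SimResult:
    """Everything one simulated instance produces, plus its ground truth."""

    config: SimConfig
    genome: list[SequenceRecord]
    reference: list[SequenceRecord]
    outgroup: list[SequenceRecord]
    target_ref_blocks: list[BlockRow]
    ref_outgroup_blocks: list[BlockRow]
    scaffolds: list[SequenceRecord]
    scaffold_ref_blocks: list[BlockRow]
    truth: list[TruthPart]
    pairs: pd.DataFrame
    gene_map: list[GeneMapRow]
    marker_map: list[MarkerMapRow]
    marker_alns: list[MarkerAlnRow]
    chrom_map: list[ChromMapRow]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.scaffolds, outdir / "scaffolds.fa")
        write_fasta(self.genome, outdir / "true_genome.fa")
        write_blocks(self.scaffold_ref_blocks, outdir / "ref_blocks.tsv")
        write_blocks(self.ref_outgroup_blocks, outdir / "outgroup_blocks.tsv")
        write_pairs(self.pairs, outdir / "pairs.tsv")
        write_gene_map(self.gene_map, outdir / "gene_map.tsv")
        write_marker_map(self.marker_map, outdir / "marker_map.tsv")
        write_marker_alns(self.marker_alns, outdir / "markers.tsv")
        write_chrom_map(self.chrom_map, outdir / "chrom_map.tsv")
        write_truth(self.truth, outdir / "truth.tsv")


def simulate(config: SimConfig) -> SimResult:
    """Run the whole generator: genome, reference/outgroup, scaffolds,
    read pairs, gene map, marker map and homology map."""
    config.validate()
    genome = simulate_true_target(config)
    deriv = derive_reference(genome, config.n_rearrangements, config.seed,
                             config.min_event_size)
    scaffolds, truth = fragment_scaffolds(
        genome, config.n_scaffolds, config.chimera_rate, config.seed,
        min_segment_length=config.min_segment_length,
        inter_scaffold_gap=config.inter_scaffold_gap,
        scaffold_flip_prob=config.scaffold_flip_prob,
    )
    sblocks = scaffold_blocks(truth, deriv.target_ref_blocks)
    pairs = simulate_read_pairs(genome, truth, config)
    gene_map = emit_gene_map(genome, truth, config.n_genes, config.seed)
    marker_map, marker_alns, chrom_map = emit_maps(
        genome, truth, deriv.target_ref_blocks, deriv.ref_outgroup_blocks, config)
    return SimResult(config, genome, deriv.reference, deriv.outgroup,
                     deriv.target_ref_blocks, deriv.ref_outgroup_blocks,
                     scaffolds, sblocks, truth, pairs, gene_map,
                     marker_map, marker_alns, chrom_map)
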