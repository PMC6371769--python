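"""Syntenic fragment (SF) construction from alignment blocks.

An SF is a maximal colinear homology segment between a target scaffold and
the reference genome, above a resolution threshold (default 150 kb).  SFs
are the atomic units later ordered and oriented into predicted chromosome
fragments.  Input scaffolds pass the length filter (strictly longer than
10 kb) first; alignment blocks are merged into colinear chains before the
resolution cut is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Optional

from .io_formats import BlockRow, SequenceRecord, _write_tsv, _parse_tsv

logger = logging.getLogger(__name__)

DEFAULT_RESOLUTION = 150_000
DEFAULT_MIN_SCAFFOLD_LENGTH = 10_000
DEFAULT_MAX_GAP = 10_000


@dataclass(frozen=True)
class SynFragment:
    """A scaffold interval colinearly aligned to a reference interval.

    ``orientation`` is the strand of the scaffold relative to the
    reference.  Outgroup homology, when assigned, is carried in reference
    terms (the outgroup interval homologous to this SF's reference span).
    """

    sf_id: str
    scaffold_id: str
    scaffold_start: int
    scaffold_end: int
    ref_chrom: str
    ref_start: int
    ref_end: int
    orientation: str
    outgroup_chrom: Optional[str] = None
    outgroup_start: Optional[int] = None
    outgroup_end: Optional[int] = None
    outgroup_strand: Optional[str] = None

    @property
    def length(self) -> int:
        return self.scaffold_end - self.scaffold_start


def filter_scaffolds(
    records: list[SequenceRecord],
    min_length: int = DEFAULT_MIN_SCAFFOLD_LENGTH,
) -> list[SequenceRecord]:
    """Keep scaffolds strictly longer than ``min_length`` base pairs."""
    kept = [r for r in records if len(r) > min_length]
    logger.info("scaffold length filter: kept %d/%d scaffolds, %d bp total",
                len(kept), len(records), sum(len(r) for r in kept))
    return kept


def _letters(n: int) -> str:
    """0 -> a, 1 -> b, ..., 25 -> z, 26 -> aa (spreadsheet-style)."""
    out = ""
    n += 1
    while n > 0:
        n, rem = divmod(n - 1, 26)
        out = chr(ord("a") + rem) + out
    return out


def merge_colinear_blocks(
    blocks: list[BlockRow], max_gap: int = DEFAULT_MAX_GAP
) -> list[BlockRow]:
    """Merge adjacent blocks lying on a consistent alignment diagonal.

    Two blocks merge when they share (query, subject, strand), follow each
    other on the query, and the gaps on both query and subject sides are in
    ``[0, max_gap]`` (strand-aware on the subject side).  Identity of the
    merged block is the query-length-weighted mean.
    """
    by_key: dict[tuple, list[BlockRow]] = {}
    for b in blocks:
        by_key.setdefault((b.query_id, b.subject_id, b.strand), []).append(b)
    merged: list[BlockRow] = []
    for key in by_key:
        chain = sorted(by_key[key], key=lambda b: b.query_start)
        cur = chain[0]
        for nxt in chain[1:]:
            qgap = nxt.query_start - cur.query_end
            if cur.strand == "+":
                sgap = nxt.subject_start - cur.subject_end
            else:
                sgap = cur.subject_start - nxt.subject_end
            if 0 <= qgap <= max_gap and 0 <= sgap <= max_gap:
                w1, w2 = cur.query_span, nxt.query_span
                ident = (cur.identity * w1 + nxt.identity * w2) / (w1 + w2)
                cur = BlockRow(
                    cur.query_id, cur.query_start, nxt.query_end,
                    cur.subject_id,
                    min(cur.subject_start, nxt.subject_start),
                    max(cur.subject_end, nxt.subject_end),
                    cur.strand, ident)
            else:
                merged.append(cur)
                cur = nxt
        merged.append(cur)
    merged.sort(key=lambda b: (b.query_id, b.query_start))
    return merged


def build_sfs(
    blocks: list[BlockRow],
    resolution: int = DEFAULT_RESOLUTION,
) -> list[SynFragment]:
    """Cut merged blocks into syntenic fragments at the resolution threshold.

    Blocks whose target-side span is below ``resolution`` are dropped and
    counted; overlapping blocks on the same scaffold keep the longer one.
    SFs of a scaffold are lettered a, b, c ... in scaffold-coordinate order
    (suffix appended to the scaffold id).
    """
    by_scaffold: dict[str, list[BlockRow]] = {}
    n_dropped = 0
    for b in blocks:
        if b.query_span < resolution:
            n_dropped += 1
            continue
        by_scaffold.setdefault(b.query_id, []).append(b)
    logger.info("SF resolution filter: dropped %d blocks < %d bp",
                n_dropped, resolution)

    sfs: list[SynFragment] = []
    for sid in sorted(by_scaffold):
        chain = sorted(by_scaffold[sid], key=lambda b: (b.query_start, -b.query_span))
        kept: list[BlockRow] = []
        for b in chain:
            if kept and b.query_start < kept[-1].query_end:
                if b.query_span > kept[-1].query_span:
                    logger.warning("overlapping blocks on %s: keeping longer", sid)
                    kept[-1] = b
                else:
                    logger.warning("overlapping blocks on %s: keeping longer", sid)
                continue
            kept.append(b)
        for i, b in enumerate(kept):
            sfs.append(SynFragment(
                sf_id=f"{sid}{_letters(i)}",
                scaffold_id=sid,
                scaffold_start=b.query_start,
                scaffold_end=b.query_end,
                ref_chrom=b.subject_id,
                ref_start=b.subject_start,
                ref_end=b.subject_end,
                orientation=b.strand,
            ))
    return sfs


def assign_outgroup(
    sfs: list[SynFragment], ref_outgroup_blocks: list[BlockRow]
) -> list[SynFragment]:
    """Attach outgroup homology to each SF.

    The outgroup chromosome is taken from the reference-vs-outgroup block
    with the largest overlap of the SF's reference interval; the SF's
    outgroup interval and strand are composed through that block.  SFs with
    no overlapping block keep ``outgroup_chrom=None``.
    """
    by_ref: dict[str, list[BlockRow]] = {}
    for b in ref_outgroup_blocks:
        by_ref.setdefault(b.query_id, []).append(b)
    out: list[SynFragment] = []
    for sf in sfs:
        best = None
        best_ov = 0
        for b in by_ref.get(sf.ref_chrom, ()):
            ov = min(sf.ref_end, b.query_end) - max(sf.ref_start, b.query_start)
            if ov > best_ov:
                best, best_ov = b, ov
        if best is None:
            out.append(sf)
            continue
        a = max(sf.ref_start, best.query_start)
        b_ = min(sf.ref_end, best.query_end)
        if best.strand == "+":
            os_ = best.subject_start + (a - best.query_start)
            oe = best.subject_start + (b_ - best.query_start)
        else:
            os_ = best.subject_end - (b_ - best.query_start)
            oe = best.subject_end - (a - best.query_start)
        strand = "+" if best.strand == sf.orientation else "-"
        # outgroup strand is relative to the scaffold, like ``orientation``
        out.append(replace(sf, outgroup_chrom=best.subject_id,
                           outgroup_start=os_, outgroup_end=oe,
                           outgroup_strand=strand))
    return out


# ---------------------------------------------------------------------------
# serialization

SF_COLUMNS = [
    "sf_id", "scaffold_id", "scaffold_start", "scaffold_end",
    "ref_chrom", "ref_start", "ref_end", "orientation",
    "outgroup_chrom", "outgroup_start", "outgroup_end", "outgroup_strand",
]


def write_sfs(sfs: Iterable[SynFragment], path) -> None:
    def fmt(v):
        return "." if v is None else v

    _write_tsv(path, SF_COLUMNS,
               ((s.sf_id, s.scaffold_id, s.scaffold_start, s.scaffold_end,
                 s.ref_chrom, s.ref_start, s.ref_end, s.orientation,
                 fmt(s.outgroup_chrom), fmt(s.outgroup_start),
                 fmt(s.outgroup_end), fmt(s.outgroup_strand)) for s in sfs))


def read_sfs(path) -> list[SynFragment]:
    def opt_int(v):
        return None if v == "." else int(v)

    def opt_str(v):
        return None if v == "." else v

    conv = {"scaffold_start": int, "scaffold_end": int, "ref_start": int,
            "ref_end": int, "outgroup_start": opt_int, "outgroup_end": opt_int,
            "outgroup_chrom": opt_str, "outgroup_strand": opt_str}
    return [SynFragment(**row) for _, row in _parse_tsv(path, SF_COLUMNS, conv)]
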