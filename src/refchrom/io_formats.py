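"""Readers and writers for every external representation the pipeline touches.

Coordinate conventions
----------------------
All internal coordinates are 0-based, half-open ``[start, end)`` base-pair
intervals.  The single exception is AGP output, which per the AGP v2.1
specification is 1-based, inclusive.  Tabular formats are tab-delimited text
with a fixed header line; lines starting with ``#`` are comments.

Formats
=======
``blocks``       query_id query_start query_end subject_id subject_start subject_end strand identity
``pairs``        pair_id scaffold_id left_start right_end proper
``gene_map``     gene_id scaffold_id start end
``marker_map``   marker_id chromosome_id map_order
``marker_aln``   marker_id scaffold_id start end span_fraction identity
``chrom_map``    chromosome_id outgroup_chrom segment_index
``pcr_results``  junction_id round1 round2_a round2_b
``truth``        scaffold_id part_index true_chrom true_start true_end orientation is_chimera

Read pairs may alternatively be ingested from a SAM file (text SAM, mapped
proper pairs only); both routes normalise to the same table.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

VALID_BASES = frozenset("ACGTN")

PAIR_COLUMNS = ["pair_id", "scaffold_id", "left_start", "right_end", "proper"]


class FormatError(ValueError):
    """Raised for malformed input files; message names the offending record."""


# ---------------------------------------------------------------------------
# sequences


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence over the alphabet {A, C, G, T, N}."""

    id: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path: str | os.PathLike) -> list[SequenceRecord]:
    """Read a multi-record FASTA file into :class:`SequenceRecord` objects.

    Sequences are uppercased.  Duplicate ids, empty files and non-IUPAC
    characters (outside ``ACGTN``) are hard errors naming the record.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"empty sequence for record {rec.id!r} in {path}")
        bad = set(seq) - VALID_BASES
        if bad:
            raise FormatError(
                f"record {rec.id!r} contains non-IUPAC characters {sorted(bad)}"
            )
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, seq))
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | os.PathLike) -> None:
    bio = (
        _BioSeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    )
    SeqIO.write(bio, str(path), "fasta")


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# generic TSV machinery


def _parse_tsv(path, columns: Sequence[str], converters: dict):
    """Yield (line_number, dict) for each data row, validating the header."""
    with open(path) as fh:
        header = None
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields_ = line.split("\t")
            if header is None:
                header = fields_
                missing = [c for c in columns if c not in header]
                if missing:
                    raise FormatError(
                        f"{path}: missing column(s) {missing} in header"
                    )
                idx = {c: header.index(c) for c in columns}
                continue
            row = {}
            for c in columns:
                try:
                    row[c] = converters.get(c, str)(fields_[idx[c]])
                except (IndexError, ValueError) as exc:
                    raise FormatError(
                        f"{path}: line {lineno}: bad value for {c!r}: {exc}"
                    ) from None
            yield lineno, row
        if header is None:
            raise FormatError(f"{path}: empty file (no header)")


def _write_tsv(path, columns: Sequence[str], rows: Iterable[Sequence]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")


def _check_interval(path, lineno, start, end):
    if start < 0 or end <= start:
        raise FormatError(
            f"{path}: line {lineno}: invalid interval [{start}, {end})"
        )


# ---------------------------------------------------------------------------
# alignment blocks


@dataclass(frozen=True)
class BlockRow:
    """One pairwise alignment block (0-based half-open on both sides)."""

    query_id: str
    query_start: int
    query_end: int
    subject_id: str
    subject_start: int
    subject_end: int
    strand: str
    identity: float

    @property
    def query_span(self) -> int:
        return self.query_end - self.query_start


BLOCK_COLUMNS = [
    "query_id", "query_start", "query_end",
    "subject_id", "subject_start", "subject_end", "strand", "identity",
]


def read_blocks(path) -> list[BlockRow]:
    conv = {c: int for c in BLOCK_COLUMNS if "start" in c or "end" in c}
    conv["identity"] = float
    out = []
    for lineno, row in _parse_tsv(path, BLOCK_COLUMNS, conv):
        _check_interval(path, lineno, row["query_start"], row["query_end"])
        _check_interval(path, lineno, row["subject_start"], row["subject_end"])
        if row["strand"] not in ("+", "-"):
            raise FormatError(f"{path}: line {lineno}: bad strand {row['strand']!r}")
        if not 0.0 <= row["identity"] <= 1.0:
            raise FormatError(
                f"{path}: line {lineno}: identity {row['identity']} outside [0, 1]"
            )
        out.append(BlockRow(**row))
    return out


def write_blocks(blocks: Iterable[BlockRow], path) -> None:
    _write_tsv(
        path,
        BLOCK_COLUMNS,
        (
            (b.query_id, b.query_start, b.query_end, b.subject_id,
             b.subject_start, b.subject_end, b.strand, f"{b.identity:.4f}")
            for b in blocks
        ),
    )


# ---------------------------------------------------------------------------
# read pairs

def _parse_bool(s: str) -> bool:
    if s in ("1", "True", "true"):
        return True
    if s in ("0", "False", "false"):
        return False
    raise ValueError(f"not a boolean: {s!r}")


def read_pairs(path) -> pd.DataFrame:
    """Read a read-pair table (TSV, or SAM if the file looks like SAM).

    Returns a DataFrame with columns ``pair_id, scaffold_id, left_start,
    right_end, proper`` (coordinates 0-based half-open over the *insert*,
    i.e. the outer span of the pair).
    """
    path = str(path)
    with open(path) as fh:
        first = fh.readline()
    if path.endswith(".sam") or first.startswith("@"):
        return read_pairs_sam(path)
    rows = []
    conv = {"left_start": int, "right_end": int, "proper": _parse_bool}
    for lineno, row in _parse_tsv(path, PAIR_COLUMNS, conv):
        _check_interval(path, lineno, row["left_start"], row["right_end"])
        rows.append(row)
    df = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    return df.astype(
        {"pair_id": str, "scaffold_id": str, "left_start": int,
         "right_end": int, "proper": bool}
    )


def read_pairs_sam(path) -> pd.DataFrame:
    """Normalise mapped proper pairs from a (text) SAM file to the pair table.

    Only the leftmost mate of each properly paired, mapped pair is used; the
    insert is ``[pos, pos + tlen)``.
    """
    import pysam

    rows = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or not aln.is_proper_pair:
                continue
            if aln.template_length <= 0:  # keep the leftmost mate only
                continue
            rows.append(
                (aln.query_name, aln.reference_name,
                 aln.reference_start, aln.reference_start + aln.template_length,
                 True)
            )
    df = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    return df.astype(
        {"pair_id": str, "scaffold_id": str, "left_start": int,
         "right_end": int, "proper": bool}
    )


def write_pairs(pairs: pd.DataFrame, path) -> None:
    out = pairs.copy()
    out["proper"] = out["proper"].map(lambda b: "1" if b else "0")
    out.to_csv(path, sep="\t", index=False, columns=PAIR_COLUMNS)


# ---------------------------------------------------------------------------
# gene map, marker map, marker alignments, chromosome map, PCR results


@dataclass(frozen=True)
class GeneMapRow:
    gene_id: str
    scaffold_id: str
    start: int
    end: int


def read_gene_map(path) -> list[GeneMapRow]:
    out = []
    for lineno, row in _parse_tsv(
        path, ["gene_id", "scaffold_id", "start", "end"], {"start": int, "end": int}
    ):
        _check_interval(path, lineno, row["start"], row["end"])
        out.append(GeneMapRow(**row))
    return out


def write_gene_map(rows: Iterable[GeneMapRow], path) -> None:
    _write_tsv(path, ["gene_id", "scaffold_id", "start", "end"],
               ((r.gene_id, r.scaffold_id, r.start, r.end) for r in rows))


@dataclass(frozen=True)
class MarkerMapRow:
    marker_id: str
    chromosome_id: str
    map_order: int


def read_marker_map(path) -> list[MarkerMapRow]:
    return [
        MarkerMapRow(**row)
        for _, row in _parse_tsv(
            path, ["marker_id", "chromosome_id", "map_order"], {"map_order": int}
        )
    ]


def write_marker_map(rows: Iterable[MarkerMapRow], path) -> None:
    _write_tsv(path, ["marker_id", "chromosome_id", "map_order"],
               ((r.marker_id, r.chromosome_id, r.map_order) for r in rows))


@dataclass(frozen=True)
class MarkerAlnRow:
    """Best-hit alignment of a marker CDS to a scaffold interval."""

    marker_id: str
    scaffold_id: str
    start: int
    end: int
    span_fraction: float
    identity: float


def read_marker_alns(path) -> list[MarkerAlnRow]:
    cols = ["marker_id", "scaffold_id", "start", "end", "span_fraction", "identity"]
    out = []
    for lineno, row in _parse_tsv(
        path, cols, {"start": int, "end": int, "span_fraction": float, "identity": float}
    ):
        _check_interval(path, lineno, row["start"], row["end"])
        out.append(MarkerAlnRow(**row))
    return out


def write_marker_alns(rows: Iterable[MarkerAlnRow], path) -> None:
    cols = ["marker_id", "scaffold_id", "start", "end", "span_fraction", "identity"]
    _write_tsv(path, cols,
               ((r.marker_id, r.scaffold_id, r.start, r.end,
                 f"{r.span_fraction:.4f}", f"{r.identity:.4f}") for r in rows))


@dataclass(frozen=True)
class ChromMapRow:
    """One (chromosome, outgroup chromosome) homology pairing from the map."""

    chromosome_id: str
    outgroup_chrom: str
    segment_index: int


def read_chrom_map(path) -> list[ChromMapRow]:
    rows = [
        ChromMapRow(**row)
        for _, row in _parse_tsv(
            path, ["chromosome_id", "outgroup_chrom", "segment_index"],
            {"segment_index": int},
        )
    ]
    seen = set()
    for r in rows:
        key = (r.chromosome_id, r.outgroup_chrom)
        if key in seen:
            raise FormatError(f"duplicate chrom_map pairing {key}")
        seen.add(key)
    return rows


def write_chrom_map(rows: Iterable[ChromMapRow], path) -> None:
    _write_tsv(path, ["chromosome_id", "outgroup_chrom", "segment_index"],
               ((r.chromosome_id, r.outgroup_chrom, r.segment_index) for r in rows))


PCR_OUTCOMES = ("amplified", "none", "unexpected_size", "untested")


@dataclass(frozen=True)
class PcrRow:
    """Two-round PCR outcomes for one candidate junction.

    ``round2_a``/``round2_b`` are the outcomes for up to two alternative
    adjacencies (one per flanking syntenic fragment); ``untested`` marks an
    alternative that was not assayed.
    """

    junction_id: str
    round1: str
    round2_a: str = "untested"
    round2_b: str = "untested"


def read_pcr_results(path) -> list[PcrRow]:
    out = []
    for lineno, row in _parse_tsv(
        path, ["junction_id", "round1", "round2_a", "round2_b"], {}
    ):
        for k in ("round1", "round2_a", "round2_b"):
            if row[k] not in PCR_OUTCOMES:
                raise FormatError(
                    f"{path}: line {lineno}: bad PCR outcome {row[k]!r} for {k}"
                )
        out.append(PcrRow(**row))
    return out


def write_pcr_results(rows: Iterable[PcrRow], path) -> None:
    _write_tsv(path, ["junction_id", "round1", "round2_a", "round2_b"],
               ((r.junction_id, r.round1, r.round2_a, r.round2_b) for r in rows))


# ---------------------------------------------------------------------------
# AGP v2.1


@dataclass(frozen=True)
class AgpRow:
    """One AGP v2.1 line; coordinates 1-based inclusive."""

    object_id: str
    object_start: int
    object_end: int
    part_number: int
    component_type: str  # W (component) or N (gap)
    # W rows:
    component_id: str = ""
    component_start: int = 0
    component_end: int = 0
    orientation: str = "+"
    # N rows:
    gap_length: int = 0


def write_agp(
    objects: Sequence[tuple[str, Sequence[tuple[str, int, str]]]],
    gap_length: int = 100,
) -> str:
    """Serialise objects built from components into AGP v2.1 text.

    ``objects`` is a sequence of ``(object_id, components)`` where each
    component is ``(component_id, length_bp, orientation)`` with orientation
    in ``{+, -, ?}``.  A fixed gap of ``gap_length`` N bases is placed between
    consecutive components.
    """
    lines = ["##agp-version\t2.1"]
    for object_id, comps in objects:
        pos = 0  # 0-based running offset; emitted 1-based
        part = 0
        for i, (comp_id, length, orientation) in enumerate(comps):
            if length <= 0:
                raise FormatError(f"component {comp_id!r} has non-positive length")
            if orientation not in ("+", "-", "?"):
                raise FormatError(f"bad orientation {orientation!r} for {comp_id!r}")
            if i > 0 and gap_length > 0:
                part += 1
                lines.append("\t".join(map(str, (
                    object_id, pos + 1, pos + gap_length, part,
                    "N", gap_length, "scaffold", "yes", "align_genus"))))
                pos += gap_length
            part += 1
            lines.append("\t".join(map(str, (
                object_id, pos + 1, pos + length, part,
                "W", comp_id, 1, length, orientation))))
            pos += length
    return "\n".join(lines) + "\n"


def read_agp(text_or_path) -> list[AgpRow]:
    """Parse AGP v2.1 text (or a path to it); validates gap-free tiling."""
    if isinstance(text_or_path, str) and "\n" in text_or_path:
        fh = io.StringIO(text_or_path)
    else:
        fh = open(text_or_path)
    rows: list[AgpRow] = []
    try:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 9:
                raise FormatError(f"AGP line {lineno}: expected 9 columns, got {len(f)}")
            obj, ob, oe, part, ctype = f[0], int(f[1]), int(f[2]), int(f[3]), f[4]
            if ob > oe:
                raise FormatError(f"AGP line {lineno}: object_start > object_end")
            if ctype == "W":
                rows.append(AgpRow(obj, ob, oe, part, "W", f[5], int(f[6]),
                                   int(f[7]), f[8]))
            elif ctype in ("N", "U"):
                rows.append(AgpRow(obj, ob, oe, part, "N", gap_length=int(f[5])))
            else:
                raise FormatError(f"AGP line {lineno}: unknown component_type {ctype!r}")
    finally:
        fh.close()
    # parts must tile each object contiguously without overlap
    expected: dict[str, int] = {}
    for r in rows:
        want = expected.get(r.object_id, 1)
        if r.object_start != want:
            raise FormatError(
                f"AGP object {r.object_id!r}: part {r.part_number} starts at "
                f"{r.object_start}, expected {want} (overlap or gap in tiling)"
            )
        expected[r.object_id] = r.object_end + 1
    return rows


def agp_components(rows: Iterable[AgpRow]) -> list[tuple[str, list[tuple[str, int, str]]]]:
    """Invert :func:`write_agp`: recover (object_id, components) structure."""
    out: dict[str, list[tuple[str, int, str]]] = {}
    order: list[str] = []
    for r in rows:
        if r.object_id not in out:
            out[r.object_id] = []
            order.append(r.object_id)
        if r.component_type == "W":
            out[r.object_id].append(
                (r.component_id, r.component_end - r.component_start + 1, r.orientation)
            )
    return [(o, out[o]) for o in order]


# ---------------------------------------------------------------------------
# ground-truth table (simulator provenance)


@dataclass(frozen=True)
class TruthPart:
    """Provenance of one scaffold part on the true genome."""

    scaffold_id: str
    part_index: int
    true_chrom: str
    true_start: int
    true_end: int
    orientation: str
    is_chimera: bool


def read_truth(path) -> list[TruthPart]:
    cols = ["scaffold_id", "part_index", "true_chrom", "true_start",
            "true_end", "orientation", "is_chimera"]
    out = []
    for lineno, row in _parse_tsv(
        path, cols,
        {"part_index": int, "true_start": int, "true_end": int,
         "is_chimera": _parse_bool},
    ):
        _check_interval(path, lineno, row["true_start"], row["true_end"])
        out.append(TruthPart(**row))
    return out


def write_truth(rows: Iterable[TruthPart], path) -> None:
    cols = ["scaffold_id", "part_index", "true_chrom", "true_start",
            "true_end", "orientation", "is_chimera"]
    _write_tsv(path, cols,
               ((r.scaffold_id, r.part_index, r.true_chrom, r.true_start,
                 r.true_end, r.orientation, int(r.is_chimera)) for r in rows))
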