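"""Reference-assisted reconstruction of predicted chromosome fragments.

The builder detects comparative conflicts inside scaffolds (junctions whose
flanking SFs are non-adjacent on the reference *and* not independently
supported by the outgroup), splits putatively chimeric scaffolds whose
junction physical coverage falls below the MIN_INTRACOV_PERC threshold, and
chains the surviving SFs into ordered, oriented predicted chromosome
fragments (PCFs) with a per-junction adjacency score.

Joining rules, in priority order: reliable adjacencies (gene-span or
PCR-verified) > intact intra-scaffold junctions > adjacency in reference
coordinates within a tolerance.  The per-junction score is a deterministic
evidence combination: 1 for reliable junctions, otherwise the mean of
comparative support and (capped) relative physical coverage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .evidence import JunctionCoverage, ReliableAdjacency
from .io_formats import SequenceRecord, _parse_tsv, _write_tsv, reverse_complement
from .sf_builder import SynFragment

logger = logging.getLogger(__name__)

DEFAULT_ADJACENCY_TOLERANCE = 100_000
DEFAULT_GAP_LENGTH = 100

_END_FROM_NAME = {"head": "L", "tail": "R"}


# ---------------------------------------------------------------------------
# conflict detection and scaffold splitting


@dataclass(frozen=True)
class SplitCandidate:
    """An intra-scaffold junction in comparative conflict with reference
    and outgroup, i.e. a putatively chimeric join."""

    junction_id: str
    scaffold_id: str
    left_sf: str
    right_sf: str
    break_start: int  # scaffold coords: end of left SF
    break_end: int    # scaffold coords: start of right SF

    @property
    def break_interval(self) -> int:
        return self.break_end - self.break_start

    @property
    def pos(self) -> int:
        return (self.break_start + self.break_end) // 2


def _directions(sf1: SynFragment, o1: str, sf2: SynFragment, o2: str,
                channel: str) -> Optional[tuple]:
    """Reference (or outgroup) travel directions of two oriented SFs."""
    if channel == "ref":
        s1 = (sf1.ref_chrom, sf1.ref_start, sf1.ref_end, sf1.orientation)
        s2 = (sf2.ref_chrom, sf2.ref_start, sf2.ref_end, sf2.orientation)
    else:
        if sf1.outgroup_chrom is None or sf2.outgroup_chrom is None:
            return None
        s1 = (sf1.outgroup_chrom, sf1.outgroup_start, sf1.outgroup_end,
              sf1.outgroup_strand)
        s2 = (sf2.outgroup_chrom, sf2.outgroup_start, sf2.outgroup_end,
              sf2.outgroup_strand)
    d1 = "+" if o1 == s1[3] else "-"
    d2 = "+" if o2 == s2[3] else "-"
    return s1, s2, d1, d2


def colinear(sf1: SynFragment, o1: str, sf2: SynFragment, o2: str,
             tolerance: int, channel: str = "ref") -> Optional[bool]:
    """Is the oriented pair (sf1, o1) -> (sf2, o2) colinear on the channel?

    Returns None when the channel is unavailable (no outgroup homology).
    Colinear means: same chromosome, same travel direction, and the signed
    coordinate gap between consecutive intervals within ``tolerance``.
    """
    got = _directions(sf1, o1, sf2, o2, channel)
    if got is None:
        return None
    s1, s2, d1, d2 = got
    if s1[0] != s2[0] or d1 != d2:
        return False
    if d1 == "+":
        gap = s2[1] - s1[2]
    else:
        gap = s1[1] - s2[2]
    return -tolerance <= gap <= tolerance


def detect_conflicts(
    sfs: list[SynFragment],
    adjacency_tolerance: int = DEFAULT_ADJACENCY_TOLERANCE,
) -> list[SplitCandidate]:
    """Candidate split junctions between consecutive SFs of each scaffold.

    A junction is a candidate iff the flanking SFs are discordant on the
    reference (different chromosome, wrong order, wrong strand, or gap
    beyond tolerance) AND the outgroup does not independently support the
    scaffold's arrangement (discordant there too, or unknown).
    """
    by_scaffold: dict[str, list[SynFragment]] = {}
    for sf in sfs:
        by_scaffold.setdefault(sf.scaffold_id, []).append(sf)
    out: list[SplitCandidate] = []
    for sid in sorted(by_scaffold):
        chain = sorted(by_scaffold[sid], key=lambda s: s.scaffold_start)
        for a, b in zip(chain, chain[1:]):
            ref_ok = colinear(a, "+", b, "+", adjacency_tolerance, "ref")
            if ref_ok:
                continue
            out_ok = colinear(a, "+", b, "+", adjacency_tolerance, "outgroup")
            if out_ok:
                continue  # target arrangement independently supported
            out.append(SplitCandidate(
                f"{a.sf_id}|{b.sf_id}", sid, a.sf_id, b.sf_id,
                a.scaffold_end, b.scaffold_start))
    return out


@dataclass(frozen=True)
class SplitDecision:
    candidate: SplitCandidate
    coverage: Optional[JunctionCoverage]
    is_reliable: bool
    split: bool


def split_scaffolds(
    candidates: list[SplitCandidate],
    coverages: dict[str, JunctionCoverage],
    min_intracov_perc: float,
    reliable: Iterable[ReliableAdjacency] = (),
) -> list[SplitDecision]:
    """Decide which candidate junctions to break.

    A candidate is split iff its junction coverage percentage is below
    ``min_intracov_perc`` and the junction is not protected by a reliable
    adjacency.  Junctions without coverage information count as zero.
    """
    reliable_pairs = {r.sf_pair() for r in reliable}
    out: list[SplitDecision] = []
    for cand in candidates:
        cov = coverages.get(cand.junction_id)
        prot = frozenset([cand.left_sf, cand.right_sf]) in reliable_pairs
        pct = cov.coverage_pct if cov is not None else 0.0
        if pct != pct:  # NaN: no median base available
            pct = 0.0
        split = (not prot) and pct < min_intracov_perc
        out.append(SplitDecision(cand, cov, prot, split))
    return out


def intact_intra_junctions(
    sfs: list[SynFragment], split_junction_ids: Iterable[str] = ()
) -> list[tuple[str, str]]:
    """All consecutive intra-scaffold SF pairs that were not split."""
    split_set = set(split_junction_ids)
    by_scaffold: dict[str, list[SynFragment]] = {}
    for sf in sfs:
        by_scaffold.setdefault(sf.scaffold_id, []).append(sf)
    out = []
    for sid in sorted(by_scaffold):
        chain = sorted(by_scaffold[sid], key=lambda s: s.scaffold_start)
        for a, b in zip(chain, chain[1:]):
            if f"{a.sf_id}|{b.sf_id}" not in split_set:
                out.append((a.sf_id, b.sf_id))
    return out


# ---------------------------------------------------------------------------
# adjacencies, PCFs


@dataclass(frozen=True)
class Adjacency:
    """An ordered, oriented junction between two SF ends, with evidence."""

    left: tuple[str, str]   # (sf_id, end in {L, R})
    right: tuple[str, str]
    source: str             # reliable | intra_scaffold | reference_order
    comparative_support: float
    coverage: Optional[JunctionCoverage]
    score: float = field(default=0.0, compare=False)


def score_adjacency(adj: Adjacency) -> float:
    """Deterministic evidence combination in [0, 1]; reliable junctions
    score 1, otherwise the mean of comparative support and capped relative
    coverage (absent coverage counts as zero)."""
    if adj.source == "reliable":
        return 1.0
    pct = 0.0
    if adj.coverage is not None and adj.coverage.coverage_pct == adj.coverage.coverage_pct:
        pct = adj.coverage.coverage_pct
    return 0.5 * adj.comparative_support + 0.5 * min(1.0, pct / 100.0)


@dataclass
class PCF:
    """A predicted chromosome fragment: an ordered, oriented SF chain."""

    pcf_id: str
    members: list[tuple[SynFragment, str]]   # (SF, orientation on scaffold)
    junctions: list[Adjacency]
    gap_length: int = DEFAULT_GAP_LENGTH
    low_confidence: bool = False

    @property
    def length(self) -> int:
        n = len(self.members)
        return sum(sf.length for sf, _ in self.members) + self.gap_length * (n - 1)

    @property
    def sf_ids(self) -> list[str]:
        return [sf.sf_id for sf, _ in self.members]

    def sf_offsets(self) -> list[int]:
        """PCF coordinate of each member SF's start."""
        offs, pos = [], 0
        for sf, _ in self.members:
            offs.append(pos)
            pos += sf.length + self.gap_length
        return offs

    def ref_content(self) -> list[str]:
        out: list[str] = []
        for sf, _ in self.members:
            if not out or out[-1] != sf.ref_chrom:
                out.append(sf.ref_chrom)
        return out


_SOURCE_PRIORITY = {"reliable": 0, "intra_scaffold": 1, "reference_order": 2}


def _edge_support(sf1, e1, sf2, e2, tolerance):
    """Comparative support for the junction realised by this edge."""
    o1 = "+" if e1 == "R" else "-"   # sf1 exits through e1
    o2 = "+" if e2 == "L" else "-"   # sf2 is entered through e2
    channels = []
    ref = colinear(sf1, o1, sf2, o2, tolerance, "ref")
    channels.append(1.0 if ref else 0.0)
    og = colinear(sf1, o1, sf2, o2, tolerance, "outgroup")
    if og is not None:
        channels.append(1.0 if og else 0.0)
    return sum(channels) / len(channels)


def build_pcfs(
    sfs: list[SynFragment],
    intact_junctions: Iterable[tuple[str, str]] = (),
    reliable: Iterable[ReliableAdjacency] = (),
    *,
    adjacency_tolerance: int = DEFAULT_ADJACENCY_TOLERANCE,
    gap_length: int = DEFAULT_GAP_LENGTH,
    coverages: Optional[dict[str, JunctionCoverage]] = None,
) -> list[PCF]:
    """Chain SFs into PCFs.

    Consecutive SFs are joined iff (a) adjacent in reference coordinates
    within the tolerance, (b) joined by an intact intra-scaffold junction,
    or (c) joined by a reliable adjacency.  Each SF appears in exactly one
    PCF; output order and naming (``PCF_1`` ... by descending length) are
    deterministic.  A reliable adjacency contradicting an intact
    intra-scaffold junction is an error.
    """
    coverages = coverages or {}
    sf_by_id = {sf.sf_id: sf for sf in sfs}

    # candidate edges: ((sf_id, end), (sf_id, end), source)
    raw_edges: list[tuple[tuple[str, str], tuple[str, str], str]] = []

    for r in reliable:
        if r.sf_id_1 not in sf_by_id or r.sf_id_2 not in sf_by_id:
            continue
        raw_edges.append(((r.sf_id_1, _END_FROM_NAME[r.end_1]),
                          (r.sf_id_2, _END_FROM_NAME[r.end_2]), "reliable"))

    for a_id, b_id in intact_junctions:
        if a_id in sf_by_id and b_id in sf_by_id:
            raw_edges.append(((a_id, "R"), (b_id, "L"), "intra_scaffold"))

    ordered = sorted(sfs, key=lambda s: (s.ref_chrom, s.ref_start, s.sf_id))
    for a, b in zip(ordered, ordered[1:]):
        if a.ref_chrom != b.ref_chrom:
            continue
        gap = b.ref_start - a.ref_end
        if not -adjacency_tolerance <= gap <= adjacency_tolerance:
            continue
        # connect a's reference-right end to b's reference-left end
        e_a = "R" if a.orientation == "+" else "L"
        e_b = "L" if b.orientation == "+" else "R"
        raw_edges.append(((a.sf_id, e_a), (b.sf_id, e_b), "reference_order"))

    # deduplicate by end pair, keeping the highest-priority source
    dedup: dict[frozenset, tuple] = {}
    for p, q, src in raw_edges:
        key = frozenset([p, q])
        if key not in dedup or _SOURCE_PRIORITY[src] < _SOURCE_PRIORITY[dedup[key][2]]:
            dedup[key] = (p, q, src)

    edges = sorted(dedup.values(),
                   key=lambda e: (_SOURCE_PRIORITY[e[2]], e[0], e[1]))
    occupied: dict[tuple[str, str], tuple] = {}
    accepted: list[tuple] = []
    for p, q, src in edges:
        if p[0] == q[0]:
            logger.warning("self-adjacency on %s ignored", p[0])
            continue
        blockers = [occupied[e] for e in (p, q) if e in occupied]
        if blockers:
            for other in blockers:
                kinds = {src, other[2]}
                if kinds == {"reliable", "intra_scaffold"}:
                    raise ValueError(
                        "reliable adjacency contradicts intact intra-scaffold "
                        f"junction: {p}-{q} ({src}) vs {other[0]}-{other[1]} "
                        f"({other[2]})")
            logger.info("edge %s-%s (%s) skipped: end already joined", p, q, src)
            continue
        occupied[p] = (p, q, src)
        occupied[q] = (p, q, src)
        accepted.append((p, q, src))

    # annotate edges with support, coverage and score
    intra_cov: dict[frozenset, JunctionCoverage] = {}
    for jid, cov in coverages.items():
        left, _, right = jid.partition("|")
        intra_cov[frozenset([left, right])] = cov

    edge_info: dict[frozenset, Adjacency] = {}
    for p, q, src in accepted:
        sf1, sf2 = sf_by_id[p[0]], sf_by_id[q[0]]
        support = _edge_support(sf1, p[1], sf2, q[1], adjacency_tolerance)
        cov = intra_cov.get(frozenset([p[0], q[0]]))
        adj = Adjacency(p, q, src, support, cov)
        adj = Adjacency(p, q, src, support, cov, score_adjacency(adj))
        edge_info[frozenset([p, q])] = adj

    # traverse maximal paths (break cycles at the lowest-scoring edge)
    link: dict[tuple[str, str], tuple[str, str]] = {}
    for p, q, _ in accepted:
        link[p] = q
        link[q] = p

    visited: set[str] = set()
    chains: list[list[tuple[SynFragment, str]]] = []
    chain_adjs: list[list[Adjacency]] = []

    def walk(start_sf: str, entry_end: str):
        seq: list[tuple[SynFragment, str]] = []
        adjs: list[Adjacency] = []
        sf_id, entry = start_sf, entry_end
        while True:
            visited.add(sf_id)
            orient = "+" if entry == "L" else "-"
            seq.append((sf_by_id[sf_id], orient))
            exit_end = "R" if entry == "L" else "L"
            nxt = link.get((sf_id, exit_end))
            if nxt is None or nxt[0] in visited:
                break
            adjs.append(edge_info[frozenset([(sf_id, exit_end), nxt])])
            sf_id, entry = nxt
        return seq, adjs

    order_ids = sorted(sf_by_id)
    # path endpoints first
    for sf_id in order_ids:
        if sf_id in visited:
            continue
        free = [e for e in ("L", "R") if (sf_id, e) not in link]
        if len(free) == 2:
            visited.add(sf_id)
            chains.append([(sf_by_id[sf_id], "+")])
            chain_adjs.append([])
        elif len(free) == 1:
            entry = free[0]
            seq, adjs = walk(sf_id, entry)
            chains.append(seq)
            chain_adjs.append(adjs)
    # remaining SFs form cycles: break at lowest score
    for sf_id in order_ids:
        if sf_id in visited:
            continue
        cyc_ids = [sf_id]
        end = link[(sf_id, "R")]
        while end[0] != sf_id:
            cyc_ids.append(end[0])
            nxt_end = "R" if end[1] == "L" else "L"
            end = link[(end[0], nxt_end)]
        cyc_edges = []
        for cid in cyc_ids:
            for e in ("L", "R"):
                other = link[(cid, e)]
                key = frozenset([(cid, e), other])
                cyc_edges.append((edge_info[key].score, sorted(key), key))
        _, _, worst = min(cyc_edges, key=lambda t: (t[0], t[1]))
        (p1, p2) = tuple(worst)
        logger.warning("breaking cycle at %s-%s", p1, p2)
        del link[p1]
        del link[p2]
        seq, adjs = walk(p1[0], p1[1])
        chains.append(seq)
        chain_adjs.append(adjs)

    # canonical orientation: run along ascending reference coordinates
    pcfs: list[PCF] = []
    for seq, adjs in zip(chains, chain_adjs):
        if len(seq) > 1:
            def key_of(s):
                sf, o = s[0]
                d = "+" if o == sf.orientation else "-"
                return (sf.ref_chrom, sf.ref_start, sf.sf_id, d != "+")

            fwd = key_of(seq)
            rev_seq = [(sf, "+" if o == "-" else "-") for sf, o in reversed(seq)]
            rev = key_of(rev_seq)
            if rev < fwd:
                seq = rev_seq
                adjs = list(reversed(adjs))
        pcfs.append(PCF("", seq, adjs, gap_length=gap_length,
                        low_confidence=len(seq) == 1))

    pcfs.sort(key=lambda p: (-p.length, p.members[0][0].sf_id))
    for i, p in enumerate(pcfs):
        p.pcf_id = f"PCF_{i + 1}"
    return pcfs


# ---------------------------------------------------------------------------
# sequence output


def assembly_to_fasta(
    pcfs: list[PCF],
    scaffolds: list[SequenceRecord],
    gap_length: int = DEFAULT_GAP_LENGTH,
) -> list[SequenceRecord]:
    """Materialise PCFs as sequences: member SF subsequences concatenated
    in order (reverse-complemented for ``-`` members) with N gaps."""
    seqs = {r.id: r.sequence for r in scaffolds}
    out: list[SequenceRecord] = []
    for pcf in pcfs:
        parts = []
        for sf, orient in pcf.members:
            if sf.scaffold_id not in seqs:
                raise KeyError(f"scaffold {sf.scaffold_id!r} missing for SF {sf.sf_id}")
            sub = seqs[sf.scaffold_id][sf.scaffold_start:sf.scaffold_end]
            if orient == "-":
                sub = reverse_complement(sub)
            parts.append(sub)
        out.append(SequenceRecord(pcf.pcf_id, ("N" * gap_length).join(parts)))
    return out


# ---------------------------------------------------------------------------
# serialization

PCF_COLUMNS = ["pcf_id", "sf_index", "sf_id", "orientation",
               "next_source", "next_support", "next_spanning", "next_score"]


def write_pcfs(pcfs: list[PCF], path) -> None:
    rows = []
    for p in pcfs:
        for i, (sf, o) in enumerate(p.members):
            if i < len(p.junctions):
                j = p.junctions[i]
                spanning = j.coverage.spanning_pairs if j.coverage else "."
                rows.append((p.pcf_id, i, sf.sf_id, o, j.source,
                             f"{j.comparative_support:.4f}", spanning,
                             f"{j.score:.4f}"))
            else:
                rows.append((p.pcf_id, i, sf.sf_id, o, ".", ".", ".", "."))
    _write_tsv(path, PCF_COLUMNS, rows)


def read_pcfs(path, sfs: list[SynFragment],
              gap_length: int = DEFAULT_GAP_LENGTH) -> list[PCF]:
    sf_by_id = {sf.sf_id: sf for sf in sfs}
    conv = {"sf_index": int}
    grouped: dict[str, list[dict]] = {}
    order: list[str] = []
    for _, row in _parse_tsv(path, PCF_COLUMNS, conv):
        if row["pcf_id"] not in grouped:
            grouped[row["pcf_id"]] = []
            order.append(row["pcf_id"])
        grouped[row["pcf_id"]].append(row)
    pcfs = []
    for pid in order:
        rows = sorted(grouped[pid], key=lambda r: r["sf_index"])
        members = [(sf_by_id[r["sf_id"]], r["orientation"]) for r in rows]
        junctions = []
        for i, r in enumerate(rows[:-1]):
            cov = None
            if r["next_spanning"] != ".":
                cov = JunctionCoverage(members[i][0].scaffold_id, 0, 0,
                                       float(r["next_spanning"]), float("nan"))
            junctions.append(Adjacency(
                (r["sf_id"], "R"), (rows[i + 1]["sf_id"], "L"),
                r["next_source"], float(r["next_support"]), cov,
                float(r["next_score"])))
        pcfs.append(PCF(pid, members, junctions, gap_length=gap_length,
                        low_confidence=len(members) == 1))
    return pcfs
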