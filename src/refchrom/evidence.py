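"""Evidence channels for accepting or breaking SF adjacencies.

Two independent channels feed the reconstruction:

* **gene-based reliable adjacencies** — a gene whose alignments hit exactly
  two SFs on two different scaffolds pins those SF ends together (breaking
  the junction would break the gene, which is unlikely given mammalian gene
  conservation);
* **read-pair physical coverage** — the number of inserts (outer pair
  spans) strictly spanning a position.  A genuine junction inside a
  scaffold is spanned by pairs at roughly the genome-wide rate; a chimeric
  join is spanned by none.

Junction coverage is evaluated as the *minimum* spanning count over
``WINDOWSIZE`` (10) positions evenly spaced across a 1 kb window centred on
the junction; this windowed-minimum interpretation of the window parameter
is a documented convention of this package.  ``coverage_pct`` is the
spanning count as a percentage of the genome-wide median physical coverage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .io_formats import GeneMapRow, SequenceRecord
from .sf_builder import SynFragment

logger = logging.getLogger(__name__)

WINDOWSIZE = 10
DEFAULT_WINDOW = 1_000


@dataclass(frozen=True)
class ReliableAdjacency:
    """An SF-SF junction asserted true a priori.

    ``end_1``/``end_2`` are ``"head"`` (scaffold-start side) or ``"tail"``
    (scaffold-end side) of the respective SF.
    """

    sf_id_1: str
    end_1: str
    sf_id_2: str
    end_2: str
    supporting_gene_ids: tuple[str, ...]
    source: str  # gene_span | verified_junction

    def key(self) -> frozenset:
        return frozenset([(self.sf_id_1, self.end_1), (self.sf_id_2, self.end_2)])

    def sf_pair(self) -> frozenset:
        return frozenset([self.sf_id_1, self.sf_id_2])


@dataclass(frozen=True)
class JunctionCoverage:
    scaffold_id: str
    junction_pos: int
    window: int
    spanning_pairs: float
    coverage_pct: float


class _PairIndex:
    """Sorted per-scaffold insert endpoints for O(log n) spanning queries."""

    def __init__(self, pairs: pd.DataFrame):
        self._by_scaffold: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        if len(pairs):
            for sid, grp in pairs.groupby("scaffold_id", sort=False):
                self._by_scaffold[str(sid)] = (
                    np.sort(grp["left_start"].to_numpy()),
                    np.sort(grp["right_end"].to_numpy()),
                )

    def spanning(self, scaffold_id: str, pos) -> np.ndarray:
        """Pairs with left_start < pos and right_end > pos (strict)."""
        pos = np.atleast_1d(np.asarray(pos))
        if scaffold_id not in self._by_scaffold:
            return np.zeros(len(pos), dtype=np.int64)
        lefts, rights = self._by_scaffold[scaffold_id]
        n_left = np.searchsorted(lefts, pos, side="left")
        n_right_le = np.searchsorted(rights, pos, side="right")
        return n_left - n_right_le


def physical_coverage(
    pairs: pd.DataFrame,
    scaffold_id: str,
    pos: int,
    window: int = DEFAULT_WINDOW,
    *,
    scaffold_length: Optional[int] = None,
    median_coverage: Optional[float] = None,
    index: Optional[_PairIndex] = None,
) -> JunctionCoverage:
    """Spanning-pair coverage at a junction point.

    With ``window > 0``, the spanning count is the minimum over
    ``WINDOWSIZE`` positions evenly spaced across the window centred on
    ``pos`` (clipped to the scaffold); with ``window = 0`` it is evaluated
    at ``pos`` alone.  ``coverage_pct`` is relative to ``median_coverage``
    (the genome-wide median physical coverage); NaN when no median is given.
    """
    if pos < 0 or (scaffold_length is not None and pos > scaffold_length):
        raise ValueError(f"position {pos} outside scaffold {scaffold_id}")
    idx = index if index is not None else _PairIndex(pairs)
    if window > 0:
        offsets = np.linspace(-window / 2, window / 2, WINDOWSIZE)
        positions = np.round(pos + offsets).astype(np.int64)
        positions = np.clip(positions, 0,
                            scaffold_length if scaffold_length is not None
                            else positions.max())
        spanning = float(idx.spanning(scaffold_id, positions).min())
    else:
        spanning = float(idx.spanning(scaffold_id, pos)[0])
    if median_coverage and median_coverage > 0:
        pct = 100.0 * spanning / median_coverage
    else:
        pct = float("nan")
    return JunctionCoverage(scaffold_id, pos, window, spanning, pct)


@dataclass
class CoverageProfile:
    per_scaffold_median: dict[str, float]
    genome_median: float
    min_median: float
    max_median: float


def coverage_profile(
    pairs: pd.DataFrame,
    scaffolds: list[SequenceRecord],
    sample_step: int = 1_000,
) -> CoverageProfile:
    """Median physical coverage per scaffold and genome-wide.

    Coverage is sampled at interior positions every ``sample_step`` bases
    (insert-length margins excluded, so edge effects do not bias the
    median).  The genome-wide median pools all sampled positions.
    """
    if sample_step < 1:
        raise ValueError("sample_step must be >= 1")
    idx = _PairIndex(pairs)
    per: dict[str, float] = {}
    pooled: list[np.ndarray] = []
    for rec in scaffolds:
        L = len(rec)
        positions = np.arange(min(1000, L // 2), max(1, L - 1000), sample_step)
        if len(positions) == 0:
            positions = np.array([L // 2])
        counts = idx.spanning(rec.id, positions)
        per[rec.id] = float(np.median(counts))
        pooled.append(counts)
    all_counts = np.concatenate(pooled) if pooled else np.array([0.0])
    medians = list(per.values()) or [0.0]
    return CoverageProfile(per, float(np.median(all_counts)),
                           float(min(medians)), float(max(medians)))


def infer_reliable_adjacencies(
    gene_map: list[GeneMapRow], sfs: list[SynFragment]
) -> list[ReliableAdjacency]:
    """Gene-based reliable SF adjacencies.

    A gene whose alignment fragments hit exactly two SFs belonging to two
    different scaffolds yields one adjacency joining the gene-proximal ends
    of the two SFs.  Genes hitting three or more scaffolds (or SFs) are
    ignored and logged; duplicate adjacencies collapse with their
    supporting genes accumulated.  The result is independent of the row
    order of ``gene_map``.
    """
    by_scaffold: dict[str, list[SynFragment]] = {}
    for sf in sfs:
        by_scaffold.setdefault(sf.scaffold_id, []).append(sf)
    for sid in by_scaffold:
        by_scaffold[sid].sort(key=lambda s: s.scaffold_start)

    hits_by_gene: dict[str, dict[str, list[GeneMapRow]]] = {}
    for row in gene_map:
        hits_by_gene.setdefault(row.gene_id, {}).setdefault(row.scaffold_id, []).append(row)

    def find_sfs(scaffold_id: str, rows: list[GeneMapRow]) -> set[str]:
        found = set()
        for r in rows:
            for sf in by_scaffold.get(scaffold_id, ()):
                if min(r.end, sf.scaffold_end) > max(r.start, sf.scaffold_start):
                    found.add(sf.sf_id)
        return found

    sf_by_id = {sf.sf_id: sf for sf in sfs}
    collected: dict[frozenset, ReliableAdjacency] = {}
    for gene_id in sorted(hits_by_gene):
        per_scaffold = hits_by_gene[gene_id]
        hit_sfs: list[tuple[str, str]] = []  # (sf_id, scaffold_id)
        for sid in sorted(per_scaffold):
            for sf_id in sorted(find_sfs(sid, per_scaffold[sid])):
                hit_sfs.append((sf_id, sid))
        if len(hit_sfs) != 2 or hit_sfs[0][1] == hit_sfs[1][1]:
            if len(hit_sfs) > 2:
                logger.info("gene %s hits %d SFs; ignored", gene_id, len(hit_sfs))
            continue

        def proximal_end(sf_id: str, rows: list[GeneMapRow]) -> str:
            sf = sf_by_id[sf_id]
            mids = [(r.start + r.end) / 2 for r in rows
                    if min(r.end, sf.scaffold_end) > max(r.start, sf.scaffold_start)]
            mid = float(np.mean(mids))
            centre = (sf.scaffold_start + sf.scaffold_end) / 2
            return "tail" if mid >= centre else "head"

        (sf1, sid1), (sf2, sid2) = hit_sfs
        e1 = proximal_end(sf1, per_scaffold[sid1])
        e2 = proximal_end(sf2, per_scaffold[sid2])
        adj = ReliableAdjacency(sf1, e1, sf2, e2, (gene_id,), "gene_span")
        key = adj.key()
        if key in collected:
            prev = collected[key]
            genes = tuple(sorted(set(prev.supporting_gene_ids) | {gene_id}))
            collected[key] = ReliableAdjacency(
                prev.sf_id_1, prev.end_1, prev.sf_id_2, prev.end_2, genes,
                prev.source)
        else:
            collected[key] = adj
    return sorted(collected.values(), key=lambda a: (a.sf_id_1, a.sf_id_2))
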