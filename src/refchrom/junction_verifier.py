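"""Verification workflow around putatively chimeric scaffold junctions.

A split junction proposed by the comparative stage is assayed in two PCR
rounds: round 1 tests the original scaffold arrangement across the join;
if it fails, round 2 tests up to two alternative (reference-suggested)
adjacencies, one per flanking SF.  The decision rule:

* round 1 amplifies -> the joint is real, the scaffold **confirmed**
  non-chimeric (an unexpected-size product counts as a round-1 failure);
* round 1 fails and any tested alternative amplifies -> the scaffold is
  **chimeric**;
* round 1 fails and every tested alternative fails -> each tested
  alternative adjacency is left **ambiguous**.

From the classified tests a physical-coverage threshold is calibrated: the
minimal observed coverage above which every tested junction was confirmed.
Confirmed junctions *below* that threshold are promoted to reliable
adjacencies for the second reconstruction run (junctions at or above it
are protected by the threshold itself).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

from .evidence import JunctionCoverage, ReliableAdjacency
from .pcf_builder import SplitCandidate

logger = logging.getLogger(__name__)

DEFAULT_MAX_TEST_INTERVAL = 6_000

ROUND1_OUTCOMES = ("amplified", "none", "unexpected_size", "untested")
ROUND2_OUTCOMES = ("amplified", "none", "untested")


@dataclass(frozen=True)
class JunctionTest:
    """A candidate chimeric junction with its two-round assay outcomes."""

    junction_id: str
    scaffold_id: str
    left_sf: str
    right_sf: str
    break_interval: int
    coverage: Optional[JunctionCoverage] = None
    round1: str = "untested"
    round2: tuple[str, ...] = ()   # per tested alternative adjacency (<= 2)
    status: str = "untested"       # confirmed | chimeric | ambiguous | untested


def select_testable(
    junctions: Sequence[JunctionTest],
    max_interval: int = DEFAULT_MAX_TEST_INTERVAL,
) -> list[JunctionTest]:
    """Junctions amenable to PCR: break interval strictly below the cap
    (a primer pair must span the whole uncertainty region)."""
    return [j for j in junctions if j.break_interval < max_interval]


@dataclass
class VerificationCounts:
    """Summary of the two-round verification, one value per table row."""

    tested_regions: int = 0
    amplified_regions: int = 0       # round-1 successes: confirmed joints
    non_amplified_regions: int = 0
    tested_alternatives: int = 0
    amplified_alternatives: int = 0  # chimeric joints
    non_amplified_alternatives: int = 0
    ambiguous_adjacencies: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def classify(tests: Sequence[JunctionTest]) -> tuple[list[JunctionTest], VerificationCounts]:
    """Apply the two-round decision rule and tally the summary counts.

    Round-2 outcomes may only be present when round 1 did not amplify.
    Ambiguous adjacencies are the tested-but-unamplified alternatives of
    regions with no amplification in either round.
    """
    out: list[JunctionTest] = []
    c = VerificationCounts()
    for t in tests:
        tested_r2 = [r for r in t.round2 if r != "untested"]
        if t.round1 == "amplified":
            if tested_r2:
                raise ValueError(
                    f"{t.junction_id}: round-2 outcomes present although "
                    "round 1 amplified")
            status = "confirmed"
            c.tested_regions += 1
            c.amplified_regions += 1
        elif t.round1 in ("none", "unexpected_size"):
            c.tested_regions += 1
            c.non_amplified_regions += 1
            c.tested_alternatives += len(tested_r2)
            n_amp = sum(1 for r in tested_r2 if r == "amplified")
            n_fail = sum(1 for r in tested_r2 if r == "none")
            c.amplified_alternatives += n_amp
            c.non_amplified_alternatives += n_fail
            if n_amp > 0:
                status = "chimeric"
            elif n_fail > 0:
                status = "ambiguous"
                c.ambiguous_adjacencies += n_fail
            else:
                status = "untested"
        else:
            status = "untested"
        out.append(replace(t, status=status))
    return out, c


@dataclass(frozen=True)
class CoverageThreshold:
    spanning_pairs: float
    percent: float   # relative to genome-wide median physical coverage


def calibrate_threshold(
    tests: Sequence[JunctionTest],
    median_coverage: Optional[float] = None,
) -> CoverageThreshold:
    """Minimal observed confirmed coverage separating confirmed junctions.

    Returns the smallest observed coverage value ``T`` among confirmed
    tests such that every classified test with coverage >= ``T`` is
    confirmed.  Raises if the classes cannot be separated by any such cut.
    """
    classified = [t for t in tests
                  if t.status in ("confirmed", "chimeric", "ambiguous")
                  and t.coverage is not None]
    confirmed = [t.coverage.spanning_pairs for t in classified
                 if t.status == "confirmed"]
    others = [t.coverage.spanning_pairs for t in classified
              if t.status != "confirmed"]
    if not confirmed or not others:
        raise ValueError("calibration needs at least one confirmed and one "
                         "non-confirmed classified test with coverage")
    ceiling = max(others)
    candidates = sorted(c for c in confirmed if c > ceiling)
    if not candidates:
        raise ValueError("no separating threshold: some non-confirmed test "
                         "covers every confirmed coverage value")
    T = candidates[0]
    pct = 100.0 * T / median_coverage if median_coverage else float("nan")
    return CoverageThreshold(T, pct)


def promote_reliable(
    tests: Sequence[JunctionTest], threshold: float
) -> list[ReliableAdjacency]:
    """Confirmed junctions below the calibrated threshold become reliable
    adjacencies (source ``verified_junction``) for the second run; those at
    or above it need no promotion — the threshold already protects them."""
    out: list[ReliableAdjacency] = []
    for t in tests:
        if t.status != "confirmed" or t.coverage is None:
            continue
        if t.coverage.spanning_pairs < threshold:
            out.append(ReliableAdjacency(
                t.left_sf, "tail", t.right_sf, "head", (), "verified_junction"))
    return out


# ---------------------------------------------------------------------------
# assembling tests from split candidates + PCR tables


def tests_from_candidates(
    candidates: Sequence[SplitCandidate],
    coverages: dict[str, JunctionCoverage],
    pcr_rows: Iterable,
) -> list[JunctionTest]:
    """Join split candidates with their coverage and PCR outcomes."""
    pcr_by_id = {r.junction_id: r for r in pcr_rows}
    tests = []
    for cand in candidates:
        r = pcr_by_id.get(cand.junction_id)
        round1 = r.round1 if r else "untested"
        round2 = tuple(v for v in ((r.round2_a, r.round2_b) if r else ())
                       if v != "untested")
        tests.append(JunctionTest(
            cand.junction_id, cand.scaffold_id, cand.left_sf, cand.right_sf,
            cand.break_interval, coverages.get(cand.junction_id),
            round1, round2))
    return tests
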