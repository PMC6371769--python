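"""Assembly statistics and the end-to-end run report."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Optional, Sequence


def _round1(x: float) -> float:
    return float(Decimal(x).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def n50(lengths: Sequence[int]) -> int:
    """Largest L such that fragments of length >= L cover at least half of
    the total assembly length."""
    if not lengths:
        raise ValueError("n50 of an empty length list is undefined")
    if any(l <= 0 for l in lengths):
        raise ValueError("lengths must be positive")
    total = sum(lengths)
    acc = 0
    for l in sorted(lengths, reverse=True):
        acc += l
        if 2 * acc >= total:
            return l
    return min(lengths)  # unreachable


@dataclass(frozen=True)
class AssemblyStats:
    n_units: int
    total_length: int
    n50: int
    max_length: int
    min_length: int
    pct_of_original: float
    n_broken_scaffolds: int
    pct_broken_scaffolds: float

    def as_dict(self) -> dict:
        return asdict(self)


def assembly_stats(
    unit_lengths: Sequence[int],
    original_total: int,
    n_broken: int = 0,
    n_original_units: Optional[int] = None,
) -> AssemblyStats:
    """Summary statistics of an assembly stage (unit = scaffold or PCF)."""
    if not unit_lengths:
        raise ValueError("no assembly units")
    if original_total <= 0:
        raise ValueError("original_total must be positive")
    total = int(sum(unit_lengths))
    denom = n_original_units if n_original_units else len(unit_lengths)
    return AssemblyStats(
        n_units=len(unit_lengths),
        total_length=total,
        n50=n50(unit_lengths),
        max_length=int(max(unit_lengths)),
        min_length=int(min(unit_lengths)),
        pct_of_original=_round1(100.0 * total / original_total),
        n_broken_scaffolds=n_broken,
        pct_broken_scaffolds=_round1(100.0 * n_broken / denom) if denom else 0.0,
    )


def run_report(stages: dict) -> tuple[str, str]:
    """Serialise the per-stage report as (json_text, plain_text).

    ``stages`` maps stage names to JSON-serialisable payloads (parameters,
    counts, warnings).  The JSON carries exact values; the text rendering
    applies display rounding only.  Output is byte-reproducible for
    identical inputs.
    """
    json_text = json.dumps(stages, indent=2, sort_keys=True, default=str) + "\n"
    lines = []
    for stage in stages:
        lines.append(f"== {stage} ==")
        payload = stages[stage]
        if isinstance(payload, dict):
            for k in payload:
                v = payload[k]
                if isinstance(v, float):
                    v = f"{v:,.1f}"
                elif isinstance(v, int):
                    v = f"{v:,}"
                lines.append(f"  {k}: {v}")
        else:
            lines.append(f"  {payload}")
        lines.append("")
    return json_text, "\n".join(lines)
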