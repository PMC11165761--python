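"""Structural-variant records, consolidation and breakpoint windowing.

An SV is described by one or two breakends.  Deletions, duplications and
inversions are intra-chromosomal with ordered breakpoints; translocations
join two chromosomes; insertions may carry a single recorded position.
Nearby calls of the same type are consolidated (a simplified re-statement of
the SURVIVOR merge), and every breakend is expanded into a fixed-width
window — by default +-10 kb, i.e. the 20 kb region surrounding the
breakpoint that enters the super-enhancer overlap analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional, Sequence

from .intervals import ConfigError, GenomicInterval, chrom_key

logger = logging.getLogger(__name__)

SV_TYPES = ("DEL", "DUP", "INV", "TRA", "INS")

Breakpoint = tuple[str, int]  # (chrom, 0-based position)


@dataclass(frozen=True)
class SVCall:
    """A typed structural-variant call from one sample.

    Invariants: DEL/DUP/INV have both breakpoints on the same chromosome
    with ``bp1.pos < bp2.pos``; TRA joins two different chromosomes; INS may
    carry a single breakpoint (``bp2 is None``).
    """

    sv_id: str
    sample_id: str
    sv_type: str
    bp1: Breakpoint
    bp2: Optional[Breakpoint] = None
    quality: Optional[float] = None
    support: int = 1

    def __post_init__(self) -> None:
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"{self.sv_id}: unknown SV type {self.sv_type!r}")
        if self.sv_type in ("DEL", "DUP", "INV"):
            if self.bp2 is None:
                raise ValueError(f"{self.sv_id}: {self.sv_type} requires two breakpoints")
            if chrom_key(self.bp1[0]) != chrom_key(self.bp2[0]):
                raise ValueError(f"{self.sv_id}: {self.sv_type} breakpoints on different chroms")
            if not self.bp1[1] < self.bp2[1]:
                raise ValueError(f"{self.sv_id}: require bp1.pos < bp2.pos")
        elif self.sv_type == "TRA":
            if self.bp2 is None:
                raise ValueError(f"{self.sv_id}: TRA requires a mate breakpoint")
            if chrom_key(self.bp1[0]) == chrom_key(self.bp2[0]):
                raise ValueError(f"{self.sv_id}: TRA breakpoints must be inter-chromosomal")
        if self.bp1[1] < 0 or (self.bp2 is not None and self.bp2[1] < 0):
            raise ValueError(f"{self.sv_id}: negative breakpoint position")


@dataclass(frozen=True)
class BreakpointWindow:
    """The flanked interval around one breakend of one SV."""

    window: GenomicInterval
    source_sv: str
    breakpoint_pos: int
    sample_id: str = ""

    def __post_init__(self) -> None:
        if not self.window.contains_point(self.breakpoint_pos):
            raise ValueError(
                f"window {self.window} does not contain breakpoint {self.breakpoint_pos}"
            )


def _sort_key(call: SVCall):
    bp2 = call.bp2 if call.bp2 is not None else ("", -1)
    return (
        chrom_key(call.bp1[0]),
        call.bp1[1],
        chrom_key(bp2[0]),
        bp2[1],
        call.sv_type,
        call.sv_id,
    )


def _mergeable(a: SVCall, b: SVCall, max_dist: int, require_type_match: bool) -> bool:
    if require_type_match and a.sv_type != b.sv_type:
        return False
    if (a.bp2 is None) != (b.bp2 is None):
        return False
    if chrom_key(a.bp1[0]) != chrom_key(b.bp1[0]):
        return False
    if abs(a.bp1[1] - b.bp1[1]) > max_dist:
        return False
    if a.bp2 is not None:
        if chrom_key(a.bp2[0]) != chrom_key(b.bp2[0]):
            return False
        if abs(a.bp2[1] - b.bp2[1]) > max_dist:
            return False
    return True


def consolidate_calls(
    calls: Sequence[SVCall],
    max_dist: int = 1000,
    require_type_match: bool = True,
) -> list[SVCall]:
    """Merge near-duplicate SV calls (transitively) within one sample.

    Two calls merge when (optionally) the types match and the positionwise
    breakpoint distances are both <= ``max_dist`` on matching chromosomes.
    Components are found by union-find; each is represented by its member
    with the smallest ``(bp1.chrom, bp1.pos, bp2.pos)`` and carries the sum
    of member support counts.  The result is order-independent and
    idempotent.
    """
    n = len(calls)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj

    for i in range(n):
        for j in range(i + 1, n):
            if _mergeable(calls[i], calls[j], max_dist, require_type_match):
                union(i, j)

    components: dict[int, list[SVCall]] = {}
    for i in range(n):
        components.setdefault(find(i), []).append(calls[i])

    merged = []
    for members in components.values():
        rep = min(members, key=_sort_key)
        merged.append(replace(rep, support=sum(m.support for m in members)))
    merged.sort(key=_sort_key)
    return merged


def extract_breakpoints(call: SVCall) -> list[Breakpoint]:
    """Breakend enumeration: two per SV, one for an INS with a single POS."""
    if call.bp2 is None:
        return [call.bp1]
    return [call.bp1, call.bp2]


def make_windows(
    breakpoints: Sequence[Breakpoint],
    flank: int = 10_000,
    source_sv: str = "",
    sample_id: str = "",
) -> list[BreakpointWindow]:
    """Expand breakpoints into ``[max(0, pos - flank), pos + flank)`` windows.

    The default flank of 10 kb yields the 20 kb region surrounding each
    breakpoint; windows are clipped at the chromosome start.
    """
    if flank <= 0:
        raise ConfigError(f"flank must be positive, got {flank}")
    windows = []
    for chrom, pos in breakpoints:
        start = max(0, pos - flank)
        windows.append(
            BreakpointWindow(
                window=GenomicInterval(chrom, start, pos + flank),
                source_sv=source_sv,
                breakpoint_pos=pos,
                sample_id=sample_id,
            )
        )
    return windows


def windows_for_calls(
    calls: Sequence[SVCall],
    flank: int = 10_000,
    both_ends: bool = True,
) -> list[BreakpointWindow]:
    """Breakpoint windows for a list of calls (both breakends by default)."""
    out: list[BreakpointWindow] = []
    for call in calls:
        bps = extract_breakpoints(call)
        if not both_ends:
            bps = bps[:1]
        out.extend(make_windows(bps, flank, source_sv=call.sv_id, sample_id=call.sample_id))
    return out
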