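"""Rank-ordering super-enhancer calling.

The procedure follows the classic rank-ordering-of-super-enhancers recipe:
H3K27Ac peaks from one sample are stitched when their gap is at most the
stitch distance (default 12,500 bp, optionally after removing TSS-proximal
peaks), stitched regions are ranked by total signal, and the rank-signal
curve — rescaled to the unit square — is split at the point where a line of
slope 1 is tangent to the hockey-stick curve.  Regions with signal strictly
above the cutoff are super-enhancers; the rest are typical enhancers.

The tangent point is computed as the first index minimizing
``scaled_signal - scaled_rank``, which for a convex (hockey-stick) curve is
exactly where the finite-difference slope crosses 1 scanning from the
right, and which degrades gracefully on noisy or near-tied inputs (the
maximal-signal region is always called super when signals are not all
equal).  An all-equal-signal input yields zero super-enhancers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .intervals import ConfigError, GeneModel, GenomicInterval, chrom_key

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StitchedRegion:
    """A stitched enhancer region: span, constituent count, summed signal."""

    region: GenomicInterval
    constituent_count: int
    total_signal: float
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.constituent_count < 1:
            raise ValueError("constituent_count must be >= 1")
        if self.total_signal < 0:
            raise ValueError("total_signal must be >= 0")


@dataclass(frozen=True)
class SECall:
    """A ranked stitched region with its super/typical label."""

    stitched: StitchedRegion
    rank: int  # 1 = highest total signal
    is_super: bool
    cutoff_signal: float


def stitch_peaks(
    peaks: Sequence[tuple[GenomicInterval, float]],
    stitch_distance: int = 12_500,
    tss_exclusion: int = 0,
    gene_models: Optional[Sequence[GeneModel]] = None,
    sample_id: str = "",
) -> list[StitchedRegion]:
    """Merge peaks whose inter-peak gap is <= ``stitch_distance`` (transitively).

    With ``tss_exclusion > 0``, peaks fully contained within +-tss_exclusion
    of any TSS are removed before stitching (requires ``gene_models``).
    """
    if stitch_distance < 0:
        raise ConfigError("stitch_distance must be >= 0")
    if tss_exclusion > 0 and gene_models is None:
        raise ConfigError("tss_exclusion > 0 requires gene_models")

    kept = list(peaks)
    if tss_exclusion > 0:
        tss_by_chrom: dict[str, list[int]] = {}
        for g in gene_models:
            tss_by_chrom.setdefault(chrom_key(g.location.chrom), []).append(g.tss)
        for positions in tss_by_chrom.values():
            positions.sort()

        def excluded(iv: GenomicInterval) -> bool:
            positions = tss_by_chrom.get(chrom_key(iv.chrom), [])
            i = np.searchsorted(positions, iv.start - tss_exclusion)
            for tss in positions[i:]:
                if tss - tss_exclusion > iv.start:
                    break
                if iv.start >= tss - tss_exclusion and iv.end <= tss + tss_exclusion + 1:
                    return True
            return False

        kept = [p for p in kept if not excluded(p[0])]

    kept.sort(key=lambda p: (chrom_key(p[0].chrom), p[0].start, p[0].end))
    regions: list[StitchedRegion] = []
    cur: Optional[dict] = None
    for iv, signal in kept:
        key = chrom_key(iv.chrom)
        if cur is not None and key == cur["key"] and iv.start - cur["end"] <= stitch_distance:
            cur["end"] = max(cur["end"], iv.end)
            cur["count"] += 1
            cur["signal"] += signal
        else:
            if cur is not None:
                regions.append(_finish(cur, sample_id))
            cur = {"key": key, "chrom": iv.chrom, "start": iv.start, "end": iv.end,
                   "count": 1, "signal": signal}
    if cur is not None:
        regions.append(_finish(cur, sample_id))
    return regions


def _finish(cur: dict, sample_id: str) -> StitchedRegion:
    return StitchedRegion(
        region=GenomicInterval(cur["chrom"], cur["start"], cur["end"]),
        constituent_count=cur["count"],
        total_signal=cur["signal"],
        sample_id=sample_id,
    )


def rank_and_cut(regions: Sequence[StitchedRegion]) -> tuple[float, list[SECall]]:
    """Rank stitched regions by signal and split super from typical.

    Signals are sorted ascending; rank index and signal are each rescaled to
    [0, 1]; the cutoff is the signal at the unit-slope tangent point of the
    scaled curve (ties toward the lower signal).  Regions strictly above the
    cutoff are super.  Returns ``(cutoff_signal, calls)`` with calls ordered
    by rank (1 = highest signal); ranks are a permutation of 1..n.
    """
    n = len(regions)
    if n == 0:
        raise ValueError("rank_and_cut requires at least one region")
    order = sorted(
        range(n),
        key=lambda i: (
            regions[i].total_signal,
            chrom_key(regions[i].region.chrom),
            regions[i].region.start,
            regions[i].region.end,
        ),
    )
    signals = np.array([regions[i].total_signal for i in order], dtype=float)
    if signals[-1] == signals[0]:
        # degenerate flat curve: no inflection, zero super-enhancers
        cutoff = float(signals[-1])
    else:
        xs = np.arange(n) / (n - 1)
        ys = (signals - signals[0]) / (signals[-1] - signals[0])
        cutoff = float(signals[int(np.argmin(ys - xs))])

    calls = []
    for pos, idx in enumerate(order):
        calls.append(
            SECall(
                stitched=regions[idx],
                rank=n - pos,
                is_super=regions[idx].total_signal > cutoff,
                cutoff_signal=cutoff,
            )
        )
    calls.sort(key=lambda c: c.rank)
    return cutoff, calls


def call_super_enhancers(
    peaks: Sequence[tuple[GenomicInterval, float]],
    stitch_distance: int = 12_500,
    tss_exclusion: int = 0,
    gene_models: Optional[Sequence[GeneModel]] = None,
    sample_id: str = "",
) -> list[SECall]:
    """Stitch, rank and label one sample's peaks; empty input -> empty list."""
    regions = stitch_peaks(peaks, stitch_distance, tss_exclusion, gene_models, sample_id)
    if not regions:
        return []
    _, calls = rank_and_cut(regions)
    return calls
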