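"""Super-enhancer x breakpoint-window intersection and cohort summaries.

One record is emitted per intersecting (SE region, SV) pair — the 20 kb
window around each breakend stands in for the SV — with at most one record
per pair (the maximal overlap is kept when both breakends of an SV hit the
same region).  Per-sample counts are log2(count + 1)-transformed and
compared between cohorts with a two-sided equal-variance Student t-test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GeneModel, GenomicInterval, find_overlaps
from .se_caller import SECall
from .sv import BreakpointWindow, SVCall

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OverlapRecord:
    """An SE region intersecting the flanked window of an SV breakend."""

    sample_id: str
    se_region: GenomicInterval
    sv_id: str
    breakpoint_pos: int
    overlap_length: int

    def __post_init__(self) -> None:
        if self.overlap_length < 1:
            raise ValueError("overlap_length must be >= 1")


def overlap_se_sv(
    se_calls: Sequence[SECall],
    windows: Sequence[BreakpointWindow],
    include_typical: bool = False,
) -> list[OverlapRecord]:
    """Intersect one sample's (super) SE regions with its breakpoint windows.

    Only ``is_super`` regions participate unless ``include_typical`` is set.
    Records are deduplicated so one SV contributes at most one record per SE
    region (maximal overlap kept), and sorted deterministically.
    """
    calls = [c for c in se_calls if c.is_super or include_typical]
    regions = [c.stitched.region for c in calls]
    win_ivs = [w.window for w in windows]
    best: dict[tuple[GenomicInterval, str], OverlapRecord] = {}
    for i, j, olen in find_overlaps(regions, win_ivs):
        w = windows[j]
        key = (regions[i], w.source_sv)
        prev = best.get(key)
        if prev is None or olen > prev.overlap_length or (
            olen == prev.overlap_length and w.breakpoint_pos < prev.breakpoint_pos
        ):
            best[key] = OverlapRecord(
                sample_id=calls[i].stitched.sample_id or w.sample_id,
                se_region=regions[i],
                sv_id=w.source_sv,
                breakpoint_pos=w.breakpoint_pos,
                overlap_length=olen,
            )
    records = list(best.values())
    records.sort(key=lambda r: (r.se_region.chrom, r.se_region.start, r.se_region.end, r.sv_id))
    return records


def per_sample_frequency(
    records: Sequence[OverlapRecord],
    sv_calls: Mapping[str, Sequence[SVCall]],
    samples,
) -> pd.DataFrame:
    """Per-sample SV-event and SE-SV-overlap counts with log2(count+1).

    ``samples`` is a sequence of :class:`~sesvlink.intervals.Sample`; a
    sample with no SV data is counted as 0 with a logged note.
    """
    n_overlap: dict[str, int] = {}
    for rec in records:
        n_overlap[rec.sample_id] = n_overlap.get(rec.sample_id, 0) + 1
    rows = []
    for s in samples:
        if s.sample_id not in sv_calls:
            logger.info("sample %s has no SV data; counted as 0", s.sample_id)
        nsv = len(sv_calls.get(s.sample_id, ()))
        nov = n_overlap.get(s.sample_id, 0)
        rows.append(
            (s.sample_id, s.cohort, nsv, nov, float(np.log2(nsv + 1)), float(np.log2(nov + 1)))
        )
    return pd.DataFrame(
        rows, columns=["sample_id", "cohort", "n_sv", "n_overlap", "log2_sv", "log2_overlap"]
    )


def compare_cohort_frequencies(summary: pd.DataFrame) -> dict[str, tuple[float, float]]:
    """Two-sided equal-variance t-test per metric between the two cohorts.

    Returns ``{"sv": (t, p), "overlap": (t, p)}`` comparing the first cohort
    label (sorted) against the second; each cohort needs >= 2 samples.
    """
    cohorts = sorted(summary["cohort"].unique())
    if len(cohorts) != 2:
        raise ValueError(f"expected exactly 2 cohorts, got {cohorts}")
    a = summary[summary["cohort"] == cohorts[0]]
    b = summary[summary["cohort"] == cohorts[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each cohort needs >= 2 samples for the t-test")
    out = {}
    for metric, col in (("sv", "log2_sv"), ("overlap", "log2_overlap")):
        t, p = stats.ttest_ind(a[col], b[col], equal_var=True)
        out[metric] = (float(t), float(p))
    return out


def annotate_overlap_genes(
    records: Sequence[OverlapRecord],
    gene_models: Sequence[GeneModel],
    flank: int = 50_000,
) -> dict[GenomicInterval, list[str]]:
    """Genes whose TSS falls within each overlapped SE region +- ``flank``.

    Assignment uses the half-open extended span ``[start - flank,
    end + flank)``; the returned gene lists are sorted by gene id.
    """
    regions = sorted({r.se_region for r in records})
    extended = [
        GenomicInterval(r.chrom, max(0, r.start - flank), r.end + flank) for r in regions
    ]
    tss_points = [
        GenomicInterval(g.location.chrom, g.tss, g.tss + 1) for g in gene_models
    ]
    result: dict[GenomicInterval, list[str]] = {r: [] for r in regions}
    for i, j, _ in find_overlaps(extended, tss_points):
        result[regions[i]].append(gene_models[j].gene_id)
    for genes in result.values():
        genes.sort()
    return result


def genes_near_regions(
    regions: Sequence[GenomicInterval],
    gene_models: Sequence[GeneModel],
    flank: int = 50_000,
) -> set[str]:
    """Gene ids whose TSS lies within ``flank`` bp of any of the regions."""
    extended = [
        GenomicInterval(r.chrom, max(0, r.start - flank), r.end + flank) for r in regions
    ]
    tss_points = [GenomicInterval(g.location.chrom, g.tss, g.tss + 1) for g in gene_models]
    return {gene_models[j].gene_id for _, j, _ in find_overlaps(extended, tss_points)}
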