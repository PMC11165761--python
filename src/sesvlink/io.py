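"""Readers and writers for the external formats the pipeline touches.

Supported inputs: BED3+score / ENCODE narrowPeak peak files, SV-VCF
(SVTYPE/END or CHR2/POS2 INFO keys, read through pysam), a 10+1 column
BEDPE dialect, and TSV tables for expression matrices, gene models and
clinical data.  Outputs are BED/TSV/VCF text, written deterministically.

Coordinate conventions: BED/BEDPE verbatim (already 0-based half-open);
VCF POS/POS2 are decremented on read and incremented on write, while the
INFO END value is used unchanged as the 0-based second breakend.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import pandas as pd
import pysam

from .intervals import GeneModel, GenomicInterval, ParseError, Sample, chrom_key
from .sv import SV_TYPES, BreakpointWindow, SVCall

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# peaks

def read_peaks(
    path: str,
    sample_id: str = "",
    signal_col: Optional[int] = None,
) -> list[tuple[GenomicInterval, float]]:
    """Read a BED3+score or narrowPeak file into (interval, signal) pairs.

    The signal column defaults to narrowPeak's ``signalValue`` (index 6)
    when the file has >= 7 columns, otherwise the BED score (index 4, or 3
    for a bare 4-column file); pass ``signal_col`` to override.  Rows are
    returned sorted by (chrom, start, end).  Malformed rows raise
    :class:`ParseError` naming the line number.
    """
    peaks: list[tuple[GenomicInterval, float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: expected >= 3 tab-separated columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ParseError(f"{path}: line {lineno}: start >= end ({start} >= {end})")
            col = signal_col
            if col is None:
                col = 6 if len(fields) >= 7 else (4 if len(fields) >= 5 else 3)
            if col >= len(fields):
                raise ParseError(f"{path}: line {lineno}: no signal column {col}")
            try:
                signal = float(fields[col])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-numeric signal") from exc
            if signal < 0:
                raise ParseError(f"{path}: line {lineno}: negative signal {signal}")
            peaks.append((GenomicInterval(fields[0], start, end), signal))
    peaks.sort(key=lambda p: (chrom_key(p[0].chrom), p[0].start, p[0].end))
    return peaks


def write_narrowpeak(
    peaks: Sequence[tuple[GenomicInterval, float]], path: str, name_prefix: str = "peak"
) -> None:
    """Write peaks as 10-column ENCODE narrowPeak (signal in column 7)."""
    with open(path, "w") as fh:
        for i, (iv, sig) in enumerate(peaks, 1):
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name_prefix}{i}\t0\t.\t{sig!r}\t-1\t-1\t-1\n"
            )


# ---------------------------------------------------------------------------
# SV calls

def read_sv_calls(path: str, sample_id: str, dialect: str = "sv-vcf") -> list[SVCall]:
    """Read SV calls from an SV-VCF or BEDPE file.

    Unknown SVTYPE values are skipped with a logged warning; a TRA record
    without mate coordinates is a rejected-record error.
    """
    if dialect == "sv-vcf":
        return _read_sv_vcf(path, sample_id)
    if dialect == "bedpe":
        return _read_bedpe(path, sample_id)
    raise ValueError(f"unknown SV dialect {dialect!r}")


def _info_get(rec, key):
    """INFO lookup tolerant of keys the header never declared."""
    try:
        return rec.info.get(key)
    except ValueError:
        return None


def _read_sv_vcf(path: str, sample_id: str) -> list[SVCall]:
    calls: list[SVCall] = []
    with pysam.VariantFile(path) as vf:
        for k, rec in enumerate(vf, 1):
            svtype = rec.info.get("SVTYPE")
            if isinstance(svtype, tuple):
                svtype = svtype[0]
            if svtype not in SV_TYPES:
                logger.warning("%s: record %s: unknown SVTYPE %r, skipped", path, rec.id or k, svtype)
                continue
            sv_id = rec.id or f"{sample_id}_sv{k}"
            bp1 = (rec.chrom, rec.start)  # pysam .start is already 0-based
            if svtype == "TRA":
                chr2 = _info_get(rec, "CHR2")
                pos2 = _info_get(rec, "POS2")
                if chr2 is None or pos2 is None:
                    raise ParseError(
                        f"{path}: record {sv_id}: TRA without CHR2/POS2 mate coordinate"
                    )
                bp2 = (str(chr2), int(pos2) - 1)
            elif svtype == "INS":
                bp2 = None
            else:
                # rec.stop carries INFO/END; as a 1-based inclusive end it
                # equals the 0-based position just after the last affected
                # base, which is the second breakend.
                bp2 = (rec.chrom, int(rec.stop))
            support = _info_get(rec, "SUPPORT")
            calls.append(
                SVCall(
                    sv_id=sv_id,
                    sample_id=sample_id,
                    sv_type=svtype,
                    bp1=bp1,
                    bp2=bp2,
                    # htslib stores QUAL as float32; renormalize to the
                    # shortest decimal so written values round-trip exactly
                    quality=None if rec.qual is None else float(f"{rec.qual:.6g}"),
                    support=int(support) if support is not None else 1,
                )
            )
    return calls


_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">
##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">
##INFO=<ID=CHR2,Number=1,Type=String,Description="Chromosome of the mate breakend">
##INFO=<ID=POS2,Number=1,Type=Integer,Description="Position of the mate breakend">
##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Number of consolidated source calls">
"""


def write_sv_vcf(calls: Sequence[SVCall], path: str) -> None:
    """Write calls as a minimal SV-VCF (symbolic ALT alleles)."""
    chroms = []
    for call in calls:
        for bp in (call.bp1, call.bp2):
            if bp is not None and bp[0] not in chroms:
                chroms.append(bp[0])
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for chrom in sorted(chroms):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for call in calls:
            info = [f"SVTYPE={call.sv_type}"]
            if call.sv_type == "TRA":
                info.append(f"CHR2={call.bp2[0]}")
                info.append(f"POS2={call.bp2[1] + 1}")
            elif call.bp2 is not None:
                info.append(f"END={call.bp2[1]}")
            if call.support != 1:
                info.append(f"SUPPORT={call.support}")
            qual = "." if call.quality is None else f"{call.quality:g}"
            fh.write(
                f"{call.bp1[0]}\t{call.bp1[1] + 1}\t{call.sv_id}\tN\t<{call.sv_type}>\t"
                f"{qual}\tPASS\t{';'.join(info)}\n"
            )


def _read_bedpe(path: str, sample_id: str) -> list[SVCall]:
    calls: list[SVCall] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 7:
                raise ParseError(f"{path}: line {lineno}: expected >= 7 BEDPE columns")
            svtype = f[10] if len(f) >= 11 else f[6]
            if svtype not in SV_TYPES:
                logger.warning("%s: line %d: unknown SV type %r, skipped", path, lineno, svtype)
                continue
            name = f[6] if len(f) >= 11 else f"{sample_id}_sv{lineno}"
            qual = None
            if len(f) >= 8 and f[7] not in (".", ""):
                qual = float(f[7])
            try:
                bp1 = (f[0], int(f[1]))
                bp2 = None if f[3] in (".", "") else (f[3], int(f[4]))
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-integer coordinates") from exc
            if svtype == "TRA" and bp2 is None:
                raise ParseError(f"{path}: line {lineno}: TRA without mate coordinates")
            calls.append(
                SVCall(
                    sv_id=name,
                    sample_id=sample_id,
                    sv_type=svtype,
                    bp1=bp1,
                    bp2=bp2,
                    quality=qual,
                )
            )
    return calls


def write_bedpe(calls: Sequence[SVCall], path: str) -> None:
    """Write calls in the 10+1 column BEDPE dialect (type in column 11)."""
    with open(path, "w") as fh:
        for call in calls:
            c1, p1 = call.bp1
            if call.bp2 is None:
                c2, p2s, p2e = ".", -1, -1
            else:
                c2, p2s, p2e = call.bp2[0], call.bp2[1], call.bp2[1] + 1
            qual = "." if call.quality is None else f"{call.quality:g}"
            fh.write(
                f"{c1}\t{p1}\t{p1 + 1}\t{c2}\t{p2s}\t{p2e}\t{call.sv_id}\t{qual}\t.\t.\t"
                f"{call.sv_type}\n"
            )


# ---------------------------------------------------------------------------
# tables

def read_expression(path: str) -> pd.DataFrame:
    """Read a genes x samples TSV (first column gene id, log-scale values)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate gene ids {dups}")
    if df.columns.duplicated().any():
        raise ParseError(f"{path}: duplicate sample ids")
    df.index.name = "gene_id"
    return df.astype(float)


def write_expression(matrix: pd.DataFrame, path: str) -> None:
    matrix.to_csv(path, sep="\t", float_format="%.6g")


def read_gene_models(path: str) -> list[GeneModel]:
    """Read a gene-model TSV: gene_id, symbol, chrom, start, end, strand."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if df["gene_id"].duplicated().any():
        raise ParseError(f"{path}: duplicate gene ids")
    genes = []
    for row in df.itertuples(index=False):
        genes.append(
            GeneModel(
                gene_id=str(row.gene_id),
                symbol=str(row.symbol),
                location=GenomicInterval(row.chrom, int(row.start), int(row.end), str(row.strand)),
            )
        )
    return genes


def write_gene_models(genes: Sequence[GeneModel], path: str) -> None:
    rows = [
        (g.gene_id, g.symbol, g.location.chrom, g.location.start, g.location.end, g.location.strand)
        for g in genes
    ]
    pd.DataFrame(rows, columns=["gene_id", "symbol", "chrom", "start", "end", "strand"]).to_csv(
        path, sep="\t", index=False
    )


_EVENT_TRUE = {"recurrence", "event", "1", "true", "yes"}
_EVENT_FALSE = {"censored", "0", "false", "no"}


def read_clinical(path: str) -> list[Sample]:
    """Read a clinical TSV: sample_id, cohort, rfs_time, rfs_event.

    ``rfs_event`` accepts recurrence/censored strings or 0/1; empty
    time+event yield a sample without survival annotation.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df["sample_id"].duplicated().any():
        raise ParseError(f"{path}: duplicate sample ids")
    samples = []
    for row in df.itertuples(index=False):
        time = None if pd.isna(row.rfs_time) or row.rfs_time == "" else float(row.rfs_time)
        raw_event = None if pd.isna(row.rfs_event) or row.rfs_event == "" else str(row.rfs_event)
        if raw_event is None:
            event = None
        else:
            key = raw_event.strip().lower()
            if key in _EVENT_TRUE:
                event = True
            elif key in _EVENT_FALSE:
                event = False
            else:
                raise ParseError(f"{path}: sample {row.sample_id}: bad rfs_event {raw_event!r}")
        samples.append(Sample(str(row.sample_id), str(row.cohort), time, event))
    return samples


def write_clinical(samples: Sequence[Sample], path: str) -> None:
    rows = []
    for s in samples:
        rows.append(
            (
                s.sample_id,
                s.cohort,
                "" if s.rfs_time is None else f"{s.rfs_time:g}",
                "" if s.rfs_event is None else ("recurrence" if s.rfs_event else "censored"),
            )
        )
    pd.DataFrame(rows, columns=["sample_id", "cohort", "rfs_time", "rfs_event"]).to_csv(
        path, sep="\t", index=False
    )


def cross_check_samples(expression: pd.DataFrame, samples: Sequence[Sample]) -> list[str]:
    """Sample ids present in the expression matrix but not the clinical table.

    Such samples are retained for the non-survival stages; a warning is
    logged per missing id.
    """
    clinical_ids = {s.sample_id for s in samples}
    missing = [sid for sid in expression.columns if sid not in clinical_ids]
    for sid in missing:
        logger.warning("sample %s has expression data but no clinical record", sid)
    return missing


# ---------------------------------------------------------------------------
# SE calls and breakpoint windows (pipeline intermediates)

def write_se_bed(se_calls, path: str) -> None:
    """BED with region_id, total_signal, rank and is_super columns."""
    with open(path, "w") as fh:
        for call in se_calls:
            region = call.stitched.region
            rid = f"{call.stitched.sample_id}_se{call.rank}"
            fh.write(
                f"{region.chrom}\t{region.start}\t{region.end}\t{rid}\t"
                f"{call.stitched.total_signal!r}\t{call.rank}\t{int(call.is_super)}\t"
                f"{call.cutoff_signal!r}\t{call.stitched.constituent_count}\n"
            )


def read_se_bed(path: str, sample_id: str = ""):
    from .se_caller import SECall, StitchedRegion

    calls = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            f = raw.rstrip("\n").split("\t")
            if len(f) < 9:
                raise ParseError(f"{path}: line {lineno}: expected 9 columns")
            calls.append(
                SECall(
                    stitched=StitchedRegion(
                        region=GenomicInterval(f[0], int(f[1]), int(f[2])),
                        constituent_count=int(f[8]),
                        total_signal=float(f[4]),
                        sample_id=sample_id,
                    ),
                    rank=int(f[5]),
                    is_super=bool(int(f[6])),
                    cutoff_signal=float(f[7]),
                )
            )
    return calls


def write_windows_bed(windows: Sequence[BreakpointWindow], path: str) -> None:
    with open(path, "w") as fh:
        for w in windows:
            fh.write(
                f"{w.window.chrom}\t{w.window.start}\t{w.window.end}\t{w.source_sv}\t"
                f"{w.breakpoint_pos}\t{w.sample_id}\n"
            )


def read_windows_bed(path: str) -> list[BreakpointWindow]:
    windows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            f = raw.rstrip("\n").split("\t")
            if len(f) < 6:
                raise ParseError(f"{path}: line {lineno}: expected 6 columns")
            windows.append(
                BreakpointWindow(
                    window=GenomicInterval(f[0], int(f[1]), int(f[2])),
                    source_sv=f[3],
                    breakpoint_pos=int(f[4]),
                    sample_id=f[5],
                )
            )
    return windows
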