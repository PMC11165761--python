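"""End-to-end orchestration: SE calling -> SV windows -> overlap -> links -> RFS.

``analyze_cohort`` runs every stage on in-memory objects and returns all
intermediate results; ``run_all`` wraps it with file input/output, a
validated configuration and a deterministic JSON run manifest (parameters,
input checksums, per-stage row counts, seed — no timestamps, so a rerun
with the same config is byte-identical).
"""

from __future__ import annotations

import dataclasses
import glob
import hashlib
import json
import logging
import os
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import io as sio
from .intervals import ConfigError, GeneModel, Sample
from .links import (
    build_consensus_matrix,
    link_table,
    lof_scores,
    se_to_gene_filter,
    sv_expression_association,
)
from .overlap import (
    annotate_overlap_genes,
    compare_cohort_frequencies,
    genes_near_regions,
    overlap_se_sv,
    per_sample_frequency,
)
from .se_caller import call_super_enhancers
from .survival import (
    OutlierGeneSet,
    call_expression_outliers,
    outlier_case_status,
    stratified_rfs,
)
from .sv import consolidate_calls, windows_for_calls

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and stage parameters for a full run."""

    cohort_dir: str = ""
    out_dir: str = "sesvlink_out"
    stitch_distance: int = 12_500
    tss_exclusion: int = 0
    sv_merge_dist: int = 1_000
    require_type_match: bool = True
    window_flank: int = 10_000
    both_breakends: bool = True
    include_typical: bool = False
    gene_flank: int = 50_000
    link_max_dist: int = 500_000
    permutations: int = 1_000
    fdr_cut: float = 0.05
    lof_k: int = 10
    seed: int = 0
    gene_set_file: Optional[str] = None


@dataclass(frozen=True)
class Diagnostic:
    level: str  # "error" | "warning"
    setting: str
    message: str


def validate_config(config: PipelineConfig, check_paths: bool = True) -> list[Diagnostic]:
    """Collect configuration problems; empty list means runnable."""
    diags: list[Diagnostic] = []
    if check_paths:
        if not config.cohort_dir or not os.path.isdir(config.cohort_dir):
            diags.append(Diagnostic("error", "cohort_dir", f"not a directory: {config.cohort_dir!r}"))
        else:
            for rel in ("expression.tsv", "genes.tsv", "clinical.tsv"):
                if not os.path.exists(os.path.join(config.cohort_dir, rel)):
                    diags.append(Diagnostic("error", "cohort_dir", f"missing input {rel}"))
        if config.gene_set_file and not os.path.exists(config.gene_set_file):
            diags.append(Diagnostic("error", "gene_set_file", f"missing {config.gene_set_file}"))
    if config.stitch_distance < 0:
        diags.append(Diagnostic("error", "stitch_distance", "must be >= 0"))
    if config.window_flank <= 0:
        diags.append(Diagnostic("error", "window_flank", "must be > 0"))
    if config.sv_merge_dist < 0:
        diags.append(Diagnostic("error", "sv_merge_dist", "must be >= 0"))
    if config.link_max_dist <= 0:
        diags.append(Diagnostic("error", "link_max_dist", "must be > 0"))
    if config.permutations < 1:
        diags.append(Diagnostic("error", "permutations", "must be >= 1"))
    elif config.permutations < 100:
        diags.append(Diagnostic("warning", "permutations", "below the recommended minimum of 100"))
    if not 0 < config.fdr_cut < 1:
        diags.append(Diagnostic("error", "fdr_cut", "must lie in (0, 1)"))
    if config.lof_k < 1:
        diags.append(Diagnostic("error", "lof_k", "must be >= 1"))
    return diags


@dataclass
class AnalysisResult:
    """Everything the pipeline computes, stage by stage."""

    se_calls: dict
    sv_consolidated: dict
    windows: dict
    overlaps: list
    frequency: pd.DataFrame
    cohort_stats: Optional[dict]
    consensus_regions: list
    consensus_signal: pd.DataFrame
    se_genes: set
    sv_genes: set
    links: pd.DataFrame
    filtered: pd.DataFrame
    overlap_gene_map: dict
    sv_association: pd.DataFrame
    outlier_calls: pd.DataFrame
    case_status: pd.Series
    rfs: Optional[object]


def analyze_cohort(
    samples: Sequence[Sample],
    gene_models: Sequence[GeneModel],
    peaks: Mapping[str, Sequence],
    sv_calls: Mapping[str, Sequence],
    expression: pd.DataFrame,
    config: Optional[PipelineConfig] = None,
) -> AnalysisResult:
    """Run every analysis stage on in-memory cohort objects."""
    cfg = config or PipelineConfig()
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))

    # stage 1: super-enhancer calling per sample
    se_calls = {
        sid: call_super_enhancers(
            peaks[sid],
            stitch_distance=cfg.stitch_distance,
            tss_exclusion=cfg.tss_exclusion,
            gene_models=gene_models if cfg.tss_exclusion > 0 else None,
            sample_id=sid,
        )
        for sid in peaks
    }

    # stage 2: SV consolidation and breakpoint windows
    sv_cons = {
        sid: consolidate_calls(list(sv_calls[sid]), cfg.sv_merge_dist, cfg.require_type_match)
        for sid in sv_calls
    }
    windows = {
        sid: windows_for_calls(sv_cons[sid], cfg.window_flank, cfg.both_breakends)
        for sid in sv_cons
    }

    # stage 3: SE x SV overlap and cohort frequencies
    overlaps = []
    for sid in se_calls:
        overlaps.extend(overlap_se_sv(se_calls[sid], windows.get(sid, []), cfg.include_typical))
    frequency = per_sample_frequency(overlaps, sv_cons, samples)
    cohort_stats = None
    counts = frequency["cohort"].value_counts()
    if len(counts) == 2 and counts.min() >= 2:
        stats_ = compare_cohort_frequencies(frequency)
        cohort_stats = {m: {"t": t, "p": p} for m, (t, p) in stats_.items()}
    overlap_gene_map = annotate_overlap_genes(overlaps, gene_models, cfg.gene_flank)

    # stage 4: consensus peak matrix and peak-to-gene links
    regions, signal = build_consensus_matrix(peaks)
    super_regions = [
        c.stitched.region for calls in se_calls.values() for c in calls if c.is_super
    ]
    se_genes = genes_near_regions(super_regions, gene_models, cfg.gene_flank)
    window_ivs = [w.window for ws in windows.values() for w in ws]
    sv_genes = genes_near_regions(window_ivs, gene_models, cfg.gene_flank)
    links = link_table(
        regions, signal, expression, gene_models, se_genes, sv_genes,
        max_dist=cfg.link_max_dist, n_perm=cfg.permutations, rng=rng,
    )
    filtered = se_to_gene_filter(links, se_genes, sv_genes, cfg.fdr_cut, gene_models)
    filtered = _attach_lof(filtered, signal, expression, cfg.lof_k)

    # stage 4b: SV carrier vs non-carrier expression association
    sv_carrier_map = _sv_carrier_map(windows, gene_models, cfg.gene_flank)
    sv_association = sv_expression_association(expression, sv_carrier_map)

    # stage 5: outlier calling and RFS stratification
    gene_set = _resolve_gene_set(cfg, filtered)
    outlier_calls = call_expression_outliers(expression, gene_set)
    case_status = outlier_case_status(outlier_calls)
    status_map = {sid: bool(v) for sid, v in case_status.items()}
    rfs = None
    with_surv = [s for s in samples if s.rfs_time is not None]
    if with_surv:
        n_pos = sum(status_map.get(s.sample_id, False) for s in with_surv)
        if 0 < n_pos < len(with_surv):
            rfs = stratified_rfs(with_surv, status_map)
        else:
            logger.warning("RFS stratification skipped: one stratum is empty")

    return AnalysisResult(
        se_calls=se_calls,
        sv_consolidated=sv_cons,
        windows=windows,
        overlaps=overlaps,
        frequency=frequency,
        cohort_stats=cohort_stats,
        consensus_regions=regions,
        consensus_signal=signal,
        se_genes=se_genes,
        sv_genes=sv_genes,
        links=links,
        filtered=filtered,
        overlap_gene_map=overlap_gene_map,
        sv_association=sv_association,
        outlier_calls=outlier_calls,
        case_status=case_status,
        rfs=rfs,
    )


def _attach_lof(
    filtered: pd.DataFrame, signal: pd.DataFrame, expression: pd.DataFrame, k: int
) -> pd.DataFrame:
    """Max per-point LOF score of each filtered gene's signal/expression scatter."""
    lofs = []
    shared = [s for s in signal.columns if s in set(expression.columns)]
    for row in filtered.itertuples(index=False):
        x = signal.loc[row.peak_id, shared].to_numpy()
        y = expression.loc[row.gene_id, shared].to_numpy()
        if len(shared) > k:
            lofs.append(float(lof_scores(np.column_stack([x, y]), k=k).max()))
        else:
            lofs.append(float("nan"))
    out = filtered.copy()
    out["max_lof"] = lofs
    return out


def _sv_carrier_map(
    windows: Mapping[str, Sequence],
    gene_models: Sequence[GeneModel],
    flank: int,
) -> dict[str, set[str]]:
    """gene_id -> sample ids with an SV breakpoint window within ``flank`` of its TSS."""
    out: dict[str, set[str]] = {}
    for sid, ws in windows.items():
        ivs = [w.window for w in ws]
        for gid in genes_near_regions(ivs, gene_models, flank):
            out.setdefault(gid, set()).add(sid)
    return out


def _resolve_gene_set(config: PipelineConfig, filtered: pd.DataFrame) -> OutlierGeneSet:
    if config.gene_set_file:
        return OutlierGeneSet.from_file(config.gene_set_file)
    return OutlierGeneSet("se_sv_links", tuple(filtered["gene_id"].tolist()))


# ---------------------------------------------------------------------------
# file-level run

class StageError(RuntimeError):
    """A pipeline stage failed; names the stage and the offending input."""


def run_all(config: PipelineConfig) -> dict:
    """Execute the full pipeline on a cohort directory; returns the manifest.

    The cohort directory layout is the one :func:`sesvlink.simulate.write_cohort`
    produces (``peaks/*.narrowPeak``, ``sv/*.vcf``, ``expression.tsv``,
    ``genes.tsv``, ``clinical.tsv``).  Stage outputs are plain TSV; the JSON
    manifest lists parameters, input checksums and row counts.
    """
    diags = validate_config(config)
    errors = [d for d in diags if d.level == "error"]
    if errors:
        raise ConfigError("; ".join(f"{d.setting}: {d.message}" for d in errors))

    from .simulate import read_cohort  # deferred: simulate imports io

    try:
        samples, gene_models, peaks, sv_calls, expression = read_cohort(config.cohort_dir)
    except Exception as exc:  # noqa: BLE001 - surface stage + input
        raise StageError(f"stage load: failed reading {config.cohort_dir}: {exc}") from exc

    sio.cross_check_samples(expression, samples)
    result = analyze_cohort(samples, gene_models, peaks, sv_calls, expression, config)

    os.makedirs(config.out_dir, exist_ok=True)
    out = lambda name: os.path.join(config.out_dir, name)  # noqa: E731

    se_rows = [
        (sid, c.stitched.region.chrom, c.stitched.region.start, c.stitched.region.end,
         c.stitched.constituent_count, f"{c.stitched.total_signal:.6g}", c.rank,
         int(c.is_super), f"{c.cutoff_signal:.6g}")
        for sid in sorted(result.se_calls) for c in result.se_calls[sid]
    ]
    pd.DataFrame(se_rows, columns=["sample_id", "chrom", "start", "end", "n_peaks",
                                   "total_signal", "rank", "is_super", "cutoff"]).to_csv(
        out("se_calls.tsv"), sep="\t", index=False)

    win_rows = [
        (w.sample_id, w.window.chrom, w.window.start, w.window.end, w.source_sv, w.breakpoint_pos)
        for sid in sorted(result.windows) for w in result.windows[sid]
    ]
    pd.DataFrame(win_rows, columns=["sample_id", "chrom", "start", "end", "sv_id",
                                    "breakpoint_pos"]).to_csv(out("windows.tsv"), sep="\t",
                                                              index=False)

    ov_rows = [
        (r.sample_id, r.se_region.chrom, r.se_region.start, r.se_region.end, r.sv_id,
         r.breakpoint_pos, r.overlap_length)
        for r in result.overlaps
    ]
    ov = pd.DataFrame(ov_rows, columns=["sample_id", "se_chrom", "se_start", "se_end",
                                        "sv_id", "breakpoint_pos", "overlap_length"])
    ov = ov.sort_values(list(ov.columns)).reset_index(drop=True)
    ov.to_csv(out("overlaps.tsv"), sep="\t", index=False)

    result.frequency.to_csv(out("frequencies.tsv"), sep="\t", index=False, float_format="%.6g")
    result.links.to_csv(out("links.tsv"), sep="\t", index=False, float_format="%.6g")
    result.filtered.to_csv(out("se_gene_table.tsv"), sep="\t", index=False, float_format="%.6g")
    result.sv_association.to_csv(out("sv_association.tsv"), sep="\t", index=False,
                                 float_format="%.6g")
    result.outlier_calls.to_csv(out("outlier_calls.tsv"), sep="\t", index=False,
                                float_format="%.6g")

    gene_rows = [
        (region.chrom, region.start, region.end, ",".join(genes))
        for region, genes in sorted(result.overlap_gene_map.items())
    ]
    pd.DataFrame(gene_rows, columns=["chrom", "start", "end", "genes"]).to_csv(
        out("overlap_genes.tsv"), sep="\t", index=False)

    rfs_summary = None
    if result.rfs is not None:
        rfs_summary = {
            "chi2": round(result.rfs.chi2, 6),
            "p": float(f"{result.rfs.p:.6g}"),
            "n_positive": result.rfs.curve_positive.n,
            "n_negative": result.rfs.curve_negative.n,
        }
        km_rows = []
        for curve in (result.rfs.curve_positive, result.rfs.curve_negative):
            for t, s, n_at, d in zip(curve.times, curve.survival, curve.at_risk, curve.events):
                km_rows.append((curve.label, f"{t:g}", f"{s:.6g}", n_at, d))
        pd.DataFrame(km_rows, columns=["stratum", "time", "survival", "at_risk",
                                       "events"]).to_csv(out("rfs_km.tsv"), sep="\t", index=False)

    # analysis parameters only: output location does not alter results
    params = {k: v for k, v in dataclasses.asdict(config).items() if k != "out_dir"}
    manifest = {
        "parameters": params,
        "seed": config.seed,
        "inputs": _input_checksums(config.cohort_dir),
        "row_counts": {
            "se_calls": len(se_rows),
            "windows": len(win_rows),
            "overlaps": len(ov_rows),
            "links": int(len(result.links)),
            "se_gene_table": int(len(result.filtered)),
            "outlier_calls": int(len(result.outlier_calls)),
        },
        "cohort_stats": result.cohort_stats,
        "rfs": rfs_summary,
    }
    with open(out("run_manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def _input_checksums(cohort_dir: str) -> dict[str, str]:
    checksums = {}
    patterns = ["expression.tsv", "genes.tsv", "clinical.tsv",
                os.path.join("peaks", "*.narrowPeak"), os.path.join("sv", "*.vcf")]
    for pattern in patterns:
        for path in sorted(glob.glob(os.path.join(cohort_dir, pattern))):
            rel = os.path.relpath(path, cohort_dir)
            h = hashlib.sha256()
            with open(path, "rb") as fh:
                for chunk in iter(lambda: fh.read(1 << 20), b""):
                    h.update(chunk)
            checksums[rel] = h.hexdigest()
    return checksums
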