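"""Synthetic cohort generator with planted SE-SV-driven outlier genes.

The generator emulates the data the pipeline consumes: per-sample H3K27Ac
peak calls over a set of recurrent enhancer sites with heavy-tailed
(log-normal) signal so that rank-ordering produces a hockey-stick curve;
per-sample structural variants; a log-scale expression matrix; and a
clinical table with exponential recurrence-free-survival times.

Ground truth is planted constructively: an outlier-positive case carries a
handful of events, each placing a tight cluster of 3-8 very-high-signal
peaks (one stitched super-enhancer) near a planted gene's TSS together
with an SV breakpoint inside +-8 kb of the cluster centre, so the default
20 kb breakpoint window always intersects the super-enhancer.  Carrier
expression is forced above the non-carriers' Q3 + 2*IQR, and the
recurrence hazard of truly positive cases is multiplied by the configured
hazard ratio.  One master seed drives named sub-streams (layout, truth,
peaks, SVs, expression, survival), so the same config and seed reproduce
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io as sio
from .intervals import ConfigError, GeneModel, GenomicInterval, Sample
from .sv import SVCall

_DEFAULT_GENOME = (
    ("chr1", 50_000_000),
    ("chr2", 50_000_000),
    ("chr3", 50_000_000),
    ("chr4", 50_000_000),
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic cohort."""

    n_noncaga: int = 120
    n_caga: int = 40
    genome: tuple = _DEFAULT_GENOME
    n_genes: int = 200
    n_enhancer_sites: int = 600
    site_activity: float = 0.5
    peak_width: tuple[int, int] = (500, 2000)
    sv_per_sample: float = 30.0
    n_planted_genes: int = 20
    planted_effect_sd: float = 3.0
    positive_rate_noncaga: float = 0.4
    positive_rate_caga: float = 0.1
    events_per_positive: tuple[int, int] = (2, 4)
    cluster_peaks: tuple[int, int] = (3, 8)
    cluster_span: int = 10_000
    cluster_signal_scale: float = 10.0
    expr_noise_sd: float = 1.0
    baseline_hazard: float = 0.02  # per month
    hazard_ratio: float = 3.0
    followup_months: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_noncaga", "n_caga", "n_genes", "n_enhancer_sites",
                     "n_planted_genes", "cluster_span"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        for name in ("site_activity", "positive_rate_noncaga", "positive_rate_caga"):
            if not 0 <= getattr(self, name) <= 1:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.hazard_ratio <= 0 or self.baseline_hazard <= 0:
            raise ConfigError("hazards must be > 0")
        if self.n_planted_genes > self.n_genes:
            raise ConfigError("n_planted_genes cannot exceed n_genes")


@dataclass(frozen=True)
class PlantedEvent:
    sample_id: str
    gene_id: str
    cluster: GenomicInterval
    breakpoint: tuple[str, int]


@dataclass(frozen=True)
class GroundTruth:
    planted_genes: tuple[str, ...]
    carriers: dict  # gene_id -> frozenset of sample ids
    positives: frozenset
    events: tuple[PlantedEvent, ...]


@dataclass
class SyntheticCohort:
    config: SyntheticConfig
    samples: list[Sample]
    gene_models: list[GeneModel]
    peaks: dict  # sample_id -> list[(GenomicInterval, signal)]
    sv_calls: dict  # sample_id -> list[SVCall]
    expression: pd.DataFrame
    truth: GroundTruth


def generate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Generate the full cohort for one seed (deterministic)."""
    ss = np.random.SeedSequence(config.seed)
    r_layout, r_truth, r_peaks, r_sv, r_expr, r_surv = (
        np.random.default_rng(s) for s in ss.spawn(6)
    )
    chroms = [c for c, _ in config.genome]
    lengths = {c: l for c, l in config.genome}
    total_len = sum(lengths.values())

    # --- gene models, evenly allocated across chromosomes
    gene_models: list[GeneModel] = []
    quotas = _allocate(config.n_genes, [lengths[c] for c in chroms])
    gi = 0
    for chrom, quota in zip(chroms, quotas):
        margin = 1_000_000
        pos = np.sort(r_layout.integers(margin, lengths[chrom] - margin, quota))
        strands = r_layout.choice(["+", "-"], size=quota)
        for p, strand in zip(pos, strands):
            gid = f"G{gi:04d}"
            gene_models.append(
                GeneModel(gid, gid, GenomicInterval(chrom, int(p), int(p) + 20_000, str(strand)))
            )
            gi += 1

    # --- recurrent enhancer sites (shared across samples)
    site_chrom, site_pos, site_width = [], [], []
    for chrom, quota in zip(chroms, _allocate(config.n_enhancer_sites, [lengths[c] for c in chroms])):
        pos = np.sort(r_layout.integers(50_000, lengths[chrom] - 50_000, quota))
        widths = r_layout.integers(config.peak_width[0], config.peak_width[1] + 1, quota)
        site_chrom.extend([chrom] * quota)
        site_pos.extend(int(p) for p in pos)
        site_width.extend(int(w) for w in widths)
    n_sites = len(site_pos)

    # --- planted genes and cluster centres
    planted_idx = np.sort(r_truth.choice(config.n_genes, config.n_planted_genes, replace=False))
    planted = [gene_models[i] for i in planted_idx]
    cluster_center = {
        g.gene_id: int(g.tss + r_truth.integers(-25_000, 25_001)) for g in planted
    }

    # --- samples, positivity and planted events
    samples_meta = [(f"S{i + 1:04d}", "non-CAGA") for i in range(config.n_noncaga)]
    samples_meta += [(f"S{config.n_noncaga + i + 1:04d}", "CAGA") for i in range(config.n_caga)]
    events: list[PlantedEvent] = []
    carriers: dict[str, set[str]] = {g.gene_id: set() for g in planted}
    positives: set[str] = set()
    lo, hi = config.events_per_positive
    for sid, cohort in samples_meta:
        rate = config.positive_rate_noncaga if cohort == "non-CAGA" else config.positive_rate_caga
        if r_truth.random() < rate:
            positives.add(sid)
            k = int(r_truth.integers(lo, hi + 1))
            chosen = r_truth.choice(len(planted), size=min(k, len(planted)), replace=False)
            for ci in np.sort(chosen):
                g = planted[ci]
                carriers[g.gene_id].add(sid)

    # --- per-sample peaks
    span = config.cluster_span
    peaks: dict[str, list[tuple[GenomicInterval, float]]] = {}
    for sid, _ in samples_meta:
        plist: list[tuple[GenomicInterval, float]] = []
        active = r_peaks.random(n_sites) < config.site_activity
        jitter = r_peaks.integers(-200, 201, n_sites)
        signals = r_peaks.lognormal(0.0, 1.0, n_sites)
        for i in range(n_sites):
            if not active[i]:
                continue
            start = max(0, site_pos[i] + int(jitter[i]))
            plist.append(
                (GenomicInterval(site_chrom[i], start, start + site_width[i]), float(signals[i]))
            )
        for g in planted:
            if sid not in carriers[g.gene_id]:
                continue
            center = cluster_center[g.gene_id]
            chrom = g.location.chrom
            npk = int(r_peaks.integers(config.cluster_peaks[0], config.cluster_peaks[1] + 1))
            offsets = np.sort(r_peaks.integers(0, span - 2_000, npk))
            widths = r_peaks.integers(config.peak_width[0], config.peak_width[1] + 1, npk)
            sigs = r_peaks.lognormal(0.0, 1.0, npk) * config.cluster_signal_scale
            for off, w, sig in zip(offsets, widths, sigs):
                start = max(0, center - span // 2 + int(off))
                plist.append((GenomicInterval(chrom, start, start + int(w)), float(sig)))
        plist.sort(key=lambda p: (p[0].chrom, p[0].start, p[0].end))
        peaks[sid] = plist

    # --- per-sample SVs (planted + background)
    sv_calls: dict[str, list[SVCall]] = {}
    for sid, _ in samples_meta:
        calls: list[SVCall] = []
        for g in planted:
            if sid not in carriers[g.gene_id]:
                continue
            chrom = g.location.chrom
            bp1 = cluster_center[g.gene_id] + int(r_sv.integers(-8_000, 8_001))
            sv_type = str(r_sv.choice(["DEL", "DUP", "INV"]))
            length = int(r_sv.integers(100_000, 2_000_001))
            bp2 = min(bp1 + length, lengths[chrom] - 1)
            cl = GenomicInterval(chrom, cluster_center[g.gene_id] - span // 2,
                                 cluster_center[g.gene_id] + span // 2)
            events.append(PlantedEvent(sid, g.gene_id, cl, (chrom, bp1)))
            calls.append(
                SVCall(f"{sid}_pl_{g.gene_id}", sid, sv_type, (chrom, bp1), (chrom, bp2),
                       quality=float(np.round(r_sv.uniform(30, 60), 1)))
            )
        n_bg = int(r_sv.poisson(config.sv_per_sample))
        for k in range(n_bg):
            sv_type = str(r_sv.choice(["DEL", "DUP", "INV", "TRA", "INS"],
                                      p=[0.3, 0.2, 0.2, 0.2, 0.1]))
            chrom = str(r_sv.choice(chroms, p=[lengths[c] / total_len for c in chroms]))
            pos = int(r_sv.integers(20_000, lengths[chrom] - 20_000))
            if sv_type == "INS":
                bp2 = None
            elif sv_type == "TRA":
                others = [c for c in chroms if c != chrom]
                c2 = str(r_sv.choice(others))
                bp2 = (c2, int(r_sv.integers(20_000, lengths[c2] - 20_000)))
            else:
                length = int(np.round(r_sv.lognormal(11.0, 1.0)))
                bp2 = (chrom, min(pos + max(length, 50), lengths[chrom] - 1))
            calls.append(
                SVCall(f"{sid}_sv{k + 1}", sid, sv_type, (chrom, pos), bp2,
                       quality=float(np.round(r_sv.uniform(20, 60), 1)))
            )
        sv_calls[sid] = calls

    # --- expression matrix
    sample_ids = [sid for sid, _ in samples_meta]
    n_samp = len(sample_ids)
    sd = config.expr_noise_sd
    means = r_expr.uniform(2.0, 10.0, config.n_genes)
    values = np.empty((config.n_genes, n_samp))
    for row in range(config.n_genes):
        values[row] = r_expr.normal(means[row], sd, n_samp)
    col_index = {sid: j for j, sid in enumerate(sample_ids)}
    for g in planted:
        row = int(g.gene_id[1:])
        car_cols = sorted(col_index[s] for s in carriers[g.gene_id])
        if not car_cols:
            continue
        mask = np.ones(n_samp, dtype=bool)
        mask[car_cols] = False
        non = values[row][mask]
        q1, q3 = np.percentile(non, [25, 75])
        bound = q3 + 2.0 * (q3 - q1)
        floor = max(bound, means[row] + config.planted_effect_sd * sd)
        lift = np.abs(r_expr.normal(0.0, 0.5 * sd, len(car_cols)))
        values[row, car_cols] = floor + 0.05 * sd + lift
    expression = pd.DataFrame(values, index=[g.gene_id for g in gene_models],
                              columns=sample_ids)
    expression.index.name = "gene_id"

    # --- clinical outcomes
    samples: list[Sample] = []
    for sid, cohort in samples_meta:
        rate = config.baseline_hazard * (config.hazard_ratio if sid in positives else 1.0)
        t_event = r_surv.exponential(1.0 / rate)
        t_censor = r_surv.uniform(3.0, config.followup_months)
        time = float(np.round(min(t_event, t_censor), 2))
        samples.append(Sample(sid, cohort, time, bool(t_event <= t_censor)))

    truth = GroundTruth(
        planted_genes=tuple(g.gene_id for g in planted),
        carriers={g: frozenset(s) for g, s in carriers.items()},
        positives=frozenset(positives),
        events=tuple(events),
    )
    return SyntheticCohort(config, samples, gene_models, peaks, sv_calls, expression, truth)


def _allocate(total: int, weights: Sequence[float]) -> list[int]:
    """Largest-remainder allocation of ``total`` items over weights."""
    w = np.asarray(weights, dtype=float)
    raw = total * w / w.sum()
    base = np.floor(raw).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    for i in order[:rem]:
        base[i] += 1
    return base.tolist()


# ---------------------------------------------------------------------------
# serialization

def write_cohort(cohort: SyntheticCohort, directory: str) -> dict:
    """Write the cohort to plain-text files and return a checksum manifest."""
    os.makedirs(directory, exist_ok=True)
    os.makedirs(os.path.join(directory, "peaks"), exist_ok=True)
    os.makedirs(os.path.join(directory, "sv"), exist_ok=True)
    files: dict[str, str] = {}

    for sid in sorted(cohort.peaks):
        rel = os.path.join("peaks", f"{sid}.narrowPeak")
        sio.write_narrowpeak(cohort.peaks[sid], os.path.join(directory, rel), name_prefix=f"{sid}_p")
        files[rel] = _sha256(os.path.join(directory, rel))
    for sid in sorted(cohort.sv_calls):
        rel = os.path.join("sv", f"{sid}.vcf")
        sio.write_sv_vcf(cohort.sv_calls[sid], os.path.join(directory, rel))
        files[rel] = _sha256(os.path.join(directory, rel))

    sio.write_expression(cohort.expression, os.path.join(directory, "expression.tsv"))
    files["expression.tsv"] = _sha256(os.path.join(directory, "expression.tsv"))
    sio.write_gene_models(cohort.gene_models, os.path.join(directory, "genes.tsv"))
    files["genes.tsv"] = _sha256(os.path.join(directory, "genes.tsv"))
    sio.write_clinical(cohort.samples, os.path.join(directory, "clinical.tsv"))
    files["clinical.tsv"] = _sha256(os.path.join(directory, "clinical.tsv"))

    truth_rows = [
        (e.sample_id, e.gene_id, e.cluster.chrom, e.cluster.start, e.cluster.end,
         e.breakpoint[1])
        for e in cohort.truth.events
    ]
    pd.DataFrame(
        truth_rows,
        columns=["sample_id", "gene_id", "cluster_chrom", "cluster_start", "cluster_end",
                 "breakpoint_pos"],
    ).to_csv(os.path.join(directory, "ground_truth.tsv"), sep="\t", index=False)
    files["ground_truth.tsv"] = _sha256(os.path.join(directory, "ground_truth.tsv"))

    manifest = {
        "config": _config_dict(cohort.config),
        "files": files,
        "n_samples": len(cohort.samples),
        "planted_genes": list(cohort.truth.planted_genes),
    }
    with open(os.path.join(directory, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def read_cohort(directory: str) -> tuple[list[Sample], list[GeneModel], dict, dict, pd.DataFrame]:
    """Re-read a written cohort (samples, genes, peaks, sv_calls, expression)."""
    samples = sio.read_clinical(os.path.join(directory, "clinical.tsv"))
    gene_models = sio.read_gene_models(os.path.join(directory, "genes.tsv"))
    expression = sio.read_expression(os.path.join(directory, "expression.tsv"))
    peaks, sv_calls = {}, {}
    for s in samples:
        peaks[s.sample_id] = sio.read_peaks(
            os.path.join(directory, "peaks", f"{s.sample_id}.narrowPeak"), s.sample_id
        )
        sv_calls[s.sample_id] = sio.read_sv_calls(
            os.path.join(directory, "sv", f"{s.sample_id}.vcf"), s.sample_id
        )
    return samples, gene_models, peaks, sv_calls, expression


def _config_dict(config: SyntheticConfig) -> dict:
    d = asdict(config)
    d["genome"] = [[c, l] for c, l in config.genome]
    return d


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
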