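"""Seed-replicated end-to-end experiments on the synthetic cohort.

These drive the same code paths as ``run_all`` but stay in memory, so
parameter-recovery and power studies across many seeds remain cheap.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .pipeline import PipelineConfig, analyze_cohort
from .simulate import SyntheticConfig, generate_cohort
from .survival import logrank_test


def derive_seeds(base_seed: int, n: int) -> list[int]:
    """n reproducible sub-seeds (< 2**31) from one master seed."""
    state = np.random.SeedSequence(base_seed).generate_state(n, dtype=np.uint64)
    return [int(s % (2**31)) for s in state]


@dataclass
class RecoveryResult:
    recovery: list[float]  # per-seed fraction of planted genes recovered
    false_positive: list[float]  # per-seed fraction of non-planted genes called
    n_planted: int
    n_genes: int

    @property
    def mean_recovery(self) -> float:
        return float(np.mean(self.recovery))

    @property
    def mean_false_positive(self) -> float:
        return float(np.mean(self.false_positive))


def recovery_experiment(
    n_seeds: int = 20,
    base_seed: int = 0,
    cohort_overrides: Optional[dict] = None,
    pipeline_overrides: Optional[dict] = None,
) -> RecoveryResult:
    """Planted-gene recovery and false-positive rate of the full pipeline.

    For each seed a fresh default cohort is generated, the complete
    analysis (SE calling through the SE-to-gene filter) is run, and the
    filtered gene table is compared against the planted ground truth.
    """
    rec, fp = [], []
    cfg0 = SyntheticConfig()
    for seed in derive_seeds(base_seed, n_seeds):
        cohort_kwargs = dict(cohort_overrides or {})
        cohort_kwargs["seed"] = seed
        scfg = dataclasses.replace(cfg0, **cohort_kwargs)
        cohort = generate_cohort(scfg)
        pcfg = PipelineConfig(seed=seed, **(pipeline_overrides or {}))
        result = analyze_cohort(
            cohort.samples, cohort.gene_models, cohort.peaks, cohort.sv_calls,
            cohort.expression, pcfg,
        )
        called = set(result.filtered["gene_id"])
        planted = set(cohort.truth.planted_genes)
        rec.append(len(called & planted) / len(planted))
        n_non = scfg.n_genes - len(planted)
        fp.append(len(called - planted) / n_non if n_non else 0.0)
    return RecoveryResult(rec, fp, cfg0.n_planted_genes, cfg0.n_genes)


def logrank_power_experiment(
    n_reps: int = 200,
    n: int = 200,
    hazard_ratio: float = 3.0,
    positive_rate: float = 0.4,
    baseline_hazard: float = 0.02,
    followup: float = 60.0,
    base_seed: int = 0,
    alpha: float = 0.05,
) -> float:
    """Fraction of replicates in which the log-rank test detects the planted HR.

    Each replicate draws exponential recurrence times with the hazard
    multiplied by ``hazard_ratio`` for outlier-positive cases and
    administrative censoring U(3, followup) months.
    """
    rng = np.random.default_rng(np.random.SeedSequence([base_seed, 2718]))
    hits = 0
    for _ in range(n_reps):
        pos = rng.random(n) < positive_rate
        rate = baseline_hazard * np.where(pos, hazard_ratio, 1.0)
        t_event = rng.exponential(1.0 / rate)
        t_censor = rng.uniform(3.0, followup, n)
        time = np.minimum(t_event, t_censor)
        event = t_event <= t_censor
        if pos.all() or (~pos).all() or not event.any():
            continue
        _, p = logrank_test(time[pos], event[pos], time[~pos], event[~pos])
        hits += p < alpha
    return hits / n_reps
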