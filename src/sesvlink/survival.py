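"""IQR outlier-expression calling and recurrence-free-survival stratification.

A sample is an expression outlier for a gene when its value exceeds
Q3 + 1.5*IQR across the cohort (type-7 linearly interpolated quartiles;
upper tail only).  A case is outlier-positive when at least one gene of the
chosen gene set is an outlier in that case.  Recurrence-free survival is
stratified by that status with the Kaplan-Meier product-limit estimator
and the standard (unweighted) 1-df log-rank test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import Sample

logger = logging.getLogger(__name__)

#: The six genes used for the primary stratification.
TOP6_GENES = ("CDK4", "ERBB2", "MDM2", "FRS2", "EGFR", "CAV2")


@dataclass(frozen=True)
class OutlierGeneSet:
    """A named gene set for outlier-status stratification."""

    name: str
    genes: tuple[str, ...]

    @classmethod
    def top6(cls) -> "OutlierGeneSet":
        return cls("top6", TOP6_GENES)

    @classmethod
    def from_file(cls, path: str, name: str = "custom") -> "OutlierGeneSet":
        with open(path) as fh:
            genes = tuple(line.strip() for line in fh if line.strip() and not line.startswith("#"))
        return cls(name, genes)


def iqr_upper_bound(values: Sequence[float]) -> tuple[float, float, float, float]:
    """(q1, q3, iqr, upper_bound) with the bound q3 + 1.5*iqr.

    Quartiles use linear interpolation (the type-7 convention); requires
    n >= 4 observations.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ValueError(f"need >= 4 values for quartiles, got {v.size}")
    q1, q3 = np.percentile(v, [25, 75], method="linear")
    iqr = q3 - q1
    return float(q1), float(q3), float(iqr), float(q3 + 1.5 * iqr)


def call_expression_outliers(
    expression: pd.DataFrame,
    gene_set: OutlierGeneSet,
) -> pd.DataFrame:
    """Per-(gene, sample) outlier calls over the whole cohort.

    The bound is computed per gene across all samples.  Genes of the set
    missing from the matrix are logged and skipped.  Returns a DataFrame
    with gene_id, sample_id, value, q1, q3, iqr, upper_bound, is_outlier.
    """
    rows = []
    for gene in gene_set.genes:
        if gene not in expression.index:
            logger.warning("gene %s not in expression matrix; skipped", gene)
            continue
        vals = expression.loc[gene]
        q1, q3, iqr, bound = iqr_upper_bound(vals.to_numpy())
        for sid, val in vals.items():
            rows.append((gene, sid, float(val), q1, q3, iqr, bound, bool(val > bound)))
    return pd.DataFrame(
        rows,
        columns=["gene_id", "sample_id", "value", "q1", "q3", "iqr", "upper_bound", "is_outlier"],
    )


def outlier_case_status(calls: pd.DataFrame) -> pd.Series:
    """Per-sample boolean: >= 1 gene of the set is an outlier in that sample."""
    if len(calls) == 0:
        return pd.Series(dtype=bool)
    return calls.groupby("sample_id")["is_outlier"].any()


def outlier_prevalence(calls: pd.DataFrame) -> pd.Series:
    """Fraction of outlier-positive cases in which each gene is an outlier."""
    status = outlier_case_status(calls)
    positive = status[status].index
    if len(positive) == 0:
        raise ValueError("no outlier-positive cases")
    sub = calls[calls["sample_id"].isin(positive)]
    prev = sub.groupby("gene_id")["is_outlier"].sum() / len(positive)
    return prev.astype(float)


# ---------------------------------------------------------------------------
# Kaplan-Meier / log-rank

@dataclass(frozen=True)
class KMCurve:
    """A product-limit survival curve over the observed event times."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    label: str = ""
    n: int = 0

    def survival_at(self, t: float) -> float:
        """Step-function value S(t); 1 before the first event."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times, events, label: str = "") -> KMCurve:
    """Kaplan-Meier product-limit estimate.

    Subjects censored at t remain in the risk set at t.  The curve steps
    only at observed event times; with no events it is identically 1.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.size == 0:
        raise ValueError("need at least one subject")
    if np.any(t < 0):
        raise ValueError("negative survival times")
    grid = np.unique(t[e])
    surv, risk, d_out = [], [], []
    s = 1.0
    for et in grid:
        n_at = int(np.sum(t >= et))
        d = int(np.sum((t == et) & e))
        s *= 1.0 - d / n_at
        surv.append(s)
        risk.append(n_at)
        d_out.append(d)
    return KMCurve(
        times=grid,
        survival=np.asarray(surv),
        at_risk=np.asarray(risk, dtype=int),
        events=np.asarray(d_out, dtype=int),
        label=label,
        n=int(t.size),
    )


def logrank_test(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Standard unweighted 1-df log-rank test between two groups.

    Sums observed minus expected events in group A over the pooled event
    times with the hypergeometric variance; returns (chi2, p).  Requires
    >= 1 event overall.
    """
    ta = np.asarray(times_a, dtype=float)
    ea = np.asarray(events_a, dtype=bool)
    tb = np.asarray(times_b, dtype=float)
    eb = np.asarray(events_b, dtype=bool)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled_events = np.unique(np.concatenate([ta[ea], tb[eb]]))
    if pooled_events.size == 0:
        raise ValueError("log-rank test requires at least one event")
    obs = exp = var = 0.0
    for t in pooled_events:
        n1 = int(np.sum(ta >= t))
        n2 = int(np.sum(tb >= t))
        d1 = int(np.sum((ta == t) & ea))
        d2 = int(np.sum((tb == t) & eb))
        n = n1 + n2
        d = d1 + d2
        if n == 0 or d == 0:
            continue
        obs += d1
        exp += d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = (obs - exp) ** 2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


@dataclass(frozen=True)
class StratifiedRFS:
    """KM curves and log-rank test for outlier-positive vs -negative cases."""

    curve_positive: KMCurve
    curve_negative: KMCurve
    chi2: float
    p: float


def stratified_rfs(
    samples: Sequence[Sample],
    status: Mapping[str, bool],
) -> StratifiedRFS:
    """Stratify recurrence-free survival by outlier-case status.

    Samples without survival annotation are skipped with a logged note;
    an empty stratum is an error naming the stratum.
    """
    pos_t, pos_e, neg_t, neg_e = [], [], [], []
    for s in samples:
        if s.rfs_time is None:
            logger.info("sample %s lacks survival data; skipped in RFS", s.sample_id)
            continue
        if status.get(s.sample_id, False):
            pos_t.append(s.rfs_time)
            pos_e.append(s.rfs_event)
        else:
            neg_t.append(s.rfs_time)
            neg_e.append(s.rfs_event)
    if not pos_t:
        raise ValueError("outlier-positive stratum is empty")
    if not neg_t:
        raise ValueError("outlier-negative stratum is empty")
    chi2, p = logrank_test(pos_t, pos_e, neg_t, neg_e)
    return StratifiedRFS(
        curve_positive=km_estimate(pos_t, pos_e, label="outlier-positive"),
        curve_negative=km_estimate(neg_t, neg_e, label="outlier-negative"),
        chi2=chi2,
        p=p,
    )
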