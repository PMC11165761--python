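"""Peak-to-gene and SE-to-gene link analysis.

Across-sample Pearson correlation between consensus-peak H3K27Ac signal
and gene expression defines peak-to-gene links for peaks within 0.5 Mb of
the gene promoter.  Each link's significance comes from a seeded label-
permutation null (add-one two-sided empirical p), adjusted with
Benjamini-Hochberg across links.  SE-to-gene links restrict to genes
annotated both to a super-enhancer region and to a structural variant, at
FDR < 0.05.  Scatter diagnostics use an ordinary least-squares fit and the
classic local-outlier-factor score with k = 10 neighbours.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist
from statsmodels.stats.multitest import multipletests

from .intervals import GeneModel, GenomicInterval, chrom_key, find_overlaps
from .se_caller import stitch_peaks

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LinkNull:
    """The permutation null attached to one link."""

    n_perm: int
    null_r: np.ndarray
    pooled: bool = False


# ---------------------------------------------------------------------------
# consensus peak matrix

def build_consensus_matrix(
    peak_sets: Mapping[str, Sequence[tuple[GenomicInterval, float]]],
) -> tuple[list[tuple[str, GenomicInterval]], pd.DataFrame]:
    """Pool per-sample peaks into consensus regions and a signal matrix.

    Overlapping or abutting peaks from any sample are merged into one
    consensus region; each sample's signal for a region is the sum of its
    peak signals intersecting that region (0 when absent).  Returns the
    region list (id, interval) and a regions x samples DataFrame.
    """
    pooled = [p for peaks in peak_sets.values() for p in peaks]
    if not pooled:
        return [], pd.DataFrame(columns=list(peak_sets))
    merged = stitch_peaks(pooled, stitch_distance=0)
    regions = [
        (f"cp{i:05d}", sr.region) for i, sr in enumerate(merged, 1)
    ]
    region_ivs = [iv for _, iv in regions]
    sample_ids = list(peak_sets)
    mat = np.zeros((len(regions), len(sample_ids)))
    for col, sid in enumerate(sample_ids):
        ivs = [iv for iv, _ in peak_sets[sid]]
        sigs = [sig for _, sig in peak_sets[sid]]
        for i, j, _ in find_overlaps(region_ivs, ivs):
            mat[i, col] += sigs[j]
    signal = pd.DataFrame(mat, index=[rid for rid, _ in regions], columns=sample_ids)
    signal.index.name = "peak_id"
    return regions, signal


def candidate_pairs(
    regions: Sequence[tuple[str, GenomicInterval]],
    gene_models: Sequence[GeneModel],
    max_dist: int = 500_000,
) -> list[tuple[str, str, int]]:
    """(peak_id, gene_id, distance) pairs with peak-to-TSS distance <= max_dist.

    The distance is 0 when the TSS falls inside the peak region, else the
    bp from the TSS to the nearest region edge.
    """
    by_chrom: dict[str, list[tuple[int, str, GenomicInterval]]] = {}
    for rid, iv in regions:
        by_chrom.setdefault(chrom_key(iv.chrom), []).append((iv.start, rid, iv))
    for lst in by_chrom.values():
        lst.sort()
    pairs = []
    for g in gene_models:
        tss = g.tss
        for start, rid, iv in by_chrom.get(chrom_key(g.location.chrom), ()):
            if start - tss > max_dist:
                break
            d = iv.distance_to_point(tss)
            if d <= max_dist:
                pairs.append((rid, g.gene_id, d))
    pairs.sort()
    return pairs


# ---------------------------------------------------------------------------
# correlation and permutation null

def pearson_link(x: np.ndarray, y: np.ndarray) -> Optional[float]:
    """Pearson product-moment r; None when either vector has zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in input")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    return float(stats.pearsonr(x, y).statistic)


def permutation_null_p(
    x: np.ndarray,
    y: np.ndarray,
    n_perm: int = 1000,
    rng: Optional[np.random.Generator] = None,
    keep_null: bool = False,
) -> tuple[Optional[float], float, Optional[LinkNull]]:
    """Two-sided permutation p-value for the Pearson correlation of x and y.

    y's sample labels are permuted ``n_perm`` times with the seeded
    generator; p = (1 + #{|r_b| >= |r_obs|}) / (n_perm + 1), so the
    attainable minimum is 1/(n_perm + 1).  Returns ``(r_obs, p, null)``;
    a zero-variance input yields ``(None, nan, None)`` so the caller can
    drop the link.
    """
    if rng is None:
        rng = np.random.default_rng()
    r_obs = pearson_link(x, y)
    if r_obs is None:
        return None, float("nan"), None
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    zx = (x - x.mean()) / x.std()
    zy = (y - y.mean()) / y.std()
    mat = np.tile(zy, (n_perm, 1))
    rng.permuted(mat, axis=1, out=mat)
    null_r = mat @ zx / n
    hits = int(np.count_nonzero(np.abs(null_r) >= abs(r_obs) - 1e-12))
    p = (1 + hits) / (n_perm + 1)
    null = LinkNull(n_perm=n_perm, null_r=null_r) if keep_null else None
    return r_obs, float(p), null


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# link table and SE-to-gene filter

def link_table(
    regions: Sequence[tuple[str, GenomicInterval]],
    signal: pd.DataFrame,
    expression: pd.DataFrame,
    gene_models: Sequence[GeneModel],
    se_genes: set[str],
    sv_genes: set[str],
    max_dist: int = 500_000,
    n_perm: int = 1000,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Compute the full peak-to-gene link table.

    One row per candidate (peak, gene) pair with r, permutation p, BH FDR
    across all links, TSS distance and the SE/SV annotation flags.  Links
    with undefined correlation (zero variance) are dropped with a logged
    reason.  Samples are aligned on the intersection of the signal and
    expression matrices' columns.
    """
    if rng is None:
        rng = np.random.default_rng()
    shared = [s for s in signal.columns if s in set(expression.columns)]
    if len(shared) < 3:
        raise ValueError("need >= 3 shared samples between signal and expression")
    sig = signal[shared]
    expr = expression[shared]
    pairs = candidate_pairs(regions, gene_models, max_dist)
    rows = []
    for peak_id, gene_id, dist in pairs:
        if gene_id not in expr.index:
            continue
        x = sig.loc[peak_id].to_numpy()
        y = expr.loc[gene_id].to_numpy()
        r, p, _ = permutation_null_p(x, y, n_perm=n_perm, rng=rng)
        if r is None:
            logger.info("link %s-%s dropped: zero variance", peak_id, gene_id)
            continue
        rows.append((peak_id, gene_id, r, p, dist, gene_id in se_genes, gene_id in sv_genes))
    df = pd.DataFrame(
        rows, columns=["peak_id", "gene_id", "r", "p", "distance_to_tss", "in_se", "has_sv"]
    )
    if len(df):
        df["fdr"] = bh_fdr(df["p"].to_numpy())
    else:
        df["fdr"] = pd.Series(dtype=float)
    return df


def se_to_gene_filter(
    links: pd.DataFrame,
    se_genes: set[str],
    sv_genes: set[str],
    fdr_cut: float = 0.05,
    gene_models: Optional[Sequence[GeneModel]] = None,
) -> pd.DataFrame:
    """Ranked SE-to-gene table: FDR < cut AND SE-annotated AND SV-annotated.

    One row per gene (its best-FDR link), sorted ascending by FDR with ties
    broken by |r| descending then gene id; gene coordinates are attached
    when ``gene_models`` is given.
    """
    keep = links[
        (links["fdr"] < fdr_cut)
        & links["gene_id"].isin(se_genes)
        & links["gene_id"].isin(sv_genes)
    ].copy()
    if len(keep):
        keep["abs_r"] = keep["r"].abs()
        keep = keep.sort_values(
            ["fdr", "abs_r", "gene_id", "peak_id"], ascending=[True, False, True, True]
        )
        keep = keep.drop_duplicates("gene_id", keep="first").drop(columns="abs_r")
    if gene_models is not None:
        meta = {
            g.gene_id: (g.symbol, g.location.chrom, g.location.start, g.location.end)
            for g in gene_models
        }
        keep["symbol"] = [meta[g][0] if g in meta else g for g in keep["gene_id"]]
        keep["chrom"] = [meta[g][1] if g in meta else "" for g in keep["gene_id"]]
        keep["start"] = [meta[g][2] if g in meta else -1 for g in keep["gene_id"]]
        keep["end"] = [meta[g][3] if g in meta else -1 for g in keep["gene_id"]]
    return keep.reset_index(drop=True)


# ---------------------------------------------------------------------------
# scatter diagnostics

def least_squares_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Ordinary least-squares line; returns (slope, intercept)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; least-squares slope undefined")
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def lof_scores(points: np.ndarray, k: int = 10, standardize: bool = True) -> np.ndarray:
    """Classic local-outlier-factor scores with k nearest neighbours.

    Axes are z-scored before Euclidean distances (peak signal and
    expression live on incommensurate scales); ties in the k-distance are
    handled by including all equidistant neighbours.  Scores are ~1 in
    homogeneous-density regions and grow for isolated points.  Requires
    n >= k + 1.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2:
        raise ValueError("points must be an (n, d) array")
    n = pts.shape[0]
    if n <= k:
        raise ValueError(f"LOF requires n > k (got n={n}, k={k})")
    if standardize:
        sd = pts.std(axis=0)
        sd[sd == 0] = 1.0
        pts = (pts - pts.mean(axis=0)) / sd
    dist = cdist(pts, pts)
    np.fill_diagonal(dist, np.inf)
    kdist = np.partition(dist, k - 1, axis=1)[:, k - 1]
    neighbors = [np.nonzero(dist[i] <= kdist[i])[0] for i in range(n)]
    lrd = np.empty(n)
    for i in range(n):
        nb = neighbors[i]
        reach = np.maximum(kdist[nb], dist[i, nb])
        lrd[i] = 1.0 / reach.mean()
    lof = np.empty(n)
    for i in range(n):
        nb = neighbors[i]
        lof[i] = (lrd[nb] / lrd[i]).mean()
    return lof


# ---------------------------------------------------------------------------
# SV-expression association

def sv_expression_association(
    expression: pd.DataFrame,
    sv_gene_map: Mapping[str, set[str]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene carrier vs non-carrier expression comparison.

    ``sv_gene_map`` maps gene id -> set of carrier sample ids.  Genes with
    >= 2 carriers and >= 2 non-carriers get a two-sided equal-variance
    t-test; BH across tested genes; status is elevated/decreased by the
    sign of the mean difference at FDR < ``alpha``, else unchanged.
    """
    rows = []
    all_samples = list(expression.columns)
    for gene in expression.index:
        carriers = sv_gene_map.get(gene, set())
        car = [s for s in all_samples if s in carriers]
        non = [s for s in all_samples if s not in carriers]
        if len(car) < 2 or len(non) < 2:
            rows.append((gene, len(car), np.nan, np.nan, 0.0))
            continue
        xv = expression.loc[gene, car].to_numpy()
        yv = expression.loc[gene, non].to_numpy()
        t, p = stats.ttest_ind(xv, yv, equal_var=True)
        rows.append((gene, len(car), float(t), float(p), float(xv.mean() - yv.mean())))
    df = pd.DataFrame(rows, columns=["gene_id", "n_carriers", "t", "p", "mean_diff"])
    tested = df["p"].notna()
    df["fdr"] = np.nan
    if tested.any():
        df.loc[tested, "fdr"] = bh_fdr(df.loc[tested, "p"].to_numpy())
    status = np.full(len(df), "unchanged", dtype=object)
    sig = tested & (df["fdr"] < alpha)
    status[sig & (df["mean_diff"] > 0)] = "elevated"
    status[sig & (df["mean_diff"] < 0)] = "decreased"
    df["status"] = status
    return df
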