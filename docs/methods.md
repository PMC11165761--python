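# Methods

## Coordinate model

All internal coordinates are 0-based half-open `[start, end)`.  BED-family
inputs are read verbatim; VCF `POS`/`POS2` are decremented on read and
incremented on write, while `INFO/END` is used unchanged (the 1-based
inclusive end equals the 0-based position just after the last affected
base, i.e. the second breakend).  Chromosome names are compared after
stripping an optional `chr` prefix, so mixed GRCh38 dialects interoperate;
normalization is configurable off.  Gaps and point-to-interval distances
follow the half-open convention: overlapping or abutting spans have gap 0,
otherwise the gap is the number of bases strictly between the spans.  Sorted
outputs break ties by (chromosome, start, end) for reproducibility.

## Super-enhancer calling

Peaks from one sample are stitched transitively when the inter-peak gap is
at most the stitch distance (default 12,500 bp, the standard rank-ordering
convention; configurable).  TSS exclusion (default off) removes peaks fully
contained within ±`tss_exclusion` of any TSS before stitching.  Stitched
regions are sorted by total signal; both the rank index and the signal are
rescaled to [0, 1], and the cutoff is the signal at the point where a line
of slope 1 is tangent to the scaled curve, computed as the first index
minimizing `scaled_signal − scaled_rank`.  For a convex hockey-stick curve
this is exactly the point where the finite-difference slope crosses 1
scanning from the right (e.g. signals `y = x²` on evenly spaced scaled
ranks cut at scaled rank 0.5).  We compute the tangent point by the
arg-min rather than a literal slope scan because the slope scan degenerates
when the two highest signals are nearly tied (the local slope at the right
edge drops below 1 and the cutoff collapses onto the maximum, labelling
zero super-enhancers); the arg-min form is identical on convex data and
keeps the invariant that the maximal-signal region is super whenever the
signals are not all equal.  Ties in the arg-min resolve toward the lower
signal.  An all-equal-signal input yields zero super-enhancers.  Regions
with signal strictly above the cutoff are super.  Signals are used as
provided (no per-sample normalization) — downstream correlation is
scale-invariant.

## SV consolidation and windows

Within a sample, two calls merge (transitively, via union–find) when their
types match (gate configurable) and both breakpoint distances are at most
`max_dist` (default 1,000 bp) with chromosomes matching positionwise — a
simplified restatement of the usual SURVIVOR merge.  The representative is
the member with the smallest `(bp1.chrom, bp1.pos, bp2.pos)`; merged
records carry the summed support.  Every breakend of every consolidated SV
(both ends by default, including both chromosomes of a translocation; one
recorded position for insertions) is expanded to
`[max(0, pos − flank), pos + flank)` with flank 10 kb, i.e. the 20 kb
region surrounding the breakpoint, read symmetrically.

## Overlap analysis and cohort comparison

An SE region and a breakpoint window overlap when they intersect by at
least 1 bp (partial or complete).  Only super regions enter by default
(typical enhancers selectable).  One record is kept per (SE region, SV)
pair — when both breakends hit the same region the larger overlap wins.
Per-sample SV counts and distinct SE-SV-overlap counts are transformed as
`log2(count + 1)` (zero counts occur) and compared between the two cohort
labels with a two-sided equal-variance Student t-test.  Genes are
associated to overlapped regions when their TSS lies within the region
extended by ±50 kb (configurable; the half-open boundary excludes a TSS at
exactly `end + flank`).

## Peak-to-gene links

The consensus peak matrix merges overlapping-or-abutting peaks pooled over
all samples; a sample's signal for a region is the sum of its peak signals
intersecting it.  Candidate pairs are consensus regions within 0.5 Mb of a
TSS.  For each pair, Pearson's r is computed across shared samples (links
with a zero-variance vector are dropped with a logged reason; Spearman is
deliberately not the default because the analysis fits a straight line).
Significance comes from a per-link label permutation null: y is permuted B
times (default 1,000) with a generator seeded from the run's master seed,
and the two-sided add-one estimate `p = (1 + #{|r_b| ≥ |r|})/(B + 1)`
bounds p away from zero at `1/(B+1)`.  Benjamini–Hochberg step-up across
all links yields the FDR (chosen as the standard procedure for large link
families; adjusted values are monotone, capped at 1, and never below the
raw p).  The SE-to-gene table keeps links with FDR < 0.05 whose gene is
annotated both to a super-enhancer and to an SV, one row per gene (best
FDR; ties by |r| descending then gene id).

Scatter diagnostics: ordinary least squares line, and the classic local
outlier factor with k = 10 — k-distance with all equidistant neighbours
included, reachability distance, local reachability density, LOF = mean
neighbour-to-own lrd ratio — computed after per-axis z-scoring because
peak signal and expression are on incommensurate scales.  LOF requires
n ≥ k + 1.

The SV–expression association labels each gene elevated/decreased/
unchanged from a two-sided equal-variance t-test of carrier vs non-carrier
samples (≥ 2 per arm, else unchanged), BH-adjusted across tested genes at
FDR < 0.05.

## Outlier expression and survival

Per gene, quartiles are computed across the cohort with linear
interpolation (type 7 — the convention is pinned and configurable because
the bound depends on it) and the upper outlier bound is `Q3 + 1.5·IQR`;
only the upper tail is called.  A case is outlier-positive when at least
one gene of the chosen set is an outlier in it.  The Kaplan–Meier
product-limit estimator steps at observed event times with
censored-at-t subjects kept in the risk set; the log-rank test is the
standard unweighted 1-df statistic with hypergeometric variance and a
chi-square tail p.  RFS time is in months; the event flag accepts
recurrence/censored strings or 0/1.

## Synthetic cohort

The generator emulates the cohort structure the pipeline expects, with one
master seed feeding named sub-streams (layout, truth, peaks, SVs,
expression, survival) so outputs are byte-identical per seed.

Defaults (the study conditions): 120 non-CAGA + 40 CAGA samples; a
4 × 50 Mb genome; 200 genes; 600 recurrent enhancer sites, each active per
sample with probability 0.5 and log-normal(0, 1) signal (heavy tail, so
rank-ordering yields a convex hockey stick and a minority of super
regions); ~30 background SVs per sample (Poisson, mixed types); 20 planted
genes with a 3-SD expression effect; outlier-positive case rates 0.4
(non-CAGA) and 0.1 (CAGA), each positive case carrying 2–4 planted events —
the 0.4 rate mirrors the ~40% SE-SV-positive case fraction this kind of
cohort exhibits.  A planted event places 3–8 peaks with 10× log-normal
signal inside a 10 kb span near the gene's TSS (10 kb < 12.5 kb stitch
distance, so the cluster always stitches into a single super-scale region)
and one SV breakpoint within ±8 kb of the cluster centre, so the 20 kb
breakpoint window intersects the SE by construction.  Carrier expression is
set above the non-carriers' `Q3 + 2·IQR` plus a positive half-normal lift;
survival is exponential with baseline hazard 0.02/month multiplied by a
hazard ratio of 3 for positives, with administrative censoring
U(3, 60) months — the simplest model whose log-rank power is analytically
checkable.

What the generator does **not** emulate: read-level noise, copy-number
structure, chromothripsis, 3D-contact data, batch effects between
RNA-seq protocols, and correlated enhancer activity between sites.
Passing recovery tests therefore demonstrates the correctness and power of
the statistical machinery under the planted model, not performance on real
tumours.

## Problem sizes and numerical choices

The seed-replicated experiments use 20 cohorts of 160 samples for recovery
(≥ 90% planted-gene recovery, ≤ 5% false-positive genes at the default
B = 1,000 permutations) and 200 replicates at n = 200 for log-rank power —
sizes chosen so the complete suite runs comfortably on one CPU.  Numerical
details: permutation comparisons use a 1e-12 slack on |r| to absorb
floating-point ties; the add-one p floor makes BH behave sensibly at small
B; LOF matches the reference implementation to 1e-6 relative tolerance on
tie-free data (exact k-neighbour sets can differ under distance ties);
log-rank returns chi2 = 0, p = 1 when the variance term is 0 (identical
groups).  Determinism contract: rerunning any stage or `run-all` with the
same inputs, parameters and seed produces byte-identical files (no
timestamps in outputs; the manifest records analysis parameters, input
checksums, row counts and the seed).

## Known limitations

- The tangent-point cutoff assumes an overall convex rank–signal curve;
  on concave (non-enhancer-like) inputs it falls back to labelling
  everything above the minimum as super rather than failing.
- The consolidation step is O(n²) per sample — appropriate for tens of
  SVs per sample, not for genome-wide call sets of millions.
- Breakend orientation and inversion phase are not modelled; translocation
  mates are taken from `CHR2`/`POS2`-style records rather than BND ALT
  parsing.
- The per-link permutation null is exchangeable-label based; it does not
  model spatial autocorrelation of peak signal along the genome.
- Whether one or both breakends should be windowed is not settled by the
  underlying design; both-ends is the default and one-end is selectable.
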