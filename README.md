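# sesvlink

Integrated analysis of **super-enhancers (SEs)** and **structural variants
(SVs)** in cancer cohorts, with gene-level outlier-expression scoring and
recurrence-free-survival (RFS) stratification.

In lung adenocarcinoma, a sizeable fraction of patients lack clinically
actionable genetic alterations (non-CAGA cases).  One proposed mechanism of
oncogene activation in these tumours is *enhancer hijacking*: a genomic
rearrangement places an active enhancer cluster next to an oncogene (for
example an inversion bringing the *ERBB2* locus ~125 kb from the *HNF1β*
locus, ~1.9 Mb apart in the GRCh38 reference), driving outlier
overexpression without a somatic driver mutation.  `sesvlink` implements the
cohort-scale computational arm of that analysis:

1. **SE calling** — per-sample H3K27Ac peaks are stitched (gap ≤ 12.5 kb),
   stitched regions are ranked by total signal, and the rank–signal curve
   (rescaled to the unit square) is cut where a line of slope 1 is tangent
   to the hockey stick; regions above the cutoff are super-enhancers.
2. **SV windowing** — per-sample SV calls (DEL/DUP/INV/TRA/INS, SV-VCF or
   BEDPE) are consolidated (both breakpoints within 1 kb, same type) and
   each breakend is expanded into the 20 kb window `bp ± 10 kb`.
3. **SE × SV overlap** — ≥ 1 bp intersection between SE regions and
   breakpoint windows; per-sample `log2(count + 1)` frequencies are compared
   between cohorts with a two-sided equal-variance t-test.
4. **Peak-to-gene links** — for consensus peaks within 0.5 Mb of a gene's
   TSS, the Pearson correlation *r* between peak signal and expression
   across samples, a seeded label-permutation *p*-value
   `p = (1 + #{|r_b| ≥ |r|}) / (B + 1)`, and Benjamini–Hochberg FDR across
   links.  **SE-to-gene links** keep genes with FDR < 0.05 that are
   annotated both to an SE and to an SV; scatters are scored with an OLS
   fit and the classic local outlier factor (k = 10).
5. **Outlier + RFS** — a case is outlier-positive when any gene of the set
   exceeds `Q3 + 1.5·IQR` (type-7 quartiles) in that case; RFS is stratified
   by that status with the Kaplan–Meier product-limit estimator and the
   1-df log-rank test.

Because the corresponding patient-level data are access-restricted, the
package ships a first-class **synthetic cohort generator** with planted
ground truth (SE-scale peak clusters + breakpoints + forced outlier
expression + elevated recurrence hazard), so every stage is testable end to
end.

## Worked example

```bash
sesvlink simulate --out cohort --seed 3          # synthetic cohort on disk
sesvlink run-all --cohort cohort --out run --seed 3
```

prints the row counts of every stage, e.g.

```
{
  "links": 29,
  "outlier_calls": 88,
  "overlaps": 19,
  "se_calls": 1337,
  "se_gene_table": 4,
  "windows": 376
}
```

Here `se_gene_table` holds the 4 genes that pass the SE-to-gene filter
(FDR < 0.05, SE- and SV-annotated) — in this run exactly the 4 planted
genes, ranked by FDR with their correlation and max LOF score:

```
peak_id  gene_id  r        p            ...  fdr         max_lof
cp00088  G0033    0.83139  0.000999001  ...  0.00724276  4.66147
cp00011  G0007    0.82607  0.000999001  ...  0.00724276  4.09754
```

Stratifying RFS by outlier status over those genes:

```bash
tail -n +2 run/se_gene_table.tsv | cut -f2 > genes.txt
sesvlink rfs --expr cohort/expression.tsv --clinical cohort/clinical.tsv \
             --gene-set genes.txt --out rfs.tsv
# outlier-positive cases: 4/22; log-rank chi2=5.478, p=0.0193
```

i.e. the 4 outlier-positive cases recur significantly earlier — the planted
hazard ratio is recovered.  The same stages are available in-library via
`sesvlink.analyze_cohort` on in-memory objects.

## Layout

- `src/sesvlink/intervals.py`, `io.py` — 0-based half-open interval model,
  overlap engine, BED/narrowPeak/SV-VCF/BEDPE/TSV readers and writers
- `src/sesvlink/se_caller.py` — stitching and the rank-ordering cutoff
- `src/sesvlink/sv.py` — SV records, consolidation, breakpoint windows
- `src/sesvlink/overlap.py` — SE×SV intersection and cohort comparison
- `src/sesvlink/links.py` — consensus matrix, correlation links,
  permutation null, BH FDR, OLS, LOF, SV-expression association
- `src/sesvlink/survival.py` — IQR outliers, Kaplan–Meier, log-rank
- `src/sesvlink/simulate.py` — synthetic cohort with planted ground truth
- `src/sesvlink/pipeline.py`, `cli.py`, `experiments.py` — orchestration,
  `sesvlink` console script, seed-replicated experiments

See `docs/methods.md` for the statistical model, parameter defaults and
known limitations.
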