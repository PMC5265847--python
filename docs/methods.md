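# Methods

## The model

`omnilevel` implements a multi-omics screen for *abnormally hyperactivated
genes* in a tumor cohort against matched or unmatched normals, followed by a
nested evidence-level prioritization. A gene counts as hyperactivated under
any of five kinds of evidence:

| Code | Evidence | Test | Call rule (defaults) |
|------|----------|------|----------------------|
| GE | higher expression | Wilcoxon signed-rank on paired tumor−normal differences | fold ≥ 2 and BH q ≤ 0.05 |
| CN | copy-number gain | signed-rank on paired gene-level linear copies | fold ≥ 1.2 and q ≤ 0.05 |
| ME | hypomethylation | Wilcoxon rank-sum per platform, two platforms | Δβ ≥ 0.05 and q ≤ 0.05 on **both** platforms |
| MR | loss of miRNA repression | Welch t on log2(x+1) miRNA values | miRNA fold ≥ 2 and q ≤ 0.05; targets of called miRNAs form the MR gene set |
| GM | frequent mutation | Fisher exact test, case vs background cohort | raw p < 0.05 and odds ratio > 1 |

Fold changes are ratios of group means, not means of per-pair ratios —
per-pair ratios are unstable when a normal-sample value approaches zero.
Copy-number folds are computed on the *linear* scale: a segment mean `v` in a
SEG file is `log2(copy/2)` and converts to `2·2^v` before any averaging,
because a 1.2-fold threshold is only meaningful on linear copies.

**Evidence levels.** Only genes that pass the expression screen enter the
scheme (the Level-1 gate). A GE gene supported by `k` of the four other
modalities has exact level `1 + k`. Reported level counts are *nested*: the
Level-k list contains every GE gene with at least `k−1` other calls, so
|L1| ≥ |L2| ≥ … ≥ |L5| on any input. Both the nested lists and the exact
per-gene level are emitted.

## Statistical kernel

The rank tests carry exact null distributions implemented as subset-sum
dynamic programs over doubled midranks (so ties are exact): sign-assignment
enumeration for the signed-rank test (used when the number of non-zero
differences is ≤ 25) and group-labeling enumeration for the rank-sum test
(combined n ≤ 20, tie-free). Larger samples use the classic normal
approximations with tie-corrected variance and a 0.5 continuity correction;
on boundary-size simulations the two paths agree within 10% relative p for
moderate p-values (tested). Zeros are dropped before ranking in the
signed-rank test (the classic Wilcoxon convention); an all-zero input returns
a flagged degenerate p = 1 rather than raising, so genome-wide loops never
abort on constant features. The same convention gives p = 1 for completely
tied rank-sum inputs, and p ∈ {0, 1} for zero-variance t-test inputs.

Fisher's exact test uses the two-sided point-probability rule (sum of
hypergeometric outcomes no more probable than the observed table) and reports
the *sample* odds ratio `a·d / (b·c)` (+∞ when `b·c = 0` with `a·d > 0`).
Benjamini–Hochberg q-values follow the step-up formula
`q_(i) = min_{j≥i} p_(j)·m/j` capped at 1; NaN inputs propagate and are
excluded from `m`. The `t` test defaults to the Welch form (the miRNA groups
are unpaired and unequal-sized); a `student` switch is available.

## Screen-level conventions

- Genes with fewer than 3 usable pairs, a zero normal mean, or identically
  zero paired differences are reported *untested* and excluded from the BH
  denominator. The all-zero-difference case covers copy-number genes whose
  samples were all imputed neutral.
- Segment-to-gene annotation takes the overlap-length-weighted mean of the
  linear copies of every segment touching the gene (1-based inclusive
  arithmetic; weights are overlapping base counts). An unweighted mean is a
  config option; the two differ only when a gene spans unequal overlaps
  (tested). Genes with no covering segment are imputed neutral (copy 2.0)
  and flagged, since "nocnv" segment files omit copy-neutral regions.
- Probe-level beta matrices collapse to gene level by the unweighted mean of
  mapped probes with non-missing values; a gene whose probes are all missing
  in a sample stays missing there.
- Hypomethylation direction is normal-minus-tumor ≥ 0.05: lower tumor
  methylation is read as hyperactivation evidence.
- The mutation screen's background cohort *includes* the case samples by
  default, matching the worked-example arithmetic (42/54 cases vs 308/992
  cohort-wide); a disjoint background simply means passing a background
  matrix without the cases. The default variant filter drops `Silent` calls;
  `all` or an explicit class set is accepted. The GM call uses the raw
  Fisher p (no FDR), with an optional flag that adds BH q for reporting.
- Chromosome names are matched verbatim; a SEG/gene-model mismatch yields
  neutral imputation plus a logged warning, never an error.

## Synthetic studies

`simulate.generate_study` produces a complete seeded study emulating a
TCGA-like cohort: 55 expression pairs, 53 copy-number pairs, 32/27 and 23/47
methylation samples on two platforms, 53/103 miRNA samples, and 54 case
samples inside a 992-sample mutation cohort. All randomness derives from one
seed through independent child streams per modality.

Distributions: expression and miRNA values are log-normal (per-feature
baseline log2 mean ~ N(8, 2²), within-group log2 noise sd 0.5; planted tumor
means shifted by log2(fold), default fold 4). Copy-number segments are
emitted per sample from a toy genome (10 kb genes, 10 kb spacing, 200 genes
per chromosome): planted genes sit inside amplified segments at linear copy
3.0 (log2 value 0.585), everything else is neutral, and each emitted segment
mean carries N(0, 0.05²) noise. With noise set to zero, re-deriving gene
copies through `map_segments_to_genes` returns the planted values exactly
(tested). Beta values are Beta-distributed around gene-level means
(baseline ~ U(0.3, 0.7) shared across platforms, concentration 60, planted
tumor depression Δβ = 0.2) with 2–5 probes per gene per platform. Mutations
are Bernoulli per gene × sample: planted genes at 0.4 in cases vs 0.05
elsewhere; all other genes at a background rate of 0.002, the empirical
average per-gene somatic rate implied by ~40 exome mutations over ~20k genes
in breast tumors. A small extra rate (0.002) of `Silent` calls exercises the
variant filter.

Planted genes follow a deterministic overlap plan (`plan_planted`): a core
block shared by GE/CN/ME, a shifted MR window overlapping GE, and a small
GM core slice, each modality topped up with fresh genes to exactly
`n_planted` (default 100 per modality at 2,000 genes). The plan yields
planted genes at every level from 1 to 4 (and 5 when the windows align),
and the ground-truth table records each planted feature, its effect, and
its expected level.

**What the generator does not emulate:** batch effects, probe-specific
biases, gene-length/GC confounds, subclonal copy-number mixtures,
mutation-signature structure, correlated genes, or miRNA regulatory
feedback. Passing recovery tests therefore demonstrates that the pipeline's
arithmetic and calling logic are correct under its stated model — not that
the thresholds are optimal for any particular real cohort.

## Problem sizes used in the checks

The recovery benchmark runs the full reference study (2,000 genes,
reference cohort shapes, 100 planted per modality) at three replicate
seeds and pools true/false calls across replicates before computing
sensitivity and false-discovery proportion — pooling is the natural
estimator for these stochastic proportions at ~100 planted features per
replicate. Null calibration uses 50 reduced all-null studies (500 genes; 20
expression/CNV pairs; 15/15 and 12/20 methylation; 20/40 miRNA; 30 cases in
a 200-sample mutation cohort), a size at which each replicate still
exercises every code path. The exact-test oracle checks run 1,000 random
instances with n ≤ 8 against full enumeration, and segment mapping is
checked against a per-base brute-force oracle on 200 random ≤ 10 kb toy
genomes.

## Known limitations and open choices

- The mutation screen intentionally uses a raw p threshold (no FDR): across
  very large gene universes it will admit false calls in proportion to the
  number of genes with ≥ 2 case mutations. `gm_use_fdr` reports BH q for
  users who want stricter control.
- Gene identifiers are harmonized across modalities by exact symbol match;
  no alias database is shipped.
- The enrichment universe defaults to the set of genes tested in the
  expression screen; it is an explicit argument everywhere.
- Exact-vs-approximate switch points (25 for signed-rank, 20 for rank-sum)
  are conventional, not optimized; both paths are exposed via `method=` for
  auditing.
- Levels are computed on called sets only; a gene missing from a platform
  (e.g. absent on one methylation chip) can never be called in ME, which is
  conservative by design.
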