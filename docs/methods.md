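# Methods

## Coordinate conventions

All intervals are BED-style: 0-based, half-open `[start, end)`. Two
intervals overlap iff they share at least one base; abutting intervals
do not overlap and have gap distance 0 (`subject.start - query.end` for
disjoint half-open intervals). BEDPE loop anchors follow the same
convention. A gene's TSS is its strand-aware start (leftmost base on
`+`, rightmost on `-`).

## Cell-averaged log fold-change

The per-gene contrast statistic is deliberately a point estimate, not a
hypothesis test: each cell is scaled to a fixed library size (default
10,000 counts), per-gene means are taken within (cell type, condition),
and

    logFC(g) = log2( (mean_num(g) + c) / (mean_den(g) + c) )

with pseudocount `c = 1` on the normalized scale (configurable). Log
base 2 is recorded in the output metadata. The estimator is exactly
antisymmetric in the condition pair and invariant to common depth
rescaling. The pseudocount bounds logFC for dropout genes at the cost
of shrinkage toward zero when normalized means are of order `c`; since
the loop statistic below is rank-based within a chromosome-wide null of
the *same* shrunken values, this shrinkage does not bias loop
percentiles.

## Loop statistic and sliding-window null

For a loop with `L` member genes (genes whose TSS lies inside the loop
span, which runs from the start of anchor A to the end of anchor B),
the loop score is the arithmetic mean of the member genes' logFC. Its
null distribution is the multiset of means over **every** window of `L`
consecutive genes on the same chromosome, in ascending-TSS order —
`n = G − L + 1` windows for `G` scored genes, retained with
multiplicity, never wrapping around chromosome ends. The percentile is

    P = 100 · #{window means ≤ loop mean} / n

with ties counted (weak inequality, matching the empirical CDF). The
null conditions on chromosome, loop size, and the global logFC
distribution, so percentiles are invariant under adding any constant to
all logFC values.

Numerical/design choices:

* **Own window included.** The loop's own gene window is a member of
  its null, flooring the percentile at `100/n`; this makes degenerate
  inputs well behaved (all-equal logFC gives percentile 100 everywhere,
  never 0/0). A flag removes the own window for users who prefer a
  leave-one-out null.
* **Minimum loop size** `min_genes = 2` (loops with fewer scored member
  genes are skipped with a logged reason, not an error): a 1-gene
  "loop average" is just the gene itself and its null the marginal
  logFC distribution.
* Nulls are cached per (chromosome, L); cached and uncached scoring are
  byte-identical.
* Output rows are deterministically ordered by (chromosome, span
  start); ties anywhere are broken lexicographically.
* Optional two-sided empirical p-values, `p = 2·min(r, n+1−r)/(n+1)`
  with `r` the weak rank, plus Benjamini–Hochberg adjustment across
  scored loops, are off by default — the percentile itself is the
  primary representation.

## Loop classification

A loop is **direct** when a differential peak overlaps one of its
boundary domains (the anchor interval, optionally extended by a
symmetric flank, default 0 bp — supply the flank when your BEDPE
carries bare anchor points rather than full boundary domains);
**indirect** when its span overlaps (≥ 1 bp) the span of at least one
direct loop; **unaffected** otherwise. The labels are mutually
exclusive with precedence direct > indirect, and indirectness is
computed against the final direct set only — it does not chain through
indirect loops, so a single pass is a fixed point. Fractions are
computed in exact rational arithmetic and always partition the loop
set.

Differential peaks between two conditions use a simple presence rule: a
peak of set A is A-specific when no peak of B overlaps it by at least
`min_overlap` bp (default 1). The overlap threshold is exposed because
no canonical reciprocal-fraction rule exists for this comparison.

## Peak-to-gene assignment and cell QC

Peaks are assigned to the nearest gene *body* (strand ignored) within
25 kb by gap distance, 0 when overlapping; ties break to the
lexicographically smallest gene id for reproducibility. scATAC cell QC
passes a barcode iff fragments > 1000 **and** promoter ratio > 0.2,
both strict, so barcodes sitting exactly on a threshold fail.

## Cut-site meta-profiles

Fragments contribute their two transposase cut sites (start and
end − 1), not whole-fragment coverage (a coverage mode exists behind a
flag). Sites reduce to their interval midpoint; counts are binned at
10 bp over a ±1 kb window (window must divide evenly into bins), and
minus-strand site rows are reversed so all rows read 5'→3' relative to
the site. Overlapping site windows count fragments once per site
(row-wise independence, matching per-site heatmap semantics). The
summary profile is the per-bin mean over sites, smoothed by a centered
moving average (odd span, truncated at the edges). "Flatness" of a
profile, where asserted in the tests, is judged by an aggregate
chi-square over bins within 3 standard errors of its expectation under
uniformity — a per-bin 3σ criterion would reject truly uniform data
about half the time purely through multiplicity across 200 bins.

## Beta / Q-Q diagnostic

The observed percentiles (divided by 100) are compared against a Beta
distribution fitted to the *bulk* of their distribution: the sample is
truncated to its own [25th, 75th] percentile range, min-max rescaled
onto [0, 1], and Beta(α, β) is fitted by the method of moments
(`k = m(1−m)/v − 1`, `α = mk`, `β = (1−m)k`). Truncation to the IQR
makes the fit insensitive to the dysregulated tails, which is the point
of the diagnostic: tail departures from the fitted Beta's quantiles (at
plotting positions `(i − 0.5)/n`) flag coordinated loops. Uniform
percentiles give α ≈ β ≈ 1. Degenerate inputs (fewer than 8 distinct
values, or zero variance inside the IQR) raise an error rather than a
meaningless fit. The alternative reading of "fit to the inter-quartile
range" — choosing (α, β) to match the sample's quartiles — was
considered and not implemented; the method-of-moments-on-truncated-data
rule is deterministic and parameter-free.

## Ligand–receptor pairing

For each (ligand, receptor) pair, the ligand is evaluated in a sender
population and the receptor in a receiver population: mean normalized
expression plus detection fraction (cells with count > 0). A pair is
called expressed-in-both when both detection fractions reach
`min_frac = 0.10` (configurable); the threshold rule is surfaced in the
output because "expressed" has no canonical single-cell definition.
Pairs referencing genes absent from the matrix are reported as skipped,
not fatal.

## Synthetic-data generator

The generator emulates the structure the analysis assumes, as the
default study conditions:

| parameter | default | meaning |
|---|---|---|
| `n_chroms` × `genes_per_chrom` | 4 × 750 | evenly spaced genes, 50 kb apart, 5 kb bodies, alternating strands |
| `n_loops`, `genes_per_loop` | 500, 5 | non-overlapping loops over consecutive genes, 1 kb anchors flanking the first/last member gene |
| `n_effect_loops`, `fold_change` | 50, 2.0 | coordinated multiplicative KO effect on all member genes (optional per-gene jitter) |
| `n_cells_per_condition` | 200 | plus optional extra-cell-type cells for pairing studies |
| `mean_depth` | 30,000 | ≈ 10 mean counts/gene; per-gene base means log-normal (σ = 0.5), floored at `min_gene_mean = 5` so every gene stays detectable |
| `dispersion` (NB size θ) | 0.5 | counts ~ NB(μ, θ), variance μ + μ²/θ |
| `anchor_peak_loss_frac` | 0.5 | KO retention probability 1 − 0.5 per anchor peak; effect-loop anchors always lost; background peaks shared and placed clear of anchors |
| `fragment_enrichment` | 5 | a fraction 1 − 1/enrichment of fragment midpoints is Gaussian (sd 50 bp) at site centers, the rest uniform; 100 bp fragments |

Every generator stream is keyed on `(seed, stage)`, so the same
configuration is byte-identical across runs, and emitted files
round-trip through the package readers without loss.

What the generator does **not** emulate — and hence what passing tests
do not show about real data: realistic gene density and loop-size
heterogeneity (real loops share genes and nest; synthetic loops are
disjoint, so the *indirect* class is structurally absent from the
default study and exercised only by targeted unit tests), ambient RNA,
doublets, batch effects, cell-type mixtures beyond a single optional
extra population, mappability artifacts, and peak-calling noise. The
calibration and recovery results characterize the statistic under its
own model, not the upstream assays.

## Problem sizes

The default study (3,000 genes, 400 cells, 500 loops) fits the full
pipeline in a few seconds on one CPU; the test suite's exact-oracle
checks use up to 60 genes and 10 loops per instance (100–200 random
instances), where brute-force enumeration is trivially affordable. The
exact-equality oracle tests draw logFC values as dyadic rationals
(k/64) so window means are exactly representable and tie counting is
unambiguous in floating point regardless of summation order.

## Known limitations

* The logFC estimator is a pseudocounted mean ratio, not a
  hurdle/mixed model; with very low normalized means its shrinkage is
  substantial (visible in the recovery study, where a true log2 FC of
  1.0 measures ≈ 0.7–0.8). Percentiles are unaffected, absolute logFC
  values should be read with this in mind.
* The sliding-window null treats genes as exchangeable along the
  chromosome; local co-expression structure unrelated to loops (e.g.
  shared enhancers outside loops) will inflate apparent coordination.
* Loop classification depends on upstream peak calls; the differential
  rule here is presence/absence by overlap, not a count-based test.
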