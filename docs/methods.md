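# Methods

## Coordinates and gene models

All intervals are 0-based half-open internally (BED convention); GTF input
(1-based closed) is converted on read. Each gene is reduced to one
representative transcript — the longest by genomic span, ties broken by
transcript id — whose strand-aware TSS (first transcribed base: `start` on
`+`, `end − 1` on `−`) anchors every window. The genome is partitioned into
`promoter_proximal > exon > intron > intergenic` with ties between genes
broken lexicographically by gene id, so the partition is a deterministic
function of the annotation. The promoter-proximal window is 5 kb upstream to
1 kb downstream of the TSS by default (a common peak-annotation convention);
both extents are configurable, and category fractions of annotated peaks are
sensitive to this choice.

## Occupancy matrices

Reads are assigned to exactly one bin by fragment midpoint — never by
overlap — so bin counts are a partition of the in-window reads and no read is
double-counted at bin edges. No fragment extension or shift model is applied;
fragments are used as aligned. Defaults: ±5 kb windows, 100 bp bins
(100 bins per condition). Replicates are pooled by summing raw counts and
library sizes before rpm normalization (`x · 10⁶ / N`), which is exactly
invertible given the stored library size.

Two geometric caveats are inherent to the half-open, strand-agnostic window
`[tss − f, tss + f)`: (i) the "sum of matrix ≤ library size" identity assumes
non-overlapping gene windows (a read inside two windows is counted in both
rows); (ii) reflecting reads and gene model reproduces the profile row
exactly for midpoints interior to a bin, but midpoints within one base of a
bin boundary may switch bins because reflection shifts the window anchor by
one base.

## Loss calling

Per gene, the WT and KO rpm profiles are concatenated (200 features) and
clustered with Lloyd's k-means under k-means++ seeding; each run keeps the
best of `n_restarts = 4` starts by within-cluster sum of squares, and an
empty cluster arising mid-iteration is re-seeded at the point farthest from
its assigned centroid. Everything is deterministic given the seed.

The promoter score is the mean rpm over the bins fully inside
±`core_halfwidth` (default 500 bp) of the TSS; the depletion ratio is
`(ko + ε)/(wt + ε)` with ε = 0.1 rpm so that empty signal has ratio 1.
`k = 10` clusters are used by default (enough to separate
promoter-loss / retained / background shapes without fragmenting them);
consensus is taken over `n_consensus = 10` runs with consecutive seeds and a
gene needs support ≥ 0.8 plus passing gene-level gates (`wt ≥ τ_wt`,
`ratio ≤ ρ = 0.25`). τ_wt defaults to the 60th percentile of nonzero WT
promoter scores: it is a *separation* threshold between background and
promoter-marked genes, and assumes the marked fraction of genes is below
~40%. Rows are deliberately not per-row standardized — absolute occupancy
carries the loss information that z-scoring would erase. Raising ρ can only
grow the called set, raising τ_wt can only shrink it (monotone gates).

## Differential expression

The DE stage is intentionally minimal: counts are pooled within condition and
the pooled KO count `k` out of `n = k + w` is tested against
`p₀ = L_KO/(L_KO + L_WT)` with a two-sided exact binomial (minimum-likelihood
rule). Fold changes are log₂ ratios of per-million rates with a 0.5 rpm-unit
pseudocount, so all-zero genes are null by construction. BH q-values control
FDR at α = 0.05.

Effective library sizes `L` default to a composition-robust estimator: for
each sample, the log-ratios of its counts to a per-gene geometric-mean
reference are summarized by the center of the shortest interval containing
half the genes (a mode-seeking location), refined by a one-step mean within
2.5 robust SDs. This matters because the biology studied here is one-sided —
nearly all changes are up in the KO — and any median or symmetrically trimmed
mean of the log-ratios is then biased by the changed block, which converts
into a systematic `p₀` error and false "down" calls at high-expression genes.
Column sums can still be supplied explicitly as `libsizes`.

Treating replicates as pooled makes the test anti-conservative on
biologically dispersed data; it captures sampling noise only and is not a
substitute for a dispersion-modeling DE method on real experiments.
Externally computed DE tables (gene, log2fc, pvalue, qvalue) are accepted and
bypass the stage.

## Set statistics and network

Set associations use the two-sided Fisher exact test (point-probability rule
for "as extreme") over the universe of all loaded gene models; the same test,
BH-corrected across collections, powers gene-set enrichment against
user-supplied GMT collections. The drafted network is a star: one repression
edge from the regulator to every gene with `loss ∧ bound ∧ up` evidence
("bound" defaults to promoter-proximal peaks only; gene-body binding can be
included via `restrict_to`). log₂ fold change travels as the
`expression_delta` node attribute. The construction is idempotent and
invariant to evidence-row order.

## Synthetic data generator

The generator emulates the statistical structure of the WT/KO erythroblast
experiment, not its sequences. One chromosome (12 Mb) carries 500 equally
spaced genes on alternating strands; 40% are planted loss genes. ChIP
fragments (75–700 bp, uniform) have midpoints drawn from three components:

* uniform background (0.002 reads/bp);
* 300 stable 5 kb enrichment domains placed away from all TSS windows, with
  identical rates in WT and KO. These stand in for the broad gene-body and
  intergenic portion of the mark that the knockout does not remove. They are
  not cosmetic: they keep the differential promoter signal a minority of the
  library, so rpm normalization leaves the KO/WT promoter ratio near the
  planted depletion. Without them, losing the promoter reads shrinks the KO
  library itself and the normalized ratio has a floor (~0.29 at these
  settings) above the ρ = 0.25 gate;
* per-gene Gaussian promoter enrichment (sd = flank/5 = 1 kb, expected 300
  fragments/gene in WT). Loss genes have it centered on the TSS and
  multiplied by 0.1 in KO; a further 10% of non-loss genes carry the same
  enrichment shifted 3 kb into the gene body in both conditions — a retained,
  non-promoter pattern that gives the clustering a third shape without
  entering the promoter-score percentile that sets τ_wt.

Mtf2-like peaks: each loss gene gets a promoter peak with probability 0.49,
other genes with probability 0.05; decoy peaks are placed outside promoter
windows so promoter peaks are 22% of all peaks. CGIs (±300 bp of the TSS)
co-occur with loss promoters at 0.985 and elsewhere at 0.05. RNA counts are
negative binomial with log-normal baselines (median 100, σ_log = 1) and two
replicates per condition; each loss-and-bound gene changes with probability
0.9 (others 0.05), changes are up with probability 0.98, effect = 2 log₂
units. Dispersion defaults to 0.002 — tightly sorted-population,
near-technical replicates — chosen for coherence with the pooled-binomial DE
stage, which assumes sampling noise only; with realistic biological
dispersion (0.01–0.1) that test would not control FDR and a
dispersion-modeling method should be used instead.

Every stage draws from its own generator seeded by `(seed, stage)`, so
outputs are byte-reproducible and independently regenerable. What passing on
these data does **not** show: robustness to mappability/GC artifacts,
fragment-size bias, overlapping genes, alternative TSSs, replicate batch
effects, or biological dispersion — none of which are modeled.

## Problem sizes and numerics

Default desk-scale sizes (500 genes, ~0.4 M fragments per condition, 10×4
k-means runs on a 500×200 matrix) complete in seconds; the null-control
dataset uses 2000 genes. k-means convergence tolerance is 1e-6 on the
objective with at most 100 iterations; Fisher p-values agree with exact
rational enumeration to <1e-12 for universes ≤200 (verified in tests);
fractions reported from peak annotation are exact ratios of counts. Degenerate
inputs are defined rather than accidental: zero-length reads are dropped and
logged, all-zero genes are non-significant, an empty evidence intersection
yields an empty network, and an empty significant set reports
`fraction_up = 0` by convention.
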