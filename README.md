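# prc2net

Analysis pipeline for a question in erythroid epigenomics: when the PRC2
accessory protein **Mtf2** is knocked out, where does the repressive histone
mark **H3K27me3** disappear, which of those genes does Mtf2 itself bind, which
become de-repressed, and what regulator→target network do those three lines of
evidence draft together?

The package is written for computational biologists integrating WT-vs-KO
ChIP-seq and RNA-seq: it takes gene models, aligned ChIP reads, peak calls and
RNA count tables, and produces promoter-occupancy matrices, a loss-gene set,
peak annotations, a differential-expression table and a repression network —
plus a synthetic-data generator with planted ground truth so every stage can
be validated quantitatively.

## Method

1. **TSS-centered occupancy.** For each gene the window `[tss − f, tss + f)`
   (default f = 5 kb) is split into `2f/w` bins (w = 100 bp); each ChIP
   fragment is counted once, in the bin containing its midpoint, with
   minus-strand rows reversed so bin 0 is always upstream. Matrices are
   depth-normalized to rpm: `x → x · 10⁶ / N` for library size N.
2. **Consensus loss calling.** WT and KO profiles are stacked per gene and
   clustered with k-means (Lloyd + k-means++, best of several restarts by
   within-cluster sum of squares), repeated over `n_consensus` seeds. A
   cluster is a *loss* cluster when its centroid satisfies
   `mean_WT(core) ≥ τ_wt` and `(mean_KO + ε)/(mean_WT + ε) ≤ ρ` over the core
   bins (±500 bp around the TSS). A gene is called a loss gene when it sits in
   loss clusters in ≥ `min_support` of runs **and** its own promoter scores
   pass the same gates. By default τ_wt is the 60th percentile of nonzero WT
   promoter scores, ρ = 0.25, ε = 0.1 rpm.
3. **Peak annotation.** The genome is partitioned into
   promoter-proximal / exon / intron / intergenic (precedence in that order;
   promoter = 5 kb upstream to 1 kb downstream of the TSS, strand-aware), and
   each peak is labeled by the category at its summit.
4. **Differential expression.** Counts are pooled within condition and the
   pooled KO count is tested against the KO library share with a two-sided
   exact binomial test; effective library sizes come from a
   composition-robust (mode-seeking) log-ratio estimator;
   Benjamini–Hochberg q-values control FDR at α = 0.05.
5. **Network drafting.** Gene sets are compared with the two-sided Fisher
   exact test over the gene-model universe, and the network is the star
   `Mtf2 ⊣ g` for every gene g with `loss ∧ bound ∧ up` evidence, carrying
   log₂ fold change as a node attribute.

## Worked example

```bash
prc2net run-all --outdir run --seed 7
```

simulates the default synthetic study (500 genes on a 12 Mb chromosome, 40%
planted loss genes) and runs every stage. The final line (also written to
`run/report.json`) is:

```json
{"bound_given_loss_fraction": 0.5053763440860215,
 "cgi_overlap_fraction": 0.989247311827957,
 "cgi_overlap_p": 7.994139138989021e-106,
 "fraction_up": 0.9512195121951219,
 "n_genes": 500, "n_loss_genes": 186,
 "n_significant_q": 123, "n_significant_rawp": 140,
 "network_size": 82,
 "promoter_peak_fraction": 0.22011385199240988}
```

Reading: 186 genes lose promoter H3K27me3 in the KO; 50.5% of them are bound
by Mtf2 at the promoter; 22.0% of all Mtf2 peaks sit at promoters; 95.1% of
significantly changed genes are up in the KO; 98.9% of loss genes have a CpG
island at the promoter (Fisher p ≈ 8e-106); and the three-way evidence
intersection drafts an 82-gene repression network. Against the generator's
planted truth this run has loss-call precision 1.00 and recall 0.93.

Each stage is also exposed as a library function and as a subcommand
(`simulate`, `matrix`, `cluster`, `annotate`, `de`, `grn`, `enrich`) for use
on real data (BED12/GTF gene models, BED6 reads, narrowPeak peaks, count
TSVs, GMT gene sets).

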