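"""Synthetic single-chromosome datasets with planted, machine-readable truth.

The generator emulates the statistical structure of a WT-vs-knockout
erythroblast multi-omic experiment:

* a toy genome of equally spaced genes on alternating strands;
* H3K27me3-like ChIP fragments: a uniform genomic background, broad stable
  enrichment domains placed away from TSS windows (standing in for the
  retained gene-body/intergenic portion of a broad histone mark, and keeping
  library composition realistic so depth normalization does not distort
  promoter ratios), and Gaussian promoter-centered enrichment at "marked"
  genes.  In the KO condition the promoter enrichment of planted loss genes
  is multiplied by a depletion factor while everything else is unchanged;
  a small set of genes carries stable enrichment shifted into the gene body
  in both conditions (a retained, non-promoter pattern);
* regulator (Mtf2-like) peak calls: promoter peaks preferentially on loss
  genes, plus gene-body/intergenic decoys emitted so promoter peaks are a
  configurable minority of all peaks;
* a CGI track co-occurring with loss-gene promoters at high frequency;
* negative-binomial RNA counts in which planted expression changes are
  biased toward loss-and-bound genes and almost all of them are up in KO.

Everything is deterministic given the seed: each stage draws from its own
``numpy`` generator derived from ``(seed, stage tag)``, so regenerating one
output never perturbs another.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .gene_annotation import GeneModel, promoter_window, tss_window
from .peak_integration import Peak
from .signal_matrix import ReadInterval

log = logging.getLogger(__name__)

# stage tags for seed derivation
_TAG_GENOME, _TAG_WT, _TAG_KO, _TAG_PEAKS, _TAG_COUNTS = range(5)


@dataclass(frozen=True)
class SimulationParams:
    """Study conditions for one synthetic dataset.

    Rates and fractions are chosen to mirror the structure of the real
    experiment this package targets: ~40% of genes carry promoter H3K27me3
    that the knockout depletes tenfold, about half of loss genes are bound by
    the regulator at the promoter, promoter peaks are ~22% of all peaks, CGIs
    co-occur with loss promoters at 98.5%, and ~98% of planted expression
    changes are up in KO.
    """

    n_genes: int = 500
    chrom: str = "chrS"
    chrom_length: int = 12_000_000
    flank: int = 5000
    gene_length: int = 2000
    loss_fraction: float = 0.4
    body_marked_fraction: float = 0.1  # of non-loss genes; stable, TSS-offset pattern
    body_offset: int = 3000
    bound_fraction_given_loss: float = 0.49
    bound_fraction_given_noloss: float = 0.05
    promoter_peak_share: float = 0.22
    cgi_cooccurrence: float = 0.985
    cgi_background_rate: float = 0.05
    cgi_halfwidth: int = 300
    de_up_fraction: float = 0.98
    de_rate_target: float = 0.9  # P(expression change | loss and bound)
    de_rate_background: float = 0.05
    effect_log2fc: float = 2.0
    baseline_log_mean: float = math.log(100.0)
    baseline_log_sd: float = 1.0
    nb_dispersion: float = 0.002
    reads_per_condition: int | None = None  # optional WT-expectation rescale
    fragment_length_range: tuple[int, int] = (75, 700)
    peak_enrichment: float = 300.0  # expected promoter fragments per marked gene (WT)
    depletion: float = 0.1  # KO promoter rate multiplier at loss genes
    background_rate: float = 0.002  # uniform background reads per bp
    stable_domain_count: int = 300
    stable_domain_width: int = 5000
    stable_domain_rate: float = 0.1  # reads per bp inside a stable domain
    promoter_up: int = 5000  # annotation window used to place decoy peaks
    promoter_down: int = 1000
    seed: int = 0

    def __post_init__(self):
        for name in ("loss_fraction", "body_marked_fraction", "bound_fraction_given_loss",
                     "bound_fraction_given_noloss", "promoter_peak_share",
                     "cgi_cooccurrence", "cgi_background_rate", "de_up_fraction",
                     "de_rate_target", "de_rate_background", "depletion"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {v}")
        lo, hi = self.fragment_length_range
        if not (0 < lo <= hi):
            raise ValueError("fragment_length_range must satisfy 0 < lo <= hi")
        if self.n_genes > 0 and self.chrom_length // self.n_genes < 2 * self.flank:
            raise ValueError(
                f"chrom_length {self.chrom_length} cannot pack {self.n_genes} "
                f"non-overlapping +-{self.flank} bp TSS windows")
        if self.n_genes > 0 and self.chrom_length // self.n_genes < 2 * (self.flank + self.body_offset):
            raise ValueError("gene spacing too tight for the body-shifted pattern")

    def _rng(self, tag: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, tag])

    def _depth_scale(self) -> float:
        """Rescale factor so expected WT reads match reads_per_condition."""
        if self.reads_per_condition is None:
            return 1.0
        n_marked = round(self.loss_fraction * self.n_genes) + round(
            self.body_marked_fraction * (self.n_genes - round(self.loss_fraction * self.n_genes)))
        expected = (self.background_rate * self.chrom_length
                    + self.stable_domain_count * self.stable_domain_width * self.stable_domain_rate
                    + n_marked * self.peak_enrichment)
        return self.reads_per_condition / expected if expected > 0 else 1.0


@dataclass(frozen=True)
class GroundTruth:
    """Planted gene sets against which every pipeline stage can be scored."""

    loss_genes: frozenset[str]
    bound_genes: frozenset[str]
    cgi_genes: frozenset[str]
    up_genes: frozenset[str]
    down_genes: frozenset[str] = frozenset()

    def to_json(self, path: str | Path) -> None:
        payload = {k: sorted(getattr(self, k)) for k in
                   ("loss_genes", "bound_genes", "cgi_genes", "up_genes", "down_genes")}
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(**{k: frozenset(v) for k, v in d.items()})


@dataclass(frozen=True)
class GenomeLayout:
    """The generated gene models plus the planted chromatin structure."""

    genes: tuple[GeneModel, ...]
    cgi_intervals: tuple[tuple[str, int, int], ...]
    loss_genes: frozenset[str]
    body_genes: frozenset[str]  # stable, body-shifted enrichment
    stable_domains: tuple[tuple[int, int], ...]
    params: SimulationParams


def generate_genome(params: SimulationParams) -> GenomeLayout:
    """Equally spaced alternating-strand genes, planted loss set, CGI track.

    Loss genes are drawn without replacement (exactly
    ``round(loss_fraction * n_genes)`` of them); CGIs are placed over a loss
    gene's promoter with probability ``cgi_cooccurrence`` and over other
    promoters at ``cgi_background_rate``.  Stable broad enrichment domains
    are placed uniformly outside all +-flank TSS windows.
    """
    p = params
    rng = p._rng(_TAG_GENOME)
    if p.n_genes == 0:
        return GenomeLayout((), (), frozenset(), frozenset(), (), p)
    spacing = p.chrom_length // p.n_genes
    width = len(str(p.n_genes))
    genes = []
    for i in range(p.n_genes):
        tss = spacing * i + spacing // 2
        strand = "+" if i % 2 == 0 else "-"
        if strand == "+":
            start, end = tss, tss + p.gene_length
        else:
            start, end = tss - p.gene_length + 1, tss + 1
        exon_len = min(500, p.gene_length // 3)
        exons = ((start, start + exon_len), (end - exon_len, end))
        genes.append(GeneModel(f"g{i:0{width}d}", p.chrom, strand, start, end, exons))

    n_loss = round(p.loss_fraction * p.n_genes)
    loss_idx = np.sort(rng.choice(p.n_genes, size=n_loss, replace=False))
    loss = frozenset(genes[i].gene_id for i in loss_idx)
    nonloss_idx = np.setdiff1d(np.arange(p.n_genes), loss_idx)
    n_body = round(p.body_marked_fraction * len(nonloss_idx))
    body_idx = np.sort(rng.choice(nonloss_idx, size=n_body, replace=False)) if n_body else np.array([], int)
    body = frozenset(genes[i].gene_id for i in body_idx)

    cgis = []
    for g in genes:
        prob = p.cgi_cooccurrence if g.gene_id in loss else p.cgi_background_rate
        if rng.random() < prob:
            lo = max(0, g.tss - p.cgi_halfwidth)
            hi = min(p.chrom_length, g.tss + p.cgi_halfwidth)
            cgis.append((p.chrom, lo, hi))

    windows = np.array([tss_window(g, p.flank) for g in genes])
    domains = _place_domains(rng, p, windows)
    return GenomeLayout(tuple(genes), tuple(cgis), loss, body, domains, p)


def _place_domains(rng: np.random.Generator, p: SimulationParams,
                   windows: np.ndarray) -> tuple[tuple[int, int], ...]:
    if p.stable_domain_count == 0:
        return ()
    w_starts = windows[:, 0]
    w_ends = windows[:, 1]
    out = []
    attempts = 0
    limit = p.stable_domain_count * 1000
    while len(out) < p.stable_domain_count:
        attempts += 1
        if attempts > limit:
            raise ValueError("cannot place stable domains outside TSS windows; "
                             "genome too densely packed")
        s = int(rng.integers(0, p.chrom_length - p.stable_domain_width))
        e = s + p.stable_domain_width
        i = np.searchsorted(w_starts, e, side="left")
        if i > 0 and (w_ends[:i] > s).any():
            continue
        out.append((s, e))
    return tuple(out)


def simulate_chip_reads(layout: GenomeLayout, condition: str) -> list[ReadInterval]:
    """ChIP fragments for one condition, sorted by coordinate.

    Fragment midpoints: uniform background + stable domains (identical rates
    in both conditions) + per-marked-gene Gaussians centered on the TSS with
    sd ``flank/5`` (loss genes) or offset into the gene body (retained
    pattern).  In KO the loss-gene promoter rate is multiplied by
    ``depletion``.  Fragment lengths are uniform in ``fragment_length_range``.
    """
    if condition not in ("WT", "KO"):
        raise ValueError(f"condition must be WT or KO, got {condition!r}")
    p = layout.params
    rng = p._rng(_TAG_WT if condition == "WT" else _TAG_KO)
    scale = p._depth_scale()
    L = p.chrom_length
    mids: list[np.ndarray] = []

    n_bg = rng.poisson(p.background_rate * L * scale)
    mids.append(rng.integers(0, L, size=n_bg))

    for (s, e) in layout.stable_domains:
        n = rng.poisson(p.stable_domain_rate * (e - s) * scale)
        mids.append(rng.integers(s, e, size=n))

    sd = p.flank / 5.0
    for g in layout.genes:
        if g.gene_id in layout.loss_genes:
            center = g.tss
            rate = p.peak_enrichment * (p.depletion if condition == "KO" else 1.0)
        elif g.gene_id in layout.body_genes:
            center = g.tss + (p.body_offset if g.strand == "+" else -p.body_offset)
            rate = p.peak_enrichment
        else:
            continue
        n = rng.poisson(rate * scale)
        if n:
            mids.append(np.rint(rng.normal(center, sd, size=n)).astype(np.int64).clip(0, L - 1))

    mid = np.concatenate(mids) if mids else np.array([], dtype=np.int64)
    lo, hi = p.fragment_length_range
    lengths = rng.integers(lo, hi + 1, size=len(mid))
    starts = np.maximum(mid - lengths // 2, 0)
    ends = np.minimum(starts + lengths, L)
    keep = starts < ends
    order = np.lexsort((ends[keep], starts[keep]))
    s_arr, e_arr = starts[keep][order], ends[keep][order]
    return [ReadInterval(p.chrom, int(s), int(e)) for s, e in zip(s_arr, e_arr)]


def simulate_mtf2_peaks(layout: GenomeLayout) -> tuple[list[Peak], frozenset[str]]:
    """Regulator peak calls plus the planted promoter-bound gene set.

    Loss genes receive a promoter peak with probability
    ``bound_fraction_given_loss``, other genes with
    ``bound_fraction_given_noloss``; decoy gene-body/intergenic peaks are
    emitted so promoter peaks make up ``promoter_peak_share`` of all peaks.
    """
    p = layout.params
    rng = p._rng(_TAG_PEAKS)
    peaks: list[Peak] = []
    bound = []
    halfw = 150
    for g in layout.genes:
        prob = (p.bound_fraction_given_loss if g.gene_id in layout.loss_genes
                else p.bound_fraction_given_noloss)
        if rng.random() < prob:
            bound.append(g.gene_id)
            lo = max(0, g.tss - halfw)
            peaks.append(Peak(g.chrom, lo, g.tss + halfw, score=100.0,
                              summit_offset=g.tss - lo, name=f"peak_{g.gene_id}"))
    n_prom = len(peaks)
    share = p.promoter_peak_share
    if n_prom and 0 < share < 1:
        n_decoy = round(n_prom * (1 - share) / share)
    else:
        n_decoy = 50 if p.n_genes else 0  # keep the track non-empty for downstream stages
    if layout.genes and n_decoy:
        promoters = np.array(sorted(promoter_window(g, p.promoter_up, p.promoter_down)
                                    for g in layout.genes))
        placed = 0
        attempts = 0
        while placed < n_decoy:
            attempts += 1
            if attempts > n_decoy * 1000:
                raise ValueError("cannot place decoy peaks outside promoter windows")
            summit = int(rng.integers(halfw, p.chrom_length - halfw))
            i = np.searchsorted(promoters[:, 0], summit, side="right")
            if i > 0 and promoters[i - 1, 1] > summit:
                continue
            peaks.append(Peak(p.chrom, summit - halfw, summit + halfw, score=50.0,
                              summit_offset=halfw, name=f"decoy_{placed}"))
            placed += 1
    peaks.sort(key=lambda pk: (pk.chrom, pk.start, pk.end, pk.name))
    return peaks, frozenset(bound)


def simulate_counts(
    layout: GenomeLayout,
    bound_genes: frozenset[str],
    n_reps_per_condition: int = 2,
) -> tuple[pd.DataFrame, frozenset[str], frozenset[str]]:
    """Negative-binomial RNA counts with de-repression planted in KO.

    Gene baselines are log-normal; each loss-and-bound gene changes with
    probability ``de_rate_target`` and any other gene with
    ``de_rate_background``; a changed gene is up with probability
    ``de_up_fraction`` (KO mean multiplied by ``2**effect_log2fc``), else
    down.  Returns ``(counts, up_genes, down_genes)``.
    """
    p = layout.params
    rng = p._rng(_TAG_COUNTS)
    n = len(layout.genes)
    gene_ids = [g.gene_id for g in layout.genes]
    baseline = rng.lognormal(p.baseline_log_mean, p.baseline_log_sd, size=n)

    target = np.array([g in layout.loss_genes and g in bound_genes for g in gene_ids])
    change_prob = np.where(target, p.de_rate_target, p.de_rate_background)
    changed = rng.random(n) < change_prob
    up = changed & (rng.random(n) < p.de_up_fraction)
    down = changed & ~up

    fold = np.ones(n)
    fold[up] = 2.0 ** p.effect_log2fc
    fold[down] = 2.0 ** (-p.effect_log2fc)

    cols = {}
    for cond, mult in (("WT", np.ones(n)), ("KO", fold)):
        for rep in range(1, n_reps_per_condition + 1):
            mu = baseline * mult
            cols[f"{cond}_{rep}"] = _nb_draw(rng, mu, p.nb_dispersion)
    counts = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id"))
    up_set = frozenset(np.array(gene_ids)[up]) if p.effect_log2fc != 0 else frozenset()
    down_set = frozenset(np.array(gene_ids)[down]) if p.effect_log2fc != 0 else frozenset()
    return counts, up_set, down_set


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion <= 0:
        return rng.poisson(mu)
    size_param = 1.0 / dispersion  # NB "n": var = mu + dispersion * mu^2
    return rng.negative_binomial(size_param, size_param / (size_param + mu))


# ---------------------------------------------------------------------------
# file emission
# ---------------------------------------------------------------------------

def write_bed12(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            sizes = ",".join(str(e - s) for s, e in g.exons) + ","
            offsets = ",".join(str(s - g.start) for s, _ in g.exons) + ","
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\t"
                     f"{g.start}\t{g.end}\t0\t{len(g.exons)}\t{sizes}\t{offsets}\n")


def write_reads_bed(reads: Sequence[ReadInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t.\t0\t{r.strand}\n")


def write_narrowpeak(peaks: Sequence[Peak], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pk in peaks:
            summit = pk.summit_offset if pk.summit_offset is not None else -1
            fh.write(f"{pk.chrom}\t{pk.start}\t{pk.end}\t{pk.name}\t"
                     f"{pk.score:g}\t.\t{pk.score:g}\t-1\t-1\t{summit}\n")


def write_cgi_bed(cgis: Sequence[tuple[str, int, int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, s, e in cgis:
            fh.write(f"{chrom}\t{s}\t{e}\tCGI\n")


@dataclass(frozen=True)
class SimulatedDataset:
    layout: GenomeLayout
    truth: GroundTruth
    gene_models: Path
    wt_reads: Path
    ko_reads: Path
    peaks: Path
    cgi: Path
    counts: Path
    truth_json: Path


def simulate_dataset(params: SimulationParams, outdir: str | Path) -> SimulatedDataset:
    """Generate and write one full dataset; returns paths and the truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    layout = generate_genome(params)
    peaks, bound = simulate_mtf2_peaks(layout)
    counts, up, down = simulate_counts(layout, bound)
    cgi_genes = frozenset(
        g.gene_id for g in layout.genes
        if any(c[1] < tss_window(g, params.flank)[1] and c[2] > tss_window(g, params.flank)[0]
               for c in layout.cgi_intervals))
    truth = GroundTruth(layout.loss_genes, bound, cgi_genes, up, down)

    paths = {name: outdir / fname for name, fname in [
        ("gene_models", "genes.bed12"), ("wt_reads", "wt_reads.bed"),
        ("ko_reads", "ko_reads.bed"), ("peaks", "mtf2_peaks.narrowPeak"),
        ("cgi", "cgi.bed"), ("counts", "counts.tsv"), ("truth_json", "truth.json")]}
    write_bed12(layout.genes, paths["gene_models"])
    write_reads_bed(simulate_chip_reads(layout, "WT"), paths["wt_reads"])
    write_reads_bed(simulate_chip_reads(layout, "KO"), paths["ko_reads"])
    write_narrowpeak(peaks, paths["peaks"])
    write_cgi_bed(layout.cgi_intervals, paths["cgi"])
    counts.to_csv(paths["counts"], sep="\t")
    truth.to_json(paths["truth_json"])
    log.info("simulate_dataset: %d genes, %d loss, %d bound, %d CGI genes, %d peaks",
             len(layout.genes), len(truth.loss_genes), len(truth.bound_genes),
             len(truth.cgi_genes), len(peaks))
    return SimulatedDataset(layout, truth, **paths)
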