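"""Gene models, TSS anchors and genome feature partitioning.

All coordinates are 0-based half-open (BED convention) internally; GTF input
(1-based, closed) is converted on read.  Each gene is represented by a single
representative transcript (the longest, when several are annotated), whose
transcription start site (TSS) anchors every promoter-centered window in the
rest of the package.

The :class:`FeatureMap` partitions every base of the genome into exactly one
of four categories -- ``promoter_proximal``, ``exon``, ``intron``,
``intergenic`` -- with the precedence promoter > exon > intron > intergenic
when annotations from different genes overlap.  Ties between genes at equal
precedence are broken lexicographically by gene id so the partition is
deterministic.
"""

from __future__ import annotations

import bisect
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

log = logging.getLogger(__name__)

CATEGORIES = ("promoter_proximal", "exon", "intron", "intergenic")
_CAT_RANK = {c: i for i, c in enumerate(CATEGORIES)}


class ParseError(ValueError):
    """A malformed record in an annotation/interval file (reports line number)."""


class EmptyInputError(ValueError):
    """An input file that yielded zero usable records."""


@dataclass(frozen=True)
class GeneModel:
    """One gene: coordinates, strand, exon structure and derived TSS.

    ``start``/``end`` are the half-open genomic span; ``exons`` is a sorted
    tuple of non-overlapping half-open intervals contained in the span.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"{self.gene_id}: need 0 <= start < end, got [{self.start},{self.end})")
        prev_end = None
        for (s, e) in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"{self.gene_id}: exon [{s},{e}) not contained in span")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or are unsorted")
            prev_end = e

    @property
    def tss(self) -> int:
        """Strand-aware TSS: first transcribed base (start on +, end-1 on -)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def length(self) -> int:
        return self.end - self.start


def tss_window(gene: GeneModel, flank_bp: int) -> tuple[int, int]:
    """Symmetric window ``[tss - flank_bp, tss + flank_bp)`` clipped at 0."""
    if flank_bp <= 0:
        raise ValueError("flank_bp must be positive")
    return (max(0, gene.tss - flank_bp), gene.tss + flank_bp)


def promoter_window(gene: GeneModel, promoter_up: int, promoter_down: int) -> tuple[int, int]:
    """Strand-aware promoter-proximal window around the TSS.

    Covers ``promoter_up`` bases upstream of the TSS and ``promoter_down``
    bases downstream starting at the TSS itself, in transcription direction.
    """
    if promoter_up < 0 or promoter_down < 0:
        raise ValueError("promoter_up/promoter_down must be non-negative")
    t = gene.tss
    if gene.strand == "+":
        lo, hi = t - promoter_up, t + promoter_down
    else:
        lo, hi = t - promoter_down + 1, t + promoter_up + 1
    return (max(0, lo), max(0, hi))


# ---------------------------------------------------------------------------
# file readers
# ---------------------------------------------------------------------------

_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_bed_line(line: str, lineno: int) -> GeneModel:
    f = line.split()
    if len(f) < 6:
        raise ParseError(f"line {lineno}: BED gene record needs >= 6 fields, got {len(f)}")
    try:
        chrom, start, end, name, _score, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
    except ValueError as exc:
        raise ParseError(f"line {lineno}: {exc}") from exc
    exons: tuple[tuple[int, int], ...]
    if len(f) >= 12:
        try:
            n_blocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
        except ValueError as exc:
            raise ParseError(f"line {lineno}: malformed BED12 blocks: {exc}") from exc
        if len(sizes) != n_blocks or len(offsets) != n_blocks:
            raise ParseError(f"line {lineno}: blockCount disagrees with block lists")
        exons = tuple((start + o, start + o + s) for o, s in zip(offsets, sizes))
    else:
        exons = ((start, end),)
    try:
        return GeneModel(name, chrom, strand, start, end, exons)
    except ValueError as exc:
        raise ParseError(f"line {lineno}: {exc}") from exc


def _load_bed(path: Path) -> list[GeneModel]:
    best: dict[str, GeneModel] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            g = _parse_bed_line(line, lineno)
            old = best.get(g.gene_id)
            if old is None or g.length > old.length:
                best[g.gene_id] = g
    return list(best.values())


def _load_gtf(path: Path) -> list[GeneModel]:
    # exon records grouped per transcript; longest transcript (genomic span)
    # represents the gene, lexicographic transcript id breaks length ties
    tx: dict[tuple[str, str], dict] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 9:
                raise ParseError(f"line {lineno}: GTF record needs 9 tab-separated fields")
            if f[2] != "exon":
                continue
            try:
                start, end = int(f[3]) - 1, int(f[4])  # 1-based closed -> 0-based half-open
            except ValueError as exc:
                raise ParseError(f"line {lineno}: bad coordinates: {exc}") from exc
            attrs = dict(_GTF_ATTR.findall(f[8]))
            gid, tid = attrs.get("gene_id"), attrs.get("transcript_id")
            if not gid or not tid:
                raise ParseError(f"line {lineno}: missing gene_id/transcript_id attribute")
            rec = tx.setdefault((gid, tid), {"chrom": f[0], "strand": f[6], "exons": []})
            if rec["chrom"] != f[0] or rec["strand"] != f[6]:
                raise ParseError(f"line {lineno}: transcript {tid} spans chromosomes/strands")
            rec["exons"].append((start, end))
    per_gene: dict[str, GeneModel] = {}
    for (gid, tid) in sorted(tx):
        rec = tx[(gid, tid)]
        exons = tuple(sorted(rec["exons"]))
        start, end = exons[0][0], max(e for _, e in exons)
        model = GeneModel(gid, rec["chrom"], rec["strand"], start, end, exons)
        old = per_gene.get(gid)
        if old is None or model.length > old.length:
            per_gene[gid] = model
    return list(per_gene.values())


def load_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from GTF or BED(12), one representative per gene.

    Returns genes sorted by ``(chrom, start, gene_id)``.  Malformed lines
    raise :class:`ParseError` naming the line; zero genes raise
    :class:`EmptyInputError`.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".gtf", ".gff"):
        genes = _load_gtf(path)
    else:
        genes = _load_bed(path)
    if not genes:
        raise EmptyInputError(f"no gene models found in {path}")
    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return genes


# ---------------------------------------------------------------------------
# feature map
# ---------------------------------------------------------------------------

_INTERGENIC_KEY = np.iinfo(np.int64).max


@dataclass
class FeatureMap:
    """Disjoint labeled partition of every chromosome into the four categories."""

    chrom_lengths: dict[str, int]
    gene_ids: list[str]
    _starts: dict[str, np.ndarray] = field(repr=False, default_factory=dict)
    _cats: dict[str, np.ndarray] = field(repr=False, default_factory=dict)
    _genes: dict[str, np.ndarray] = field(repr=False, default_factory=dict)  # -1 = none

    def query(self, chrom: str, pos: int) -> tuple[str, str | None]:
        """Category and owning gene id (None for intergenic) at one base."""
        if chrom not in self._starts:
            return ("intergenic", None)
        L = self.chrom_lengths[chrom]
        if not (0 <= pos < L):
            raise ValueError(f"position {pos} outside {chrom} [0,{L})")
        i = int(np.searchsorted(self._starts[chrom], pos, side="right")) - 1
        cat = CATEGORIES[self._cats[chrom][i]]
        gi = self._genes[chrom][i]
        return (cat, self.gene_ids[gi] if gi >= 0 else None)

    def query_many(self, chrom: str, positions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized query: (category codes, gene indices (-1 = none))."""
        positions = np.asarray(positions)
        if chrom not in self._starts:
            return (np.full(positions.shape, _CAT_RANK["intergenic"], dtype=np.int8),
                    np.full(positions.shape, -1, dtype=np.int64))
        idx = np.searchsorted(self._starts[chrom], positions, side="right") - 1
        return (self._cats[chrom][idx], self._genes[chrom][idx])

    def segments(self, chrom: str) -> list[tuple[int, int, str, str | None]]:
        """The (start, end, category, gene_id) partition of one chromosome."""
        starts = self._starts[chrom]
        L = self.chrom_lengths[chrom]
        out = []
        for i, s in enumerate(starts):
            e = starts[i + 1] if i + 1 < len(starts) else L
            gi = self._genes[chrom][i]
            out.append((int(s), int(e), CATEGORIES[self._cats[chrom][i]],
                        self.gene_ids[gi] if gi >= 0 else None))
        return out

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.chrom_lengths):
                for s, e, cat, gid in self.segments(chrom):
                    name = cat if gid is None else f"{cat}|{gid}"
                    fh.write(f"{chrom}\t{s}\t{e}\t{name}\n")


def build_feature_map(
    genes: Sequence[GeneModel],
    promoter_up: int = 5000,
    promoter_down: int = 1000,
    chrom_lengths: dict[str, int] | None = None,
) -> FeatureMap:
    """Partition the genome into promoter/exon/intron/intergenic features.

    Overlaps are resolved by category precedence, then by lexicographically
    smaller gene id; resolved conflicts between genes are reported in the log.
    Chromosome lengths default to the furthest annotated coordinate per
    chromosome (including promoter windows).
    """
    if not genes:
        raise ValueError("genes must be non-empty")
    gene_order = sorted(g.gene_id for g in genes)
    if len(set(gene_order)) != len(gene_order):
        raise ValueError("duplicate gene ids")
    grank = {gid: i for i, gid in enumerate(gene_order)}
    n = len(gene_order)

    # candidate labeled intervals per chromosome: (start, end, rank, gene_rank)
    per_chrom: dict[str, list[tuple[int, int, int, int]]] = {}
    reach: dict[str, int] = {}
    for g in genes:
        ivs = per_chrom.setdefault(g.chrom, [])
        p_lo, p_hi = promoter_window(g, promoter_up, promoter_down)
        if p_lo < p_hi:
            ivs.append((p_lo, p_hi, 0, grank[g.gene_id]))
        for (s, e) in g.exons:
            ivs.append((s, e, 1, grank[g.gene_id]))
        ivs.append((g.start, g.end, 2, grank[g.gene_id]))  # introns = span at lower precedence
        reach[g.chrom] = max(reach.get(g.chrom, 0), g.end, p_hi)

    if chrom_lengths is None:
        chrom_lengths = dict(reach)
    else:
        for c, r in reach.items():
            if chrom_lengths.get(c, 0) < r:
                raise ValueError(f"chromosome {c} length {chrom_lengths.get(c)} shorter than annotation reach {r}")

    fmap = FeatureMap(chrom_lengths=dict(chrom_lengths), gene_ids=gene_order)
    for chrom, L in chrom_lengths.items():
        ivs = per_chrom.get(chrom, [])
        bounds = {0, L}
        for (s, e, _, _) in ivs:
            bounds.add(min(max(s, 0), L))
            bounds.add(min(max(e, 0), L))
        starts = np.array(sorted(bounds)[:-1], dtype=np.int64)
        # encoded key: rank * n + gene_rank, lower wins
        best = np.full(len(starts), _INTERGENIC_KEY, dtype=np.int64)
        for (s, e, rank, gr) in sorted(ivs, key=lambda iv: (iv[2], iv[3])):
            s, e = max(s, 0), min(e, L)
            if s >= e:
                continue
            i0 = int(np.searchsorted(starts, s, side="right")) - 1
            i1 = int(np.searchsorted(starts, e, side="left"))
            key = rank * n + gr
            seg = best[i0:i1]
            overridden = (seg != _INTERGENIC_KEY) & (seg % n != gr) & (key < seg)
            if overridden.any():
                log.debug("feature map: %s overrides %d segment(s) of other genes on %s",
                          gene_order[gr], int(overridden.sum()), chrom)
            np.minimum(seg, key, out=seg)
        cats = np.where(best == _INTERGENIC_KEY, _CAT_RANK["intergenic"], best // n).astype(np.int8)
        gidx = np.where(best == _INTERGENIC_KEY, -1, best % n).astype(np.int64)
        # merge adjacent identical segments
        keep = np.ones(len(starts), dtype=bool)
        keep[1:] = (cats[1:] != cats[:-1]) | (gidx[1:] != gidx[:-1])
        fmap._starts[chrom] = starts[keep]
        fmap._cats[chrom] = cats[keep]
        fmap._genes[chrom] = gidx[keep]
    return fmap
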