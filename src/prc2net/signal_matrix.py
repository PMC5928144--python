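"""Strand-aware, TSS-centered, binned read-density matrices.

A :class:`SignalMatrix` is a genes x bins grid of read densities around each
gene's TSS.  Reads are assigned to exactly one bin by their fragment midpoint,
so a read is never double-counted across bin edges.  Bin 0 is always the 5'
(upstream) end of the window: rows of minus-strand genes are reversed, which
makes profiles from both strands directly comparable and stackable.

Raw count matrices are depth-normalized to reads per million mapped reads
(rpm) before conditions are compared; the transformation is exactly
invertible given the stored library size.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .gene_annotation import GeneModel, ParseError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReadInterval:
    """One aligned fragment as a half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"read interval [{self.start},{self.end}) is empty")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def read_alignments(path: str | Path) -> tuple[list[ReadInterval], int]:
    """Read aligned fragments from BED6 (or BAM when pysam is available).

    Returns ``(reads, library_size)`` where ``library_size`` is the number of
    usable mapped reads.  Zero-length records are dropped and counted in the
    log; malformed records raise :class:`ParseError` with their line number.
    """
    path = Path(path)
    if path.suffix.lower() == ".bam":
        return _read_bam(path)
    reads: list[ReadInterval] = []
    dropped = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split()
            if len(f) < 3:
                raise ParseError(f"line {lineno}: BED read record needs >= 3 fields")
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: bad coordinates: {exc}") from exc
            if start > end or start < 0:
                raise ParseError(f"line {lineno}: invalid interval [{start},{end})")
            if start == end:
                dropped += 1
                continue
            strand = f[5] if len(f) >= 6 else "."
            reads.append(ReadInterval(f[0], start, end, strand))
    if dropped:
        log.info("read_alignments(%s): dropped %d zero-length record(s)", path, dropped)
    return reads, len(reads)


def _read_bam(path: Path) -> tuple[list[ReadInterval], int]:
    import pysam  # optional dependency, only needed for BAM input

    reads: list[ReadInterval] = []
    dropped = 0
    with pysam.AlignmentFile(str(path), "rb") as bam:
        for aln in bam.fetch(until_eof=True):
            if aln.is_unmapped or aln.reference_end is None:
                dropped += 1
                continue
            if aln.reference_start >= aln.reference_end:
                dropped += 1
                continue
            reads.append(ReadInterval(aln.reference_name, aln.reference_start,
                                      aln.reference_end, "-" if aln.is_reverse else "+"))
    if dropped:
        log.info("read_alignments(%s): dropped %d unmapped/degenerate record(s)", path, dropped)
    return reads, len(reads)


@dataclass(frozen=True)
class SignalMatrix:
    """Genes x bins occupancy grid with its bin geometry and depth metadata."""

    gene_ids: tuple[str, ...]
    values: np.ndarray  # shape (n_genes, bins), non-negative
    bin_size: int
    flank: int
    units: str  # "raw_counts" | "rpm"
    library_size: int

    def __post_init__(self):
        if self.flank % self.bin_size != 0:
            raise ValueError("flank must be divisible by bin_size")
        expect = 2 * self.flank // self.bin_size
        if self.values.ndim != 2 or self.values.shape != (len(self.gene_ids), expect):
            raise ValueError(f"values must be ({len(self.gene_ids)}, {expect}), got {self.values.shape}")
        if (self.values < 0).any():
            raise ValueError("signal values must be non-negative")
        if self.units not in ("raw_counts", "rpm"):
            raise ValueError(f"unknown units {self.units!r}")

    @property
    def bins(self) -> int:
        return self.values.shape[1]

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]


def build_signal_matrix(
    reads: Sequence[ReadInterval],
    genes: Sequence[GeneModel],
    flank: int = 5000,
    bin_size: int = 100,
) -> SignalMatrix:
    """Count fragment midpoints into TSS-centered bins, one row per gene.

    Minus-strand rows are reversed so bin 0 is always upstream.  Windows
    extending past chromosome bounds simply accumulate zero in the
    out-of-range bins.  Units are raw counts; library size is ``len(reads)``.
    """
    if not genes:
        raise ValueError("genes must be non-empty")
    if flank % bin_size != 0:
        raise ValueError("flank must be divisible by bin_size")
    nbins = 2 * flank // bin_size
    by_chrom: dict[str, np.ndarray] = {}
    for chrom in {r.chrom for r in reads}:
        mids = np.sort(np.array([r.midpoint for r in reads if r.chrom == chrom], dtype=np.int64))
        by_chrom[chrom] = mids
    values = np.zeros((len(genes), nbins), dtype=np.float64)
    for gi, g in enumerate(genes):
        mids = by_chrom.get(g.chrom)
        if mids is None or len(mids) == 0:
            continue
        lo = g.tss - flank
        i0, i1 = np.searchsorted(mids, [lo, lo + 2 * flank])
        if i0 == i1:
            continue
        b = (mids[i0:i1] - lo) // bin_size
        row = np.bincount(b, minlength=nbins).astype(np.float64)
        if g.strand == "-":
            row = row[::-1]
        values[gi] = row
    return SignalMatrix(tuple(g.gene_id for g in genes), values, bin_size, flank,
                        "raw_counts", len(reads))


def sum_matrices(matrices: Sequence[SignalMatrix]) -> SignalMatrix:
    """Pool replicate raw-count matrices by summing counts and library sizes."""
    if not matrices:
        raise ValueError("need at least one matrix")
    first = matrices[0]
    for m in matrices[1:]:
        if (m.gene_ids, m.bin_size, m.flank) != (first.gene_ids, first.bin_size, first.flank):
            raise ValueError("matrices have mismatched geometry or gene order")
        if m.units != "raw_counts" or first.units != "raw_counts":
            raise ValueError("only raw-count matrices can be pooled")
    return replace(first,
                   values=np.sum([m.values for m in matrices], axis=0),
                   library_size=sum(m.library_size for m in matrices))


def normalize_rpm(matrix: SignalMatrix) -> SignalMatrix:
    """Scale raw counts to reads per million mapped reads."""
    if matrix.units != "raw_counts":
        raise ValueError("matrix is not in raw counts")
    if matrix.library_size <= 0:
        raise ValueError("cannot rpm-normalize with library_size == 0")
    return replace(matrix, values=matrix.values * (1e6 / matrix.library_size), units="rpm")


def core_bin_range(matrix: SignalMatrix, core_halfwidth: int) -> tuple[int, int]:
    """Bin index range ``[lo, hi)`` fully inside ``[tss-core, tss+core)``."""
    if core_halfwidth > matrix.flank:
        raise ValueError("core_halfwidth must not exceed flank")
    half = core_halfwidth // matrix.bin_size
    if half < 1:
        raise ValueError("core window must cover at least one full bin")
    mid = matrix.bins // 2
    return mid - half, mid + half


def promoter_score(matrix: SignalMatrix, core_halfwidth: int) -> np.ndarray:
    """Per-gene mean signal over the bins immediately around the TSS."""
    lo, hi = core_bin_range(matrix, core_halfwidth)
    return matrix.values[:, lo:hi].mean(axis=1)


# ---------------------------------------------------------------------------
# TSV + JSON sidecar persistence
# ---------------------------------------------------------------------------

def write_matrix(matrix: SignalMatrix, path: str | Path) -> None:
    path = Path(path)
    cols = [f"bin{(i * matrix.bin_size) - matrix.flank}" for i in range(matrix.bins)]
    df = pd.DataFrame(matrix.values, index=list(matrix.gene_ids), columns=cols)
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.10g")
    meta = {"bin_size": matrix.bin_size, "flank": matrix.flank,
            "units": matrix.units, "library_size": matrix.library_size}
    Path(str(path) + ".json").write_text(json.dumps(meta, sort_keys=True) + "\n")


def read_matrix(path: str | Path) -> SignalMatrix:
    path = Path(path)
    meta = json.loads(Path(str(path) + ".json").read_text())
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    return SignalMatrix(tuple(df.index), df.to_numpy(dtype=np.float64),
                        meta["bin_size"], meta["flank"], meta["units"], meta["library_size"])
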