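"""Annotation of peak calls against the genome feature partition.

Each peak is assigned exactly one category -- the category of its summit (or
of its midpoint when no summit is recorded) in the :class:`FeatureMap` -- so
the per-category fractions are mutually exclusive and sum to one.  The
gene-level "bound" set is derived from annotations restricted to a chosen set
of categories (promoter-proximal by default).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .gene_annotation import CATEGORIES, FeatureMap, GeneModel, ParseError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Peak:
    chrom: str
    start: int
    end: int
    score: float = 0.0
    summit_offset: int | None = None
    name: str = "."

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"peak [{self.start},{self.end}) is empty")

    @property
    def point(self) -> int:
        """The single base representing the peak: summit, else midpoint."""
        if self.summit_offset is not None and self.summit_offset >= 0:
            return self.start + self.summit_offset
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class PeakAnnotation:
    peak: Peak
    category: str
    gene_id: str | None
    distance_to_tss: int | None


@dataclass(frozen=True)
class PeakAnnotationResult:
    annotations: tuple[PeakAnnotation, ...]
    counts: dict[str, int]

    @property
    def fractions(self) -> dict[str, float]:
        total = sum(self.counts.values())
        if total == 0:
            return {c: 0.0 for c in CATEGORIES}
        return {c: self.counts.get(c, 0) / total for c in CATEGORIES}

    def exact_fractions(self) -> dict[str, Fraction]:
        total = sum(self.counts.values())
        return {c: Fraction(self.counts.get(c, 0), total) for c in CATEGORIES}


def read_peaks(path: str | Path) -> list[Peak]:
    """Read narrowPeak (10 columns, summit in column 10) or plain BED peaks."""
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split()
            if len(f) < 3:
                raise ParseError(f"line {lineno}: peak record needs >= 3 fields")
            try:
                start, end = int(f[1]), int(f[2])
                score = float(f[4]) if len(f) >= 5 and f[4] != "." else 0.0
                summit = None
                if len(f) >= 10:
                    s = int(f[9])
                    summit = s if s >= 0 else None
                peaks.append(Peak(f[0], start, end, score, summit,
                                  f[3] if len(f) >= 4 else "."))
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from exc
    return peaks


def annotate_peaks(
    peaks: Sequence[Peak],
    fmap: FeatureMap,
    genes: Sequence[GeneModel],
) -> PeakAnnotationResult:
    """Label each peak by the feature category at its summit point.

    Peaks on chromosomes absent from the feature map are counted intergenic
    (and logged).  ``distance_to_tss`` is signed in transcription direction
    of the owning gene (negative = upstream); for intergenic peaks it is the
    distance to the nearest TSS on the chromosome, when one exists.
    """
    tss_by_chrom: dict[str, tuple[np.ndarray, list[GeneModel]]] = {}
    for g in sorted(genes, key=lambda g: (g.chrom, g.tss)):
        arr = tss_by_chrom.setdefault(g.chrom, ([], []))
        arr[0].append(g.tss)
        arr[1].append(g)
    tss_by_chrom = {c: (np.array(t), gl) for c, (t, gl) in tss_by_chrom.items()}
    gene_by_id = {g.gene_id: g for g in genes}

    annotations = []
    unknown = 0
    for p in peaks:
        point = p.point
        if p.chrom not in fmap.chrom_lengths:
            unknown += 1
            annotations.append(PeakAnnotation(p, "intergenic", None,
                                              _nearest_tss_distance(p, tss_by_chrom)))
            continue
        if not (0 <= point < fmap.chrom_lengths[p.chrom]):
            annotations.append(PeakAnnotation(p, "intergenic", None,
                                              _nearest_tss_distance(p, tss_by_chrom)))
            continue
        cat, gid = fmap.query(p.chrom, point)
        if gid is None:
            dist = _nearest_tss_distance(p, tss_by_chrom)
        else:
            g = gene_by_id[gid]
            d = point - g.tss
            dist = -d if g.strand == "-" else d
        annotations.append(PeakAnnotation(p, cat, gid, dist))
    if unknown:
        log.warning("annotate_peaks: %d peak(s) on chromosomes absent from the "
                    "feature map counted as intergenic", unknown)
    counts = Counter(a.category for a in annotations)
    return PeakAnnotationResult(tuple(annotations), {c: counts.get(c, 0) for c in CATEGORIES})


def _nearest_tss_distance(peak: Peak, tss_by_chrom) -> int | None:
    entry = tss_by_chrom.get(peak.chrom)
    if entry is None:
        return None
    tss, gl = entry
    i = int(np.argmin(np.abs(tss - peak.point)))
    d = peak.point - gl[i].tss
    return -d if gl[i].strand == "-" else d


def genes_bound(
    annotations: Iterable[PeakAnnotation],
    restrict_to: frozenset[str] | set[str] = frozenset({"promoter_proximal"}),
) -> set[str]:
    """Unique gene ids with at least one peak in the given categories."""
    bad = set(restrict_to) - set(CATEGORIES)
    if bad:
        raise ValueError(f"unknown categories: {sorted(bad)}")
    return {a.gene_id for a in annotations
            if a.category in restrict_to and a.gene_id is not None}


def write_annotations(result: PeakAnnotationResult, path: str | Path) -> None:
    rows = [{
        "chrom": a.peak.chrom, "start": a.peak.start, "end": a.peak.end,
        "name": a.peak.name, "score": a.peak.score, "point": a.peak.point,
        "category": a.category, "gene_id": a.gene_id if a.gene_id else "",
        "distance_to_tss": "" if a.distance_to_tss is None else a.distance_to_tss,
    } for a in result.annotations]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
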