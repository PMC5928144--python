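"""Evidence assembly, set-overlap statistics and regulatory-network drafting.

The drafted network is the tri-modal intersection of (i) genes losing
promoter-proximal H3K27me3 in the knockout, (ii) genes bound by the regulator
at the promoter, and (iii) genes significantly upregulated in the knockout.
Each such gene receives one repression edge from the regulator; node
attributes carry the expression change (log2 fold change) and the evidence
flags.  Between-set association is quantified with the two-sided Fisher exact
test over a fixed gene universe, and the same machinery powers a simple
gene-set (Fisher + BH) enrichment against user-supplied collections.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .expression_integration import DiffExprRecord, bh_adjust
from .gene_annotation import GeneModel, tss_window
from .occupancy_clustering import LossCall

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class OverlapTestResult:
    """2x2 membership table for two gene sets over a universe, with Fisher p."""

    a: int  # |A ∩ B|
    b: int  # |A \ B|
    c: int  # |B \ A|
    d: int  # |universe| - a - b - c
    overlap_fraction: float  # a / |A|, 0 when A is empty
    odds_ratio: float  # (a*d)/(b*c), inf when b*c == 0 and a*d > 0
    pvalue: float

    @property
    def table(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


def overlap_test(setA: set[str], setB: set[str], universe: set[str]) -> OverlapTestResult:
    """Two-sided Fisher exact association of two gene sets in a universe.

    Two-sided by the point-probability rule: the p-value sums hypergeometric
    probabilities of all tables (at fixed margins) no more probable than the
    observed one.
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    if not setA <= universe or not setB <= universe:
        raise ValueError("both sets must be contained in the universe")
    a = len(setA & setB)
    b = len(setA - setB)
    c = len(setB - setA)
    d = len(universe) - a - b - c
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if b * c == 0:
        odds = np.inf if a * d > 0 else np.nan
    else:
        odds = (a * d) / (b * c)
    frac = a / len(setA) if setA else 0.0
    return OverlapTestResult(a, b, c, d, frac, float(odds), float(min(p, 1.0)))


def assemble_evidence(
    loss_calls: Sequence[LossCall],
    bound_set: set[str],
    de_records: Sequence[DiffExprRecord],
    genes: Sequence[GeneModel],
    flank: int = 5000,
    cgi_intervals: Sequence[tuple[str, int, int]] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene evidence table over the full gene-model universe.

    Columns: ``is_loss, is_bound, is_up, has_cgi, log2fc, support``.  A CGI
    flags a gene when the interval strictly overlaps the gene's half-open
    +-flank TSS window (an abutting interval does not).  Genes absent from
    the DE input get ``is_up=False, log2fc=0``.  Evidence for a gene outside
    the universe is an error.
    """
    universe = [g.gene_id for g in genes]
    uset = set(universe)
    if len(uset) != len(universe):
        raise ValueError("duplicate gene ids in universe")
    for c in loss_calls:
        if c.gene_id not in uset:
            raise ValueError(f"loss call for unknown gene {c.gene_id!r}")
    if not bound_set <= uset:
        raise ValueError(f"bound genes outside universe: {sorted(bound_set - uset)[:5]}")
    for r in de_records:
        if r.gene_id not in uset:
            raise ValueError(f"DE record for unknown gene {r.gene_id!r}")

    df = pd.DataFrame(index=pd.Index(universe, name="gene_id"))
    df["is_loss"] = False
    df["is_bound"] = df.index.isin(bound_set)
    df["is_up"] = False
    df["has_cgi"] = False
    df["log2fc"] = 0.0
    df["support"] = 0.0
    for c in loss_calls:
        df.loc[c.gene_id, "is_loss"] = c.is_loss
        df.loc[c.gene_id, "support"] = c.support
    for r in de_records:
        df.loc[r.gene_id, "log2fc"] = r.log2fc
        df.loc[r.gene_id, "is_up"] = bool(r.qvalue <= alpha and r.log2fc > 0)

    if cgi_intervals:
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e in cgi_intervals:
            by_chrom.setdefault(chrom, []).append((int(s), int(e)))
        arr = {c: (np.array(sorted(s for s, _ in iv)), np.array([e for _, e in sorted(iv)]))
               for c, iv in by_chrom.items()}
        for g in genes:
            if g.chrom not in arr:
                continue
            starts, ends = arr[g.chrom]
            lo, hi = tss_window(g, flank)
            # strict half-open overlap: cgi.start < hi and cgi.end > lo
            i = np.searchsorted(starts, hi, side="left")
            if i > 0 and (ends[:i] > lo).any():
                df.loc[g.gene_id, "has_cgi"] = True
    return df


@dataclass(frozen=True)
class RegulatoryNetwork:
    """Star-shaped repression network: one regulator, one edge per target."""

    regulator: str
    graph: nx.DiGraph

    @property
    def targets(self) -> set[str]:
        return {t for _, t in self.graph.edges()}

    @property
    def size(self) -> int:
        return len(self.targets)


def draft_grn(evidence: pd.DataFrame, regulator: str = "Mtf2") -> RegulatoryNetwork:
    """Targets = genes with loss AND binding AND upregulation evidence."""
    need = {"is_loss", "is_bound", "is_up", "log2fc"}
    if not need <= set(evidence.columns):
        raise ValueError(f"evidence table missing columns: {sorted(need - set(evidence.columns))}")
    mask = evidence["is_loss"] & evidence["is_bound"] & evidence["is_up"]
    g = nx.DiGraph()
    g.add_node(regulator, role="regulator")
    for gid in sorted(evidence.index[mask]):
        row = evidence.loc[gid]
        g.add_node(gid, expression_delta=float(row["log2fc"]),
                   is_loss=bool(row["is_loss"]), is_bound=bool(row["is_bound"]),
                   is_up=bool(row["is_up"]),
                   has_cgi=bool(row["has_cgi"]) if "has_cgi" in evidence.columns else False)
        g.add_edge(regulator, gid, sign="repression")
    log.info("draft_grn: %d target gene(s)", g.number_of_edges())
    return RegulatoryNetwork(regulator, g)


def gene_set_enrichment(
    query: set[str],
    collections: Mapping[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """Fisher-test enrichment of a query set against named gene collections.

    One two-sided Fisher test per collection (collections are intersected
    with the universe first), BH-adjusted across collections; sorted by
    p-value then name.
    """
    if not collections:
        raise ValueError("collections must be non-empty")
    if not query <= universe:
        raise ValueError("query genes outside universe")
    rows = []
    for name in sorted(collections):
        cset = set(collections[name]) & universe
        r = overlap_test(query, cset, universe)
        rows.append({"set": name, "set_size": len(cset), "overlap": r.a,
                     "odds_ratio": r.odds_ratio, "pvalue": r.pvalue})
    df = pd.DataFrame(rows)
    df["qvalue"] = bh_adjust(df["pvalue"].to_numpy())
    return df.sort_values(["pvalue", "set"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT-style gene sets: name <tab> description <tab> gene1 <tab> gene2 ..."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) < 3 or not f[0]:
                continue
            out[f[0]] = {g for g in f[2:] if g}
    return out


def read_bed_intervals(path: str | Path) -> list[tuple[str, int, int]]:
    """Plain (chrom, start, end) intervals from a BED file (e.g. a CGI track)."""
    out = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split()
            if len(f) < 3:
                raise ValueError(f"line {lineno}: interval record needs >= 3 fields")
            out.append((f[0], int(f[1]), int(f[2])))
    return out


def write_sif(network: RegulatoryNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        for tgt in sorted(network.targets):
            fh.write(f"{network.regulator}\trepresses\t{tgt}\n")


def write_network_tables(network: RegulatoryNetwork, nodes_path: str | Path,
                         edges_path: str | Path) -> None:
    node_rows = []
    for gid in sorted(network.targets):
        attrs = network.graph.nodes[gid]
        node_rows.append({"gene_id": gid,
                          "expression_delta": attrs.get("expression_delta", 0.0),
                          "has_cgi": attrs.get("has_cgi", False)})
    pd.DataFrame(node_rows, columns=["gene_id", "expression_delta", "has_cgi"]) \
        .to_csv(nodes_path, sep="\t", index=False, float_format="%.10g")
    edge_rows = [{"source": network.regulator, "target": t, "sign": "repression"}
                 for t in sorted(network.targets)]
    pd.DataFrame(edge_rows, columns=["source", "target", "sign"]) \
        .to_csv(edges_path, sep="\t", index=False)
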