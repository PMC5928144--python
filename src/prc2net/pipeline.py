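"""End-to-end orchestration: config validation, staged execution, report.

A run executes, in dependency order: (optional) data simulation, gene-model
loading and feature-map construction, signal-matrix building and rpm
normalization, consensus loss calling, peak annotation, differential
expression, and network drafting.  Every run directory contains the fully
resolved configuration and a machine-readable ``report.json`` whose contents
depend only on the inputs and the seed (no timestamps), so identical runs are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import yaml

from . import (gene_annotation, grn_builder, occupancy_clustering,
               peak_integration, signal_matrix, synthetic_data)
from . import expression_integration as expr

log = logging.getLogger(__name__)

STAGES = ("config", "simulate", "gene_annotation", "signal_matrix",
          "occupancy_clustering", "peak_integration", "expression_integration",
          "grn_builder")

# distinct CLI exit code per failing stage
STAGE_EXIT_CODES = {s: i + 2 for i, s in enumerate(STAGES)}


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Resolved parameters for one pipeline run; unknown keys are rejected."""

    outdir: str = "run"
    simulate: bool = True
    sim: dict[str, Any] = field(default_factory=dict)  # SimulationParams overrides

    # external inputs (used when simulate=False)
    gene_models: str | None = None
    wt_reads: list[str] = field(default_factory=list)
    ko_reads: list[str] = field(default_factory=list)
    peaks: str | None = None
    counts: str | None = None
    cgi: str | None = None
    gene_sets: str | None = None  # GMT, optional
    de_table: str | None = None  # external DE table bypassing the internal test

    # stage parameters
    flank: int = 5000
    bin_size: int = 100
    core_halfwidth: int = 500
    k: int = 10
    n_restarts: int = 4
    n_consensus: int = 10
    min_support: float = 0.8
    tau_wt: float | None = None
    rho: float = 0.25
    eps: float = 0.1
    promoter_up: int = 5000
    promoter_down: int = 1000
    alpha: float = 0.05
    pseudocount: float = 0.5
    regulator: str = "Mtf2"
    seed: int = 0

    def __post_init__(self):
        if self.flank <= 0 or self.bin_size <= 0 or self.flank % self.bin_size != 0:
            raise ValueError("flank must be a positive multiple of bin_size")
        if not (0 < self.core_halfwidth <= self.flank):
            raise ValueError("core_halfwidth must be in (0, flank]")
        if self.k < 1 or self.n_consensus < 1 or self.n_restarts < 1:
            raise ValueError("k, n_consensus and n_restarts must be >= 1")
        for name, lo, hi in (("min_support", 0.0, 1.0), ("rho", 0.0, None),
                             ("eps", 0.0, None), ("alpha", 0.0, 1.0),
                             ("pseudocount", 0.0, None)):
            v = getattr(self, name)
            if v < lo or (hi is not None and v > hi):
                raise ValueError(f"{name} out of range: {v}")
        if self.promoter_up < 0 or self.promoter_down < 0:
            raise ValueError("promoter window extents must be non-negative")

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        d = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) else json.loads(text)
        if not isinstance(d, dict):
            raise ValueError("config file must contain a mapping")
        return cls.from_dict(d)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, str(exc)) from exc
        return wrapped
    return deco


@_stage("simulate")
def _run_simulate(config: PipelineConfig, outdir: Path):
    sim_overrides = dict(config.sim)
    sim_overrides.setdefault("seed", config.seed)
    sim_overrides.setdefault("flank", config.flank)
    params = synthetic_data.SimulationParams(**sim_overrides)
    ds = synthetic_data.simulate_dataset(params, outdir / "sim")
    return ds


@_stage("gene_annotation")
def _run_annotation(config: PipelineConfig, gene_models_path):
    if gene_models_path is None or not Path(gene_models_path).exists():
        raise FileNotFoundError(f"gene model file not found: {gene_models_path}")
    genes = gene_annotation.load_gene_models(gene_models_path)
    fmap = gene_annotation.build_feature_map(genes, config.promoter_up, config.promoter_down)
    return genes, fmap

@_stage("signal_matrix")
def _run_matrices(config: PipelineConfig, genes, wt_paths, ko_paths, outdir: Path):
    def build(paths: Sequence[str | Path], label: str):
        if not paths:
            raise FileNotFoundError(f"no {label} read files supplied")
        mats = []
        for pth in paths:
            if not Path(pth).exists():
                raise FileNotFoundError(f"{label} reads file not found: {pth}")
            reads, _ = signal_matrix.read_alignments(pth)
            mats.append(signal_matrix.build_signal_matrix(reads, genes,
                                                          config.flank, config.bin_size))
        pooled = signal_matrix.sum_matrices(mats)
        rpm = signal_matrix.normalize_rpm(pooled)
        signal_matrix.write_matrix(rpm, outdir / f"{label.lower()}_matrix.tsv")
        return rpm
    return build(wt_paths, "WT"), build(ko_paths, "KO")


@_stage("occupancy_clustering")
def _run_clustering(config: PipelineConfig, wt, ko, outdir: Path):
    calls = occupancy_clustering.call_loss_genes(
        wt, ko, k=config.k, core_halfwidth=config.core_halfwidth,
        tau_wt=config.tau_wt, rho=config.rho, eps=config.eps,
        n_consensus=config.n_consensus, min_support=config.min_support,
        base_seed=config.seed, n_restarts=config.n_restarts)
    occupancy_clustering.write_loss_calls(calls, outdir / "loss_calls.tsv")
    return calls


@_stage("peak_integration")
def _run_peaks(config: PipelineConfig, peaks_path, fmap, genes, outdir: Path):
    if peaks_path is None or not Path(peaks_path).exists():
        raise FileNotFoundError(f"peak file not found: {peaks_path}")
    peaks = peak_integration.read_peaks(peaks_path)
    result = peak_integration.annotate_peaks(peaks, fmap, genes)
    peak_integration.write_annotations(result, outdir / "peak_annotations.tsv")
    bound = peak_integration.genes_bound(result.annotations)
    return result, bound


@_stage("expression_integration")
def _run_expression(config: PipelineConfig, counts_path, de_table_path, outdir: Path):
    if de_table_path is not None:
        records = expr.read_de_table(de_table_path, alpha=config.alpha)
    else:
        if counts_path is None or not Path(counts_path).exists():
            raise FileNotFoundError(f"counts file not found: {counts_path}")
        counts = expr.read_counts(counts_path)
        labels = expr.conditions_from_columns(counts.columns)
        records = expr.simple_de_test(counts, labels,
                                      pseudocount=config.pseudocount, alpha=config.alpha)
    expr.write_de_table(records, outdir / "de.tsv")
    return records


@_stage("grn_builder")
def _run_grn(config: PipelineConfig, calls, bound, records, genes, cgi_path, outdir: Path):
    cgis = grn_builder.read_bed_intervals(cgi_path) if cgi_path else None
    evidence = grn_builder.assemble_evidence(calls, bound, records, genes,
                                             flank=config.flank, cgi_intervals=cgis,
                                             alpha=config.alpha)
    evidence.to_csv(outdir / "evidence.tsv", sep="\t", float_format="%.10g")
    network = grn_builder.draft_grn(evidence, regulator=config.regulator)
    grn_builder.write_sif(network, outdir / "network.sif")
    grn_builder.write_network_tables(network, outdir / "network_nodes.tsv",
                                     outdir / "network_edges.tsv")
    enrichment = None
    if config.gene_sets:
        collections = grn_builder.read_gmt(config.gene_sets)
        universe = set(evidence.index)
        enrichment = grn_builder.gene_set_enrichment(network.targets & universe,
                                                     collections, universe)
        enrichment.to_csv(outdir / "enrichment.tsv", sep="\t", index=False,
                          float_format="%.10g")
    return evidence, network, enrichment


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute all stages; returns the report written to ``report.json``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "resolved_config.json").write_text(
        json.dumps(config.to_dict(), indent=1, sort_keys=True) + "\n")

    if config.simulate:
        ds = _run_simulate(config, outdir)
        gene_models_path = ds.gene_models
        wt_paths, ko_paths = [ds.wt_reads], [ds.ko_reads]
        peaks_path, counts_path, cgi_path = ds.peaks, ds.counts, ds.cgi
    else:
        gene_models_path = config.gene_models
        wt_paths, ko_paths = config.wt_reads, config.ko_reads
        peaks_path, counts_path, cgi_path = config.peaks, config.counts, config.cgi

    genes, fmap = _run_annotation(config, gene_models_path)
    wt, ko = _run_matrices(config, genes, wt_paths, ko_paths, outdir)
    calls = _run_clustering(config, wt, ko, outdir)
    peak_result, bound = _run_peaks(config, peaks_path, fmap, genes, outdir)
    records = _run_expression(config, counts_path, config.de_table, outdir)
    evidence, network, _ = _run_grn(config, calls, bound, records, genes,
                                    cgi_path, outdir)

    loss_genes = {c.gene_id for c in calls if c.is_loss}
    up, down, fraction_up = expr.classify_direction(records, alpha=config.alpha)
    universe = {g.gene_id for g in genes}
    cgi_genes = set(evidence.index[evidence["has_cgi"]])
    cgi_overlap = grn_builder.overlap_test(loss_genes, cgi_genes, universe) \
        if loss_genes else None
    bound_given_loss = (len(bound & loss_genes) / len(loss_genes)) if loss_genes else 0.0

    report = {
        "n_genes": len(genes),
        "n_loss_genes": len(loss_genes),
        "bound_given_loss_fraction": bound_given_loss,
        "promoter_peak_fraction": peak_result.fractions["promoter_proximal"],
        "fraction_up": fraction_up,
        "n_significant_q": int(sum(r.qvalue <= config.alpha for r in records)),
        "n_significant_rawp": int(sum(r.pvalue <= config.alpha for r in records)),
        "cgi_overlap_fraction": cgi_overlap.overlap_fraction if cgi_overlap else 0.0,
        "cgi_overlap_p": cgi_overlap.pvalue if cgi_overlap else 1.0,
        "network_size": network.size,
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True) + "\n")
    log.info("pipeline finished: %s", json.dumps(report, sort_keys=True))
    return report
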