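"""Minimal two-condition differential-expression stage with BH control.

The test is deliberately simple: counts are pooled within condition and the
pooled KO count is compared to its expectation under equal per-read sampling
with a two-sided exact binomial test (success probability = KO library share).
This treats replicates as technical-grade -- it captures sampling noise but
not biological dispersion, and is therefore anti-conservative on strongly
overdispersed data.  It makes no attempt to reproduce any particular
dispersion-modeling DE tool; externally computed DE tables can be supplied
instead and bypass this stage entirely.

Fold changes are ``log2`` ratios of per-million-scaled pooled rates with a
pseudocount, so all-zero genes have log2fc 0 and p-value 1.  Benjamini-
Hochberg q-values control the false discovery rate across genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DiffExprRecord:
    gene_id: str
    mean_wt: float  # pooled reads per million in WT
    mean_ko: float  # pooled reads per million in KO
    log2fc: float  # KO vs WT
    pvalue: float
    qvalue: float
    status: str  # up | down | ns


def _robust_log_location(m: np.ndarray) -> float:
    """Mode-seeking location of log-ratios, robust to one-sided contamination.

    A changed block of genes shifts every quantile-based estimator (median,
    symmetric trimmed mean) because it occupies one tail only; the center of
    the shortest interval containing half of the points tracks the unchanged
    majority instead.  A one-step mean over points near that center restores
    root-n convergence.
    """
    m = np.sort(m)
    n = len(m)
    h = max(1, (n + 1) // 2)
    widths = m[h - 1:] - m[: n - h + 1]
    i = int(np.argmin(widths))
    center = 0.5 * (m[i] + m[i + h - 1])
    spread = max(np.median(np.abs(m - center)) * 1.4826, 1e-12)
    kept = m[np.abs(m - center) <= 2.5 * spread]
    return float(kept.mean()) if kept.size else center


def effective_libsizes(counts: pd.DataFrame) -> np.ndarray:
    """Composition-robust effective library sizes, in count units.

    Raw column sums are biased by asymmetric expression changes (a block of
    strongly upregulated genes inflates that condition's total and makes
    every unchanged gene look shifted the other way).  For each sample the
    per-gene log-ratios to a geometric-mean pseudo-reference are summarized
    by a mode-seeking robust location (see :func:`_robust_log_location`), so
    the unchanged majority of genes defines the scale even when all changes
    point one way.  Size factors are rescaled so their sum matches the grand
    total of counts.
    """
    x = counts.to_numpy(dtype=np.float64)
    pos = (x > 0).all(axis=1)
    if pos.sum() < 3:
        sf = x.sum(axis=0)  # degenerate table: fall back to column sums
    else:
        logx = np.log(x[pos])
        ref = logx.mean(axis=1)
        sf = np.exp([_robust_log_location(logx[:, j] - ref) for j in range(x.shape[1])])
    if sf.sum() <= 0:
        raise ValueError("cannot derive library sizes from an all-zero table")
    return sf * (x.sum() / sf.sum())


def bh_adjust(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=np.float64)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def simple_de_test(
    counts: pd.DataFrame,
    condition_labels: Sequence[str],
    libsizes: Sequence[float] | None = None,
    pseudocount: float = 0.5,
    alpha: float = 0.05,
) -> list[DiffExprRecord]:
    """Exact-binomial DE test of pooled KO counts against the library split.

    ``counts`` is genes x samples (non-negative integers); ``condition_labels``
    gives each column's condition and must contain exactly the labels ``WT``
    and ``KO``.  ``libsizes`` default to median-of-ratios effective library
    sizes (see :func:`effective_libsizes`), which are robust to one-sided
    expression shifts; pass column sums explicitly to disable that.
    ``pseudocount`` is in reads-per-million units.
    """
    labels = list(condition_labels)
    if len(labels) != counts.shape[1]:
        raise ValueError("one condition label per column is required")
    if set(labels) != {"WT", "KO"}:
        raise ValueError(f"condition labels must be WT/KO, got {sorted(set(labels))}")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    wt_cols = [c for c, l in zip(counts.columns, labels) if l == "WT"]
    ko_cols = [c for c, l in zip(counts.columns, labels) if l == "KO"]
    libs = effective_libsizes(counts) if libsizes is None \
        else np.asarray(libsizes, dtype=np.float64)
    lib_wt = float(libs[[l == "WT" for l in labels]].sum())
    lib_ko = float(libs[[l == "KO" for l in labels]].sum())
    if lib_wt <= 0 or lib_ko <= 0:
        raise ValueError("both conditions need a positive library size")
    p0 = lib_ko / (lib_ko + lib_wt)

    wt_pool = counts[wt_cols].sum(axis=1).to_numpy()
    ko_pool = counts[ko_cols].sum(axis=1).to_numpy()
    rpm_wt = wt_pool / lib_wt * 1e6
    rpm_ko = ko_pool / lib_ko * 1e6
    log2fc = np.log2((rpm_ko + pseudocount) / (rpm_wt + pseudocount))

    pvals = np.ones(len(counts))
    for i, (w, k) in enumerate(zip(wt_pool, ko_pool)):
        n = int(w + k)
        if n == 0:
            continue
        pvals[i] = stats.binomtest(int(k), n, p0).pvalue
    qvals = bh_adjust(pvals)

    records = []
    for i, gid in enumerate(counts.index):
        records.append(DiffExprRecord(
            str(gid), float(rpm_wt[i]), float(rpm_ko[i]), float(log2fc[i]),
            float(pvals[i]), float(qvals[i]),
            _status(qvals[i], log2fc[i], alpha)))
    return records


def _status(q: float, lfc: float, alpha: float) -> str:
    if q <= alpha and lfc > 0:
        return "up"
    if q <= alpha and lfc < 0:
        return "down"
    return "ns"


def classify_direction(
    records: Sequence[DiffExprRecord],
    alpha: float = 0.05,
) -> tuple[set[str], set[str], float]:
    """Significant up/down gene sets and the upregulated fraction among them."""
    up = {r.gene_id for r in records if r.qvalue <= alpha and r.log2fc > 0}
    down = {r.gene_id for r in records if r.qvalue <= alpha and r.log2fc < 0}
    n = len(up) + len(down)
    if n == 0:
        log.info("classify_direction: no significant genes at alpha=%g; "
                 "fraction_up reported as 0 by convention", alpha)
        return up, down, 0.0
    return up, down, len(up) / n


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_counts(path: str | Path) -> pd.DataFrame:
    """Genes x samples count table; first column gene ids, header = samples."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def conditions_from_columns(columns: Sequence[str]) -> list[str]:
    """Condition label per column from the prefix before the last underscore."""
    return [str(c).rsplit("_", 1)[0] for c in columns]


def de_records_to_frame(records: Sequence[DiffExprRecord]) -> pd.DataFrame:
    df = pd.DataFrame([r.__dict__ for r in records]).set_index("gene_id")
    return df[["mean_wt", "mean_ko", "log2fc", "pvalue", "qvalue", "status"]]


def write_de_table(records: Sequence[DiffExprRecord], path: str | Path) -> None:
    de_records_to_frame(records).to_csv(path, sep="\t", float_format="%.10g")


def read_de_table(path: str | Path, alpha: float = 0.05) -> list[DiffExprRecord]:
    """Load an externally computed DE table (gene, log2fc, pvalue, qvalue ...).

    Missing q-values are recomputed by BH; missing means default to 0.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if "qvalue" not in df.columns:
        df["qvalue"] = bh_adjust(df["pvalue"].to_numpy())
    records = []
    for gid, r in df.iterrows():
        records.append(DiffExprRecord(
            gid, float(r.get("mean_wt", 0.0)), float(r.get("mean_ko", 0.0)),
            float(r["log2fc"]), float(r["pvalue"]), float(r["qvalue"]),
            _status(float(r["qvalue"]), float(r["log2fc"]), alpha)))
    return records
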