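"""k-means clustering of stacked WT/KO occupancy profiles and loss calling.

Each gene contributes one row: its WT TSS-centered profile concatenated with
its KO profile, both in rpm.  Rows are clustered with Lloyd's algorithm under
k-means++ seeding, repeated over several restarts (best within-cluster sum of
squares kept) and over several consensus runs with consecutive seeds.  A run's
"loss clusters" are those whose centroid shows strong WT signal in the core
bins around the TSS together with a low KO/WT core ratio; a gene's support is
the fraction of consensus runs that place it in a loss cluster.

A gene is finally called a loss gene when its support reaches ``min_support``
AND its own promoter scores pass the same gates: WT score at least ``tau_wt``
(by default the 60th percentile of nonzero WT promoter scores, separating
promoter-marked genes from background) and KO/WT ratio at most ``rho`` (a
small pseudocount ``eps`` stabilizes ratios of weak signals).

Rows are deliberately NOT per-row standardized: absolute occupancy carries
the loss information that z-scoring would erase.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .signal_matrix import SignalMatrix, core_bin_range, promoter_score

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClusterAssignment:
    gene_ids: tuple[str, ...]
    labels: np.ndarray  # int, in [0, k)
    centroids: np.ndarray  # k x n_features
    wcss: float
    seed: int

    @property
    def k(self) -> int:
        return self.centroids.shape[0]


@dataclass(frozen=True)
class ClusterSummary:
    cluster: int
    size: int
    wt_center_mean: float
    ko_center_mean: float
    ratio: float


@dataclass(frozen=True)
class LossCall:
    gene_id: str
    wt_score: float
    ko_score: float
    ratio: float
    is_loss: bool
    support: float


def _sq_dists(x: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    # ||x||^2 - 2 x.c + ||c||^2, clipped at 0 against roundoff
    d = (x * x).sum(1)[:, None] - 2.0 * (x @ centroids.T) + (centroids * centroids).sum(1)[None, :]
    return np.maximum(d, 0.0)


def _kmeanspp(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = x.shape[0]
    centroids = np.empty((k, x.shape[1]))
    centroids[0] = x[rng.integers(n)]
    d2 = ((x - centroids[0]) ** 2).sum(1)
    for j in range(1, k):
        total = d2.sum()
        if total <= 0:  # all points coincide with chosen centers
            centroids[j] = x[rng.integers(n)]
            continue
        centroids[j] = x[rng.choice(n, p=d2 / total)]
        d2 = np.minimum(d2, ((x - centroids[j]) ** 2).sum(1))
    return centroids


def compute_wcss(x: np.ndarray, labels: np.ndarray, centroids: np.ndarray) -> float:
    return float(((x - centroids[labels]) ** 2).sum())


def kmeans_profiles(
    stacked: np.ndarray,
    k: int,
    seed: int = 0,
    n_restarts: int = 4,
    max_iter: int = 100,
    tol: float = 1e-6,
    gene_ids: Sequence[str] | None = None,
) -> ClusterAssignment:
    """Lloyd's k-means with k-means++ seeding; best of ``n_restarts`` by wcss.

    Deterministic given ``seed``.  An empty cluster arising during iteration
    is re-seeded at the point farthest from its assigned centroid.
    """
    x = np.asarray(stacked, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("stacked profile matrix must be 2-D")
    n = x.shape[0]
    if not (1 <= k <= n):
        raise ValueError(f"k must be in [1, {n}], got {k}")
    if gene_ids is None:
        gene_ids = tuple(f"g{i}" for i in range(n))
    elif len(gene_ids) != n:
        raise ValueError("gene_ids length does not match matrix")

    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for _ in range(max(1, n_restarts)):
        centroids = _kmeanspp(x, k, rng)
        prev = np.inf
        for _ in range(max_iter):
            d2 = _sq_dists(x, centroids)
            labels = d2.argmin(1)
            # re-seed empty clusters at the current farthest point
            for _ in range(k):
                counts = np.bincount(labels, minlength=k)
                empty = np.flatnonzero(counts == 0)
                if empty.size == 0:
                    break
                far = int(d2[np.arange(n), labels].argmax())
                centroids[empty[0]] = x[far]
                d2 = _sq_dists(x, centroids)
                labels = d2.argmin(1)
            for j in range(k):
                members = labels == j
                if members.any():
                    centroids[j] = x[members].mean(0)
            wcss = compute_wcss(x, labels, centroids)
            if prev - wcss <= tol:
                break
            prev = wcss
        if best is None or wcss < best[0]:
            best = (wcss, labels.copy(), centroids.copy())
    wcss, labels, centroids = best
    return ClusterAssignment(tuple(gene_ids), labels, centroids, wcss, seed)


def characterize_clusters(
    assignment: ClusterAssignment,
    bins: int,
    core_bins: tuple[int, int],
    eps: float = 0.1,
) -> list[ClusterSummary]:
    """Per-cluster core means of the WT and KO halves of the stacked centroid.

    ``core_bins`` is a half-open index range inside one condition's profile.
    The ratio is ``(ko_mean + eps) / (wt_mean + eps)``; a flat-zero centroid
    therefore has ratio 1 (the empty-signal convention).
    """
    if assignment.centroids.shape[1] != 2 * bins:
        raise ValueError("centroid length does not match 2*bins")
    lo, hi = core_bins
    if not (0 <= lo < hi <= bins):
        raise ValueError(f"core bin range [{lo},{hi}) outside [0,{bins})")
    out = []
    counts = np.bincount(assignment.labels, minlength=assignment.k)
    for j in range(assignment.k):
        wt = float(assignment.centroids[j, lo:hi].mean())
        ko = float(assignment.centroids[j, bins + lo:bins + hi].mean())
        out.append(ClusterSummary(j, int(counts[j]), wt, ko, (ko + eps) / (wt + eps)))
    return out


def default_tau_wt(wt_scores: np.ndarray, percentile: float = 60.0) -> float:
    """Default WT-strength gate: percentile of nonzero WT promoter scores."""
    nz = wt_scores[wt_scores > 0]
    if nz.size == 0:
        return np.inf  # no WT signal anywhere: nothing can be called a loss
    return float(np.percentile(nz, percentile))


def call_loss_genes(
    wt: SignalMatrix,
    ko: SignalMatrix,
    k: int = 10,
    core_halfwidth: int = 500,
    tau_wt: float | None = None,
    rho: float = 0.25,
    eps: float = 0.1,
    n_consensus: int = 10,
    min_support: float = 0.8,
    base_seed: int = 0,
    n_restarts: int = 4,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> list[LossCall]:
    """Consensus k-means loss calling over stacked WT/KO rpm profiles.

    Runs ``n_consensus`` clusterings with seeds ``base_seed .. base_seed +
    n_consensus - 1``; see the module docstring for the gating logic.
    """
    if wt.gene_ids != ko.gene_ids:
        raise ValueError("WT and KO matrices must share gene ids and order")
    if (wt.bin_size, wt.flank) != (ko.bin_size, ko.flank):
        raise ValueError("WT and KO matrices must share bin geometry")
    if wt.units != "rpm" or ko.units != "rpm":
        raise ValueError("loss calling requires rpm-normalized matrices")

    wt_scores = promoter_score(wt, core_halfwidth)
    ko_scores = promoter_score(ko, core_halfwidth)
    ratios = (ko_scores + eps) / (wt_scores + eps)
    if tau_wt is None:
        tau_wt = default_tau_wt(wt_scores)
        log.info("call_loss_genes: tau_wt defaulted to %.4g rpm", tau_wt)

    stacked = np.hstack([wt.values, ko.values])
    core = core_bin_range(wt, core_halfwidth)
    support = np.zeros(len(wt.gene_ids))
    for i in range(n_consensus):
        assignment = kmeans_profiles(stacked, k, seed=base_seed + i,
                                     n_restarts=n_restarts, max_iter=max_iter,
                                     tol=tol, gene_ids=wt.gene_ids)
        summaries = characterize_clusters(assignment, wt.bins, core, eps=eps)
        loss_clusters = {s.cluster for s in summaries
                         if s.wt_center_mean >= tau_wt and s.ratio <= rho}
        if loss_clusters:
            support += np.isin(assignment.labels, list(loss_clusters))
    support /= max(1, n_consensus)

    calls = []
    for i, gid in enumerate(wt.gene_ids):
        is_loss = bool(support[i] >= min_support
                       and wt_scores[i] >= tau_wt and ratios[i] <= rho)
        calls.append(LossCall(gid, float(wt_scores[i]), float(ko_scores[i]),
                              float(ratios[i]), is_loss, float(support[i])))
    log.info("call_loss_genes: %d/%d genes called loss (tau_wt=%.4g, rho=%.3g)",
             sum(c.is_loss for c in calls), len(calls), tau_wt, rho)
    return calls


def heatmap_order(assignment: ClusterAssignment, stacked: np.ndarray) -> np.ndarray:
    """Gene order for heatmap export: by cluster, then by distance to centroid."""
    x = np.asarray(stacked, dtype=np.float64)
    d = ((x - assignment.centroids[assignment.labels]) ** 2).sum(1)
    return np.lexsort((d, assignment.labels))


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def loss_calls_to_frame(calls: Sequence[LossCall]) -> pd.DataFrame:
    df = pd.DataFrame([c.__dict__ for c in calls]).set_index("gene_id")
    return df[["wt_score", "ko_score", "ratio", "is_loss", "support"]]


def write_loss_calls(calls: Sequence[LossCall], path: str | Path) -> None:
    loss_calls_to_frame(calls).to_csv(path, sep="\t", float_format="%.10g")


def read_loss_calls(path: str | Path) -> list[LossCall]:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    return [LossCall(gid, float(r.wt_score), float(r.ko_score), float(r.ratio),
                     bool(r.is_loss), float(r.support))
            for gid, r in df.iterrows()]
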