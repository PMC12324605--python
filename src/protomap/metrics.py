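"""Evaluation metrics: per-cell similarity/correlation, cross-modal
retrieval (FOSCTTM, match score, cell-type retrieval), spatial
autocorrelation (Moran's I), and weighted kernel MMD.

Conventions: FOSCTTM uses Euclidean distance by default (cosine by flag)
with average ranks on ties; Moran's I uses a symmetric, row-standardized
k-nearest-neighbor weight graph; MMD is a biased V-statistic with a
Gaussian kernel of bandwidth ``blur`` on weighted 2-D point sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import rankdata
from sklearn.neighbors import NearestNeighbors

__all__ = ["MetricReport", "SpatialMetricReport", "per_cell_metrics",
           "foscttm", "match_score", "celltype_retrieval", "morans_i",
           "cell_level_mmd"]


@dataclass
class MetricReport:
    """Per-cell similarity arrays with their means over the evaluated cells."""

    cosine: np.ndarray = None
    pearson: np.ndarray = None
    spearman: np.ndarray = None
    mean_cosine: float = None
    mean_pearson: float = None
    mean_spearman: float = None
    n_excluded: int = 0
    foscttm: float = None
    match_score: float = None
    acc: float = None
    topk_curve: list = field(default_factory=list)
    n_cells: int = 0
    n_proteins: int = 0


@dataclass
class SpatialMetricReport:
    morans_i: dict = field(default_factory=dict)
    mmd: list = field(default_factory=list)
    knn_k: int = 8
    row_standardized: bool = True


def _rowwise_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    num = (ac * bc).sum(axis=1)
    den = np.sqrt((ac**2).sum(axis=1) * (bc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def per_cell_metrics(truth: np.ndarray, pred: np.ndarray) -> MetricReport:
    """Cosine, Pearson and Spearman per cell, averaged over valid cells.

    Cells where either vector has zero variance have undefined
    correlations; they are excluded from the correlation means and counted
    in ``n_excluded``. Spearman uses average ranks on ties.
    """
    truth = np.asarray(truth, dtype=np.float64)
    pred = np.asarray(pred, dtype=np.float64)
    if truth.shape != pred.shape:
        raise ValueError(f"shape mismatch {truth.shape} vs {pred.shape}")
    n, p = truth.shape
    if p < 2:
        raise ValueError("correlations need at least 2 proteins per cell")

    tn = np.linalg.norm(truth, axis=1)
    pn = np.linalg.norm(pred, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosine = (truth * pred).sum(axis=1) / (tn * pn)

    pearson = _rowwise_pearson(truth, pred)
    spearman = _rowwise_pearson(rankdata(truth, axis=1), rankdata(pred, axis=1))

    valid = np.isfinite(pearson) & np.isfinite(spearman)
    return MetricReport(
        cosine=cosine, pearson=pearson, spearman=spearman,
        mean_cosine=float(np.nanmean(cosine)),
        mean_pearson=float(pearson[valid].mean()) if valid.any() else float("nan"),
        mean_spearman=float(spearman[valid].mean()) if valid.any() else float("nan"),
        n_excluded=int((~valid).sum()), n_cells=n, n_proteins=p)


def _cross_distances(Z_a: np.ndarray, Z_b: np.ndarray, metric: str) -> np.ndarray:
    Z_a = np.asarray(Z_a, dtype=np.float64)
    Z_b = np.asarray(Z_b, dtype=np.float64)
    if Z_a.shape != Z_b.shape:
        raise ValueError("embedding sets must have equal shapes")
    return cdist(Z_a, Z_b, metric="euclidean" if metric == "euclidean" else "cosine")


def foscttm(Z_a: np.ndarray, Z_b: np.ndarray, metric: str = "euclidean") -> float:
    """Fraction of samples closer than the true match.

    For each cell i, the rank (average rank on ties, 1 = closest) of its
    true match d(i, i) among {d(i, j)}_j; returns mean (rank−1)/(N−1).
    0 = perfect alignment, 0.5 = random.
    """
    D = _cross_distances(Z_a, Z_b, metric)
    n = D.shape[0]
    if n < 2:
        raise ValueError("need at least 2 cells")
    d_true = np.diag(D)[:, None]
    less = (D < d_true).sum(axis=1)
    equal = (D == d_true).sum(axis=1)  # includes the true match itself
    ranks = less + (equal + 1) / 2.0
    return float(((ranks - 1) / (n - 1)).mean())


def match_score(Z_a: np.ndarray, Z_b: np.ndarray, metric: str = "euclidean") -> float:
    """Fraction of cells whose opposite-modality nearest neighbor is their
    true partner; ties broken toward the smallest index (and warned about)."""
    D = _cross_distances(Z_a, Z_b, metric)
    mins = D.min(axis=1, keepdims=True)
    tie_rows = int(((D == mins).sum(axis=1) > 1).sum())
    if tie_rows:
        warnings.warn(f"{tie_rows} row(s) had tied nearest neighbors; "
                      "smallest index used")
    return float((D.argmin(axis=1) == np.arange(D.shape[0])).mean())


def celltype_retrieval(Z_query: np.ndarray, Z_ref: np.ndarray,
                       query_labels, ref_labels,
                       k_percents: list[float] = (1, 5, 10, 20, 50, 100),
                       ) -> tuple[list[tuple[float, float]], float]:
    """Top-k% cell-type matching accuracy curve plus top-1 accuracy.

    For each query, references are sorted by cosine similarity; a curve
    point at k% is the fraction of queries whose label appears among the
    top ⌈k%·n_ref⌉ references. ``acc`` is nearest-reference label accuracy.
    """
    Z_query = np.asarray(Z_query, dtype=np.float64)
    Z_ref = np.asarray(Z_ref, dtype=np.float64)
    if Z_ref.shape[0] == 0:
        raise ValueError("empty reference set")
    q = np.asarray(query_labels, dtype=object)
    r = np.asarray(ref_labels, dtype=object)
    qn = Z_query / np.linalg.norm(Z_query, axis=1, keepdims=True)
    rn = Z_ref / np.linalg.norm(Z_ref, axis=1, keepdims=True)
    sim = qn @ rn.T
    order = np.argsort(-sim, axis=1, kind="stable")
    sorted_labels = r[order]
    acc = float((sorted_labels[:, 0] == q).mean())
    curve = []
    n_ref = Z_ref.shape[0]
    for k in k_percents:
        top = int(np.ceil(k / 100.0 * n_ref))
        hit = (sorted_labels[:, :top] == q[:, None]).any(axis=1)
        curve.append((float(k), float(hit.mean())))
    return curve, acc


def knn_weight_matrix(coords: np.ndarray, k: int = 8,
                      row_standardize: bool = True) -> np.ndarray:
    """Symmetric k-nearest-neighbor spatial weights, optionally
    row-standardized."""
    coords = np.asarray(coords, dtype=np.float64)
    n = coords.shape[0]
    if n <= k:
        raise ValueError(f"need more than k={k} spots, got {n}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    _, idx = nn.kneighbors(coords)
    W = np.zeros((n, n))
    rows = np.repeat(np.arange(n), k)
    W[rows, idx[:, 1:].ravel()] = 1.0
    W = np.maximum(W, W.T)  # symmetrize
    if row_standardize:
        W = W / W.sum(axis=1, keepdims=True)
    return W


def morans_i(values: np.ndarray, coords: np.ndarray, k: int = 8,
             W: np.ndarray | None = None) -> float:
    """Moran's I over a symmetric row-standardized k-NN weight graph.

    I = (n/ΣW) · Σ_ij w_ij (x_i−x̄)(x_j−x̄) / Σ_i (x_i−x̄)².
    A precomputed weight matrix ``W`` may be supplied to amortize the
    graph build over many proteins.
    """
    x = np.asarray(values, dtype=np.float64)
    z = x - x.mean()
    denom = (z**2).sum()
    if denom == 0:
        raise ValueError("Moran's I is undefined for constant values")
    if W is None:
        W = knn_weight_matrix(coords, k=k)
    n = x.shape[0]
    if W.shape != (n, n):
        raise ValueError("weight matrix does not match number of spots")
    return float((n / W.sum()) * (z @ W @ z) / denom)


def cell_level_mmd(points_a: np.ndarray, points_b: np.ndarray,
                   blur: float | list[float],
                   weights_a: np.ndarray | None = None,
                   weights_b: np.ndarray | None = None):
    """Squared MMD between two weighted 2-D point sets, Gaussian kernel.

    ``blur`` is the kernel bandwidth (the spatial scale compared); a list
    of blurs returns one value per blur. Weights are normalized to sum to
    1; the biased V-statistic is clamped at 0.
    """
    A = np.atleast_2d(np.asarray(points_a, dtype=np.float64))
    B = np.atleast_2d(np.asarray(points_b, dtype=np.float64))
    if A.shape[0] == 0 or B.shape[0] == 0:
        raise ValueError("point sets must be non-empty")
    wa = np.ones(A.shape[0]) if weights_a is None else np.asarray(weights_a, float)
    wb = np.ones(B.shape[0]) if weights_b is None else np.asarray(weights_b, float)
    if np.any(wa < 0) or np.any(wb < 0):
        raise ValueError("weights must be nonnegative")
    if wa.sum() <= 0 or wb.sum() <= 0:
        raise ValueError("weights must sum to a positive value")
    wa = wa / wa.sum()
    wb = wb / wb.sum()
    daa = cdist(A, A, "sqeuclidean")
    dbb = cdist(B, B, "sqeuclidean")
    dab = cdist(A, B, "sqeuclidean")

    blurs = np.atleast_1d(np.asarray(blur, dtype=np.float64))
    if np.any(blurs <= 0):
        raise ValueError("blur must be positive")
    out = []
    for b in blurs:
        s = 2.0 * b * b
        val = (wa @ np.exp(-daa / s) @ wa
               + wb @ np.exp(-dbb / s) @ wb
               - 2.0 * wa @ np.exp(-dab / s) @ wb)
        out.append(max(float(val), 0.0))
    return out[0] if np.isscalar(blur) else out
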