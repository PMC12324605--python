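"""Zero-shot soft assignment of RNA cells to spatial protein spots.

Cells and spots are matched purely by cosine similarity of their shared-
space embeddings: a temperature-controlled softmax over spots turns each
cell's similarity row into a soft assignment, and predicted per-cell
protein panels are projected into space as weighted spot averages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import cosine_similarity_matrix

__all__ = ["SpatialAssignment", "soft_assign", "project_to_spots",
           "map_cell_types"]


@dataclass
class SpatialAssignment:
    """Similarity matrix S, row-stochastic soft assignment W, temperature."""

    S: np.ndarray
    W: np.ndarray
    tau_m: float
    renormalized: bool = True

    def __post_init__(self):
        if np.any(self.W < 0):
            raise ValueError("W entries must be nonnegative")
        rowsums = self.W.sum(axis=1)
        if not np.allclose(rowsums, 1.0, atol=1e-6):
            raise ValueError("each row of W must sum to 1")


def soft_assign(Z_rna: np.ndarray, Z_prot: np.ndarray, tau_m: float = 0.1,
                top_k: int | None = None) -> SpatialAssignment:
    """W rows = softmax over spots of S/τ_m (max-subtraction stabilized).

    ``top_k`` optionally truncates each row to its K largest similarities
    before renormalization (an approximation for large instances).
    """
    if tau_m <= 0:
        raise ValueError("tau_m must be positive")
    S = cosine_similarity_matrix(Z_rna, Z_prot)
    logits = S / tau_m
    logits = logits - logits.max(axis=1, keepdims=True)
    W = np.exp(logits)
    if top_k is not None and top_k < W.shape[1]:
        thresh = -np.partition(-W, top_k - 1, axis=1)[:, top_k - 1][:, None]
        W = np.where(W >= thresh, W, 0.0)
    W = W / W.sum(axis=1, keepdims=True)
    return SpatialAssignment(S=S, W=W, tau_m=float(tau_m))


def project_to_spots(assignment: SpatialAssignment, predicted: np.ndarray,
                     renormalize: bool | None = None) -> np.ndarray:
    """x̂ = Wᵀ · predicted, per spot.

    With ``renormalize`` (default from the assignment, normally True) each
    spot's incoming cell weights are rescaled to sum to 1, making the
    projection a weighted mean that stays on the normalized intensity
    scale; without it the literal weighted sum is returned.
    """
    predicted = np.asarray(predicted, dtype=np.float64)
    if predicted.ndim == 1:
        predicted = predicted[:, None]
    if predicted.shape[0] != assignment.W.shape[0]:
        raise ValueError(
            f"predicted has {predicted.shape[0]} rows but W has "
            f"{assignment.W.shape[0]} cells")
    renorm = assignment.renormalized if renormalize is None else renormalize
    out = assignment.W.T @ predicted
    if renorm:
        colsums = assignment.W.sum(axis=0)
        out = out / np.where(colsums > 0, colsums, 1.0)[:, None]
    return out


def map_cell_types(assignment: SpatialAssignment, cell_labels,
                   ) -> tuple[np.ndarray, list[str]]:
    """Per-spot W-weighted label distribution (rows sum to 1) and label order.

    ``argmax`` of a row gives the spot's hard label.
    """
    labels = np.asarray(cell_labels, dtype=object)
    if labels.shape[0] != assignment.W.shape[0]:
        raise ValueError("labels must cover all cells")
    categories = sorted(set(map(str, labels)))
    onehot = np.stack([(labels == c).astype(np.float64) for c in categories], axis=1)
    dist = assignment.W.T @ onehot
    colsums = assignment.W.sum(axis=0)
    dist = dist / np.where(colsums > 0, colsums, 1.0)[:, None]
    return dist, categories
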