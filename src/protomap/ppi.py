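"""Per-feature node embeddings from a protein–protein interaction graph.

Embeddings are learned by link prediction: a dot-product score between
endpoint vectors is trained with a logistic loss against held-out positive
edges and sampled non-edges. Features missing from the network get zero
vectors downstream, so their tokens reduce to the expression projection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
from sklearn.metrics import roc_auc_score

__all__ = ["PPIEmbeddingTable", "embed_graph", "lookup",
           "read_edge_list", "write_edge_list"]


@dataclass
class PPIEmbeddingTable:
    """feature_id → fixed vector of dimension ``d_ppi``."""

    vectors: dict[str, np.ndarray] = field(default_factory=dict)
    d_ppi: int = 0

    def __post_init__(self):
        for k, v in self.vectors.items():
            v = np.asarray(v, dtype=np.float64)
            if v.shape != (self.d_ppi,):
                raise ValueError(f"vector for {k!r} has shape {v.shape}, "
                                 f"expected ({self.d_ppi},)")
            if not np.all(np.isfinite(v)):
                raise ValueError(f"non-finite embedding for {k!r}")
            self.vectors[k] = v

    @property
    def coverage(self) -> set[str]:
        return set(self.vectors)

    def save(self, path) -> None:
        ids = sorted(self.vectors)
        with h5py.File(path, "w") as f:
            f.create_dataset("ids", data=np.array(ids, dtype="S"))
            f.create_dataset("vectors",
                             data=np.stack([self.vectors[i] for i in ids])
                             if ids else np.zeros((0, self.d_ppi)))
            f.attrs["d_ppi"] = self.d_ppi

    @classmethod
    def load(cls, path) -> "PPIEmbeddingTable":
        with h5py.File(path, "r") as f:
            ids = [s.decode() for s in f["ids"][...]]
            mat = f["vectors"][...]
            d = int(f.attrs["d_ppi"])
        return cls(vectors={i: mat[k] for k, i in enumerate(ids)}, d_ppi=d)


def read_edge_list(path) -> list[tuple[str, str, float]]:
    """Read a 3-column tab-delimited (node, node, confidence) edge list."""
    edges = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{ln}: expected 3 tab-separated fields")
            try:
                w = float(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: bad weight {parts[2]!r}") from exc
            edges.append((parts[0], parts[1], w))
    return edges


def write_edge_list(edges, path) -> None:
    with open(path, "w") as fh:
        for a, b, w in edges:
            fh.write(f"{a}\t{b}\t{w}\n")


def embed_graph(edges: list[tuple[str, str, float]], d_ppi: int = 32,
                holdout_fraction: float = 0.1, seed: int = 0,
                n_epochs: int = 60, lr: float = 0.05,
                n_negatives: int = 5) -> tuple[PPIEmbeddingTable, float]:
    """Train node embeddings by weighted link prediction.

    Positive edges score ``sigmoid(u_i · u_j)``; each positive draws
    ``n_negatives`` random non-neighbors as negatives. Returns the table
    and the AUC on a held-out edge set scored against an equal number of
    sampled non-edges.
    """
    if not edges:
        raise ValueError("graph has no edges")
    if d_ppi < 2:
        raise ValueError("d_ppi must be ≥ 2")
    if not (0 < holdout_fraction < 1):
        raise ValueError("holdout_fraction must be in (0, 1)")

    rng = np.random.default_rng(seed)
    nodes = sorted({n for a, b, _ in edges for n in (a, b)})
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    eidx = np.array([[index[a], index[b]] for a, b, _ in edges])
    weights = np.array([w for _, _, w in edges], dtype=np.float64)

    if len(edges) < 2:
        raise ValueError("no eligible held-out edges: need at least 2 edges "
                         "to split into train and holdout")
    n_hold = min(max(1, int(round(holdout_fraction * len(edges)))),
                 len(edges) - 1)
    perm = rng.permutation(len(edges))
    hold, train = perm[:n_hold], perm[n_hold:]

    edge_set = {frozenset(e) for e in map(tuple, eidx)}
    emb = 0.1 * rng.standard_normal((n, d_ppi))

    def sample_non_edges(k: int) -> np.ndarray:
        out = []
        while len(out) < k:
            i, j = rng.integers(0, n, size=2)
            if i != j and frozenset((int(i), int(j))) not in edge_set:
                out.append((i, j))
        return np.array(out)

    for _ in range(n_epochs):
        order = rng.permutation(train)
        for batch_start in range(0, len(order), 256):
            batch = order[batch_start:batch_start + 256]
            pos = eidx[batch]
            w = weights[batch]
            neg = sample_non_edges(len(batch) * n_negatives)
            grad = np.zeros_like(emb)
            # positives: maximize log sigmoid(u_i . u_j), weighted by confidence
            ui, uj = emb[pos[:, 0]], emb[pos[:, 1]]
            s = 1.0 / (1.0 + np.exp(-(ui * uj).sum(axis=1)))
            coef = (w * (1.0 - s))[:, None]
            np.add.at(grad, pos[:, 0], coef * uj)
            np.add.at(grad, pos[:, 1], coef * ui)
            # negatives: minimize log sigmoid(u_i . u_j)
            vi, vj = emb[neg[:, 0]], emb[neg[:, 1]]
            sn = 1.0 / (1.0 + np.exp(-(vi * vj).sum(axis=1)))
            coefn = (-sn)[:, None]
            np.add.at(grad, neg[:, 0], coefn * vj)
            np.add.at(grad, neg[:, 1], coefn * vi)
            emb += lr * grad

    # held-out AUC: positive held-out edges vs an equal number of non-edges
    pos = eidx[hold]
    neg = sample_non_edges(len(hold))
    pos_scores = (emb[pos[:, 0]] * emb[pos[:, 1]]).sum(axis=1)
    neg_scores = (emb[neg[:, 0]] * emb[neg[:, 1]]).sum(axis=1)
    y = np.concatenate([np.ones(len(pos_scores)), np.zeros(len(neg_scores))])
    auc = float(roc_auc_score(y, np.concatenate([pos_scores, neg_scores])))

    table = PPIEmbeddingTable(
        vectors={nodes[i]: emb[i].copy() for i in range(n)}, d_ppi=d_ppi)
    return table, auc


def lookup(table: PPIEmbeddingTable, feature_ids: list[str],
           ) -> tuple[np.ndarray, list[str]]:
    """Rows in input order; uncovered features get zero vectors.

    Returns the matrix and the list of feature IDs that fell back to zero.
    """
    out = np.zeros((len(feature_ids), table.d_ppi))
    missing = []
    for r, fid in enumerate(feature_ids):
        vec = table.vectors.get(fid)
        if vec is None:
            missing.append(fid)
        else:
            out[r] = vec
    if missing:
        warnings.warn(f"{len(missing)} feature(s) not in PPI coverage; zero vectors used")
    return out, missing
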