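"""Contrastive fine-tuning that aligns RNA and protein cell embeddings.

A symmetric InfoNCE objective on the cosine-similarity matrix of paired
cells: each cell's RNA embedding should be most similar to its own
protein embedding (and vice versa), with all other cells in the minibatch
acting as negatives. Temperature τ divides the similarities before the
softmax and may be learned jointly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .data import ExpressionDataset
from .encoder import EncoderModel, build_tokens, encode, integrate_batch_token
from .nn.autograd import Parameter, Tensor
from .nn.layers import Adam

__all__ = ["ContrastiveConfig", "cosine_similarity_matrix", "contrastive_loss",
           "finetune"]


@dataclass
class ContrastiveConfig:
    tau: float = 0.07
    learnable_tau: bool = True
    n_epochs: int = 40
    batch_size: int = 128
    learning_rate: float = 3e-3
    use_projection_head: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be positive")


def _normalize_rows(E: Tensor) -> Tensor:
    norms = ((E * E).sum(axis=-1, keepdims=True) + 1e-30).sqrt()
    return E / norms


def cosine_similarity_matrix(E_rna: np.ndarray, E_prot: np.ndarray) -> np.ndarray:
    """S_ij = cosine of RNA row i and protein row j."""
    E_rna = np.asarray(E_rna, dtype=np.float64)
    E_prot = np.asarray(E_prot, dtype=np.float64)
    for name, E in (("rna", E_rna), ("protein", E_prot)):
        bad = np.where(np.linalg.norm(E, axis=1) == 0)[0]
        if bad.size:
            raise ValueError(f"zero-norm {name} embedding row(s): {bad[:5].tolist()}")
    a = E_rna / np.linalg.norm(E_rna, axis=1, keepdims=True)
    b = E_prot / np.linalg.norm(E_prot, axis=1, keepdims=True)
    return a @ b.T


def contrastive_loss(S: np.ndarray, tau: float) -> float:
    """½·(row-wise + column-wise) InfoNCE cross-entropy on the diagonal.

    Computed in float64; exactly symmetric under S → Sᵀ.
    """
    S = np.asarray(S, dtype=np.float64)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("S must be square")
    if tau <= 0:
        raise ValueError("tau must be positive")
    logits = S / tau
    diag = np.diag(logits)
    row = (logsumexp(logits, axis=1) - diag).mean()
    col = (logsumexp(logits, axis=0) - diag).mean()
    return float(0.5 * (row + col))


def _contrastive_loss_t(S: Tensor, tau) -> Tensor:
    logits = S / tau
    n = S.shape[0]
    diag = (np.arange(n), np.arange(n))
    row = -logits.log_softmax(axis=1)[diag].mean()
    col = -logits.log_softmax(axis=0)[diag].mean()
    return 0.5 * (row + col)


def _embed_batch(model: EncoderModel, X: np.ndarray, feature_ids, dataset_ids,
                 use_head: bool) -> Tensor:
    batch = build_tokens(X, feature_ids, model)
    _, c = encode(batch, model, pooling="cls_token")
    z = integrate_batch_token(c, dataset_ids, model)
    return model.projection_head(z) if use_head else z


def finetune(rna: ExpressionDataset, protein: ExpressionDataset,
             models: tuple[EncoderModel, EncoderModel],
             config: ContrastiveConfig) -> tuple[EncoderModel, EncoderModel, list[float]]:
    """Contrastive fine-tuning on index-paired CITE-seq-style data.

    Both datasets must list identical cell IDs in identical order (the
    pairing contract); both encoders (and τ, if learnable) are updated in
    place. Returns the model pair and the per-epoch loss trace.
    """
    if rna.cell_ids != protein.cell_ids:
        raise ValueError("rna and protein cells are not paired "
                         "(cell_ids differ in content or order)")
    if not (rna.normalized and protein.normalized):
        raise ValueError("datasets must be normalized")
    rna_model, prot_model = models
    log_tau = Parameter(np.array(np.log(config.tau)))
    params = rna_model.parameters() + prot_model.parameters()
    if config.learnable_tau:
        params = params + [log_tau]
    opt = Adam(params, lr=config.learning_rate, clip_norm=1.0)
    rng = np.random.default_rng(config.seed + 29)
    trace: list[float] = []
    n = rna.n_cells
    for _ in range(config.n_epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            sel = order[start:start + config.batch_size]
            if len(sel) < 2:
                continue
            e_r = _normalize_rows(_embed_batch(
                rna_model, rna.values[sel], rna.feature_ids, rna.batch_id[sel],
                config.use_projection_head))
            e_p = _normalize_rows(_embed_batch(
                prot_model, protein.values[sel], protein.feature_ids,
                protein.batch_id[sel], config.use_projection_head))
            S = e_r @ e_p.swapaxes(0, 1)
            tau = log_tau.exp() if config.learnable_tau else config.tau
            loss = _contrastive_loss_t(S, tau)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        trace.append(float(np.mean(losses)) if losses else float("nan"))
    return rna_model, prot_model, trace
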