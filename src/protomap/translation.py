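"""RNA → protein abundance prediction via cross-attention translation.

An RNA cell embedding is expanded by a translation MLP into ``m`` slot
vectors (keys/values). Each protein is represented by a query vector
obtained by running the protein encoder on a single identity token for
that protein (no expression value). Scaled dot-product attention of the
query over the slots yields a context vector, and a linear head maps it
to the predicted normalized abundance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import ExpressionDataset
from .encoder import EncoderModel, integrate_batch_token
from .nn.autograd import Parameter, Tensor
from .nn.layers import MLP, Adam, Module

__all__ = ["TranslationConfig", "TranslationModel", "translate", "protein_query",
           "cross_attend", "predict_abundance", "train_translation",
           "predict_panel"]


@dataclass
class TranslationConfig:
    m_slots: int = 8
    hidden: int = 64
    use_output_bias: bool = True
    learning_rate: float = 3e-3
    n_epochs: int = 200
    batch_size: int = 256
    freeze_encoders: bool = True
    seed: int = 0


class TranslationModel(Module):
    """Translation MLP, protein-ID queries, attention scale, output head."""

    def __init__(self, d: int, config: TranslationConfig,
                 protein_model: EncoderModel, dataset_id: int = 0):
        self.config = config
        self.d = d
        rng = np.random.default_rng(config.seed + 101)
        self.mlp_trans = MLP([d, config.hidden, config.m_slots * d], rng)
        self.w_o = Parameter(0.1 * rng.standard_normal(d))
        self.bias_o = Parameter(np.array(0.0)) if config.use_output_bias else None
        self.attention_scale = 1.0 / np.sqrt(d)
        self.protein_model = protein_model
        self.dataset_id = dataset_id
        self.trained = False
        self._query_cache: dict[tuple[str, int], np.ndarray] = {}

    def parameters(self):
        # the protein encoder is frozen during translation training
        trainable = Module()
        trainable.mlp_trans = self.mlp_trans
        trainable.w_o = self.w_o
        if self.bias_o is not None:
            trainable.bias_o = self.bias_o
        return Module.parameters(trainable)


def translate(e_rna: np.ndarray | Tensor, model: TranslationModel) -> Tensor:
    """e_trans = MLP_trans(e_rna), reshaped to (..., m, d) slot vectors."""
    x = e_rna if isinstance(e_rna, Tensor) else Tensor(np.asarray(e_rna, float))
    if x.shape[-1] != model.d:
        raise ValueError(f"embedding dim {x.shape[-1]} != model dim {model.d}")
    out = model.mlp_trans(x)
    new_shape = x.shape[:-1] + (model.config.m_slots, model.d)
    return out.reshape(*new_shape)


def protein_query(protein_id: str, dataset_id: int, protein_model: EncoderModel,
                  ) -> np.ndarray:
    """u_p: pooled protein-encoder output for a single identity token.

    The token is the protein's learned ID embedding plus its adapted PPI
    vector — no expression value — integrated with the dataset token.
    """
    idx = protein_model.feature_index.get(protein_id)
    if idx is None:
        near = sorted(protein_model.feature_ids,
                      key=lambda f: abs(len(f) - len(protein_id)))[:5]
        raise KeyError(f"unknown protein {protein_id!r}; known IDs include {near}")
    d = protein_model.config.d
    tok = protein_model.id_embedding[np.array([idx])]  # (1, d)
    if protein_model.ppi_adapter is not None:
        tok = tok + protein_model.ppi_adapter(
            Tensor(protein_model.ppi_matrix[idx][None, :]))
    G = tok.reshape(1, 1, d)
    from .encoder import TokenBatch  # local import to avoid cycle at module load
    batch = TokenBatch(G=G, original_values=np.zeros((1, 1)),
                       feature_positions=np.array([idx]),
                       pad_mask=np.zeros((1, 1), dtype=bool))
    H = protein_model.transformer(batch.G, None)
    c = H[:, 0, :]
    z = integrate_batch_token(c, np.array([dataset_id]), protein_model,
                              strict=False)
    return z.data[0].copy()


def cross_attend(u_p: np.ndarray, e_trans: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """α_p = softmax(u_pᵀ e_transᵀ / √d); c_p = α_p · e_trans."""
    u_p = np.asarray(u_p, dtype=np.float64)
    e_trans = np.asarray(e_trans, dtype=np.float64)
    if e_trans.ndim != 2 or e_trans.shape[1] != u_p.shape[0]:
        raise ValueError("dimension mismatch between query and slots")
    logits = e_trans @ u_p / np.sqrt(u_p.shape[0])
    logits = logits - logits.max()
    alpha = np.exp(logits)
    alpha /= alpha.sum()
    return alpha, alpha @ e_trans


def predict_abundance(c_p: np.ndarray, model: TranslationModel,
                      clip: bool = True) -> float:
    """ŷ = w_oᵀ c_p (+ bias); clipped to [0, 1] at inference."""
    y = float(np.dot(model.w_o.data, np.asarray(c_p, dtype=np.float64)))
    if model.bias_o is not None:
        y += model.bias_o.item()
    return float(np.clip(y, 0.0, 1.0)) if clip else y


def _queries_for(model: TranslationModel, panel: list[str]) -> np.ndarray:
    rows = []
    for pid in panel:
        key = (pid, model.dataset_id)
        if key not in model._query_cache:
            model._query_cache[key] = protein_query(pid, model.dataset_id,
                                                    model.protein_model)
        rows.append(model._query_cache[key])
    return np.stack(rows)


def _forward_panel(model: TranslationModel, E: Tensor, U: np.ndarray) -> Tensor:
    """Batched prediction: E (B, d) embeddings, U (P, d) queries → (B, P)."""
    e_trans = translate(E, model)                       # (B, m, d)
    logits = (Tensor(U) @ e_trans.swapaxes(-1, -2)) * model.attention_scale
    alpha = logits.softmax(axis=-1)                     # (B, P, m)
    c = alpha @ e_trans                                 # (B, P, d)
    y = (c * model.w_o).sum(axis=-1)
    if model.bias_o is not None:
        y = y + model.bias_o
    return y


def train_translation(rna_embeddings: np.ndarray, protein: ExpressionDataset,
                      protein_model: EncoderModel,
                      config: TranslationConfig | None = None,
                      train_index: np.ndarray | None = None,
                      dataset_id: int = 0) -> TranslationModel:
    """Fit the translation head by MSE on normalized protein intensities.

    ``rna_embeddings`` are the aligned RNA cell embeddings (rows paired
    with ``protein`` cells); encoders stay frozen, only the translation
    MLP and output head are trained. ``train_index`` restricts training to
    a split's cells (few-shot / OOD regimes).
    """
    config = config or TranslationConfig()
    if protein.n_features == 0:
        raise ValueError("empty protein panel")
    if not protein.normalized:
        raise ValueError("protein dataset must be normalized")
    E = np.asarray(rna_embeddings, dtype=np.float64)
    if E.shape[0] != protein.n_cells:
        raise ValueError("embedding rows must pair with protein cells")
    idx = np.arange(protein.n_cells) if train_index is None else np.asarray(train_index)
    if idx.size == 0:
        raise ValueError("empty training index")

    model = TranslationModel(E.shape[1], config, protein_model, dataset_id)
    U = _queries_for(model, protein.feature_ids)
    Y = protein.values
    opt = Adam(model.parameters(), lr=config.learning_rate, clip_norm=1.0)
    rng = np.random.default_rng(config.seed + 37)
    for _ in range(config.n_epochs):
        order = rng.permutation(idx)
        for start in range(0, len(order), config.batch_size):
            sel = order[start:start + config.batch_size]
            pred = _forward_panel(model, Tensor(E[sel]), U)
            diff = pred - Tensor(Y[sel])
            loss = (diff * diff).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
    model.trained = True
    return model


def predict_panel(rna_embeddings: np.ndarray, panel: list[str],
                  model: TranslationModel, cell_ids: list[str] | None = None,
                  clip: bool = True) -> ExpressionDataset:
    """Predict one value per (cell, panel protein); panel order preserved.

    The panel may exceed any measured panel — every protein in the
    encoder vocabulary can be imputed.
    """
    if len(set(panel)) != len(panel):
        dupes = sorted({p for p in panel if panel.count(p) > 1})
        raise ValueError(f"duplicated protein(s) in panel: {dupes}")
    unknown = [p for p in panel if p not in model.protein_model.feature_index]
    if unknown:
        raise KeyError(f"unknown panel protein(s): {unknown}")
    E = np.asarray(rna_embeddings, dtype=np.float64)
    U = _queries_for(model, panel)
    pred = _forward_panel(model, Tensor(E), U).data
    pred = np.clip(pred, 0.0, 1.0) if clip else np.maximum(pred, 0.0)
    return ExpressionDataset(
        values=pred, feature_ids=list(panel),
        cell_ids=cell_ids or [f"cell{i}" for i in range(E.shape[0])],
        modality="protein", normalized=clip)
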