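"""Modality encoders: token construction, masking, transformer encoding,
batch-token integration, and masked-reconstruction pretraining.

Each cell's expression vector becomes a token sequence: token i is the
linearly projected expression value plus (optionally) an adapted PPI
vector for that feature. A learnable pooling (cls) token is prepended.
There are no positional encodings — feature identity is carried by the
PPI/ID embeddings, so encoding is permutation-equivariant in the tokens.
A cell embedding ``c`` (token mean or the cls row) is combined with a
learnable dataset token, ``z = c + α·b_d``, and a reconstruction head
predicts masked expression values from ``[z ; feature-ID embedding]``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field

import h5py
import numpy as np

from .data import ExpressionDataset
from .nn.autograd import Parameter, Tensor, concat
from .nn.layers import MLP, Adam, Linear, Module, TransformerEncoder
from .ppi import PPIEmbeddingTable, lookup

__all__ = ["EncoderConfig", "EncoderModel", "TokenBatch", "CellEmbeddingSet",
           "build_tokens", "mask_tokens", "encode", "integrate_batch_token",
           "encode_cells", "pretrain", "masked_reconstruction_loss"]


@dataclass
class EncoderConfig:
    """Architecture and optimizer settings shared by both modality encoders."""

    d: int = 32
    n_layers: int = 1
    n_heads: int = 2
    mask_rate: float = 0.3
    attention_kind: str = "exact"
    max_tokens: int = 2048
    learning_rate: float = 3e-3
    n_epochs: int = 10
    batch_size: int = 32
    use_batch_token: bool = True
    use_ppi: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.d % self.n_heads != 0:
            raise ValueError("d must be divisible by n_heads")
        if not (0 < self.mask_rate < 1):
            raise ValueError("mask_rate must be in (0, 1)")
        if self.attention_kind not in ("exact", "linear_favor"):
            raise ValueError(f"unknown attention_kind {self.attention_kind!r}")


class EncoderModel(Module):
    """One modality's encoder parameters.

    Parameters are created from ``config.seed`` (offset per modality) so a
    model build is a pure function of (vocabulary, config, n_datasets).
    """

    def __init__(self, feature_ids: list[str], config: EncoderConfig,
                 n_datasets: int = 1, ppi_table: PPIEmbeddingTable | None = None,
                 modality: str = "rna"):
        self.config = config
        self.modality = modality
        self.feature_ids = list(feature_ids)
        self.feature_index = {f: i for i, f in enumerate(self.feature_ids)}
        self.n_datasets = n_datasets
        d = config.d
        rng = np.random.default_rng(config.seed + (0 if modality == "rna" else 7919))

        self.expr_projection = Linear(1, d, rng)
        if config.use_ppi and ppi_table is not None:
            mat, _ = lookup(ppi_table, self.feature_ids)
            self.ppi_matrix = mat  # fixed (n_vocab, d_ppi), not trained
            self.ppi_adapter = Linear(ppi_table.d_ppi, d, rng)
        else:
            self.ppi_matrix = None
            self.ppi_adapter = None
        self.id_embedding = Parameter(0.1 * rng.standard_normal((len(self.feature_ids), d)))
        self.transformer = TransformerEncoder(d, config.n_layers, config.n_heads,
                                              rng, kind=config.attention_kind)
        if config.use_batch_token:
            self.batch_token_table = Parameter(
                0.01 * rng.standard_normal((n_datasets, d)))
        else:
            self.batch_token_table = None
        self.alpha = Parameter(np.array(1.0))
        self.mask_token = Parameter(0.1 * rng.standard_normal(d))
        self.cls_token = Parameter(0.1 * rng.standard_normal(d))
        self.reconstruction_head = MLP([2 * d, 2 * d, 1], rng)
        self.projection_head = Linear(d, d, rng)

    # -- persistence -----------------------------------------------------
    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.attrs["config"] = json.dumps(asdict(self.config))
            f.attrs["modality"] = self.modality
            f.attrs["n_datasets"] = self.n_datasets
            f.create_dataset("feature_ids", data=np.array(self.feature_ids, dtype="S"))
            if self.ppi_matrix is not None:
                f.create_dataset("ppi_matrix", data=self.ppi_matrix)
            for i, arr in enumerate(self.state_arrays()):
                f.create_dataset(f"param_{i}", data=arr)

    @classmethod
    def load(cls, path) -> "EncoderModel":
        with h5py.File(path, "r") as f:
            config = EncoderConfig(**json.loads(f.attrs["config"]))
            feature_ids = [s.decode() for s in f["feature_ids"][...]]
            model = cls(feature_ids, config, n_datasets=int(f.attrs["n_datasets"]),
                        modality=f.attrs["modality"])
            if "ppi_matrix" in f:
                mat = f["ppi_matrix"][...]
                rng = np.random.default_rng(config.seed)
                model.ppi_matrix = mat
                model.ppi_adapter = Linear(mat.shape[1], config.d, rng)
            n = 0
            while f"param_{n}" in f:
                n += 1
            model.load_state_arrays([f[f"param_{i}"][...] for i in range(n)])
        return model


@dataclass
class TokenBatch:
    """Token embeddings for a minibatch of cells.

    ``G`` has shape (batch, 1 + n_real + n_pad, d): a leading cls token,
    the feature tokens, then padding. ``feature_positions`` maps token
    columns to vocabulary rows.
    """

    G: Tensor
    original_values: np.ndarray          # (batch, n_real)
    feature_positions: np.ndarray        # (n_real,) vocabulary indices
    pad_mask: np.ndarray                 # (batch, n_cols) True at pads
    mask_indices: np.ndarray | None = None  # (batch, k) column indices in G

    @property
    def n_real(self) -> int:
        return self.original_values.shape[1]


@dataclass
class CellEmbeddingSet:
    """Per-cell embeddings in the shared space."""

    Z: np.ndarray
    pooling: str
    modality: str
    cell_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not np.all(np.isfinite(self.Z)):
            raise ValueError("non-finite cell embeddings")


def _select_features(X: np.ndarray, feature_ids: list[str], max_tokens: int,
                     ) -> tuple[np.ndarray, list[str]]:
    """Truncate to the highest-variance features, ties broken by feature ID."""
    if X.shape[1] <= max_tokens:
        return X, feature_ids
    var = X.var(axis=0)
    order = sorted(range(len(feature_ids)), key=lambda j: (-var[j], feature_ids[j]))
    keep = sorted(order[:max_tokens])
    return X[:, keep], [feature_ids[j] for j in keep]


def build_tokens(X: np.ndarray, feature_ids: list[str], model: EncoderModel,
                 n_pad: int = 0) -> TokenBatch:
    """Construct g_i = expr_projection(x_i) [+ ppi_adapter(x_i^ppi)] tokens.

    ``X`` is (cells, features) with normalized values in [0, 1]. A cls
    token is prepended and ``n_pad`` padding tokens appended.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite expression values")
    X, feature_ids = _select_features(X, list(feature_ids), model.config.max_tokens)
    try:
        positions = np.array([model.feature_index[f] for f in feature_ids])
    except KeyError as exc:
        raise KeyError(f"feature {exc.args[0]!r} not in encoder vocabulary") from exc
    B, n = X.shape
    d = model.config.d

    tokens = model.expr_projection(Tensor(X[..., None]))  # (B, n, d)
    if model.ppi_adapter is not None:
        ppi_rows = model.ppi_matrix[positions]
        tokens = tokens + model.ppi_adapter(Tensor(ppi_rows))  # broadcast (n, d)

    cls = model.cls_token.reshape(1, 1, d) + Tensor(np.zeros((B, 1, d)))
    parts = [cls, tokens]
    if n_pad > 0:
        parts.append(Tensor(np.zeros((B, n_pad, d))))
    G = concat(parts, axis=1)
    pad_mask = np.zeros((B, 1 + n + n_pad), dtype=bool)
    if n_pad > 0:
        pad_mask[:, 1 + n:] = True
    return TokenBatch(G=G, original_values=X, feature_positions=positions,
                      pad_mask=pad_mask)


def mask_tokens(batch: TokenBatch, mask_rate: float, seed, model: EncoderModel,
                ) -> TokenBatch:
    """Replace a random ``mask_rate`` fraction of real tokens by the mask token.

    ``round(mask_rate · n_real)`` positions per cell are drawn uniformly
    without replacement from the feature tokens (never the cls or padding
    positions). Original values are retained for the loss. ``seed`` may be
    an int or a ``numpy.random.Generator``.
    """
    if not (0 < mask_rate < 1):
        raise ValueError("mask_rate must be in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    B, n_cols, d = batch.G.shape
    n_real = batch.n_real
    k = int(np.floor(mask_rate * n_real + 0.5))
    if k == 0:
        raise ValueError(f"mask_rate {mask_rate} masks zero of {n_real} tokens")
    cols = np.stack([1 + rng.choice(n_real, size=k, replace=False)
                     for _ in range(B)])  # column indices, offset past cls
    mask = np.zeros((B, n_cols), dtype=bool)
    np.put_along_axis(mask, cols, True, axis=1)
    m = Tensor(mask[..., None].astype(np.float64))
    G = batch.G * (1.0 - m) + model.mask_token.reshape(1, 1, d) * m
    return TokenBatch(G=G, original_values=batch.original_values,
                      feature_positions=batch.feature_positions,
                      pad_mask=batch.pad_mask, mask_indices=cols)


def encode(batch: TokenBatch, model: EncoderModel, pooling: str = "mean_tokens",
           ) -> tuple[Tensor, Tensor]:
    """Run the transformer; return contextual tokens H and pooled cell vector c.

    Padding positions are excluded from attention and from mean pooling;
    ``mean_tokens`` averages the real feature tokens, ``cls_token`` takes
    the leading pooling-token row.
    """
    if batch.G.shape[-1] != model.config.d:
        raise ValueError("token batch dimension does not match model")
    pad = batch.pad_mask if batch.pad_mask.any() else None
    H = model.transformer(batch.G, pad)
    if pooling == "cls_token":
        c = H[:, 0, :]
    elif pooling == "mean_tokens":
        real = ~batch.pad_mask.copy()
        real[:, 0] = False  # cls row is not a feature token
        w = Tensor(real[..., None].astype(np.float64))
        c = (H * w).sum(axis=1) / real.sum(axis=1)[:, None]
    else:
        raise ValueError(f"unknown pooling {pooling!r}")
    return H, c


def integrate_batch_token(c: Tensor, dataset_ids: np.ndarray, model: EncoderModel,
                          strict: bool = True) -> Tensor:
    """z = c + α · b_d; identity when the model has no batch-token table.

    With ``strict=False``, unseen dataset indices use the zero batch
    vector (a warning is emitted) — the inference rule for new batches.
    """
    if model.batch_token_table is None:
        return c
    ids = np.atleast_1d(np.asarray(dataset_ids, dtype=np.int64))
    known = (ids >= 0) & (ids < model.n_datasets)
    if not known.all():
        if strict:
            raise KeyError(f"unknown dataset id(s): {np.unique(ids[~known])}")
        warnings.warn("unseen dataset id(s) at inference; using zero batch vector")
    b = model.batch_token_table[np.where(known, ids, 0)]
    keep = Tensor(known.astype(np.float64)[:, None])
    return c + model.alpha * (b * keep)


def encode_cells(model: EncoderModel, ds: ExpressionDataset,
                 pooling: str = "cls_token", use_projection_head: bool = True,
                 batch_size: int = 256, strict_batch: bool = False,
                 ) -> CellEmbeddingSet:
    """Embed every cell of a normalized dataset (inference path)."""
    if not ds.normalized:
        raise ValueError("dataset must be normalized before encoding")
    out = []
    for start in range(0, ds.n_cells, batch_size):
        sl = slice(start, start + batch_size)
        batch = build_tokens(ds.values[sl], ds.feature_ids, model)
        _, c = encode(batch, model, pooling=pooling)
        z = integrate_batch_token(c, ds.batch_id[sl], model, strict=strict_batch)
        if use_projection_head:
            z = model.projection_head(z)
        out.append(z.data)
    return CellEmbeddingSet(Z=np.concatenate(out, axis=0), pooling=pooling,
                            modality=model.modality, cell_ids=list(ds.cell_ids))


def masked_reconstruction_loss(model: EncoderModel, batch: TokenBatch,
                               dataset_ids: np.ndarray) -> Tensor:
    """Mean squared error over the masked positions only.

    Predictions come from the reconstruction head applied to
    ``[z ; id-embedding of the masked feature]`` per masked position, so
    unmasked positions never enter the loss.
    """
    if batch.mask_indices is None:
        raise ValueError("batch has no mask; call mask_tokens first")
    _, c = encode(batch, model, pooling="mean_tokens")
    z = integrate_batch_token(c, dataset_ids, model)
    B, k = batch.mask_indices.shape
    d = model.config.d
    vocab_rows = batch.feature_positions[batch.mask_indices - 1]  # (B, k)
    ids = model.id_embedding[vocab_rows]                          # (B, k, d)
    zrep = z.reshape(B, 1, d) + Tensor(np.zeros((B, k, d)))
    pred = model.reconstruction_head(concat([zrep, ids], axis=-1)).reshape(B, k)
    target = np.take_along_axis(batch.original_values, batch.mask_indices - 1, axis=1)
    diff = pred - Tensor(target)
    return (diff * diff).mean()


def _global_batch_ids(datasets: list[ExpressionDataset]) -> tuple[list[np.ndarray], int]:
    """Shift per-dataset batch indices to a shared contiguous 0-based range."""
    shifted, offset = [], 0
    for ds in datasets:
        local = ds.batch_id - ds.batch_id.min()
        shifted.append(local + offset)
        offset += int(local.max()) + 1
    return shifted, offset


def pretrain(datasets: list[ExpressionDataset], config: EncoderConfig,
             ppi_table: PPIEmbeddingTable | None = None, modality: str | None = None,
             ) -> tuple[EncoderModel, list[float]]:
    """Masked-token pretraining of one modality encoder.

    All datasets must share the modality and be normalized; the vocabulary
    is the union of their features. Masks are resampled independently per
    cell each epoch. Returns the model and the per-epoch mean loss trace.
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    modality = modality or datasets[0].modality
    for ds in datasets:
        if ds.modality != modality:
            raise ValueError("mixed modalities in pretraining set")
        if not ds.normalized:
            raise ValueError("datasets must be normalized before pretraining")

    vocab: list[str] = []
    seen: set[str] = set()
    for ds in datasets:
        for f in ds.feature_ids:
            if f not in seen:
                seen.add(f)
                vocab.append(f)
    batch_ids, n_datasets = _global_batch_ids(datasets)

    model = EncoderModel(vocab, config, n_datasets=n_datasets,
                         ppi_table=ppi_table if config.use_ppi else None,
                         modality=modality)
    opt = Adam(model.parameters(), lr=config.learning_rate, clip_norm=1.0)
    rng = np.random.default_rng(config.seed + 13)
    trace: list[float] = []
    for _ in range(config.n_epochs):
        losses, weights = [], []
        for ds, ids in zip(datasets, batch_ids):
            order = rng.permutation(ds.n_cells)
            for start in range(0, ds.n_cells, config.batch_size):
                sel = order[start:start + config.batch_size]
                batch = build_tokens(ds.values[sel], ds.feature_ids, model)
                batch = mask_tokens(batch, config.mask_rate, rng, model)
                loss = masked_reconstruction_loss(model, batch, ids[sel])
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(loss.item())
                weights.append(len(sel))
        trace.append(float(np.average(losses, weights=weights)))
    return model, trace
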