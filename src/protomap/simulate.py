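"""Synthetic paired CITE-seq-like and CODEX-like data with known ground truth.

Both modalities are generated from a shared per-cell latent factor vector:
cell types define latent means, modality-specific loading matrices map
latents to genes/proteins, and a softplus link keeps expression
nonnegative. Spatial fixtures place cells so that same-type cells cluster
in the unit square and expose only a small measured protein panel —
mimicking the limited marker panels of multiplexed imaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import ExpressionDataset

__all__ = ["SimulationConfig", "GroundTruth", "simulate_paired",
           "simulate_spatial", "simulate_ppi"]


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


@dataclass
class SimulationConfig:
    """Study conditions for the paired-modality generator.

    Defaults follow the desk-scale paired fixture: 2,000 cells sharing
    8 latent factors across a 100-gene / 30-protein panel, four cell
    types, two batches with additive per-feature offsets, and moderate
    Gaussian measurement noise.
    """

    n_cells: int = 2000
    n_genes: int = 100
    n_proteins: int = 30
    n_factors: int = 8
    n_cell_types: int = 4
    n_batches: int = 2
    batch_effect_sd: float = 0.3
    noise_sd: float = 0.1
    spatial_cluster_scale: float = 0.05
    measured_panel_size: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.n_factors > min(self.n_genes, self.n_proteins):
            raise ValueError("n_factors must be ≤ min(n_genes, n_proteins)")
        if not (1 <= self.measured_panel_size <= self.n_proteins):
            raise ValueError("measured_panel_size must be in [1, n_proteins]")
        for name in ("n_cells", "n_genes", "n_proteins", "n_cell_types", "n_batches"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be ≥ 1")
        if self.batch_effect_sd < 0 or self.noise_sd < 0:
            raise ValueError("noise/batch SDs must be nonnegative")
        if self.spatial_cluster_scale <= 0:
            raise ValueError("spatial_cluster_scale must be positive")


@dataclass
class GroundTruth:
    """Latent state behind a paired simulation (recovery oracle)."""

    latents: np.ndarray
    rna_loadings: np.ndarray
    protein_loadings: np.ndarray
    type_assignment: np.ndarray
    true_protein: np.ndarray
    batch_assignment: np.ndarray = field(default=None)
    config: SimulationConfig = field(default=None)


def simulate_paired(
    config: SimulationConfig,
) -> tuple[ExpressionDataset, ExpressionDataset, GroundTruth]:
    """Generate index-paired RNA and protein datasets from shared latents.

    Per cell: a type is drawn uniformly, a latent vector is drawn around the
    type mean, and each modality observes
    ``softplus(latents @ loadingsᵀ + batch_offset + noise)``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    type_means = rng.standard_normal((cfg.n_cell_types, cfg.n_factors)) * 1.5
    types = rng.integers(0, cfg.n_cell_types, size=cfg.n_cells)
    latents = type_means[types] + 0.4 * rng.standard_normal(
        (cfg.n_cells, cfg.n_factors))

    w_rna = rng.standard_normal((cfg.n_genes, cfg.n_factors)) / np.sqrt(cfg.n_factors)
    w_prot = rng.standard_normal((cfg.n_proteins, cfg.n_factors)) / np.sqrt(cfg.n_factors)

    batches = rng.integers(0, cfg.n_batches, size=cfg.n_cells)
    rna_batch_offsets = cfg.batch_effect_sd * rng.standard_normal(
        (cfg.n_batches, cfg.n_genes))
    prot_batch_offsets = cfg.batch_effect_sd * rng.standard_normal(
        (cfg.n_batches, cfg.n_proteins))

    true_protein = latents @ w_prot.T
    rna_lin = (latents @ w_rna.T + rna_batch_offsets[batches]
               + cfg.noise_sd * rng.standard_normal((cfg.n_cells, cfg.n_genes)))
    prot_lin = (true_protein + prot_batch_offsets[batches]
                + cfg.noise_sd * rng.standard_normal((cfg.n_cells, cfg.n_proteins)))

    cell_ids = [f"cell{i}" for i in range(cfg.n_cells)]
    type_labels = np.array([f"type{t}" for t in types], dtype=object)
    rna = ExpressionDataset(
        values=_softplus(rna_lin),
        feature_ids=[f"gene{j}" for j in range(cfg.n_genes)],
        cell_ids=cell_ids, modality="rna", batch_id=batches,
        cell_type=type_labels,
    )
    protein = ExpressionDataset(
        values=_softplus(prot_lin),
        feature_ids=[f"prot{j}" for j in range(cfg.n_proteins)],
        cell_ids=cell_ids, modality="protein", batch_id=batches,
        cell_type=type_labels,
    )
    truth = GroundTruth(latents=latents, rna_loadings=w_rna,
                        protein_loadings=w_prot, type_assignment=type_labels,
                        true_protein=true_protein, batch_assignment=batches,
                        config=cfg)
    return rna, protein, truth


def simulate_spatial(config: SimulationConfig, truth: GroundTruth) -> ExpressionDataset:
    """Place the simulated cells in space and expose the measured panel.

    Cell-type centers are drawn uniformly in the unit square; each cell
    scatters around its type's center with SD ``spatial_cluster_scale``,
    producing spatially clustered types. The returned protein dataset is
    restricted to the first ``measured_panel_size`` proteins and carries
    per-spot coordinates.
    """
    cfg = config
    if truth.config is not None and truth.config != cfg:
        raise ValueError("truth was generated under a different config")
    if truth.latents.shape != (cfg.n_cells, cfg.n_factors):
        raise ValueError("truth dimensions do not match config")
    rng = np.random.default_rng(cfg.seed + 104729)

    centers = rng.uniform(0, 1, size=(cfg.n_cell_types, 2))
    type_index = np.array([int(t[4:]) for t in truth.type_assignment])
    coords = centers[type_index] + cfg.spatial_cluster_scale * rng.standard_normal(
        (cfg.n_cells, 2))

    panel = slice(0, cfg.measured_panel_size)
    prot_lin = (truth.true_protein[:, panel]
                + cfg.noise_sd * rng.standard_normal(
                    (cfg.n_cells, cfg.measured_panel_size)))
    return ExpressionDataset(
        values=_softplus(prot_lin),
        feature_ids=[f"prot{j}" for j in range(cfg.measured_panel_size)],
        cell_ids=[f"spot{i}" for i in range(cfg.n_cells)],
        modality="protein",
        cell_type=truth.type_assignment.copy(),
        coords=coords,
    )


def simulate_ppi(n_nodes: int, n_communities: int, p_in: float, p_out: float,
                 seed: int, node_prefix: str = "gene",
                 ) -> list[tuple[str, str, float]]:
    """Stochastic-block-model interaction network with confidence weights.

    Node IDs reuse the simulated feature naming (``gene0``, ``gene1``, …)
    so the embedding table joins directly onto expression features.
    Within-community edges appear with probability ``p_in``, cross-community
    edges with ``p_out`` (< ``p_in``); weights are confidences in (0.5, 1]
    for within- and (0, 0.5] for cross-community edges.
    """
    if not (0 <= p_out < p_in <= 1):
        raise ValueError("need p_in > p_out (both in [0, 1]) for community signal")
    rng = np.random.default_rng(seed)
    community = rng.integers(0, n_communities, size=n_nodes)
    ids = [f"{node_prefix}{i}" for i in range(n_nodes)]
    edges: list[tuple[str, str, float]] = []
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            same = community[i] == community[j]
            p = p_in if same else p_out
            if rng.uniform() < p:
                w = rng.uniform(0.5, 1.0) if same else rng.uniform(0.05, 0.5)
                edges.append((ids[i], ids[j], round(float(w), 6)))
    return edges
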