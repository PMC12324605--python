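"""End-to-end orchestration: simulate → pretrain → align → translate →
map → evaluate, with seeding, logging, and a reproducibility manifest.

Every stage draws its seed from the global run seed unless the stage
config overrides it; the manifest records the resolved configs, per-stage
metrics, and content checksums of the written artifacts so a rerun can
detect drift.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import alignment, encoder, metrics, ppi, simulate, spatial, translation
from .data import SplitSpec, make_split, normalize, write_expression

__all__ = ["RunConfig", "run_end_to_end"]

logger = logging.getLogger("protomap")


_SECTION_TYPES = {
    "simulation": simulate.SimulationConfig,
    "encoder": encoder.EncoderConfig,
    "contrastive": alignment.ContrastiveConfig,
    "translation": translation.TranslationConfig,
}


@dataclass
class RunConfig:
    """Nested stage configs plus global seed and output directory."""

    seed: int = 0
    out_dir: str = "runs/demo"
    verbosity: str = "INFO"
    train_fraction: float = 0.8
    tau_m: float = 0.1
    blurs: tuple = (0.02, 0.05, 0.2)
    knn_k: int = 8
    simulation: simulate.SimulationConfig = None
    encoder: encoder.EncoderConfig = None
    contrastive: alignment.ContrastiveConfig = None
    translation: translation.TranslationConfig = None

    def __post_init__(self):
        for name, typ in _SECTION_TYPES.items():
            val = getattr(self, name)
            if val is None:
                val = typ()
            elif isinstance(val, dict):
                val = _build_section(typ, val, name)
            setattr(self, name, val)
            # global seed propagates unless the stage sets its own
            if getattr(val, "seed", None) == typ().seed and self.seed != 0:
                val.seed = self.seed

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        out = asdict(self)
        out["blurs"] = list(out["blurs"])
        for sec in _SECTION_TYPES:
            if isinstance(out[sec].get("held_out_labels", None), frozenset):
                out[sec]["held_out_labels"] = sorted(out[sec]["held_out_labels"])
        return out


def _build_section(typ, raw: dict, name: str):
    known = {f.name for f in dataclasses.fields(typ)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s) in section {name!r}: "
                         f"{sorted(unknown)}")
    return typ(**raw)


def _checksum(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def run_end_to_end(config: RunConfig) -> dict:
    """Execute all stages on simulated data and write a run manifest.

    Returns the manifest dict (also written to ``<out_dir>/manifest.json``).
    Any stage failure raises with the stage name; artifacts written up to
    that point remain on disk.
    """
    logging.basicConfig(level=getattr(logging, config.verbosity, logging.INFO),
                        format="%(levelname)s %(name)s: %(message)s")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "config": config.to_dict(),
                      "stages": {}, "artifacts": {}}
    stage = "simulate"
    try:
        t0 = time.time()
        sim = config.simulation
        rna_raw, prot_raw, truth = simulate.simulate_paired(sim)
        spatial_raw = simulate.simulate_spatial(sim, truth)
        n_comm_g = max(2, min(4, sim.n_genes // 8))
        n_comm_p = max(2, min(4, sim.n_proteins // 8))
        gene_edges = simulate.simulate_ppi(sim.n_genes, n_comm_g, 0.3, 0.02,
                                           seed=config.seed, node_prefix="gene")
        prot_edges = simulate.simulate_ppi(sim.n_proteins, n_comm_p, 0.3, 0.02,
                                           seed=config.seed + 1,
                                           node_prefix="prot")
        manifest["stages"][stage] = {
            "n_cells": sim.n_cells, "n_genes": sim.n_genes,
            "n_proteins": sim.n_proteins, "seconds": round(time.time() - t0, 2)}
        logger.info("simulated %d paired cells", sim.n_cells)

        stage = "normalize_split"
        rna = normalize(rna_raw)
        protein = normalize(prot_raw)
        spots = normalize(spatial_raw)
        train_idx, test_idx = make_split(
            rna, SplitSpec(regime="random", train_fraction=config.train_fraction,
                           seed=config.seed))
        manifest["stages"][stage] = {"n_train": len(train_idx),
                                     "n_test": len(test_idx)}

        stage = "ppi_embed"
        t0 = time.time()
        enc_cfg = config.encoder
        gene_table, gene_auc = ppi.embed_graph(gene_edges, d_ppi=enc_cfg.d,
                                               seed=config.seed)
        prot_table, prot_auc = ppi.embed_graph(prot_edges, d_ppi=enc_cfg.d,
                                               seed=config.seed + 1)
        manifest["stages"][stage] = {
            "gene_holdout_auc": round(gene_auc, 4),
            "protein_holdout_auc": round(prot_auc, 4),
            "seconds": round(time.time() - t0, 2)}
        logger.info("PPI embeddings: gene AUC %.3f, protein AUC %.3f",
                    gene_auc, prot_auc)

        stage = "pretrain"
        t0 = time.time()
        rna_train = rna.subset_cells(train_idx)
        prot_train = protein.subset_cells(train_idx)
        rna_model, rna_trace = encoder.pretrain([rna_train], enc_cfg,
                                                ppi_table=gene_table)
        prot_model, prot_trace = encoder.pretrain([prot_train], enc_cfg,
                                                  ppi_table=prot_table)
        manifest["stages"][stage] = {
            "rna_final_loss": round(rna_trace[-1], 6),
            "protein_final_loss": round(prot_trace[-1], 6),
            "seconds": round(time.time() - t0, 2)}
        logger.info("pretraining losses: rna %.4f, protein %.4f",
                    rna_trace[-1], prot_trace[-1])

        stage = "align"
        t0 = time.time()
        rna_model, prot_model, c_trace = alignment.finetune(
            rna_train, prot_train, (rna_model, prot_model), config.contrastive)
        emb_r = encoder.encode_cells(rna_model, rna)
        emb_p = encoder.encode_cells(prot_model, protein)
        fos = metrics.foscttm(emb_r.Z[test_idx], emb_p.Z[test_idx])
        ms = metrics.match_score(emb_r.Z[test_idx], emb_p.Z[test_idx])
        manifest["stages"][stage] = {
            "final_loss": round(c_trace[-1], 6),
            "heldout_foscttm": round(fos, 4),
            "heldout_match_score": round(ms, 4),
            "seconds": round(time.time() - t0, 2)}
        logger.info("alignment: held-out FOSCTTM %.4f, match score %.4f", fos, ms)

        stage = "translate"
        t0 = time.time()
        trans_model = translation.train_translation(
            emb_r.Z, protein, prot_model, config.translation,
            train_index=train_idx)
        pred = translation.predict_panel(emb_r.Z, protein.feature_ids,
                                         trans_model, cell_ids=protein.cell_ids)
        rep = metrics.per_cell_metrics(protein.values[test_idx],
                                       pred.values[test_idx])
        manifest["stages"][stage] = {
            "heldout_mean_cosine": round(rep.mean_cosine, 4),
            "heldout_mean_pearson": round(rep.mean_pearson, 4),
            "heldout_mean_spearman": round(rep.mean_spearman, 4),
            "seconds": round(time.time() - t0, 2)}
        logger.info("translation: held-out cosine %.3f, pearson %.3f",
                    rep.mean_cosine, rep.mean_pearson)

        stage = "map"
        t0 = time.time()
        emb_spots = encoder.encode_cells(prot_model, spots, strict_batch=False)
        assign = spatial.soft_assign(emb_r.Z, emb_spots.Z, tau_m=config.tau_m)
        spot_pred = spatial.project_to_spots(assign, pred.values)
        dist, cats = spatial.map_cell_types(assign, rna.cell_type)
        hard = np.array(cats, dtype=object)[dist.argmax(axis=1)]
        label_acc = float((hard == spots.cell_type).mean())
        manifest["stages"][stage] = {
            "label_transfer_accuracy": round(label_acc, 4),
            "seconds": round(time.time() - t0, 2)}
        logger.info("spatial mapping: label transfer accuracy %.3f", label_acc)

        stage = "evaluate"
        t0 = time.time()
        W = metrics.knn_weight_matrix(spots.coords, k=config.knn_k)
        morans = {pid: round(metrics.morans_i(spot_pred[:, j], spots.coords,
                                              W=W), 4)
                  for j, pid in enumerate(pred.feature_ids)}
        mmd_vals = []
        for b in config.blurs:
            v = metrics.cell_level_mmd(
                spots.coords, spots.coords, b,
                weights_a=spots.values[:, 0], weights_b=spot_pred[:, 0])
            mmd_vals.append((float(b), round(float(v), 6)))
        manifest["stages"][stage] = {
            "median_morans_i": round(float(np.median(list(morans.values()))), 4),
            "mmd_first_protein": mmd_vals,
            "seconds": round(time.time() - t0, 2)}

        stage = "persist"
        write_expression(pred, out / "predicted_protein.h5")
        rna_model.save(out / "rna_encoder.h5")
        prot_model.save(out / "protein_encoder.h5")
        np.savetxt(out / "spot_predictions.tsv", spot_pred, delimiter="\t")
        manifest["artifacts"] = {
            "predicted_protein.h5": _checksum(pred.values),
            "rna_encoder.h5": _checksum(
                np.concatenate([a.ravel() for a in rna_model.state_arrays()])),
            "protein_encoder.h5": _checksum(
                np.concatenate([a.ravel() for a in prot_model.state_arrays()])),
            "spot_predictions.tsv": _checksum(spot_pred),
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
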