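import numpy as np
import pytest

import protomap as pm


@pytest.fixture(scope="session")
def small_sim():
    """A small paired simulation shared by cheap unit tests."""
    cfg = pm.SimulationConfig(n_cells=200, n_genes=30, n_proteins=10,
                              n_factors=4, n_cell_types=3, n_batches=2,
                              measured_panel_size=6, seed=11)
    rna, protein, truth = pm.simulate_paired(cfg)
    return cfg, rna, protein, truth


@pytest.fixture(scope="session")
def small_normalized(small_sim):
    cfg, rna, protein, truth = small_sim
    return cfg, pm.normalize(rna), pm.normalize(protein), truth


@pytest.fixture(scope="session")
def tiny_encoder(small_normalized):
    """A briefly pretrained RNA encoder for structural tests."""
    cfg, rnan, protn, _ = small_normalized
    edges = pm.simulate_ppi(cfg.n_genes, 3, 0.4, 0.02, seed=3)
    table, _ = pm.embed_graph(edges, d_ppi=16, seed=3, n_epochs=10)
    enc_cfg = pm.EncoderConfig(d=16, n_layers=1, n_heads=2, n_epochs=2,
                               batch_size=64, seed=3)
    model, trace = pm.pretrain([rnan], enc_cfg, ppi_table=table)
    return model, table, trace
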