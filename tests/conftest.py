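import numpy as np
import pytest

import tcrbind as tb


@pytest.fixture()
def tiny_model():
    """A small untrained model for mechanical checks (deterministic)."""
    cfg = tb.ModelConfig(max_len_cdr3a=8, max_len_cdr3b=8, max_len_peptide=6,
                         embed_dim=8, heads_per_side=2, encoder_layers=1,
                         mlp_hidden=8, dropout=0.0, seed=0)
    return tb.CrossAttentionModel(cfg)


@pytest.fixture()
def tiny_records():
    return [
        tb.InteractionRecord("CAVRGG", "CASSLG", "GILGFV", 1),
        tb.InteractionRecord("CAVKYT", "CATSDR", "NLVPMV", 0),
        tb.InteractionRecord("CAVRGG", "CASSLG", "GILGFV", 1),  # duplicate of 0
    ]


@pytest.fixture(scope="session")
def trained_tiny():
    """A tiny model trained on motif-rule data; shared across tests.

    Returns (model, rule, train_ds, heldout_ds).  The motif rule plants a
    fixed trigram into CDR3b and peptide; a trained model should be sensitive
    to it, which the perturbation and attention tests rely on.
    """
    rule = tb.MotifRule(epsilon=0.05, seed=11)
    ds = tb.gen_interactions(180, 120, rule, records_per_pair=4)   # 720 records
    rng = np.random.default_rng(11)
    perm = rng.permutation(len(ds))
    test_idx, train_idx = perm[:120], perm[120:]
    train_ds = tb.InteractionDataset(
        [ds.records[i] for i in train_idx]).compute_length_limits()
    model_cfg = tb.ModelConfig(
        max_len_cdr3a=train_ds.max_len_cdr3a,
        max_len_cdr3b=train_ds.max_len_cdr3b,
        max_len_peptide=train_ds.max_len_peptide,
        embed_dim=32, heads_per_side=4, encoder_layers=1,
        mlp_hidden=64, dropout=0.1, seed=11)
    train_cfg = tb.TrainConfig(max_epochs=6, patience=10, batch_size=64,
                               learning_rate=2e-3, seed=11)
    result = tb.train(train_ds, train_cfg, model_cfg)
    heldout = tb.InteractionDataset(
        [ds.records[i] for i in test_idx
         if len(ds.records[i].cdr3a) <= train_ds.max_len_cdr3a
         and len(ds.records[i].cdr3b) <= train_ds.max_len_cdr3b
         and len(ds.records[i].peptide) <= train_ds.max_len_peptide])
    return result.model, rule, train_ds, heldout
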