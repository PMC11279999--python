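"""Shared fixtures: reduced model configuration and small planted datasets."""

from __future__ import annotations

import numpy as np
import pytest

from adesig import SyntheticConfig, generate_ade_records
from adesig.model import SDAJMConfig


def reduced_config(**overrides) -> SDAJMConfig:
    """Small-but-real model configuration used throughout the suite.

    The planted signal lives in the fingerprint and SOC channels, so
    narrow trainable encoders suffice; sizes are chosen for desk-scale
    runtimes, not tuned to any particular outcome.
    """
    base = dict(
        epochs=8, learning_rate=3e-3, batch_size=256,
        gin_hidden_dim=16, gin_layers=2, seq_embed_dim=16, seq_layers=1,
        seq_ff_dim=32, adr_embed_dim=16, head_hidden_dim=32, n_heads=2,
        max_len=64,
    )
    base.update(overrides)
    return SDAJMConfig(**base)


@pytest.fixture(scope="session")
def tiny_planted():
    """200-record planted dataset for fast model-level tests."""
    cfg = SyntheticConfig(n_records=200, seed=3)
    records, soc_map, truth = generate_ade_records(cfg)
    return records, soc_map, truth


@pytest.fixture
def small_model_config() -> SDAJMConfig:
    return reduced_config()


def shuffle_suspect_labels(records, seed: int):
    """Return a copy of the records with suspect labels permuted across all
    (record, drug) instances — the null-signal control."""
    from dataclasses import replace

    labels = [d.suspect for r in records for d in r.drugs]
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(labels))
    shuffled = [labels[i] for i in perm]
    out = []
    pos = 0
    for rec in records:
        drugs = []
        for d in rec.drugs:
            drugs.append(replace(d, suspect=shuffled[pos]))
            pos += 1
        out.append(replace(rec, drugs=tuple(drugs)))
    return out
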