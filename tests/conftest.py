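"""Shared fixtures: synthetic datasets, vocabularies, and one trained model.

Everything is generated at test time; the trained model is session-scoped
because supervised training is the expensive step.
"""

from __future__ import annotations

import numpy as np
import pytest

from rxncond.chem import ConditionVocabulary, split_dataset, strip_atom_maps
from rxncond.model import ConditionTransformer, ModelConfig
from rxncond.synthetic import GeneratorConfig, generate_dataset
from rxncond.tokenizer import TokenVocabulary
from rxncond.train import TrainConfig, train

TINY_CONFIG = dict(d_model=64, d_ff=128, enc_layers=2, enc_heads=4,
                   dec_layers=3, dec_heads=4, max_len=96)


@pytest.fixture(scope="session")
def dataset():
    """200 synthetic records with ground-truth centers (noise-free)."""
    return generate_dataset(GeneratorConfig(n_records=200, seed=7))


@pytest.fixture(scope="session")
def records(dataset):
    return dataset[0]


@pytest.fixture(scope="session")
def centers(dataset):
    return dataset[1]


@pytest.fixture(scope="session")
def vocabs(records):
    stripped = [strip_atom_maps(r.rxn_smiles) for r in records]
    return TokenVocabulary.from_corpus(stripped), ConditionVocabulary.from_records(records)


@pytest.fixture(scope="session")
def untrained_model(vocabs):
    token_vocab, cond_vocab = vocabs
    return ConditionTransformer(ModelConfig(**TINY_CONFIG, seed=0), token_vocab, cond_vocab)


@pytest.fixture(scope="session")
def learnability_split():
    """500 noise-free records split 8:1:1 — labels are a deterministic
    function of the input, so Bayes top-1 accuracy is 1."""
    records, centers = generate_dataset(GeneratorConfig(n_records=500, seed=11))
    train_set, val_set, test_set = split_dataset(records, seed=0)
    return records, centers, train_set, val_set, test_set


def fit_learnability_model(learnability_split, seed: int):
    records, _, train_set, val_set, _ = learnability_split
    stripped = [strip_atom_maps(r.rxn_smiles) for r in records]
    token_vocab = TokenVocabulary.from_corpus(stripped)
    cond_vocab = ConditionVocabulary.from_records(records)
    model = ConditionTransformer(
        ModelConfig(**TINY_CONFIG, seed=seed), token_vocab, cond_vocab
    )
    model, history = train(
        model, train_set, val_set,
        TrainConfig(epochs=40, batch_size=50, lr=2e-3, seed=seed),
    )
    return model, history


@pytest.fixture(scope="session")
def trained_model(learnability_split):
    """One fully trained tiny model (seed 0) shared across tests."""
    model, _ = fit_learnability_model(learnability_split, seed=0)
    return model
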