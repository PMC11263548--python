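"""Shared fixtures: synthetic corpora and trained models.

The two trained models are expensive (minutes on one CPU) and session
scoped; tests share them rather than retraining.  All randomness is
seed-pinned so the suite is reproducible.
"""

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", database=None, deadline=None)
settings.load_profile("suite")

from s4clm.chem_io import build_vocabulary, tokenize_smiles
from s4clm.clm import CLMConfig
from s4clm.fixtures import GrammarSpec, planted_bioactivity_dataset, synthetic_smiles_corpus
from s4clm.training import TrainingConfig, pretrain

SYNTAX_SEED = 11
MEMORIZE_SEED = 5


@pytest.fixture(scope="session")
def small_corpus():
    """60 synthetic molecules for cheap unit tests."""
    return synthetic_smiles_corpus(GrammarSpec(), n=60, seed=1)


@pytest.fixture(scope="session")
def memorize_run():
    """Tiny model fully overfit on 32 fixture SMILES (the overfit regime)."""
    corpus = synthetic_smiles_corpus(GrammarSpec(), n=32, seed=MEMORIZE_SEED)
    vocab = build_vocabulary(corpus)
    cfg = CLMConfig(
        vocab_size=len(vocab), n_blocks=2, model_width=64, state_size=16,
        content_length=max(len(tokenize_smiles(s)) for s in corpus))
    model, vocab, history = pretrain(
        corpus, cfg,
        TrainingConfig(learning_rate=5e-3, batch_size=32, max_epochs=400,
                       seed=0),
        valid_fraction=0.0)
    return dict(model=model, vocab=vocab, history=history, corpus=corpus)


@pytest.fixture(scope="session")
def syntax_run():
    """Scaled-down syntax-learning run: pre-training on 3,000 fixtures."""
    corpus = synthetic_smiles_corpus(GrammarSpec(), n=3000, seed=SYNTAX_SEED)
    vocab = build_vocabulary(corpus)
    cfg = CLMConfig(
        vocab_size=len(vocab), n_blocks=2, model_width=128, state_size=32,
        content_length=max(len(tokenize_smiles(s)) for s in corpus))
    model, vocab, history = pretrain(
        corpus, cfg,
        TrainingConfig(learning_rate=5e-3, batch_size=100, max_epochs=60,
                       seed=0, lr_schedule="cosine", dtype="float32"))
    return dict(model=model, vocab=vocab, history=history, corpus=corpus)


@pytest.fixture(scope="session")
def planted():
    """Planted-bioactivity fixture: 56 motif actives vs 2,000 inactives."""
    return planted_bioactivity_dataset(n_act=56, n_inact=2000, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
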