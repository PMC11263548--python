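import numpy as np
import pytest

from s4clm.chem_io import build_vocabulary, tokenize_smiles
from s4clm.clm import CLMConfig
from s4clm.training import (TrainingConfig, encode_corpus, finetune,
                            make_splits, pretrain)


def _tiny_cfg(vocab, content):
    return CLMConfig(vocab_size=len(vocab), n_blocks=1, model_width=8,
                     state_size=4, content_length=content)


def _quick_pretrain(corpus, epochs=2, **kw):
    vocab = build_vocabulary(corpus)
    content = max(len(tokenize_smiles(s)) for s in corpus)
    return pretrain(corpus, _tiny_cfg(vocab, content),
                    TrainingConfig(max_epochs=epochs, batch_size=16, **kw),
                    valid_fraction=0.2)


def test_make_splits_sizes_and_reproducibility():
    (tr, va, te), = make_splits(100, (0.8, 0.1, 0.1), seed=0)
    assert (len(tr), len(va), len(te)) == (80, 10, 10)
    assert sorted(np.concatenate([tr, va, te])) == list(range(100))
    (tr2, va2, te2), = make_splits(100, (0.8, 0.1, 0.1), seed=0)
    np.testing.assert_array_equal(tr, tr2)


def test_make_splits_remainder_to_training():
    (tr, va, te), = make_splits(105, (0.8, 0.1, 0.1), seed=1)
    assert (len(tr), len(va), len(te)) == (85, 10, 10)


def test_make_splits_ten_runs_distinct():
    splits = make_splits(100, n_runs=10, seed=2)
    keys = {tuple(tr) for tr, _, _ in splits}
    assert len(keys) == 10


def test_initial_loss_near_log_vocab(small_corpus):
    corpus = small_corpus[:20]
    vocab = build_vocabulary(corpus)
    content = max(len(tokenize_smiles(s)) for s in corpus)
    from s4clm.clm import CLM
    model = CLM(_tiny_cfg(vocab, content), seed=0)
    ids = encode_corpus(corpus, vocab, content)
    loss, _ = model.loss(ids, pad_id=0)
    assert loss == pytest.approx(np.log(len(vocab)), rel=0.05)


def test_pad_masking_invariant_to_extra_padding(small_corpus):
    corpus = small_corpus[:10]
    vocab = build_vocabulary(corpus)
    content = max(len(tokenize_smiles(s)) for s in corpus)
    from s4clm.clm import CLM
    model = CLM(_tiny_cfg(vocab, content + 7), seed=0)
    short = encode_corpus(corpus, vocab, content)
    padded = encode_corpus(corpus, vocab, content + 7)
    l1, _ = model.loss(short, pad_id=0)
    l2, _ = model.loss(padded, pad_id=0)
    assert l1 == pytest.approx(l2, abs=1e-9)


def test_pretrain_reproducible(small_corpus):
    h1 = _quick_pretrain(small_corpus[:30], seed=3)[2]
    h2 = _quick_pretrain(small_corpus[:30], seed=3)[2]
    assert h1.to_frame().equals(h2.to_frame())


def test_finetune_early_stopping_rule(small_corpus):
    # zero learning rate: no improvement after epoch 1, so training stops
    # after exactly patience more epochs and epoch 1 is selected
    model, vocab, _ = _quick_pretrain(small_corpus[:30])
    res = finetune(model, vocab, small_corpus[:20], small_corpus[20:30],
                   TrainingConfig(learning_rate=0.0, max_epochs=50,
                                  patience=5, batch_size=16))
    assert len(res.history.rows) == 1 + 5
    assert res.selected_epoch == 1


def test_finetune_keeps_shape_and_vocab(small_corpus):
    model, vocab, _ = _quick_pretrain(small_corpus[:30])
    res = finetune(model, vocab, small_corpus[:20], small_corpus[20:30],
                   TrainingConfig(max_epochs=3, batch_size=16))
    assert res.model.config == model.config
    assert len(res.checkpoints) == 3
    for _, ckpt in res.checkpoints:
        assert ckpt.params["emb"].shape == model.params["emb"].shape


def test_finetune_drops_out_of_vocabulary(small_corpus, caplog):
    model, vocab, _ = _quick_pretrain(small_corpus[:30])
    bad = "BrCCBr"  # Br never occurs in the fixture alphabet's vocabulary
    res = finetune(model, vocab, small_corpus[:20] + [bad],
                   small_corpus[20:30],
                   TrainingConfig(max_epochs=1, batch_size=16))
    assert res.n_dropped == 1


def test_finetune_raises_when_nothing_usable(small_corpus):
    model, vocab, _ = _quick_pretrain(small_corpus[:30])
    with pytest.raises(ValueError, match="usable"):
        finetune(model, vocab, ["BrCBr"], ["BrCCBr"],
                 TrainingConfig(max_epochs=1))


def test_memorization_reaches_prefix_ceiling(memorize_run):
    """Full memorization: training accuracy equals the majority-vote
    ceiling imposed by prefix ambiguity, and cannot exceed it."""
    from collections import Counter, defaultdict
    corpus, hist = memorize_run["corpus"], memorize_run["history"]
    seqs = [["<bos>"] + tokenize_smiles(s) + ["<eos>"] for s in corpus]
    nxt = defaultdict(Counter)
    for seq in seqs:
        for i in range(1, len(seq)):
            nxt[tuple(seq[:i])][seq[i]] += 1
    tot = hits = 0
    for seq in seqs:
        for i in range(1, len(seq)):
            tot += 1
            hits += seq[i] == nxt[tuple(seq[:i])].most_common(1)[0][0]
    ceiling = hits / tot
    final_acc = hist.rows[-1]["train_acc"]
    assert final_acc <= ceiling + 1e-9
    assert final_acc >= 0.995 * ceiling
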