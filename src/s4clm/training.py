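"""Next-token pre-training and transfer-learning fine-tuning.

Pre-training minimizes teacher-forced next-token cross-entropy in
convolutional mode over a large corpus; fine-tuning continues training on a
small task-focused set with early stopping on validation cross-entropy
(patience 5 epochs, tolerance 1e-5 by default) and retains the model of
each of the last five epochs for checkpoint pooling during generation.

Optimization uses Adam with a single learning rate and no weight decay.
The state-space spectra (Λ, P, Q) and step sizes Δ are frozen at their
HiPPO initialization, so no parameter group needs special treatment.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .chem_io import Vocabulary, build_vocabulary, encode_sequence, tokenize_smiles
from .clm import CLM, CLMConfig

logger = logging.getLogger(__name__)

__all__ = ["TrainingConfig", "TrainingHistory", "Adam", "make_splits",
           "encode_corpus", "pretrain", "finetune", "FinetuneResult"]


@dataclass(frozen=True)
class TrainingConfig:
    learning_rate: float = 3e-3
    batch_size: int = 64
    max_epochs: int = 20
    patience: int = 5
    tolerance: float = 1e-5
    seed: int = 0
    keep_last: int = 5  # fine-tuning checkpoints retained
    lr_schedule: str = "constant"  # or "cosine" (decays to 0 over max_epochs)
    dtype: str = "float64"  # "float32" roughly halves CPU training time

    def __post_init__(self) -> None:
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")


@dataclass
class TrainingHistory:
    """Per-epoch losses; ``selected_epoch`` is 1-based (0 = none selected)."""

    rows: list[dict] = field(default_factory=list)
    selected_epoch: int = 0

    def append(self, **row) -> None:
        self.rows.append(row)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


class Adam:
    """Plain Adam over a named-parameter dictionary."""

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray],
             grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.betas
        c1 = 1 - b1 ** self.t
        c2 = 1 - b2 ** self.t
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            params[k] -= self.lr * (self.m[k] / c1) / (
                np.sqrt(self.v[k] / c2) + self.eps)


def make_splits(
    n_or_corpus, fractions=(0.8, 0.1, 0.1), n_runs: int = 1, seed: int = 0,
) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Disjoint, exhaustive (train, valid, test) index splits.

    ``n_runs`` independent shuffles from one seeded generator; fractional
    remainders are assigned to the training split.
    """
    n = n_or_corpus if isinstance(n_or_corpus, int) else len(n_or_corpus)
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    if n < 10:
        raise ValueError("corpus too small to split (need >= 10)")
    n_valid = int(n * fractions[1])
    n_test = int(n * fractions[2])
    n_train = n - n_valid - n_test
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_runs):
        perm = rng.permutation(n)
        out.append((perm[:n_train], perm[n_train:n_train + n_valid],
                    perm[n_train + n_valid:]))
    return out


def encode_corpus(corpus: list[str], vocab: Vocabulary,
                  content_length: int) -> np.ndarray:
    """Encode canonical SMILES into an (n, content_length + 2) id matrix."""
    return np.array([
        encode_sequence(tokenize_smiles(s), vocab, content_length).ids
        for s in corpus
    ], dtype=np.int64)


def _train_epochs(model, ids_train, ids_valid, config, history,
                  start_epoch=1, stop_early=False, keep_last=0):
    """Shared epoch loop; returns (kept checkpoints, selected epoch)."""
    pad = 0  # PAD id is 0 by vocabulary construction
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.params, config.learning_rate)
    kept: deque = deque(maxlen=max(keep_last, 1))
    best_val, best_epoch, since = np.inf, 0, 0
    for epoch in range(start_epoch, start_epoch + config.max_epochs):
        if config.lr_schedule == "cosine":
            frac = (epoch - start_epoch) / max(config.max_epochs, 1)
            opt.lr = config.learning_rate * 0.5 * (1 + np.cos(np.pi * frac))
        order = rng.permutation(len(ids_train))
        losses, accs = [], []
        for lo in range(0, len(order), config.batch_size):
            batch = ids_train[order[lo:lo + config.batch_size]]
            loss, acc, grads = model.loss_and_grads(batch, pad)
            opt.step(model.params, grads)
            losses.append(loss)
            accs.append(acc)
        row = dict(epoch=epoch, train_loss=float(np.mean(losses)),
                   train_acc=float(np.mean(accs)))
        if ids_valid is not None and len(ids_valid):
            vl, va = _eval(model, ids_valid, pad, config.batch_size)
            row.update(val_loss=vl, val_acc=va)
        history.append(**row)
        logger.info("epoch %d: %s", epoch, row)
        if keep_last:
            kept.append((epoch, model.copy()))
        if stop_early:
            vl = row["val_loss"]
            if vl < best_val - config.tolerance:
                best_val, best_epoch, since = vl, epoch, 0
            else:
                since += 1
                if since >= config.patience:
                    break
        elif "val_loss" in row and row["val_loss"] < best_val:
            best_val, best_epoch = row["val_loss"], epoch
    history.selected_epoch = best_epoch
    return list(kept), best_epoch


def _eval(model, ids, pad, batch_size):
    losses, accs, weights = [], [], []
    for lo in range(0, len(ids), batch_size):
        batch = ids[lo:lo + batch_size]
        l, a = model.loss(batch, pad)
        losses.append(l)
        accs.append(a)
        weights.append(len(batch))
    w = np.asarray(weights, float)
    return (float(np.average(losses, weights=w)),
            float(np.average(accs, weights=w)))


def pretrain(
    corpus: list[str],
    clm_config: CLMConfig | None = None,
    train_config: TrainingConfig = TrainingConfig(),
    valid_fraction: float = 0.1,
    content_length: int | None = None,
) -> tuple[CLM, Vocabulary, TrainingHistory]:
    """Pre-train a model from scratch on a curated canonical corpus.

    Builds the vocabulary from the corpus, holds out ``valid_fraction`` for
    monitoring, and minimizes next-token cross-entropy (PAD masked, EOS
    scored) in convolutional mode.  Deterministic given the seeds up to
    floating-point reduction order.
    """
    vocab = build_vocabulary(corpus)
    if content_length is None:
        content_length = (clm_config.content_length if clm_config
                          else min(100, max(len(tokenize_smiles(s))
                                            for s in corpus)))
    if clm_config is None:
        clm_config = CLMConfig(vocab_size=len(vocab),
                               content_length=content_length)
    elif clm_config.vocab_size != len(vocab):
        raise ValueError(
            f"clm_config.vocab_size={clm_config.vocab_size} does not match "
            f"the corpus vocabulary ({len(vocab)} tokens)")
    ids = encode_corpus(corpus, vocab, clm_config.content_length)
    rng = np.random.default_rng(train_config.seed)
    perm = rng.permutation(len(ids))
    n_val = int(len(ids) * valid_fraction)
    ids_valid = ids[perm[:n_val]] if n_val else None
    ids_train = ids[perm[n_val:]]
    model = CLM(clm_config, seed=train_config.seed,
                dtype=np.dtype(train_config.dtype))
    history = TrainingHistory()
    _train_epochs(model, ids_train, ids_valid, train_config, history)
    return model, vocab, history


@dataclass
class FinetuneResult:
    """Outcome of a fine-tuning run.

    ``checkpoints`` holds the models of the last ``keep_last`` epochs as
    ``(epoch, model)`` pairs; ``selected_epoch`` minimizes validation loss
    under the tolerance rule.
    """

    checkpoints: list[tuple[int, CLM]]
    selected_epoch: int
    history: TrainingHistory
    model: CLM  # model at the final trained epoch
    n_dropped: int = 0


def finetune(
    pretrained: CLM,
    vocab: Vocabulary,
    train_smiles: list[str],
    valid_smiles: list[str],
    train_config: TrainingConfig = TrainingConfig(max_epochs=50),
) -> FinetuneResult:
    """Continue training on a small set with early stopping.

    Molecules not expressible in the pre-training vocabulary (or longer
    than the model's content length) are dropped with a warning — the
    vocabulary and model shape are never altered.  Early stopping follows
    the validation cross-entropy with the configured patience and
    tolerance; an improvement smaller than the tolerance counts as no
    improvement.
    """
    def usable(smiles):
        kept = []
        for s in smiles:
            try:
                toks = tokenize_smiles(s)
                if len(toks) > pretrained.config.content_length:
                    raise ValueError("too long")
                for t in toks:
                    vocab.id_of(t)
                kept.append(s)
            except Exception:
                logger.warning("dropping fine-tuning molecule outside the "
                               "pre-training vocabulary: %s", s)
        return kept

    train_ok = usable(train_smiles)
    valid_ok = usable(valid_smiles)
    n_dropped = len(train_smiles) + len(valid_smiles) - len(train_ok) - len(valid_ok)
    if not train_ok or not valid_ok:
        raise ValueError("no usable fine-tuning molecules after filtering")
    ids_train = encode_corpus(train_ok, vocab, pretrained.config.content_length)
    ids_valid = encode_corpus(valid_ok, vocab, pretrained.config.content_length)
    model = pretrained.copy()
    history = TrainingHistory()
    kept, best = _train_epochs(model, ids_train, ids_valid, train_config,
                               history, stop_early=True,
                               keep_last=train_config.keep_last)
    return FinetuneResult(checkpoints=kept, selected_epoch=best,
                          history=history, model=model, n_dropped=n_dropped)
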