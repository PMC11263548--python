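"""Temperature-controlled autoregressive SMILES sampling (recurrent mode).

Generation starts from BOS with zeroed recurrent states and steps the
linear recurrence — never the convolution — sampling each next token from
the temperature-scaled softmax

    p_i = exp(y_i / T) / sum_j exp(y_j / T)

where ``y`` are the model's next-token logits.  ``T = 1`` samples from the
model's own predictive distribution, ``T -> 0`` is greedy decoding, larger
``T`` flattens the distribution toward uniform.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .chem_io import Vocabulary, detokenize
from .clm import CLM

__all__ = ["GenerationConfig", "DesignBatch", "temperature_probabilities",
           "sample_next_token", "generate_batch", "SWEEP_TEMPERATURES",
           "design_campaign_plan"]

#: Temperature sweep protocol: 1.0 to 2.0 with a step of 0.25.
SWEEP_TEMPERATURES = (1.0, 1.25, 1.5, 1.75, 2.0)


@dataclass(frozen=True)
class GenerationConfig:
    n_samples: int
    temperature: float = 1.0
    max_len: int = 100  # content-token cutoff
    seed: int = 0
    checkpoint_epoch: int | None = None

    def __post_init__(self) -> None:
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0 (0 = greedy)")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


def temperature_probabilities(logits: np.ndarray, T: float) -> np.ndarray:
    """Sampling probabilities at temperature ``T`` (rows sum to 1).

    ``T = 0`` returns a point mass on the argmax (first index on ties).
    Computed with max-subtraction for numerical stability, so ``T = 1``
    reproduces the model's softmax probabilities exactly.
    """
    logits = np.asarray(logits, dtype=float)
    if np.all(np.isneginf(logits), axis=-1).any():
        raise ValueError("all logits are -inf; no token can be sampled")
    if T == 0.0:
        p = np.zeros_like(logits)
        idx = np.argmax(logits, axis=-1)
        np.put_along_axis(np.atleast_2d(p), np.atleast_1d(idx)[..., None], 1.0,
                          axis=-1)
        return p
    z = logits / T
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def sample_next_token(p: np.ndarray, rng: np.random.Generator) -> int:
    """Draw one token id from a probability vector (weighted random)."""
    p = np.asarray(p, dtype=float)
    return int(rng.choice(len(p), p=p / p.sum()))


@dataclass
class DesignBatch:
    """Generated SMILES with per-design metadata."""

    smiles: list[str]
    completed: list[bool]  # EOS reached (vs truncated at max length)
    temperature: float
    seed: int
    checkpoint_epoch: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "smiles": self.smiles,
            "temperature": self.temperature,
            "seed": self.seed,
            "epoch": self.checkpoint_epoch,
            "completed": self.completed,
        })

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def generate_batch(model: CLM, vocab: Vocabulary,
                   config: GenerationConfig) -> DesignBatch:
    """Sample ``n_samples`` SMILES strings autoregressively.

    One random stream per batch, split per sequence (each sequence owns a
    spawned child stream), so results do not depend on batch composition
    and the batch can be re-generated reproducibly.  The greedy path
    (``T = 0``) never consults the random streams.  Strings that reach the
    content-length cutoff without emitting EOS are returned truncated with
    ``completed = False``.
    """
    n = config.n_samples
    max_len = min(config.max_len, model.config.content_length)
    greedy = config.temperature == 0.0
    if not greedy:
        children = np.random.SeedSequence(config.seed).spawn(n)
        # pre-drawn per-sequence uniforms: step t of sequence i uses U[i, t]
        U = np.stack([np.random.default_rng(c).random(max_len + 1)
                      for c in children])
    state = model.init_recurrent_state(n)
    current = np.full(n, vocab.bos_id)
    emitted = np.full((n, max_len + 1), vocab.pad_id)
    done = np.zeros(n, dtype=bool)
    for t in range(max_len + 1):
        logits = state.step(current)
        p = temperature_probabilities(logits, config.temperature)
        if greedy:
            nxt = p.argmax(axis=-1)
        else:
            cum = np.cumsum(p, axis=-1)
            cum /= cum[:, -1:]
            nxt = (cum < U[:, t, None]).sum(axis=-1)
        nxt = np.where(done, vocab.pad_id, nxt)
        emitted[:, t] = nxt
        done |= nxt == vocab.eos_id
        if done.all():
            break
        current = np.where(done, vocab.eos_id, nxt)
    smiles, completed = [], []
    special = {vocab.pad_id, vocab.bos_id, vocab.eos_id}
    for i in range(n):
        row = emitted[i]
        toks = []
        finished = False
        for tid in row:
            if tid == vocab.eos_id:
                finished = True
                break
            if len(toks) == max_len:
                break  # content cutoff reached without EOS: truncated
            if tid not in special:
                toks.append(vocab.tokens[tid])
        smiles.append(detokenize(toks))
        completed.append(finished)
    return DesignBatch(smiles=smiles, completed=completed,
                       temperature=config.temperature, seed=config.seed,
                       checkpoint_epoch=config.checkpoint_epoch)


def design_campaign_plan(
    checkpoint_epochs: tuple[int, ...] | list[int],
    temperatures: tuple[float, ...] = SWEEP_TEMPERATURES,
    n_per_job: int = 10240,
    seed: int = 0,
) -> list[GenerationConfig]:
    """Enumerate the generation jobs of a design campaign.

    The prospective protocol pools the models of the last five fine-tuning
    epochs and samples ``n_per_job`` designs per (epoch, temperature) pair
    over the temperature sweep — five epochs × five temperatures × 10,240
    designs = 256K designs in the default configuration.  Each job gets its
    own derived seed.
    """
    jobs = []
    for i, epoch in enumerate(checkpoint_epochs):
        for j, T in enumerate(temperatures):
            jobs.append(GenerationConfig(
                n_samples=n_per_job, temperature=T,
                seed=seed + 1000 * i + j, checkpoint_epoch=epoch))
    return jobs
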