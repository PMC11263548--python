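"""Likelihood computation, bias-corrected scoring, ranking and enrichment.

The joint log-likelihood of a molecule M with tokens t_1..t_n is

    L(M) = sum_i log p(t_i)

summing the teacher-forced log-probability of every content token and the
closing EOS (BOS is conditioning only).  To isolate what fine-tuning added
on top of general chemistry knowledge, the bias-corrected score subtracts
the pre-training likelihood:

    L_score(M) = L(M_ft) - L(M_pt)

and molecules are ranked by descending score — the ranking signal used for
retrospective enrichment and prospective design selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chem_io import Vocabulary, encode_sequence, tokenize_smiles
from .clm import CLM

logger = logging.getLogger(__name__)

__all__ = ["LikelihoodResult", "ScoreResult", "RankedList",
           "sequence_log_likelihood", "batch_log_likelihood",
           "bias_corrected_score", "batch_scores", "rank_molecules",
           "enrichment_at_k"]


@dataclass(frozen=True)
class LikelihoodResult:
    molecule: str
    tokens: tuple[str, ...]
    token_probs: tuple[float, ...]  # p(t_i) incl. EOS, teacher-forced
    log_likelihood: float  # nats, <= 0


@dataclass(frozen=True)
class ScoreResult:
    molecule: str
    loglik_ft: float
    loglik_pt: float

    @property
    def score(self) -> float:
        return self.loglik_ft - self.loglik_pt


def _batch_token_logprobs(model: CLM, vocab: Vocabulary,
                          smiles: list[str]) -> list[np.ndarray]:
    """Per-token log-probabilities (content + EOS) for each molecule."""
    tok_lists = [tokenize_smiles(s) for s in smiles]
    content = max(len(t) for t in tok_lists)
    if content > model.config.content_length:
        raise ValueError("molecule longer than the model content length")
    ids = np.array([encode_sequence(t, vocab, content).ids
                    for t in tok_lists])
    logp = model.log_probs(ids[:, :-1])  # (n, content+1, V)
    out = []
    for i, toks in enumerate(tok_lists):
        n_scored = len(toks) + 1  # content tokens + EOS
        tgt = ids[i, 1:1 + n_scored]
        out.append(logp[i, np.arange(n_scored), tgt])
    return out


def sequence_log_likelihood(model: CLM, vocab: Vocabulary,
                            smiles: str) -> LikelihoodResult:
    """Joint log-likelihood of one canonical SMILES under ``model``.

    Deterministic teacher-forced pass; padding length does not affect the
    result (the model is strictly causal and PAD positions are never
    scored).  Raises on out-of-vocabulary tokens.
    """
    lps = _batch_token_logprobs(model, vocab, [smiles])[0]
    toks = tuple(tokenize_smiles(smiles)) + ("<eos>",)
    return LikelihoodResult(molecule=smiles, tokens=toks,
                            token_probs=tuple(np.exp(lps)),
                            log_likelihood=float(lps.sum()))


def batch_log_likelihood(model: CLM, vocab: Vocabulary, smiles: list[str],
                         batch_size: int = 256) -> np.ndarray:
    """Joint log-likelihoods for a list of molecules (vectorized)."""
    out = np.empty(len(smiles))
    for lo in range(0, len(smiles), batch_size):
        chunk = smiles[lo:lo + batch_size]
        lps = _batch_token_logprobs(model, vocab, chunk)
        out[lo:lo + len(chunk)] = [float(l.sum()) for l in lps]
    return out


def bias_corrected_score(ft_model: CLM, pt_model: CLM, vocab: Vocabulary,
                         smiles: str) -> ScoreResult:
    """Fine-tuned minus pre-trained log-likelihood for one molecule.

    Both models must share the tokenization and vocabulary (their
    vocabulary sizes are checked; checkpoint loading verifies hashes).
    The higher the score, the better the rank.
    """
    if ft_model.config.vocab_size != pt_model.config.vocab_size:
        raise ValueError("fine-tuned and pre-trained models use different "
                         "vocabularies")
    lf = sequence_log_likelihood(ft_model, vocab, smiles).log_likelihood
    lp = sequence_log_likelihood(pt_model, vocab, smiles).log_likelihood
    return ScoreResult(molecule=smiles, loglik_ft=lf, loglik_pt=lp)


def batch_scores(ft_model: CLM, pt_model: CLM, vocab: Vocabulary,
                 smiles: list[str], batch_size: int = 256) -> pd.DataFrame:
    """Score table (smiles, loglik_ft, loglik_pt, score) for many molecules."""
    if ft_model.config.vocab_size != pt_model.config.vocab_size:
        raise ValueError("fine-tuned and pre-trained models use different "
                         "vocabularies")
    lf = batch_log_likelihood(ft_model, vocab, smiles, batch_size)
    lp = batch_log_likelihood(pt_model, vocab, smiles, batch_size)
    return pd.DataFrame({"smiles": smiles, "loglik_ft": lf, "loglik_pt": lp,
                         "score": lf - lp})


@dataclass
class RankedList:
    """Molecule indices ordered by non-increasing score."""

    order: np.ndarray  # indices into the original score array
    scores: np.ndarray  # scores in ranked order
    tie_seed: int


def rank_molecules(scores: np.ndarray, tie_seed: int = 0) -> RankedList:
    """Rank descending by score; exact ties broken by a seeded shuffle."""
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    rng = np.random.default_rng(tie_seed)
    shuffled = rng.permutation(len(scores))
    order = shuffled[np.argsort(-scores[shuffled], kind="stable")]
    return RankedList(order=order, scores=scores[order], tie_seed=tie_seed)


def enrichment_at_k(
    ranked: RankedList, labels: np.ndarray, ks=(10, 50, 100),
    mode: str = "recall",
) -> dict[int, float]:
    """Fraction of actives found in the top-k of a ranked list.

    ``recall`` (default): actives in top k / total actives — the fraction
    of known actives retrieved per considered number of test molecules.
    ``precision``: actives in top k / k.  ``k`` larger than the list is
    clamped with a warning.
    """
    labels = np.asarray(labels).astype(bool)
    if len(labels) != len(ranked.order):
        raise ValueError("labels do not align with the ranking")
    n_act = int(labels.sum())
    if n_act == 0:
        raise ValueError("at least one active is required")
    ranked_labels = labels[ranked.order]
    out = {}
    for k in ks:
        kk = min(k, len(ranked_labels))
        if kk < k:
            logger.warning("k=%d clamped to list length %d", k, kk)
        hits = int(ranked_labels[:kk].sum())
        out[k] = hits / n_act if mode == "recall" else hits / kk
    return out
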