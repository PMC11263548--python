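"""SMILES parsing, tokenization, curation, vocabulary handling and file I/O.

The tokenizer follows the standard SMILES token classes used by chemical
language models: bracket atoms (``[...]``), two-digit ring labels (``%nn``)
and the two-letter organic-subset halogens (``Cl``, ``Br``) are single
tokens; every other character is its own token.  Concatenating the tokens
always reproduces the input string, so tokenize/detokenize is the identity
on every accepted string.
"""

from __future__ import annotations

import hashlib
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

#: Reserved special tokens, in serialization order (PAD first so PAD id is 0).
PAD, BOS, EOS = "<pad>", "<bos>", "<eos>"
RESERVED_TOKENS = (PAD, BOS, EOS)

_TOKEN_RE = re.compile(r"\[[^\[\]]*\]|%\d\d|Cl|Br|.")

#: Default element whitelist for drug-like corpora.
DEFAULT_ELEMENTS = frozenset({"C", "H", "O", "N", "S", "P", "F", "Cl", "Br", "I"})

#: Canonical SMILES of counter-ions stripped before the multi-fragment check.
COUNTERION_SMILES = frozenset({
    "[Na+]", "[K+]", "[Li+]", "[Ca+2]", "[Mg+2]", "[Cl-]", "[Br-]", "[I-]",
    "[F-]", "O", "[OH-]", "[NH4+]", "[H+]",
})


class TokenizationError(ValueError):
    """Raised when a SMILES string cannot be split into tokens."""


class EncodingError(KeyError):
    """Raised when a token is missing from the vocabulary."""


def tokenize_smiles(s: str) -> list[str]:
    """Split a SMILES string into tokens.

    Token classes, in precedence order: bracket atoms, ``%nn`` ring labels,
    ``Cl``/``Br``, single characters.  Raises :class:`TokenizationError` on
    an unterminated bracket atom.
    """
    if not s:
        raise ValueError("cannot tokenize an empty SMILES string")
    depth = 0
    for ch in s:
        if ch == "[":
            if depth:
                raise TokenizationError(f"nested bracket atom in {s!r}")
            depth += 1
        elif ch == "]":
            if not depth:
                raise TokenizationError(f"unmatched ']' in {s!r}")
            depth -= 1
    if depth:
        raise TokenizationError(f"unterminated bracket atom in {s!r}")
    tokens = _TOKEN_RE.findall(s)
    assert "".join(tokens) == s
    return tokens


def detokenize(tokens: Iterable[str]) -> str:
    return "".join(tokens)


@dataclass(frozen=True)
class SmilesRecord:
    """Outcome of canonicalizing and validating one raw SMILES string."""

    raw: str
    canonical: str | None
    valid: bool
    n_tokens: int


def canonicalize_and_validate(s: str) -> SmilesRecord:
    """Canonicalize ``s`` with RDKit; never raises on invalid input.

    ``valid`` is True iff RDKit parses and sanitizes the string (which
    includes valence checks).  ``n_tokens`` counts tokens of the canonical
    form when valid, otherwise of the raw string (falling back to character
    count if the raw string does not even tokenize).
    """
    mol = Chem.MolFromSmiles(s) if s else None
    if mol is None:
        try:
            n = len(tokenize_smiles(s)) if s else 0
        except TokenizationError:
            n = len(s)
        return SmilesRecord(raw=s, canonical=None, valid=False, n_tokens=n)
    canonical = Chem.MolToSmiles(mol)
    return SmilesRecord(
        raw=s, canonical=canonical, valid=True,
        n_tokens=len(tokenize_smiles(canonical)),
    )


@dataclass(frozen=True)
class CurationPolicy:
    """Rules applied when curating a raw corpus for model training."""

    allowed_elements: frozenset[str] = DEFAULT_ELEMENTS
    max_tokens: int = 100
    strip_stereo: bool = True
    strip_charge: bool = True

    def __post_init__(self) -> None:
        if not self.allowed_elements:
            raise ValueError("allowed_elements must be non-empty")
        if self.max_tokens <= 0:
            raise ValueError("max_tokens must be positive")


def _strip_salts(mol: Chem.Mol) -> Chem.Mol | None:
    """Drop known counter-ion fragments; None if >1 fragment remains."""
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) == 1:
        return mol
    kept = [f for f in frags if Chem.MolToSmiles(f) not in COUNTERION_SMILES]
    if len(kept) != 1:
        return None
    return kept[0]


def _neutralize(mol: Chem.Mol) -> Chem.Mol | None:
    """Neutralize chemically trivial formal charges, else return None.

    Protonated/deprotonated heteroatoms (e.g. ammonium, carboxylate) are
    reset to neutral by adjusting hydrogen counts; anything that cannot be
    neutralized this way (quaternary N, metals, zwitterions that fail
    sanitization) causes the record to be discarded by the caller.
    """
    mol = Chem.RWMol(mol)
    for atom in mol.GetAtoms():
        q = atom.GetFormalCharge()
        if q == 0:
            continue
        h = atom.GetNumExplicitHs() + atom.GetNumImplicitHs()
        if q > 0 and h >= q:
            atom.SetFormalCharge(0)
            atom.SetNumExplicitHs(max(atom.GetNumExplicitHs() - q, 0))
        elif q < 0:
            atom.SetFormalCharge(0)
            atom.SetNumExplicitHs(atom.GetNumExplicitHs() - q)
        else:
            return None
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    return mol.GetMol()


def curate_corpus(
    smiles: Sequence[str] | Sequence[SmilesRecord],
    policy: CurationPolicy = CurationPolicy(),
) -> list[str]:
    """Curate a raw corpus into canonical training SMILES.

    Pipeline per record: parse -> strip counter-ion salts then discard any
    remaining multi-fragment entry -> remove stereochemistry -> neutralize
    trivial charges (discard otherwise) -> element whitelist -> canonicalize
    -> token-count cutoff.  Duplicates are removed after canonicalization,
    preserving first-occurrence order.  Idempotent on its own output.
    """
    out: list[str] = []
    seen: set[str] = set()
    for item in smiles:
        raw = item.raw if isinstance(item, SmilesRecord) else item
        mol = Chem.MolFromSmiles(raw)
        if mol is None:
            continue
        mol = _strip_salts(mol)
        if mol is None:
            continue
        if policy.strip_stereo:
            Chem.RemoveStereochemistry(mol)
        if policy.strip_charge and any(a.GetFormalCharge() for a in mol.GetAtoms()):
            mol = _neutralize(mol)
            if mol is None:
                logger.info("discarded non-neutralizable record: %s", raw)
                continue
        if any(a.GetSymbol() not in policy.allowed_elements for a in mol.GetAtoms()):
            continue
        canonical = Chem.MolToSmiles(mol)
        # re-parse so the canonical form itself is guaranteed valid
        if Chem.MolFromSmiles(canonical) is None:
            continue
        if len(tokenize_smiles(canonical)) > policy.max_tokens:
            continue
        if canonical not in seen:
            seen.add(canonical)
            out.append(canonical)
    if not out:
        logger.warning("curation produced an empty corpus")
    return out


@dataclass(frozen=True)
class Vocabulary:
    """Bijective token <-> id mapping with reserved PAD/BOS/EOS ids.

    Non-reserved tokens are stored sorted so the mapping is a deterministic
    function of the token set, making checkpoints portable across runs.
    """

    tokens: tuple[str, ...]  # reserved tokens first, then sorted corpus tokens
    index: dict[str, int] = field(repr=False, compare=False, default_factory=dict)

    def __post_init__(self) -> None:
        if self.tokens[: len(RESERVED_TOKENS)] != RESERVED_TOKENS:
            raise ValueError("vocabulary must start with the reserved tokens")
        if len(set(self.tokens)) != len(self.tokens):
            raise ValueError("duplicate tokens in vocabulary")
        object.__setattr__(self, "index", {t: i for i, t in enumerate(self.tokens)})

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def pad_id(self) -> int:
        return self.index[PAD]

    @property
    def bos_id(self) -> int:
        return self.index[BOS]

    @property
    def eos_id(self) -> int:
        return self.index[EOS]

    def id_of(self, token: str) -> int:
        try:
            return self.index[token]
        except KeyError:
            raise EncodingError(f"token {token!r} not in vocabulary") from None

    def content_hash(self) -> str:
        return hashlib.sha256("\n".join(self.tokens).encode()).hexdigest()

    def save(self, path: str | Path) -> None:
        Path(path).write_text("\n".join(self.tokens) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "Vocabulary":
        lines = Path(path).read_text().splitlines()
        return cls(tokens=tuple(lines))


def build_vocabulary(corpus: Sequence[str]) -> Vocabulary:
    """Build the sorted vocabulary covering exactly the corpus token set."""
    if not corpus:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    seen: set[str] = set()
    for s in corpus:
        seen.update(tokenize_smiles(s))
    return Vocabulary(tokens=RESERVED_TOKENS + tuple(sorted(seen)))


@dataclass(frozen=True)
class TokenSequence:
    """A tokenized SMILES encoded as ids: [BOS] tokens [EOS] [PAD]*."""

    tokens: tuple[str, ...]
    ids: tuple[int, ...]
    padded_length: int


def encode_sequence(
    tokens: Sequence[str], vocab: Vocabulary, content_length: int = 100
) -> TokenSequence:
    """Encode tokens as ``[BOS] ids [EOS]`` padded to ``content_length + 2``."""
    if len(tokens) > content_length:
        raise ValueError(
            f"sequence of {len(tokens)} tokens exceeds content length {content_length}"
        )
    ids = [vocab.bos_id] + [vocab.id_of(t) for t in tokens] + [vocab.eos_id]
    ids += [vocab.pad_id] * (content_length + 2 - len(ids))
    return TokenSequence(tokens=tuple(tokens), ids=tuple(ids),
                         padded_length=content_length)


def decode_sequence(ids: Sequence[int], vocab: Vocabulary) -> list[str]:
    """Invert :func:`encode_sequence`: strip BOS/EOS/PAD, map ids to tokens."""
    special = {vocab.pad_id, vocab.bos_id, vocab.eos_id}
    out = []
    for i in ids:
        if i == vocab.eos_id:
            break
        if i not in special:
            out.append(vocab.tokens[i])
    return out


def read_smiles_file(path: str | Path) -> list[str]:
    """Read a one-SMILES-per-line text file (blank lines skipped)."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    out = [ln for ln in lines if ln]
    if not out:
        logger.warning("no SMILES found in %s", path)
    return out


def write_smiles_file(smiles: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("".join(s + "\n" for s in smiles))


def read_smiles_csv(
    path: str | Path, smiles_column: str = "smiles", label_column: str | None = None
) -> tuple[list[str], list | None]:
    """Read SMILES (and optional activity labels) from a headered CSV."""
    df = pd.read_csv(path)
    if smiles_column not in df.columns:
        raise KeyError(f"column {smiles_column!r} missing from {path}")
    smiles = df[smiles_column].astype(str).tolist()
    labels = None
    if label_column is not None:
        if label_column not in df.columns:
            raise KeyError(f"column {label_column!r} missing from {path}")
        labels = df[label_column].tolist()
    return smiles, labels
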