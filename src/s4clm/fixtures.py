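"""Synthetic data generation for desk-scale experiments.

Every stage of the pipeline is exercisable without external databases:

* :func:`synthetic_smiles_corpus` emulates a curated pre-training corpus
  (drug-like regime: short canonical SMILES over a fixed element set),
* :func:`planted_bioactivity_dataset` emulates a fine-tuning campaign with
  tens of actives sharing a substructure motif against thousands of
  motif-free inactives,
* :func:`corrupt_smiles` manufactures invalid strings whose error category
  is known by construction.

Molecules are built constructively on a molecular graph (random trees with
valence bookkeeping, plus optional ring closures) and exported as canonical
SMILES, so validity is guaranteed by construction rather than by rejection
sampling over raw strings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .chem_io import canonicalize_and_validate, tokenize_smiles

__all__ = [
    "GrammarSpec",
    "PlantedSet",
    "synthetic_smiles_corpus",
    "planted_bioactivity_dataset",
    "corrupt_smiles",
    "CorruptionError",
]

_MAX_VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2, "P": 3,
                "F": 1, "Cl": 1, "Br": 1, "I": 1}


@dataclass(frozen=True)
class GrammarSpec:
    """Parameters of the constructive molecule generator.

    ``atoms`` is a sampling alphabet (repeats raise an element's frequency);
    ``branch_prob`` is the chance a new atom attaches to a random earlier
    atom rather than the chain head; ``ring_prob`` controls how many ring
    closures are attempted; sizes are heavy-atom counts.
    """

    atoms: tuple[str, ...] = ("C", "C", "C", "C", "C", "C", "C", "C",
                              "N", "O", "S", "F", "Cl")
    branch_prob: float = 0.3
    ring_prob: float = 0.5
    min_atoms: int = 6
    max_atoms: int = 18

    def __post_init__(self) -> None:
        if not 0 <= self.branch_prob <= 1 or not 0 <= self.ring_prob <= 1:
            raise ValueError("probabilities must be in [0, 1]")
        if not set(self.atoms) <= set(_MAX_VALENCE):
            raise ValueError(f"unsupported atoms in {self.atoms}")
        if not 1 <= self.min_atoms <= self.max_atoms:
            raise ValueError("need 1 <= min_atoms <= max_atoms")


def _random_mol(rng: np.random.Generator, spec: GrammarSpec) -> Chem.Mol | None:
    """Grow a random single-fragment molecule; None if sanitization fails.

    Organic-chemistry realism constraints: heteroatoms and halogens attach
    to carbon only (no heteroatom-heteroatom bonds, as in typical screening
    compounds), and ring closures prefer 5- and 6-membered rings.
    """
    n_target = int(rng.integers(spec.min_atoms, spec.max_atoms + 1))
    mol = Chem.RWMol()
    symbols = [str(rng.choice(spec.atoms))]
    mol.AddAtom(Chem.Atom(symbols[0]))
    free = {0: _MAX_VALENCE[symbols[0]]}
    last = 0
    while mol.GetNumAtoms() < n_target and free:
        sym = str(rng.choice(spec.atoms))
        if sym != "C":
            carbons = [i for i, v in free.items() if v > 0 and symbols[i] == "C"]
            if not carbons:
                sym = "C"
        open_atoms = ([i for i, v in free.items() if v > 0] if sym == "C"
                      else carbons)
        if not open_atoms:
            break
        if (last in open_atoms and rng.random() >= spec.branch_prob):
            parent = last
        else:
            parent = int(rng.choice(open_atoms))
        idx = mol.AddAtom(Chem.Atom(sym))
        mol.AddBond(parent, idx, Chem.BondType.SINGLE)
        free[parent] -= 1
        if free[parent] == 0:
            del free[parent]
        v = _MAX_VALENCE[sym] - 1
        if v > 0:
            free[idx] = v
        last = idx
        symbols.append(sym)
    # carbon-carbon ring closures, preferring 5-/6-membered rings
    n_rings = int(rng.binomial(3, spec.ring_prob))
    if n_rings:
        dist = Chem.GetDistanceMatrix(mol, force=True)
        for _ in range(n_rings):
            open_c = [i for i, v in free.items() if v > 0 and symbols[i] == "C"]
            pairs = [(a, b, dist[a, b]) for ai, a in enumerate(open_c)
                     for b in open_c[ai + 1:] if 3 <= dist[a, b] <= 5
                     and not mol.GetBondBetweenAtoms(a, b)]
            if not pairs:
                break
            preferred = [p for p in pairs if p[2] >= 4] or pairs
            a, b, _d = preferred[int(rng.integers(len(preferred)))]
            mol.AddBond(a, b, Chem.BondType.SINGLE)
            for i in (a, b):
                free[i] -= 1
                if free[i] == 0:
                    del free[i]
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    return mol.GetMol()


def synthetic_smiles_corpus(
    spec: GrammarSpec = GrammarSpec(), n: int = 3000,
    seed: int | np.random.Generator = 0,
) -> list[str]:
    """Generate ``n`` canonical SMILES (duplicates allowed, all valid).

    Reproducible from the seed; every output parses, stays within 100
    tokens, and survives corpus curation unchanged (single fragment,
    whitelist elements, no stereo/charge annotations).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out: list[str] = []
    while len(out) < n:
        mol = _random_mol(rng, spec)
        if mol is None:
            continue
        smi = Chem.MolToSmiles(mol)
        if len(tokenize_smiles(smi)) <= 100:
            out.append(smi)
    return out


@dataclass(frozen=True)
class PlantedSet:
    """Labeled fixture: actives share ``motif``, inactives are motif-free."""

    actives: tuple[str, ...]
    inactives: tuple[str, ...]
    motif: str
    seed: int = 0
    spec: GrammarSpec = field(default=GrammarSpec())


def planted_bioactivity_dataset(
    motif: str = "C1CCSC1",
    n_act: int = 50,
    n_inact: int = 5000,
    seed: int = 0,
    spec: GrammarSpec | None = None,
    max_tries: int = 200,
) -> PlantedSet:
    """Build a planted-bioactivity set for enrichment and fine-tuning tests.

    Actives are random molecules with the motif grafted on (verified by
    substructure search afterwards); inactives are plain random molecules
    verified NOT to match the motif.  Canonical sets are disjoint and
    duplicate-free.  Raises if the retry budget is exhausted.
    """
    query = Chem.MolFromSmiles(motif)
    if query is None:
        raise ValueError(f"motif {motif!r} is not a valid substructure pattern")
    rng = np.random.default_rng(seed)
    if spec is None:
        spec = GrammarSpec(atoms=("C", "C", "C", "C", "N", "O", "F"),
                           ring_prob=0.3, min_atoms=4, max_atoms=12)
    motif_free_valence = [
        a.GetIdx() for a in query.GetAtoms()
        if a.GetImplicitValence() + a.GetNumExplicitHs() > 0
    ]
    if not motif_free_valence:
        raise ValueError("motif has no attachment point with free valence")

    actives: list[str] = []
    inactives: list[str] = []
    seen: set[str] = set()
    budget = max_tries * (n_act + n_inact)
    while len(actives) < n_act and budget > 0:
        budget -= 1
        frag = _random_mol(rng, spec)
        if frag is None:
            continue
        combo = Chem.RWMol(Chem.CombineMols(query, frag))
        open_frag = [a.GetIdx() for a in combo.GetAtoms()
                     if a.GetIdx() >= query.GetNumAtoms()
                     and a.GetImplicitValence() + a.GetNumExplicitHs() > 0]
        if not open_frag:
            continue
        a = int(rng.choice(motif_free_valence))
        b = int(rng.choice(open_frag))
        combo.AddBond(a, b, Chem.BondType.SINGLE)
        try:
            Chem.SanitizeMol(combo)
        except Exception:
            continue
        smi = Chem.MolToSmiles(combo)
        mol = Chem.MolFromSmiles(smi)
        if mol is None or not mol.HasSubstructMatch(query) or smi in seen:
            continue
        if len(tokenize_smiles(smi)) > 100:
            continue
        seen.add(smi)
        actives.append(smi)
    while len(inactives) < n_inact and budget > 0:
        budget -= 1
        mol = _random_mol(rng, spec)
        if mol is None:
            continue
        smi = Chem.MolToSmiles(mol)
        if smi in seen or Chem.MolFromSmiles(smi).HasSubstructMatch(query):
            continue
        seen.add(smi)
        inactives.append(smi)
    if len(actives) < n_act or len(inactives) < n_inact:
        raise RuntimeError(
            f"could not satisfy motif constraints within the retry budget "
            f"({len(actives)}/{n_act} actives, {len(inactives)}/{n_inact} inactives)"
        )
    return PlantedSet(actives=tuple(actives), inactives=tuple(inactives),
                      motif=motif, seed=seed, spec=spec)


class CorruptionError(RuntimeError):
    """Corruption of the requested category could not be produced."""


def corrupt_smiles(valid_smiles: str, error_type: str, seed: int = 0) -> str:
    """Turn a valid SMILES into an invalid one of a known error category.

    The returned string fails validation and is classified exactly as
    ``error_type`` by :func:`s4clm.evaluation.classify_invalid_smiles`
    (verified before returning).

    * ``branching`` — insert an unmatched ``(``.
    * ``ring`` — delete one ring-closure digit (or insert an unmatched one
      on ring-free strings).
    * ``bond`` — prepend ``F=``: fluorine cannot carry a double bond, so
      the string stays syntactically balanced but violates valence.
    * ``other`` — insert a character outside the SMILES alphabet.
    """
    from .evaluation import classify_invalid_smiles  # local: avoids cycle

    rec = canonicalize_and_validate(valid_smiles)
    if not rec.valid:
        raise ValueError(f"input {valid_smiles!r} is not a valid SMILES")
    rng = np.random.default_rng(seed)
    tokens = tokenize_smiles(valid_smiles)

    if error_type == "branching":
        pos = int(rng.integers(1, len(tokens) + 1))
        corrupted = "".join(tokens[:pos]) + "(" + "".join(tokens[pos:])
    elif error_type == "ring":
        ring_pos = [i for i, t in enumerate(tokens)
                    if t.isdigit() or t.startswith("%")]
        if ring_pos:
            drop = int(rng.choice(ring_pos))
            corrupted = "".join(t for i, t in enumerate(tokens) if i != drop)
        else:
            corrupted = tokens[0] + "9" + "".join(tokens[1:])
    elif error_type == "bond":
        corrupted = "F=" + valid_smiles
    elif error_type == "other":
        pos = int(rng.integers(1, len(tokens) + 1))
        corrupted = "".join(tokens[:pos]) + "&" + "".join(tokens[pos:])
    else:
        raise ValueError(f"unknown error type {error_type!r}")

    if canonicalize_and_validate(corrupted).valid:
        raise CorruptionError(
            f"{error_type} corruption of {valid_smiles!r} stayed valid")
    got = classify_invalid_smiles(corrupted)
    if got != error_type:
        raise CorruptionError(
            f"{error_type} corruption of {valid_smiles!r} classified as {got}")
    return corrupted
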