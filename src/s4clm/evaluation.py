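"""Design-quality evaluation: validity/uniqueness/novelty, invalid-SMILES
error taxonomy, molecular property profiles with Kolmogorov–Smirnov
distances, rediscovery of held-out actives, scaffold clustering, and the
prospective design-selection protocol.
"""

from __future__ import annotations

import logging
import os
import sys
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem, DataStructs
from rdkit.Chem import Descriptors, GraphDescriptors, QED, rdMolDescriptors
from rdkit.Chem.Crippen import MolLogP
from rdkit.Chem.Scaffolds import MurckoScaffold
from rdkit.Chem import rdFingerprintGenerator, RDConfig
from scipy import stats

from .chem_io import canonicalize_and_validate, tokenize_smiles

logger = logging.getLogger(__name__)

ERROR_CATEGORIES = ("branching", "ring", "bond", "other")

#: Fingerprint convention used throughout: extended-connectivity
#: (Morgan) fingerprints with radius 3, hashed to 2048 bits.
FP_RADIUS, FP_BITS = 3, 2048

_fp_gen = rdFingerprintGenerator.GetMorganGenerator(radius=FP_RADIUS,
                                                    fpSize=FP_BITS)

for _sub in ("SA_Score", "NP_Score"):
    _p = os.path.join(RDConfig.RDContribDir, _sub)
    if _p not in sys.path:
        sys.path.append(_p)
import sascorer  # noqa: E402  (RDKit Contrib)
import npscorer  # noqa: E402

_np_model = None


def _np_likeness(mol: Chem.Mol) -> float:
    global _np_model
    if _np_model is None:
        _np_model = npscorer.readNPModel()
    return npscorer.scoreMol(mol, _np_model)


def fingerprint(mol: Chem.Mol):
    """ECFP-like Morgan fingerprint (radius 3, 2048 bits)."""
    return _fp_gen.GetFingerprint(mol)


# ----------------------------------------------------------------- taxonomy

def classify_invalid_smiles(s: str) -> str:
    """Categorize why a SMILES string is invalid.

    Precedence: ``branching`` (unbalanced parentheses) > ``ring``
    (unmatched ring-closure labels) > ``bond`` (syntactically balanced but
    the molecule fails valence/bond-order sanitization) > ``other``
    (any remaining parse failure).  Calling this on a valid string is a
    contract violation and raises ``ValueError``.
    """
    if canonicalize_and_validate(s).valid:
        raise ValueError(f"{s!r} is a valid SMILES; nothing to classify")
    depth = 0
    balanced = True
    for ch in s:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                balanced = False
                break
    if depth != 0:
        balanced = False
    if not balanced:
        return "branching"
    try:
        tokens = tokenize_smiles(s)
    except ValueError:
        return "other"
    counts: dict[str, int] = {}
    for t in tokens:
        if t.isdigit() or (t.startswith("%") and len(t) == 3):
            label = t.lstrip("%")
            counts[label] = counts.get(label, 0) + 1
    if any(c % 2 for c in counts.values()):
        return "ring"
    mol = Chem.MolFromSmiles(s, sanitize=False)
    if mol is None:
        return "other"
    return "bond"


# ----------------------------------------------------------------- VUN core

@dataclass
class EvaluationReport:
    """Core design-quality counts plus the invalid-SMILES taxonomy.

    Counts are nested (``novel <= unique <= valid <= generated``) and all
    fractions use the total generated count as denominator.  Taxonomy
    counts sum to ``n_generated - n_valid``.
    """

    n_generated: int
    n_valid: int
    n_unique: int
    n_novel: int
    taxonomy: dict[str, int] = field(default_factory=dict)
    novel_smiles: list[str] = field(default_factory=list)

    @property
    def fractions(self) -> dict[str, float]:
        n = max(self.n_generated, 1)
        return {"valid": self.n_valid / n, "unique": self.n_unique / n,
                "novel": self.n_novel / n}

    def to_frame(self) -> pd.DataFrame:
        f = self.fractions
        return pd.DataFrame(
            [{"n_generated": self.n_generated, "n_valid": self.n_valid,
              "n_unique": self.n_unique, "n_novel": self.n_novel,
              "valid_frac": f["valid"], "unique_frac": f["unique"],
              "novel_frac": f["novel"], **{f"err_{k}": v
                                           for k, v in self.taxonomy.items()}}])


def validity_uniqueness_novelty(
    designs: list[str], training_set: set[str] | list[str],
    classify_errors: bool = True,
) -> EvaluationReport:
    """Count valid, unique and novel designs (fractions over all designs).

    ``valid``: parses chemically; ``unique``: distinct canonical forms among
    the valid; ``novel``: unique and absent from the (canonicalized)
    training set.  Invalid designs are classified into the error taxonomy.
    """
    training_set = set(training_set)
    taxonomy = dict.fromkeys(ERROR_CATEGORIES, 0)
    seen: set[str] = set()
    n_valid = 0
    novel: list[str] = []
    for s in designs:
        rec = canonicalize_and_validate(s)
        if not rec.valid:
            if classify_errors:
                taxonomy[classify_invalid_smiles(s)] += 1
            continue
        n_valid += 1
        if rec.canonical in seen:
            continue
        seen.add(rec.canonical)
        if rec.canonical not in training_set:
            novel.append(rec.canonical)
    return EvaluationReport(
        n_generated=len(designs), n_valid=n_valid, n_unique=len(seen),
        n_novel=len(novel), taxonomy=taxonomy if classify_errors else {},
        novel_smiles=novel)


# ------------------------------------------------------------- descriptors

def _largest_fused_ring_system(mol: Chem.Mol) -> int:
    """Number of SSSR rings in the largest group of atom-sharing rings."""
    rings = [set(r) for r in mol.GetRingInfo().AtomRings()]
    if not rings:
        return 0
    parent = list(range(len(rings)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(rings)):
        for j in range(i + 1, len(rings)):
            if rings[i] & rings[j]:
                parent[find(i)] = find(j)
    sizes: dict[int, int] = {}
    for i in range(len(rings)):
        r = find(i)
        sizes[r] = sizes.get(r, 0) + 1
    return max(sizes.values())


def _n_sp3_carbons(mol: Chem.Mol) -> int:
    return sum(1 for a in mol.GetAtoms()
               if a.GetAtomicNum() == 6
               and a.GetHybridization() == Chem.HybridizationType.SP3)


_DESCRIPTORS = {
    "logp": MolLogP,
    "qed": QED.qed,
    "bertz_complexity": GraphDescriptors.BertzCT,
    "sa_score": sascorer.calculateScore,
    "np_likeness": _np_likeness,
    "n_sp3_carbons": _n_sp3_carbons,
    "n_aliphatic_rings": rdMolDescriptors.CalcNumAliphaticRings,
    "n_spiro_atoms": rdMolDescriptors.CalcNumSpiroAtoms,
    "mol_weight": Descriptors.MolWt,
    "largest_fused_ring_system": _largest_fused_ring_system,
    "n_heavy_atoms": lambda m: m.GetNumHeavyAtoms(),
}


def property_profile(smiles: list[str]) -> pd.DataFrame:
    """Per-molecule descriptor table (valid molecules only).

    Molecules failing any descriptor are excluded with a log entry.
    Columns: logP, QED drug-likeness, Bertz complexity, synthetic
    accessibility, NP-likeness, sp3-carbon / aliphatic-ring / spiro-atom /
    heavy-atom counts, molecular weight (Da), largest fused ring system.
    """
    rows = []
    for s in smiles:
        mol = Chem.MolFromSmiles(s)
        if mol is None:
            logger.info("property_profile: skipping invalid SMILES %s", s)
            continue
        try:
            rows.append({"smiles": s,
                         **{k: f(mol) for k, f in _DESCRIPTORS.items()}})
        except Exception as exc:  # descriptor failure
            logger.info("descriptor failure on %s: %s", s, exc)
    return pd.DataFrame(rows)


def profile_summary(profile: pd.DataFrame) -> pd.DataFrame:
    """Mean ± standard deviation per descriptor."""
    num = profile.drop(columns=["smiles"], errors="ignore")
    return pd.DataFrame({"mean": num.mean(), "sd": num.std(ddof=1)})


def ks_distance(sample_a, sample_b) -> float:
    """Two-sample Kolmogorov–Smirnov statistic as a percentage in [0, 100].

    The supremum difference of the two empirical CDFs; 0% iff the ECDFs
    coincide at every sample point, 100% for disjoint supports.
    """
    a, b = np.asarray(sample_a, float), np.asarray(sample_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("KS distance requires non-empty samples")
    return float(stats.ks_2samp(a, b).statistic * 100.0)


def ks_table(design_profile: pd.DataFrame, train_profile: pd.DataFrame,
             test_profile: pd.DataFrame) -> pd.DataFrame:
    """Property table in Table-2 layout: mean ± sd plus KS_train / KS_test."""
    rows = []
    for col in design_profile.columns:
        if col == "smiles":
            continue
        rows.append({
            "descriptor": col,
            "mean": design_profile[col].mean(),
            "sd": design_profile[col].std(ddof=1),
            "ks_train_pct": ks_distance(design_profile[col], train_profile[col]),
            "ks_test_pct": ks_distance(design_profile[col], test_profile[col]),
        })
    return pd.DataFrame(rows)


# ------------------------------------------------------------- rediscovery

def rediscovery_rate(
    designs: list[str], held_out_actives: list[str],
    threshold: float = 0.6, mode: str = "relaxed",
) -> float:
    """Fraction of held-out actives matched by at least one design.

    ``exact``: identical canonical structure.  ``relaxed``: Tanimoto
    similarity on ECFP (radius 3, 2048 bits) strictly above ``threshold``.
    """
    if not held_out_actives:
        raise ValueError("held_out_actives must be non-empty")
    design_canon = {r.canonical for r in map(canonicalize_and_validate, designs)
                    if r.valid}
    if mode == "exact":
        hits = sum(1 for a in held_out_actives
                   if canonicalize_and_validate(a).canonical in design_canon)
        return hits / len(held_out_actives)
    if mode != "relaxed":
        raise ValueError(f"unknown rediscovery mode {mode!r}")
    design_fps = [fingerprint(Chem.MolFromSmiles(s)) for s in design_canon]
    hits = 0
    for a in held_out_actives:
        mol = Chem.MolFromSmiles(a)
        if mol is None:
            continue
        fp = fingerprint(mol)
        if design_fps and max(DataStructs.BulkTanimotoSimilarity(
                fp, design_fps)) > threshold:
            hits += 1
    return hits / len(held_out_actives)


# ---------------------------------------------------------------- scaffolds

@dataclass
class ClusterResult:
    """Scaffold clustering outcome (single linkage at a Tanimoto cutoff)."""

    labels: np.ndarray
    n_clusters: int
    threshold: float
    linkage: str = "single"


def murcko_scaffold_smiles(smiles: str) -> str:
    """Bemis–Murcko scaffold as canonical SMILES ('' for acyclic input)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES {smiles!r}")
    scaf = MurckoScaffold.GetScaffoldForMol(mol)
    return Chem.MolToSmiles(scaf) if scaf.GetNumAtoms() else ""


def scaffold_cluster_count(
    designs: list[str], threshold: float = 0.6,
) -> ClusterResult:
    """Cluster designs by Bemis–Murcko scaffold similarity.

    Scaffolds are fingerprinted (ECFP radius 3, 2048 bits) and two designs
    belong to the same cluster when connected by a chain of scaffold pairs
    with Tanimoto similarity strictly above ``threshold`` — i.e. single
    linkage cut at distance ``1 - threshold``, realized as the connected
    components of the threshold graph.  Acyclic molecules (empty scaffold)
    share one dedicated no-scaffold cluster.
    """
    n = len(designs)
    labels = np.full(n, -1)
    scaffolds = [murcko_scaffold_smiles(s) for s in designs]
    cyc = [i for i, s in enumerate(scaffolds) if s]
    acyclic = [i for i, s in enumerate(scaffolds) if not s]
    if acyclic:
        logger.info("%d acyclic designs assigned to the no-scaffold cluster",
                    len(acyclic))
    fps = [fingerprint(Chem.MolFromSmiles(scaffolds[i])) for i in cyc]
    parent = list(range(len(cyc)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(cyc)):
        if i + 1 < len(cyc):
            sims = DataStructs.BulkTanimotoSimilarity(fps[i], fps[i + 1:])
            for off, sim in enumerate(sims):
                if sim > threshold:
                    parent[find(i)] = find(i + 1 + off)
    roots = {}
    for i, gi in enumerate(cyc):
        r = find(i)
        roots.setdefault(r, len(roots))
        labels[gi] = roots[r]
    n_clusters = len(roots)
    if acyclic:
        labels[acyclic] = n_clusters
        n_clusters += 1
    return ClusterResult(labels=labels, n_clusters=n_clusters,
                         threshold=threshold)


# ---------------------------------------------- prospective design selection

@dataclass
class ProspectiveSelection:
    """Shortlists from the prospective protocol.

    ``high`` / ``low`` hold designs whose Bemis–Murcko scaffold similarity
    to the fine-tuning set is above / at-or-below the threshold, one design
    per nearest-training-molecule group (the group's highest bias-corrected
    scorer), ranked by score.
    """

    high: pd.DataFrame
    low: pd.DataFrame


def select_prospective_designs(
    designs: pd.DataFrame,
    finetune_set: list[str],
    top_n: int = 5000,
    sim_threshold: float = 0.6,
) -> ProspectiveSelection:
    """Apply the prospective design-selection protocol.

    ``designs`` needs columns ``smiles``, ``loglik_ft`` (fine-tuning joint
    log-likelihood used for the top-N cut) and ``score`` (bias-corrected
    log-likelihood score used for within-group ranking).  Steps: keep valid,
    unique designs novel w.r.t. the fine-tuning set; rank by ``loglik_ft``
    and keep the top N; split at scaffold-fingerprint Tanimoto
    ``sim_threshold`` against the fine-tuning molecules; group each side by
    its most-similar fine-tuning molecule and keep the top scorer per group.
    """
    ft_canon = {canonicalize_and_validate(s).canonical for s in finetune_set}
    rows = []
    seen: set[str] = set()
    for _, row in designs.iterrows():
        rec = canonicalize_and_validate(row["smiles"])
        if not rec.valid or rec.canonical in seen or rec.canonical in ft_canon:
            continue
        seen.add(rec.canonical)
        rows.append({**row.to_dict(), "smiles": rec.canonical})
    pool = pd.DataFrame(rows)
    if pool.empty:
        return ProspectiveSelection(high=pool, low=pool.copy())
    pool = pool.sort_values("loglik_ft", ascending=False, kind="stable")
    if len(pool) < top_n:
        logger.warning("only %d candidates for top_n=%d; keeping all",
                       len(pool), top_n)
    pool = pool.head(top_n).reset_index(drop=True)

    ft_scafs = [murcko_scaffold_smiles(s) for s in finetune_set]
    ft_fps = [fingerprint(Chem.MolFromSmiles(s if s else ss))
              for s, ss in zip(ft_scafs, finetune_set)]
    nearest, nearest_sim = [], []
    for s in pool["smiles"]:
        scaf = murcko_scaffold_smiles(s)
        fp = fingerprint(Chem.MolFromSmiles(scaf if scaf else s))
        sims = DataStructs.BulkTanimotoSimilarity(fp, ft_fps)
        j = int(np.argmax(sims))
        nearest.append(j)
        nearest_sim.append(sims[j])
    pool["nearest_ft"] = nearest
    pool["nearest_ft_similarity"] = nearest_sim

    def _shortlist(side: pd.DataFrame) -> pd.DataFrame:
        if side.empty:
            return side
        best = side.sort_values("score", ascending=False, kind="stable") \
                   .groupby("nearest_ft", as_index=False).head(1)
        return best.sort_values("score", ascending=False,
                                kind="stable").reset_index(drop=True)

    high = _shortlist(pool[pool["nearest_ft_similarity"] > sim_threshold])
    low = _shortlist(pool[pool["nearest_ft_similarity"] <= sim_threshold])
    return ProspectiveSelection(high=high, low=low)
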