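import numpy as np
import pandas as pd
import pytest
from rdkit import Chem

from s4clm.evaluation import (classify_invalid_smiles, fingerprint,
                              ks_distance, murcko_scaffold_smiles,
                              property_profile, rediscovery_rate,
                              scaffold_cluster_count,
                              select_prospective_designs,
                              validity_uniqueness_novelty)


def _tanimoto_oracle(s1, s2):
    """Independent Tanimoto: explicit bit arithmetic on the fingerprints."""
    a = np.array(fingerprint(Chem.MolFromSmiles(s1)))
    b = np.array(fingerprint(Chem.MolFromSmiles(s2)))
    return (a & b).sum() / (a | b).sum()


def test_vun_counts_by_definition():
    rep = validity_uniqueness_novelty(["CCO", "CCO", "C1CC1", "C(C"], {"CCO"})
    assert (rep.n_generated, rep.n_valid, rep.n_unique, rep.n_novel) \
        == (4, 3, 2, 1)
    assert rep.taxonomy["branching"] == 1
    assert sum(rep.taxonomy.values()) == rep.n_generated - rep.n_valid


def test_vun_degenerate_cases():
    rep = validity_uniqueness_novelty(["C(C", "C1CC"], set())
    assert (rep.n_valid, rep.n_unique, rep.n_novel) == (0, 0, 0)
    designs = ["CCO", "CCN", "CCS"]
    rep = validity_uniqueness_novelty(designs, {"CCCCCC"})
    assert rep.n_valid == rep.n_unique == rep.n_novel == 3
    assert rep.fractions["novel"] == 1.0


@pytest.mark.parametrize("smiles,category", [
    ("C(C", "branching"),
    ("CC)C", "branching"),
    ("C1CC", "ring"),
    ("C1(C", "branching"),  # precedence: branching before ring
    ("F=F", "bond"),
    ("c1cccc1", "bond"),  # balanced but unkekulizable
    ("CC&O", "other"),
])
def test_error_taxonomy(smiles, category):
    assert classify_invalid_smiles(smiles) == category


def test_classifier_rejects_valid_input():
    with pytest.raises(ValueError):
        classify_invalid_smiles("CCO")


def test_property_profile_known_molecules():
    prof = property_profile(["c1ccccc1", "C1CCCCC1", "C1CCC2(C1)CCCC2"])
    benzene, cyclohexane, spiro = prof.iloc[0], prof.iloc[1], prof.iloc[2]
    assert benzene["n_heavy_atoms"] == 6
    assert benzene["n_aliphatic_rings"] == 0
    assert benzene["n_spiro_atoms"] == 0
    assert cyclohexane["n_sp3_carbons"] == 6
    assert cyclohexane["n_aliphatic_rings"] == 1
    assert spiro["n_spiro_atoms"] == 1
    # naphthalene's two rings are one fused system
    naph = property_profile(["c1ccc2ccccc2c1"]).iloc[0]
    assert naph["largest_fused_ring_system"] == 2


def test_ks_identity_symmetry_and_disjoint():
    a = [1.0, 2.0, 3.0, 4.0]
    assert ks_distance(a, a) == 0.0
    assert ks_distance([1, 2], [10, 20]) == 100.0
    assert ks_distance(a, [2, 3]) == ks_distance([2, 3], a)
    with pytest.raises(ValueError):
        ks_distance([], [1.0])


def test_ks_matches_brute_force_ecdf():
    a, b = np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 4.0])
    pts = np.concatenate([a, b])
    sup = max(abs((a <= x).mean() - (b <= x).mean()) for x in pts)
    assert ks_distance(a, b) == pytest.approx(100 * sup)


def test_rediscovery_exact_and_relaxed():
    actives = ["CCCCCCCCO"]
    assert rediscovery_rate(["OCCCCCCCC"], actives, mode="exact") == 1.0
    assert rediscovery_rate(["OCCCCCCCC"], actives, mode="relaxed") == 1.0
    # a dissimilar design matches in neither mode
    assert rediscovery_rate(["c1ccncc1"], actives, mode="relaxed") == 0.0
    assert rediscovery_rate(["c1ccncc1"], actives, mode="exact") == 0.0


def test_rediscovery_threshold_strict():
    a, d = "CCCCCCCCCCO", "CCCCCCCCCCN"  # close homologs
    sim = _tanimoto_oracle(a, d)
    rate = rediscovery_rate([d], [a], threshold=0.6, mode="relaxed")
    assert rate == (1.0 if sim > 0.6 else 0.0)
    # exactly-at-threshold must NOT count
    assert rediscovery_rate([d], [a], threshold=sim, mode="relaxed") == 0.0


def test_relaxed_rediscovery_dominates_exact(planted):
    designs = list(planted.actives[:10]) + list(planted.inactives[:40])
    actives = list(planted.actives[40:56])
    relaxed = rediscovery_rate(designs, actives, mode="relaxed")
    exact = rediscovery_rate(designs, actives, mode="exact")
    assert relaxed >= exact


def test_scaffold_clusters_single_shared_scaffold():
    designs = ["c1ccccc1CC", "c1ccccc1CCC", "c1ccccc1CCCC"]
    res = scaffold_cluster_count(designs)
    assert res.n_clusters == 1


def test_scaffold_clusters_match_component_oracle():
    designs = ["c1ccccc1C", "C1CCCCC1C", "C1CC2(C1)CCCC2C",
               "c1ccc2ccccc2c1C", "c1ccncc1C"]
    res = scaffold_cluster_count(designs, threshold=0.6)
    # brute-force oracle: union-find over pairwise scaffold Tanimoto > 0.6
    scafs = [murcko_scaffold_smiles(s) for s in designs]
    n = len(scafs)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if _tanimoto_oracle(scafs[i], scafs[j]) > 0.6:
                parent[find(i)] = find(j)
    expected = len({find(i) for i in range(n)})
    assert res.n_clusters == expected


def test_scaffold_clusters_acyclic_and_order_invariance():
    designs = ["CCO", "CCCN", "c1ccccc1C"]
    res = scaffold_cluster_count(designs)
    assert res.n_clusters == 2  # no-scaffold cluster + benzene
    shuffled = ["c1ccccc1C", "CCO", "CCCN"]
    assert scaffold_cluster_count(shuffled).n_clusters == res.n_clusters


def _protocol_oracle(designs, ft, top_n, thr):
    """Exhaustive re-application of the selection rules."""
    from s4clm.chem_io import canonicalize_and_validate
    ft_canon = {canonicalize_and_validate(s).canonical for s in ft}
    pool, seen = [], set()
    for row in designs.to_dict("records"):
        c = canonicalize_and_validate(row["smiles"]).canonical
        if c is None or c in seen or c in ft_canon:
            continue
        seen.add(c)
        pool.append({**row, "smiles": c})
    pool = sorted(pool, key=lambda r: -r["loglik_ft"])[:top_n]
    ft_scafs = [murcko_scaffold_smiles(s) or s for s in ft]
    for r in pool:
        scaf = murcko_scaffold_smiles(r["smiles"]) or r["smiles"]
        sims = [_tanimoto_oracle(scaf, fs) for fs in ft_scafs]
        r["nn"], r["sim"] = int(np.argmax(sims)), max(sims)
    out = {}
    for side, rows in (("high", [r for r in pool if r["sim"] > thr]),
                       ("low", [r for r in pool if r["sim"] <= thr])):
        best = {}
        for r in rows:
            if r["nn"] not in best or r["score"] > best[r["nn"]]["score"]:
                best[r["nn"]] = r
        out[side] = sorted((r["smiles"] for r in best.values()),
                           key=lambda s: -next(r["score"] for r in rows
                                               if r["smiles"] == s))
    return out


def test_prospective_selection_against_oracle(planted):
    ft = list(planted.actives[:2])
    designs = pd.DataFrame({
        "smiles": list(planted.actives[2:6]) + list(planted.inactives[:2]),
        "loglik_ft": [-1.0, -2.0, -3.0, -4.0, -5.0, -6.0],
        "score": [0.5, 2.0, 1.0, 3.0, -1.0, 4.0],
    })
    sel = select_prospective_designs(designs, ft, top_n=6, sim_threshold=0.6)
    oracle = _protocol_oracle(designs, ft, 6, 0.6)
    assert list(sel.high["smiles"]) == oracle["high"]
    assert list(sel.low["smiles"]) == oracle["low"]


def test_prospective_selection_trivial_cases():
    ft = ["c1ccccc1CCN"]
    # identical Bemis-Murcko scaffold to the training molecule -> high list
    designs = pd.DataFrame({"smiles": ["c1ccccc1CCO", "C1CC1CCCC"],
                            "loglik_ft": [-1.0, -2.0], "score": [1.0, 2.0]})
    sel = select_prospective_designs(designs, ft, top_n=5000)
    from s4clm.chem_io import canonicalize_and_validate
    expected = canonicalize_and_validate("c1ccccc1CCO").canonical
    assert list(sel.high["smiles"]) == [expected]
    assert sel.high.iloc[0]["nearest_ft_similarity"] == 1.0
    # fewer candidates than top_n: all inputs retained across the two lists
    assert len(sel.high) + len(sel.low) == 2
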