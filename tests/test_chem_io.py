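import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from s4clm.chem_io import (
    CurationPolicy, EncodingError, TokenizationError, Vocabulary,
    build_vocabulary, canonicalize_and_validate, curate_corpus,
    decode_sequence, detokenize, encode_sequence, read_smiles_csv,
    read_smiles_file, tokenize_smiles, write_smiles_file, RESERVED_TOKENS,
)
from s4clm.fixtures import GrammarSpec, synthetic_smiles_corpus


@pytest.mark.parametrize("smiles,expected", [
    ("CCO", ["C", "C", "O"]),
    ("c1ccccc1Cl", ["c", "1", "c", "c", "c", "c", "c", "1", "Cl"]),
    ("C%10CC%10", ["C", "%10", "C", "C", "%10"]),
    ("[nH]", ["[nH]"]),
    ("CC(=O)[O-].[Na+]", ["C", "C", "(", "=", "O", ")", "[O-]", ".", "[Na+]"]),
])
def test_tokenize_known_classes(smiles, expected):
    assert tokenize_smiles(smiles) == expected


def test_tokenize_errors():
    with pytest.raises(TokenizationError):
        tokenize_smiles("C[nH")
    with pytest.raises(ValueError):
        tokenize_smiles("")


@given(st.integers(0, 59))
@settings(max_examples=30, deadline=None)
def test_tokenize_detokenize_identity(idx):
    corpus = synthetic_smiles_corpus(GrammarSpec(), n=60, seed=1)
    s = corpus[idx]
    assert detokenize(tokenize_smiles(s)) == s


def test_canonicalize_same_molecule():
    rec = canonicalize_and_validate("OCC")
    assert rec.valid and rec.canonical == "CCO" and rec.n_tokens == 3


def test_canonicalize_invalid_never_raises():
    rec = canonicalize_and_validate("C(C")
    assert not rec.valid and rec.canonical is None and rec.n_tokens == 3


def test_canonical_form_is_fixed_point():
    # canonical form of benzene under RDKit, frozen once as a fixture
    rec = canonicalize_and_validate("c1ccccc1")
    assert rec.valid and rec.canonical == "c1ccccc1"


def test_curate_element_filter():
    assert curate_corpus(["CCO", "CC[Si](C)C"]) == ["CCO"]


def test_curate_strips_stereo():
    assert curate_corpus(["C[C@H](N)C(=O)O"]) == ["CC(N)C(=O)O"]


def test_curate_token_cutoff():
    long_chain = "C" * 101  # valid alkane of 101 tokens
    assert canonicalize_and_validate(long_chain).valid
    assert curate_corpus([long_chain]) == []
    assert curate_corpus([long_chain], CurationPolicy(max_tokens=101)) \
        == [long_chain]


def test_curate_salts_and_fragments():
    # counter-ion stripped, true multi-fragment discarded, charge neutralized
    assert curate_corpus(["CC[NH3+].[Cl-]"]) == ["CCN"]
    assert curate_corpus(["CCO.CCN"]) == []


def test_curate_idempotent(small_corpus):
    once = curate_corpus(small_corpus)
    assert curate_corpus(once) == once
    for s in once:
        rec = canonicalize_and_validate(s)
        assert rec.valid and rec.n_tokens <= 100


def test_vocabulary_contents_and_determinism():
    v1 = build_vocabulary(["CCO"])
    assert len(v1) == 5  # C, O + 3 reserved
    v2 = build_vocabulary(["CCO", "CCN"])
    assert set(v2.tokens) == set(RESERVED_TOKENS) | {"C", "O", "N"}
    assert build_vocabulary(["CCO", "CCN"]).tokens == v2.tokens


def test_vocabulary_round_trip(tmp_path):
    v = build_vocabulary(["CC(N)Cl", "C1CC1O"])
    path = tmp_path / "vocab.txt"
    v.save(path)
    loaded = Vocabulary.load(path)
    assert loaded.tokens == v.tokens
    assert loaded.content_hash() == v.content_hash()


def test_encode_layout():
    v = build_vocabulary(["CCO"])
    seq = encode_sequence(["C", "C", "O"], v, content_length=5)
    c, o = v.id_of("C"), v.id_of("O")
    assert seq.ids == (v.bos_id, c, c, o, v.eos_id, v.pad_id, v.pad_id)


def test_encode_empty_and_round_trip():
    v = build_vocabulary(["CCO"])
    seq = encode_sequence([], v, content_length=3)
    assert seq.ids == (v.bos_id, v.eos_id, v.pad_id, v.pad_id, v.pad_id)
    toks = ["C", "O", "C"]
    assert decode_sequence(encode_sequence(toks, v, 6).ids, v) == toks


def test_encode_oov_names_token():
    v = build_vocabulary(["CCO"])
    with pytest.raises(EncodingError, match="Br"):
        encode_sequence(["C", "Br"], v, 5)


def test_smiles_file_round_trip(tmp_path):
    path = tmp_path / "mols.smi"
    write_smiles_file(["CCO", "CCN"], path)
    assert read_smiles_file(path) == ["CCO", "CCN"]
    (tmp_path / "empty.smi").write_text("")
    assert read_smiles_file(tmp_path / "empty.smi") == []


def test_csv_round_trip(tmp_path):
    path = tmp_path / "mols.csv"
    path.write_text("smiles,label\nCCO,1\nCCN,0\n")
    smiles, labels = read_smiles_csv(path, "smiles", "label")
    assert smiles == ["CCO", "CCN"] and labels == [1, 0]
    with pytest.raises(KeyError):
        read_smiles_csv(path, "nope")
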