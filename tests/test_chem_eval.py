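"""Descriptors: Fsp3, Morgan/Tanimoto, nearest-active, distance summaries."""

import numpy as np
import pytest
from rdkit import DataStructs
from rdkit.Chem import AllChem, MolFromSmiles
from rdkit.Chem.rdMolDescriptors import CalcFractionCSP3

from beamchem.chem_eval import (
    DistanceSummary,
    FingerprintSpec,
    distance_distribution,
    fsp3,
    morgan_fingerprint,
    nearest_reference_similarity,
    tanimoto,
)
from beamchem.fixtures import CorpusSpec, make_corpus


def _bitvec(bits, size=16):
    v = DataStructs.ExplicitBitVect(size)
    for b in bits:
        v.SetBit(b)
    return v


@pytest.mark.parametrize(
    ("smiles", "expected"),
    [
        ("C1CCCCC1", 1.0),      # cyclohexane: all sp3
        ("c1ccccc1", 0.0),      # benzene: all aromatic
        ("CCc1ccccc1", 0.25),   # ethylbenzene: 2 of 8
        ("CC(=O)O", 0.5),       # acetic acid: methyl sp3, carboxyl sp2
    ],
)
def test_fsp3_examples(smiles, expected):
    assert fsp3(smiles) == pytest.approx(expected)


def test_fsp3_agrees_with_independent_implementation():
    corpus = make_corpus(CorpusSpec(family="mixed", size=200, seed=3))
    for s in corpus:
        mol = MolFromSmiles(s)
        if not any(a.GetAtomicNum() == 6 for a in mol.GetAtoms()):
            continue
        val = fsp3(s)
        assert 0.0 <= val <= 1.0
        assert val == pytest.approx(CalcFractionCSP3(mol), abs=1e-9)


def test_fsp3_errors():
    with pytest.raises(ValueError, match="invalid"):
        fsp3("C((C")
    with pytest.raises(ValueError, match="carbon-free"):
        fsp3("O")  # water has no carbon


def test_tanimoto_identity_disjoint_overlap():
    a = _bitvec({1, 2, 3})
    b = _bitvec({2, 3, 4})
    assert tanimoto(a, a) == 1.0
    assert tanimoto(a, _bitvec({7, 8})) == 0.0
    assert tanimoto(a, b) == 0.5  # |{2,3}| / |{1,2,3,4}|
    assert tanimoto(a, b) == tanimoto(b, a)


def test_tanimoto_empty_and_mismatch():
    assert tanimoto(_bitvec(set()), _bitvec(set())) == 0.0
    with pytest.raises(ValueError, match="mismatch"):
        tanimoto(_bitvec({1}, size=16), _bitvec({1}, size=32))


def test_morgan_fingerprint_spec():
    fp = morgan_fingerprint("CCO", FingerprintSpec(radius=2, n_bits=1024))
    assert fp.GetNumBits() == 1024
    ref = AllChem.GetMorganFingerprintAsBitVect(MolFromSmiles("CCO"), 2, 1024)
    assert tanimoto(fp, ref) == 1.0


def test_nearest_reference_similarity():
    designs = ["CCO", "CCCN"]
    refs = ["OCC", "c1ccccc1"]
    out = nearest_reference_similarity(designs, refs)
    assert out[0] == (1.0, "OCC")  # identical to a reference
    single = nearest_reference_similarity(["CCO"], ["CCC"])
    pair = tanimoto(morgan_fingerprint("CCO"), morgan_fingerprint("CCC"))
    assert single[0][0] == pytest.approx(pair)
    with pytest.raises(ValueError):
        nearest_reference_similarity(["CCO"], [])


def test_self_reference_similarity_is_one():
    mols = make_corpus(CorpusSpec(family="mixed", size=10, seed=9))
    out = nearest_reference_similarity(mols, mols)
    assert all(s == 1.0 for s, _ in out)


def test_distance_distribution_degenerate_sets():
    same = distance_distribution(["CCO", "OCC", "CCO"])
    assert same.q25 == same.median == same.q75 == same.mean == 0.0
    two = distance_distribution(["CCO", "CCC"])
    d = 1.0 - tanimoto(morgan_fingerprint("CCO"), morgan_fingerprint("CCC"))
    assert two.n_pairs == 1
    assert two.q25 == two.median == two.q75 == pytest.approx(d)
    with pytest.raises(ValueError):
        distance_distribution(["CCO"])


def test_distance_distribution_matches_brute_force():
    mols = ["CCO", "CCCC", "c1ccccc1", "CC(C)O"]
    spec = FingerprintSpec()
    fps = [morgan_fingerprint(s, spec) for s in mols]
    expected = []
    for i in range(4):
        for j in range(i + 1, 4):
            expected.append(1.0 - tanimoto(fps[i], fps[j]))
    summary = distance_distribution(mols, spec=spec)
    assert summary.n_pairs == 6
    assert sorted(summary.distances) == pytest.approx(sorted(expected))
    assert summary.q25 == pytest.approx(np.percentile(expected, 25))
    assert summary.median == pytest.approx(np.percentile(expected, 50))
    assert summary.q75 == pytest.approx(np.percentile(expected, 75))
    assert summary.mean == pytest.approx(np.mean(expected))
    iqr = summary.q75 - summary.q25
    assert summary.whisker_low == pytest.approx(summary.q25 - 1.5 * iqr)
    assert summary.whisker_high == pytest.approx(summary.q75 + 1.5 * iqr)


def test_distance_distribution_between_sets():
    a = ["CCO", "CCC"]
    b = ["c1ccccc1", "CCN", "CCCl"]
    summary = distance_distribution(a, b)
    assert summary.n_pairs == 6
    brute = [1.0 - tanimoto(morgan_fingerprint(x), morgan_fingerprint(y))
             for x in a for y in b]
    assert sorted(summary.distances) == pytest.approx(sorted(brute))


def test_duplicated_set_distances_replicate():
    """Doubling every record adds n zero self-copy pairs and replicates each
    original pair four times; the nonzero distance multiset scales exactly."""
    mols = ["CCO", "CCCC", "c1ccccc1"]
    base = distance_distribution(mols)
    doubled = distance_distribution(mols + mols)
    assert doubled.n_pairs == 15  # C(6,2)
    nonzero = sorted(d for d in doubled.distances if d > 0)
    assert nonzero == pytest.approx(sorted(list(base.distances) * 4))
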