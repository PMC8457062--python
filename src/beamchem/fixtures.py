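"""Synthetic inputs: small SMILES corpora and closed-form toy models.

Every other module is testable offline through these generators. The
chemistry is deliberately simple — linear chains, random acyclic trees over
C/N/O, and one benzene-scaffold family — so that enumeration oracles stay
exact and validity is guaranteed by construction. Realism is not a goal:
these corpora stand in for the large general-purpose and small
target-focused ligand collections a real study would use.

Toy models expose an explicit conditional-probability table with the same
decoding interface as a trained checkpoint, so exact sequence probabilities
are available in closed form for oracle tests of the decoders.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from rdkit import Chem

from beamchem.tokenizer import BEGIN, END, Vocabulary
from beamchem.sampling import ToyModel

FAMILIES = ("alkanes", "alcohols", "ethers", "amines", "aromatics", "mixed")

#: The shared scaffold of the narrow "aromatics" family (monosubstituted
#: benzene); fine-tuning-bias experiments rely on family membership being a
#: crisp structural predicate.
AROMATIC_SCAFFOLD = "c1ccccc1"

#: Five short, mutually distinct molecules for memorization-recovery
#: experiments: a model overfit on these should return exactly these five
#: strings at the top of a width-5 beam.
MEMORIZATION_SET = ("CCO", "CCC", "COC", "CCN", "CNC")

#: Five structurally diverse drug-like molecules (~43 tokens each) whose
#: opening tokens differ, so a memorizing model's mean per-token
#: cross-entropy can approach the corpus floor ln(5)/mean_length ~= 0.037
#: nats/token. Repetitive strings (e.g. long alkanes) are deliberately
#: avoided: their next token is only predictable by position counting, which
#: a small recurrent model learns far more slowly than context-driven
#: transitions.
DIVERSE_OVERFIT_SET = (
    "CC(C)Cc1ccc(cc1)C(C)C(=O)NCCOC(=O)c2ccccc2",
    "COc1cc(C=CC(=O)NCCCN(C)C)ccc1OCC(O)CNC(C)=O",
    "CCN(CC)C(=O)c1ccc(NC(=O)C(C)OC)cc1OC(F)(F)F",
    "OCC(O)C(O)C(O)C(O)COC(=O)c1ccncc1CNC(=O)CCl",
    "BrCC(=O)N1CCN(CC1)S(=O)(=O)c1ccc(CC(C)=O)cc1",
)


@dataclass(frozen=True)
class CorpusSpec:
    """Recipe for a deterministic synthetic SMILES corpus.

    ``family`` selects the structural family; enumerable families (alkanes,
    alcohols, ethers, amines, aromatics) are listed in a fixed enumeration
    order and ``seed`` is ignored for them; ``mixed`` draws random acyclic
    C/N/O trees (plus a sprinkling of aromatics) using ``seed``.
    """

    family: str = "mixed"
    size: int = 100
    max_heavy_atoms: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; one of {FAMILIES}")
        if self.size < 1:
            raise ValueError("size must be >= 1")
        if self.max_heavy_atoms < 1:
            raise ValueError("max_heavy_atoms must be >= 1")


def _enumerate_family(family: str, max_heavy: int) -> list[str]:
    if family == "alkanes":
        return ["C" * n for n in range(1, max_heavy + 1)]
    if family == "alcohols":
        return ["C" * n + "O" for n in range(1, max_heavy)]
    if family == "ethers":
        return ["C" * i + "O" + "C" * j
                for n in range(2, max_heavy)
                for i in range(1, n + 1)
                for j in [n + 1 - i] if j >= i]
    if family == "amines":
        return ["C" * n + "N" for n in range(1, max_heavy)]
    if family == "aromatics":
        out = []
        for m in range(1, max_heavy - 5):
            for head in ("", "O", "N"):
                if 6 + m + len(head) <= max_heavy:
                    out.append(head + "C" * m + AROMATIC_SCAFFOLD)
        return out
    raise ValueError(family)


_VALENCE = {"C": 4, "N": 3, "O": 2}


def _random_tree_molecule(rng: np.random.Generator, n_heavy: int) -> str:
    """A random acyclic molecule over C/N/O, valid by valence construction."""
    elements = ["C", "N", "O"]
    weights = np.array([0.7, 0.15, 0.15])
    mol = Chem.RWMol()
    symbols: list[str] = []
    degree: list[int] = []
    first = elements[int(rng.choice(3, p=weights))]
    mol.AddAtom(Chem.Atom(first))
    symbols.append(first)
    degree.append(0)
    for _ in range(n_heavy - 1):
        free = [i for i in range(len(symbols)) if degree[i] < _VALENCE[symbols[i]]]
        if not free:
            break
        parent = int(free[rng.integers(len(free))])
        sym = elements[int(rng.choice(3, p=weights))]
        idx = mol.AddAtom(Chem.Atom(sym))
        mol.AddBond(parent, idx, Chem.BondType.SINGLE)
        symbols.append(sym)
        degree.append(1)
        degree[parent] += 1
    return Chem.MolToSmiles(mol.GetMol())


def make_corpus(spec: CorpusSpec) -> list[str]:
    """Generate a deterministic corpus of valid, canonical, unique SMILES.

    Raises
    ------
    ValueError
        If the family cannot supply ``size`` unique molecules within
        ``max_heavy_atoms``; the message states the enumerable count.
    """
    if spec.family != "mixed":
        pool = _enumerate_family(spec.family, spec.max_heavy_atoms)
        # enumeration order is canonical output order; dedupe conservatively
        seen: set[str] = set()
        unique = []
        for s in pool:
            c = Chem.MolToSmiles(Chem.MolFromSmiles(s))
            if c not in seen:
                seen.add(c)
                unique.append(s)
        if spec.size > len(unique):
            raise ValueError(
                f"family {spec.family!r} with max_heavy_atoms="
                f"{spec.max_heavy_atoms} enumerates only {len(unique)} "
                f"molecules; {spec.size} requested")
        return unique[:spec.size]

    rng = np.random.default_rng(spec.seed)
    aromatic_pool = _enumerate_family("aromatics", max(spec.max_heavy_atoms, 9))
    seen = set()
    corpus: list[str] = []
    attempts = 0
    aromatic_ptr = 0
    max_attempts = 200 * spec.size
    while len(corpus) < spec.size and attempts < max_attempts:
        attempts += 1
        # every tenth molecule comes from the aromatic family (while it
        # lasts) so the vocabulary covers aromatic tokens and the baseline
        # model assigns them nonzero probability
        if len(corpus) % 10 == 9 and aromatic_ptr < len(aromatic_pool):
            cand = aromatic_pool[aromatic_ptr]
            aromatic_ptr += 1
        else:
            n_heavy = int(rng.integers(2, spec.max_heavy_atoms + 1))
            cand = _random_tree_molecule(rng, n_heavy)
        canon = Chem.MolToSmiles(Chem.MolFromSmiles(cand))
        if canon and canon not in seen:
            seen.add(canon)
            corpus.append(canon)
    if len(corpus) < spec.size:
        raise ValueError(
            f"could not generate {spec.size} unique mixed molecules within "
            f"{max_attempts} attempts ({len(corpus)} found)")
    return corpus


def is_aromatic_family(smiles: str) -> bool:
    """Membership predicate of the narrow fixture family: a valid molecule
    containing the benzene scaffold."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return False
    return mol.HasSubstructMatch(Chem.MolFromSmarts("c1ccccc1"))


# ---------------------------------------------------------------------------
# Toy probability models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyModelSpec:
    """Recipe for a closed-form toy token model.

    ``order`` is "iid" (one row shared by every context) or "markov"
    (first-order: one row per previous token, BEGIN included). ``table``
    maps token (or, for markov, context → token) to probability; the END
    token is named by the END sentinel. Rows must sum to 1.
    """

    tokens: tuple[str, ...]
    order: str = "iid"
    table: Mapping = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.order not in ("iid", "markov"):
            raise ValueError("order must be 'iid' or 'markov'")
        if not self.tokens:
            raise ValueError("need at least one chemical token")


def _row_vector(vocab: Vocabulary, row: Mapping[str, float]) -> np.ndarray:
    v = np.zeros(len(vocab))
    for tok, p in row.items():
        if p < 0:
            raise ValueError(f"negative probability for {tok!r}")
        v[vocab.index[tok]] = p
    s = v.sum()
    if s <= 0:
        raise ValueError("row is not normalizable (sums to 0)")
    if abs(s - 1.0) > 1e-9:
        raise ValueError(f"row sums to {s}, expected 1")
    return v


def make_toy_model(spec: ToyModelSpec) -> ToyModel:
    """Build a :class:`~beamchem.sampling.ToyModel` from an explicit table."""
    vocab = Vocabulary.from_chemical_tokens(spec.tokens)
    if spec.order == "iid":
        row = _row_vector(vocab, spec.table)
        table = {BEGIN: row}
    else:
        table = {}
        for ctx, row in spec.table.items():
            table[ctx] = _row_vector(vocab, row)
        if BEGIN not in table:
            raise ValueError("markov table must include a BEGIN context row")
        for tok in spec.tokens:
            if tok not in table:
                raise ValueError(f"markov table missing a row for context {tok!r}")
    return ToyModel(vocabulary=vocab, table=table)


def random_toy_model(
    n_tokens: int,
    order: str,
    seed: int,
    min_end_probability: float = 0.1,
) -> ToyModel:
    """A randomly parameterised toy model with END probability bounded below.

    The END floor keeps total terminating mass high so bounded-depth
    enumeration covers nearly all probability; useful for randomised oracle
    comparisons of the decoders.
    """
    rng = np.random.default_rng(seed)
    tokens = tuple("abde"[:n_tokens])
    contexts = (BEGIN,) + tokens if order == "markov" else (BEGIN,)
    table = {}
    for ctx in contexts:
        p_end = min_end_probability + (0.4 - min_end_probability) * rng.random()
        rest = rng.dirichlet(np.ones(n_tokens)) * (1.0 - p_end)
        row = {tok: float(p) for tok, p in zip(tokens, rest)}
        row[END] = float(p_end)
        table[ctx] = row
    spec = ToyModelSpec(
        tokens=tokens, order="markov" if order == "markov" else "iid",
        table=table if order == "markov" else table[BEGIN],
    )
    return make_toy_model(spec)
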