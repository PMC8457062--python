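"""Descriptor-based characterization of design libraries.

The descriptors used to judge whether generated molecules look like the
intended chemotype: Fsp3 (fraction of sp3-hybridised carbon atoms, a proxy
for natural-product-like three-dimensionality), Morgan circular fingerprints
with Tanimoto similarity/distance, nearest-known-active similarity, and
boxplot-style summaries of pairwise distance distributions.

Additional descriptor families (e.g. 3-D shape/electrostatics vectors) can
be plugged in through :class:`DescriptorSet` without changing the
distribution machinery.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product
from typing import Callable, Protocol, Sequence

import numpy as np
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator


@dataclass(frozen=True)
class FingerprintSpec:
    """Morgan fingerprint parameters: bond radius and bit-vector length."""

    radius: int = 2
    n_bits: int = 1024


class DescriptorSet(Protocol):
    """Plug-in interface for alternative per-molecule descriptor vectors.

    Any callable mapping a SMILES string to a 1-D numeric vector can serve;
    distance semantics are the caller's choice. The built-in implementation
    is the Morgan/Tanimoto pair; holistic 3-D shape-and-electrostatics
    descriptors are an example of what a user may plug in here.
    """

    def __call__(self, smiles: str) -> np.ndarray: ...


def _mol(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES: {smiles!r}")
    return mol


def fsp3(smiles: str) -> float:
    """Fraction of carbon atoms that are sp3-hybridised, in [0, 1].

    Computed on the sanitised molecular graph with implicit hydrogens:
    (number of sp3 carbons) / (total carbons). Carbon-free molecules have no
    defined value and raise.
    """
    mol = _mol(smiles)
    carbons = [a for a in mol.GetAtoms() if a.GetAtomicNum() == 6]
    if not carbons:
        raise ValueError(f"Fsp3 undefined for carbon-free molecule {smiles!r}")
    n_sp3 = sum(
        1 for a in carbons if a.GetHybridization() == Chem.HybridizationType.SP3
    )
    return n_sp3 / len(carbons)


def morgan_fingerprint(smiles: str, spec: FingerprintSpec = FingerprintSpec()):
    """Morgan circular fingerprint as an RDKit explicit bit vector."""
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=spec.radius, fpSize=spec.n_bits
    )
    return gen.GetFingerprint(_mol(smiles))


def tanimoto(a, b) -> float:
    """Tanimoto similarity |a∩b| / |a∪b| of two equal-length bit vectors.

    Two all-zero fingerprints are defined to have similarity 0 (the formula
    itself is 0/0 there).
    """
    if a.GetNumBits() != b.GetNumBits():
        raise ValueError(
            f"fingerprint length mismatch: {a.GetNumBits()} vs {b.GetNumBits()}")
    if a.GetNumOnBits() == 0 and b.GetNumOnBits() == 0:
        return 0.0
    return float(DataStructs.TanimotoSimilarity(a, b))


def nearest_reference_similarity(
    designs: Sequence[str],
    references: Sequence[str],
    spec: FingerprintSpec = FingerprintSpec(),
) -> list[tuple[float, str]]:
    """Per design, the max Tanimoto to any reference and the argmax reference.

    Used to report how close each design sits to the closest known active
    molecule of the target.
    """
    if not references:
        raise ValueError("reference set must be non-empty")
    ref_fps = [(r, morgan_fingerprint(r, spec)) for r in references]
    out: list[tuple[float, str]] = []
    for d in designs:
        fp = morgan_fingerprint(d, spec)
        best_sim, best_ref = -1.0, ref_fps[0][0]
        for r, rfp in ref_fps:
            s = tanimoto(fp, rfp)
            if s > best_sim:
                best_sim, best_ref = s, r
        out.append((best_sim, best_ref))
    return out


@dataclass(frozen=True)
class DistanceSummary:
    """Boxplot-style summary of a pairwise Tanimoto-distance distribution:
    quartiles, mean, and 1.5x-interquartile-range whisker bounds."""

    n_pairs: int
    q25: float
    median: float
    q75: float
    mean: float
    whisker_low: float
    whisker_high: float
    distances: tuple[float, ...]


def distance_distribution(
    set_a: Sequence[str],
    set_b: Sequence[str] | None = None,
    spec: FingerprintSpec = FingerprintSpec(),
) -> DistanceSummary:
    """Pairwise Tanimoto-distance (1 - similarity) distribution summary.

    Within-set mode (``set_b=None``) uses all unordered pairs of distinct
    records of ``set_a`` (duplicated entries still pair with each other —
    only a record paired with itself is excluded); between-set mode uses all
    cross pairs. Requires at least one pair.
    """
    fps_a = [morgan_fingerprint(s, spec) for s in set_a]
    if set_b is None:
        if len(set_a) < 2:
            raise ValueError("within-set distribution needs >= 2 molecules")
        pairs = [(fps_a[i], fps_a[j]) for i, j in combinations(range(len(fps_a)), 2)]
    else:
        if not set_a or not set_b:
            raise ValueError("both sets must be non-empty")
        fps_b = [morgan_fingerprint(s, spec) for s in set_b]
        pairs = list(product(fps_a, fps_b))
    d = np.array([1.0 - tanimoto(x, y) for x, y in pairs])
    q25, med, q75 = np.percentile(d, [25, 50, 75])
    iqr = q75 - q25
    return DistanceSummary(
        n_pairs=len(d),
        q25=float(q25),
        median=float(med),
        q75=float(q75),
        mean=float(d.mean()),
        whisker_low=float(q25 - 1.5 * iqr),
        whisker_high=float(q75 + 1.5 * iqr),
        distances=tuple(float(x) for x in d),
    )
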