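"""Molecular featurization: 300-dim fingerprints and 9 functional-group counts.

Two kinds of features feed the downstream models:

* a 300-component real fingerprint ``x`` used by the ranking SVM.  The
  default scheme ("default-hashed") sums hash-bucketed counts of each atom's
  radius-0 and radius-1 Morgan environment identifiers — the same
  sum-of-substructure-vectors shape as Mol2vec, but fully deterministic and
  self-contained.  An embedding-table scheme ("embedding-table:<path>")
  instead sums looked-up substructure embeddings (the Mol2vec pathway) when a
  table of identifier -> vector rows is supplied.

* a vector of nine functional-group counts (ester, alkyl carbon, hydroxyl,
  ether, benzene ring, amide, carbonate, heteroatom, urethane) used by the
  regression-tree factor analysis.

Counts are evaluated per repeat unit *with the chain closed*: when the SMILES
has exactly two attachment points, a head-to-tail macrocyclic dimer is built
and counts are halved, so that groups spanning the polymerization boundary
(e.g. the second ester of poly(ethylene terephthalate), the carbonate of
polycarbonate) are counted as a chemist would count them in the polymer.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from sklearn.base import BaseEstimator, TransformerMixin

from .data import Polymer, parse_smiles
from .errors import ConfigurationError, SmilesParseError

DEFAULT_DIM = 300
DEFAULT_SCHEME = "default-hashed"

#: Fixed feature order for the descriptor vector; also the tie-break order
#: for regression-tree splits.
DESCRIPTOR_NAMES = (
    "ester",
    "alkyl_carbon",
    "hydroxyl",
    "ether",
    "benzene_ring",
    "amide",
    "carbonate",
    "heteroatom",
    "urethane",
)


def _as_mol(item) -> Chem.Mol:
    if isinstance(item, Chem.Mol):
        return item
    if isinstance(item, Polymer):
        return item.mol()
    return parse_smiles(str(item))


# ---------------------------------------------------------------------------
# Fingerprints
# ---------------------------------------------------------------------------

def _morgan_identifiers(mol: Chem.Mol, radius: int):
    """Yield (identifier, count, is_wildcard_root) for Morgan environments.

    ``is_wildcard_root`` flags the radius-0 identifier of a ``*`` atom, which
    is routed to a reserved hash bucket so the polymerization point always
    contributes the same component.
    """
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius)
    extra = rdFingerprintGenerator.AdditionalOutput()
    extra.AllocateBitInfoMap()
    sfp = gen.GetSparseCountFingerprint(mol, additionalOutput=extra)
    bit_info = extra.GetBitInfoMap()
    for ident, count in sfp.GetNonzeroElements().items():
        envs = bit_info.get(ident, ())
        wildcard_root = any(
            rad == 0 and mol.GetAtomWithIdx(atom).GetAtomicNum() == 0
            for atom, rad in envs
        )
        yield ident, count, wildcard_root


def _stable_bucket(identifier: int, seed: int, n_buckets: int) -> int:
    digest = hashlib.blake2b(
        f"{seed}:{identifier}".encode(), digest_size=8
    ).digest()
    return int.from_bytes(digest, "big") % n_buckets


class HashedEnvironmentFingerprinter(TransformerMixin, BaseEstimator):
    """Deterministic hashed-substructure fingerprint (scheme "default-hashed").

    For each atom, its radius-0 and radius-1 Morgan environment identifiers
    are hash-bucketed into ``dim - 1`` components and their occurrence counts
    summed; the last component is reserved for the wildcard (``*``)
    attachment-point atom.  Stateless: ``fit`` is a no-op.
    """

    def __init__(self, dim: int = DEFAULT_DIM, radius: int = 1, hash_seed: int = 0):
        self.dim = dim
        self.radius = radius
        self.hash_seed = hash_seed

    @property
    def scheme_id(self) -> str:
        if (self.dim, self.radius, self.hash_seed) == (DEFAULT_DIM, 1, 0):
            return DEFAULT_SCHEME
        return f"hashed:dim={self.dim},radius={self.radius},seed={self.hash_seed}"

    def fit(self, X, y=None):
        return self

    def transform(self, X: Iterable) -> np.ndarray:
        rows = []
        for item in X:
            mol = _as_mol(item)
            vec = np.zeros(self.dim)
            for ident, count, wildcard in _morgan_identifiers(mol, self.radius):
                if wildcard:
                    bucket = self.dim - 1
                else:
                    bucket = _stable_bucket(ident, self.hash_seed, self.dim - 1)
                vec[bucket] += count
            rows.append(vec)
        return np.asarray(rows)


class EmbeddingTableFingerprinter(TransformerMixin, BaseEstimator):
    """Sum-of-substructure-embedding fingerprint (the Mol2vec pathway).

    ``table_path`` points at a whitespace/TSV file with one row per Morgan
    substructure identifier followed by its embedding components (word2vec
    text format; an optional one-line header of two integers is skipped).
    Unknown identifiers contribute the zero vector.
    """

    def __init__(self, table_path: str | Path, radius: int = 1):
        self.table_path = table_path
        self.radius = radius

    @property
    def scheme_id(self) -> str:
        return f"embedding-table:{self.table_path}"

    def _load(self) -> tuple[dict[int, np.ndarray], int]:
        path = Path(self.table_path)
        if not path.exists():
            raise ConfigurationError(f"embedding table not found: {path}")
        table: dict[int, np.ndarray] = {}
        dim = None
        with open(path) as fh:
            for line_no, line in enumerate(fh):
                parts = line.split()
                if not parts:
                    continue
                if line_no == 0 and len(parts) == 2:
                    continue  # word2vec-style header: <vocab> <dim>
                key = int(parts[0])
                vec = np.array([float(v) for v in parts[1:]])
                if dim is None:
                    dim = vec.size
                elif vec.size != dim:
                    raise ConfigurationError(
                        f"embedding table {path}: inconsistent dimension at line {line_no + 1}"
                    )
                table[key] = vec
        if not table:
            raise ConfigurationError(f"embedding table {path} is empty")
        return table, int(dim)

    def fit(self, X=None, y=None):
        self.table_, self.dim_ = self._load()
        return self

    def transform(self, X: Iterable) -> np.ndarray:
        if not hasattr(self, "table_"):
            self.fit()
        rows = []
        for item in X:
            mol = _as_mol(item)
            vec = np.zeros(self.dim_)
            for ident, count, _ in _morgan_identifiers(mol, self.radius):
                emb = self.table_.get(ident)
                if emb is not None:
                    vec += count * emb
            rows.append(vec)
        return np.asarray(rows)


def make_fingerprinter(scheme: str = DEFAULT_SCHEME, hash_seed: int = 0):
    """Instantiate the fingerprinter named by a scheme string."""
    if scheme == DEFAULT_SCHEME:
        return HashedEnvironmentFingerprinter(hash_seed=hash_seed)
    if scheme.startswith("embedding-table:"):
        return EmbeddingTableFingerprinter(scheme.split(":", 1)[1]).fit()
    raise ConfigurationError(f"unknown featurization scheme {scheme!r}")


def fingerprint(polymer, scheme: str = DEFAULT_SCHEME) -> np.ndarray:
    """Fingerprint one polymer/SMILES under ``scheme`` (300 components)."""
    return make_fingerprinter(scheme).transform([polymer])[0]


@dataclass(frozen=True)
class FingerprintSet:
    """Fingerprints for a set of polymers, tagged with their scheme."""

    scheme_id: str
    vectors: dict[str, np.ndarray]  # polymer id -> x

    def __getitem__(self, polymer_id: str) -> np.ndarray:
        return self.vectors[polymer_id]

    def __contains__(self, polymer_id: str) -> bool:
        return polymer_id in self.vectors


def fingerprint_polymers(polymers: Sequence[Polymer], fingerprinter) -> FingerprintSet:
    X = fingerprinter.transform(polymers)
    return FingerprintSet(
        scheme_id=fingerprinter.scheme_id,
        vectors={p.id: X[i] for i, p in enumerate(polymers)},
    )


# ---------------------------------------------------------------------------
# Functional-group descriptors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DescriptorVector:
    """Counts of the nine functional-group descriptors, per repeat unit."""

    ester: int
    alkyl_carbon: int
    hydroxyl: int
    ether: int
    benzene_ring: int
    amide: int
    carbonate: int
    heteroatom: int
    urethane: int

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in DESCRIPTOR_NAMES], dtype=int)

    def as_dict(self) -> dict[str, int]:
        return {n: getattr(self, n) for n in DESCRIPTOR_NAMES}


def _closed_dimer(mol: Chem.Mol) -> Chem.Mol | None:
    """Macrocyclic head-to-tail dimer of a 2-attachment-point repeat unit.

    Returns None when the closure cannot be built (not exactly two ``*``
    atoms, a multivalent wildcard, or a non-single attachment bond); callers
    then fall back to counting on the open unit.
    """
    stars = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() == 0]
    if len(stars) != 2:
        return None
    for idx in stars:
        atom = mol.GetAtomWithIdx(idx)
        if atom.GetDegree() != 1:
            return None
        if atom.GetBonds()[0].GetBondType() != Chem.BondType.SINGLE:
            return None
    n = mol.GetNumAtoms()
    combined = Chem.RWMol(Chem.CombineMols(mol, mol))
    ends = []  # (star_idx, neighbor_idx) per copy, head then tail
    for offset in (0, n):
        for idx in stars:
            star = combined.GetAtomWithIdx(idx + offset)
            ends.append((idx + offset, star.GetNeighbors()[0].GetIdx()))
    (s1h, n1h), (s1t, n1t), (s2h, n2h), (s2t, n2t) = ends
    for a, b in ((n1t, n2h), (n2t, n1h)):
        if combined.GetBondBetweenAtoms(a, b) is None and a != b:
            combined.AddBond(a, b, Chem.BondType.SINGLE)
    for star_idx in sorted((s1h, s1t, s2h, s2t), reverse=True):
        combined.RemoveAtom(star_idx)
    closed = combined.GetMol()
    try:
        Chem.SanitizeMol(closed)
    except Exception:
        return None
    return closed


def _count_on_mol(mol: Chem.Mol) -> dict[str, int]:
    counts = dict.fromkeys(DESCRIPTOR_NAMES, 0)
    carbonyl_oxygens: set[int] = set()  # single-bonded O in ester/carbonate/urethane
    for atom in mol.GetAtoms():
        z = atom.GetAtomicNum()
        if z == 6:
            if not atom.GetIsAromatic() and atom.GetHybridization() == Chem.HybridizationType.SP3:
                counts["alkyl_carbon"] += 1
            # carbonyl-centric classification of C(=O) groups
            double_o = [
                b.GetOtherAtom(atom)
                for b in atom.GetBonds()
                if b.GetBondType() == Chem.BondType.DOUBLE
                and b.GetOtherAtom(atom).GetAtomicNum() == 8
            ]
            if not double_o:
                continue
            single_o = [
                nb
                for nb in atom.GetNeighbors()
                if nb.GetAtomicNum() == 8 and nb.GetIdx() not in {o.GetIdx() for o in double_o}
            ]
            n_nbrs = [nb for nb in atom.GetNeighbors() if nb.GetAtomicNum() == 7]
            if len(single_o) >= 2:
                counts["carbonate"] += 1
                carbonyl_oxygens.update(o.GetIdx() for o in single_o)
            elif n_nbrs and single_o:
                counts["urethane"] += 1
                carbonyl_oxygens.update(o.GetIdx() for o in single_o)
            elif n_nbrs:
                counts["amide"] += 1
            elif single_o:
                # ester requires a carbon on the far side of the ester oxygen
                o = single_o[0]
                far = [
                    nb for nb in o.GetNeighbors()
                    if nb.GetIdx() != atom.GetIdx() and nb.GetAtomicNum() == 6
                ]
                if far:
                    counts["ester"] += 1
                    carbonyl_oxygens.add(o.GetIdx())
        elif z == 8:
            if atom.GetTotalNumHs() >= 1:
                counts["hydroxyl"] += 1
        if z not in (0, 1, 6):
            counts["heteroatom"] += 1
    # ethers: O with two carbon neighbors, not already claimed by an
    # ester/carbonate/urethane match and not a hydroxyl
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() != 8 or atom.GetIdx() in carbonyl_oxygens:
            continue
        if atom.GetTotalNumHs() >= 1:
            continue
        carbons = [nb for nb in atom.GetNeighbors() if nb.GetAtomicNum() == 6]
        if len(carbons) == 2:
            counts["ether"] += 1
    # benzene rings: six-membered all-carbon aromatic rings in the SSSR
    for ring in Chem.GetSymmSSSR(mol):
        atoms = [mol.GetAtomWithIdx(i) for i in ring]
        if len(atoms) == 6 and all(
            a.GetAtomicNum() == 6 and a.GetIsAromatic() for a in atoms
        ):
            counts["benzene_ring"] += 1
    return counts


def count_descriptors(polymer) -> DescriptorVector:
    """Count the nine functional-group descriptors of a repeat unit.

    With exactly two attachment points the repeat unit is closed into a
    macrocyclic dimer and counts are halved, so boundary-spanning groups are
    seen; otherwise the open structure is counted with ``*`` matching
    nothing.
    """
    mol = _as_mol(polymer)
    dimer = _closed_dimer(mol)
    if dimer is not None:
        raw = _count_on_mol(dimer)
        counts = {k: round(v / 2) for k, v in raw.items()}
    else:
        counts = _count_on_mol(mol)
    return DescriptorVector(**counts)


class FunctionalGroupCounter(TransformerMixin, BaseEstimator):
    """Transformer emitting the (n_polymers, 9) descriptor-count matrix."""

    def fit(self, X, y=None):
        return self

    def transform(self, X: Iterable) -> np.ndarray:
        return np.array([count_descriptors(item).as_array() for item in X])

    def get_feature_names_out(self, input_features=None):
        return np.array(DESCRIPTOR_NAMES)
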