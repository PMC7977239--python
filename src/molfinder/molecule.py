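"""Molecule substrate: validity, canonical SMILES, fingerprints, distances, scaffolds.

Every other module builds on the primitives here.  Molecular identity is
defined throughout the package as canonical-SMILES string equality, and the
engine's chemical distance between two molecules is one minus the Tanimoto
coefficient of their topological path fingerprints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from rdkit import Chem, RDLogger
from rdkit.Chem import DataStructs, MACCSkeys, rdFingerprintGenerator
from rdkit.Chem.Scaffolds import MurckoScaffold

from .errors import KindMismatch, ParseError

# RDKit is chatty about every rejected candidate; operator retry loops
# produce thousands of expected parse failures.
RDLogger.DisableLog("rdApp.*")

#: Fingerprint kinds understood by :func:`fingerprint`.
FP_RDKIT = "topological-path"
FP_MORGAN = "morgan-r2"
FP_MACCS = "maccs"

_NBITS = {FP_RDKIT: 2048, FP_MORGAN: 2048, FP_MACCS: 167}

_rdkit_gen = rdFingerprintGenerator.GetRDKitFPGenerator(fpSize=_NBITS[FP_RDKIT])
_morgan_gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=_NBITS[FP_MORGAN])


def mol_from_smiles(smiles: str) -> Chem.Mol:
    """Parse a SMILES string, raising :class:`ParseError` on failure."""
    if not isinstance(smiles, str) or not smiles:
        raise ParseError(f"not a SMILES string: {smiles!r}")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"invalid SMILES: {smiles!r}")
    return mol


def is_valid(smiles: str) -> bool:
    """True if the string parses (and sanitizes) as a molecule."""
    return bool(smiles) and Chem.MolFromSmiles(smiles) is not None


def canonicalize(smiles: str) -> str:
    """Return the unique canonical SMILES; idempotent on valid input."""
    return Chem.MolToSmiles(mol_from_smiles(smiles))


def safe_canonical(smiles: str) -> str | None:
    """Canonical SMILES, or ``None`` unless the canonical form re-parses.

    The toolkit occasionally writes a canonical string (typically for
    unusual fused aromatic systems) that its own parser then rejects;
    such molecules are unusable downstream and are treated as invalid.
    """
    mol = Chem.MolFromSmiles(smiles) if smiles else None
    if mol is None:
        return None
    canonical = Chem.MolToSmiles(mol)
    if Chem.MolFromSmiles(canonical) is None:
        return None
    return canonical


def heavy_atom_count(smiles: str) -> int:
    return mol_from_smiles(smiles).GetNumHeavyAtoms()


@dataclass(frozen=True)
class BitFingerprint:
    """A fixed-length binary fingerprint of a declared kind."""

    kind: str
    bits: DataStructs.ExplicitBitVect
    nbits: int

    def popcount(self) -> int:
        return self.bits.GetNumOnBits()


def fingerprint(mol_or_smiles, kind: str = FP_RDKIT) -> BitFingerprint:
    """Compute a fingerprint of the requested kind.

    ``topological-path``: RDKit path fingerprint, 2048 bits (engine distance).
    ``morgan-r2``: Morgan circular fingerprint, radius 2, 2048 bits
    (similarity-guided objective).  ``maccs``: 166 structural keys
    (diversity analysis).
    """
    mol = mol_or_smiles if isinstance(mol_or_smiles, Chem.Mol) else mol_from_smiles(mol_or_smiles)
    if kind == FP_RDKIT:
        bits = _rdkit_gen.GetFingerprint(mol)
    elif kind == FP_MORGAN:
        bits = _morgan_gen.GetFingerprint(mol)
    elif kind == FP_MACCS:
        bits = MACCSkeys.GenMACCSKeys(mol)
    else:
        raise ValueError(f"unknown fingerprint kind: {kind!r}")
    return BitFingerprint(kind=kind, bits=bits, nbits=bits.GetNumBits())


def tanimoto(a: BitFingerprint, b: BitFingerprint) -> float:
    """Tanimoto coefficient |a∩b| / |a∪b| between two same-kind fingerprints.

    Two all-zero fingerprints are defined as identical (similarity 1) so
    that a molecule is always at distance zero from itself; an empty versus
    a non-empty set has similarity 0.
    """
    if a.kind != b.kind:
        raise KindMismatch(f"cannot compare {a.kind!r} with {b.kind!r}")
    if a.popcount() == 0 or b.popcount() == 0:
        return 1.0 if a.popcount() == b.popcount() else 0.0
    return DataStructs.TanimotoSimilarity(a.bits, b.bits)


def distance(a: "MoleculeRecord", b: "MoleculeRecord") -> float:
    """Engine distance 1 − Tanimoto on topological path fingerprints."""
    return 1.0 - tanimoto(a.fingerprint(FP_RDKIT), b.fingerprint(FP_RDKIT))


def murcko_scaffold(smiles: str) -> str:
    """Canonical SMILES of the Bemis–Murcko framework.

    Ring systems plus the linkers between them, with side chains stripped.
    Acyclic molecules have no framework and yield the empty string.
    """
    mol = mol_from_smiles(smiles)
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    if scaffold is None or scaffold.GetNumAtoms() == 0:
        return ""
    return Chem.MolToSmiles(scaffold)


@dataclass
class MoleculeRecord:
    """A validated, scored molecule as stored in the bank.

    ``breakdown`` holds the individual property scores the objective was
    assembled from (``qed``, ``sa`` and, for the similarity objective,
    ``sim``), so the objective value is always recomputable.
    """

    canonical_smiles: str
    objective_value: float = float("-inf")
    breakdown: dict = field(default_factory=dict)
    fp_cache: dict = field(default_factory=dict, repr=False, compare=False)
    generation_born: int = 0

    def mol(self) -> Chem.Mol:
        return mol_from_smiles(self.canonical_smiles)

    def fingerprint(self, kind: str = FP_RDKIT) -> BitFingerprint:
        fp = self.fp_cache.get(kind)
        if fp is None:
            fp = fingerprint(self.canonical_smiles, kind)
            self.fp_cache[kind] = fp
        return fp
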