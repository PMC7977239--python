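"""Seed-molecule fixtures: an embedded drug list and a random seed generator.

The engine needs a pool of at least ``n_bank`` unique drug-like molecules
to initialize its bank.  Two sources are provided, neither requiring a
download:

* :data:`druglike_smiles` — ~200 named, public-domain drug structures,
  used as realistic inputs for operator validity measurements;
* :func:`generate_seeds` — a deterministic random generator that grafts
  drug-like fragments (ring systems, linkers, substituents) into novel
  molecules of a requested size and ring count, emulating a random sample
  of a purchasable screening library.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from ._druglike import DRUGLIKE_SMILES
from .errors import GenerationStall
from .molecule import canonicalize, safe_canonical

#: Ring systems common in oral drugs (aromatic heterocycles, saturated
#: amines/ethers, fused bicyclics).
RING_FRAGMENTS = (
    "c1ccccc1",          # benzene
    "c1ccncc1",          # pyridine
    "c1cncnc1",          # pyrimidine
    "c1ccc2ccccc2c1",    # naphthalene
    "c1ccc2ncccc2c1",    # quinoline
    "c1cc[nH]n1",        # pyrazole
    "c1cnc[nH]1",        # imidazole
    "c1cscn1",           # thiazole
    "c1ccsc1",           # thiophene
    "c1ccoc1",           # furan
    "c1cnoc1",           # isoxazole
    "c1cn[nH]n1",        # triazole
    "c1ccc2[nH]ccc2c1",  # indole
    "c1ccc2[nH]cnc2c1",  # benzimidazole
    "C1CCNCC1",          # piperidine
    "C1CNCCN1",          # piperazine
    "C1COCCN1",          # morpholine
    "C1CCNC1",           # pyrrolidine
    "C1CCOC1",           # tetrahydrofuran
    "C1CCOCC1",          # tetrahydropyran
    "C1CCCCC1",          # cyclohexane
    "C1CCCC1",           # cyclopentane
    "C1CC1",             # cyclopropane
)

#: Acyclic connectors grafted between ring systems.
LINKER_FRAGMENTS = (
    "C", "CC", "CCC", "CO", "OC", "CN", "NC", "CNC", "COC",
    "C=O", "CC=O", "NC=O", "CNC=O", "CS", "C(F)F",
)

#: Terminal substituents.
CAP_FRAGMENTS = (
    "C", "CC", "C(C)C", "O", "OC", "N", "NC", "N(C)C", "F", "Cl", "Br",
    "C#N", "C(F)(F)F", "C(=O)O", "C(=O)N", "C(=O)C", "S(=O)(=O)C", "CO",
)


def druglike_smiles(canonical: bool = True) -> list[str]:
    """The embedded drug-like fixture set (canonical SMILES by default)."""
    if canonical:
        return [canonicalize(s) for _, s in DRUGLIKE_SMILES]
    return [s for _, s in DRUGLIKE_SMILES]


def druglike_named() -> list[tuple[str, str]]:
    """(name, SMILES) pairs of the embedded fixture set."""
    return list(DRUGLIKE_SMILES)


@dataclass
class FixtureSpec:
    """Parameters of the random seed generator."""

    n_molecules: int = 1000
    heavy_atom_range: tuple[int, int] = (15, 35)
    ring_count_range: tuple[int, int] = (1, 4)
    #: relative frequency of single-atom substituent elements
    element_weights: dict[str, float] = field(
        default_factory=lambda: {"C": 0.45, "N": 0.20, "O": 0.20, "F": 0.06, "Cl": 0.05, "S": 0.04}
    )
    rng_seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.element_weights.values())
        if not np.isclose(total, 1.0):
            self.element_weights = {k: v / total for k, v in self.element_weights.items()}
        if self.heavy_atom_range[0] > self.heavy_atom_range[1]:
            raise ValueError("empty heavy_atom_range")
        if self.ring_count_range[0] > self.ring_count_range[1]:
            raise ValueError("empty ring_count_range")


def _free_valence_atoms(mol: Chem.Mol) -> list[int]:
    return [a.GetIdx() for a in mol.GetAtoms() if a.GetTotalNumHs() >= 1]


def _graft(core: Chem.Mol, frag: Chem.Mol, rng: np.random.Generator) -> Chem.Mol | None:
    """Join two fragments by a single bond between random open-valence atoms."""
    sites_core = _free_valence_atoms(core)
    sites_frag = _free_valence_atoms(frag)
    if not sites_core or not sites_frag:
        return None
    combined = Chem.RWMol(Chem.CombineMols(core, frag))
    i = int(rng.choice(sites_core))
    j = core.GetNumAtoms() + int(rng.choice(sites_frag))
    combined.AddBond(i, j, Chem.BondType.SINGLE)
    try:
        Chem.SanitizeMol(combined)
    except Exception:
        return None
    return combined.GetMol()


def _assemble_one(spec: FixtureSpec, rng: np.random.Generator) -> str | None:
    lo, hi = spec.heavy_atom_range
    n_rings = int(rng.integers(spec.ring_count_range[0], spec.ring_count_range[1] + 1))
    mol = Chem.MolFromSmiles(RING_FRAGMENTS[int(rng.integers(0, len(RING_FRAGMENTS)))])
    for _ in range(n_rings - 1):
        ring = Chem.MolFromSmiles(RING_FRAGMENTS[int(rng.integers(0, len(RING_FRAGMENTS)))])
        if rng.random() < 0.6:
            linker = Chem.MolFromSmiles(
                LINKER_FRAGMENTS[int(rng.integers(0, len(LINKER_FRAGMENTS)))]
            )
            grown = _graft(ring, linker, rng)
            ring = grown if grown is not None else ring
        joined = _graft(mol, ring, rng)
        if joined is None:
            return None
        mol = joined
    elements = list(spec.element_weights)
    weights = np.array([spec.element_weights[e] for e in elements])
    while mol.GetNumHeavyAtoms() < lo or (
        mol.GetNumHeavyAtoms() < hi and rng.random() < 0.5
    ):
        if rng.random() < 0.5:
            cap = CAP_FRAGMENTS[int(rng.integers(0, len(CAP_FRAGMENTS)))]
        else:
            cap = str(rng.choice(elements, p=weights))
        frag = Chem.MolFromSmiles(cap)
        if frag is None:
            continue
        if mol.GetNumHeavyAtoms() + frag.GetNumHeavyAtoms() > hi:
            break
        grown = _graft(mol, frag, rng)
        if grown is None:
            break
        mol = grown
    n = mol.GetNumHeavyAtoms()
    if not lo <= n <= hi:
        return None
    return safe_canonical(Chem.MolToSmiles(mol))


def generate_seeds(spec: FixtureSpec) -> list[str]:
    """Generate ``spec.n_molecules`` unique, valid, canonical seed SMILES.

    Deterministic under ``spec.rng_seed``.  Raises
    :class:`~molfinder.errors.GenerationStall` if uniqueness cannot be
    reached within a bounded number of assembly attempts.
    """
    rng = np.random.default_rng(spec.rng_seed)
    seen: set[str] = set()
    out: list[str] = []
    max_attempts = 200 * spec.n_molecules + 1000
    attempts = 0
    while len(out) < spec.n_molecules:
        attempts += 1
        if attempts > max_attempts:
            raise GenerationStall(
                f"only {len(out)}/{spec.n_molecules} unique molecules "
                f"after {attempts} attempts"
            )
        smi = _assemble_one(spec, rng)
        if smi is None or smi in seen:
            continue
        seen.add(smi)
        out.append(smi)
    return out
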